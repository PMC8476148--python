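# Human-like isolation-with-migration model for `jointdfe build-cache`
# and as a starting point for `fit-demo`.
id: IM
s_frac: 0.8     # fraction of the ancestral population founding pop 1
nu1: 2.5        # final size of pop 1 (units of the ancestral size)
nu2: 3.0        # final size of pop 2
T: 0.15         # divergence time (units of 2*Na generations)
m12: 1.0        # population-scaled migration into pop 1
m21: 0.8        # population-scaled migration into pop 2
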