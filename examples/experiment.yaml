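# Precision experiment spec for `jointdfe simulate`.
# Truth: lognormal mixture joint DFE under the default IM demography.
mu: 3.6
sigma: 5.1
w: 0.9
theta_ns: 13842.5
n1: 20
n2: 20
replicates: 10
grid_points: 25
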