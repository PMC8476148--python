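# jointdfe

Inference of the **joint distribution of fitness effects (DFE)** between
two diverged populations from their joint allele frequency spectrum
(AFS), for population geneticists asking whether a mutation that is
deleterious in one population is equally deleterious in the other —
across environments (out-of-Africa humans, European *Drosophila*) or
across sister species (wild tomatoes).

A mutation carries population-scaled selection coefficients
`γ₁ = 2·N_a·s₁` in the ancestral/first population and `γ₂` in the
second. The joint DFE `G(γ₁, γ₂)` is modeled as a mixture

    G_mix = w·G_1d + (1 − w)·G_2d,      0 ≤ w ≤ 1,

of a perfectly correlated component (`γ₁ = γ₂`, drawn from a shared
lognormal or gamma marginal) and an independent component with the same
marginal, so the **DFE correlation equals the mixture weight `w`** — the
statistic this package estimates. The expected selected spectrum is

    E[S_ij] = θ_sel · ∬ F_ij(γ₁, γ₂ | Θ_demo) · G(γ₁, γ₂) dγ₁ dγ₂,

where `F` is the expected joint AFS under the fitted two-population
demography, computed by a finite-volume diffusion solver and cached on a
log-spaced grid of selection-coefficient pairs (2,500 spectra for the
50-point production grid). Entries of the observed spectrum are treated
as independent Poisson counts (a Poisson Random Field), giving a
composite likelihood that is maximized over the DFE parameters with
`θ_sel` fixed at a known multiple of the neutral rate; parameter
uncertainty uses the Godambe (sandwich) information with genomic-block
bootstraps, and `w` is tested against perfect correlation (`w = 1`) by
two-tailed z-tests with Benjamini–Hochberg FDR control.

Functionality: expected joint spectra under equilibrium, split,
isolation-with-migration (IM, IM_pre) histories with selection and
dominance; lognormal-mixture, gamma-mixture and bivariate-lognormal
joint DFEs; selection caches; hypergeometric projection and
ancestral-misidentification handling; demographic and DFE composite-
likelihood fits; Godambe standard errors; a discrete Wright–Fisher
oracle; and a simulation harness for precision/robustness studies.
See `docs/methods.md` for the model and numerics, and `examples/` for
runnable walkthroughs of each capability.

## Worked example

```python
from jointdfe import (SampleConfig, ThetaConfig, LognormalMixtureDFE,
                      build_cache, build_gamma_grid, expected_selected_afs,
                      fit_dfe, poisson_sample_afs, FitOptions)
from jointdfe.simulate import DEFAULT_TRUTH_DEMO

truth = LognormalMixtureDFE(mu=3.6, sigma=5.1, w=0.9)
theta = ThetaConfig.from_theta_sel(13842.5)          # nonsynonymous theta
cache = build_cache(DEFAULT_TRUTH_DEMO, SampleConfig(20, 20),
                    build_gamma_grid(25))            # 625 cached spectra
data = poisson_sample_afs(expected_selected_afs(cache, truth, theta), seed=42)
fit = fit_dfe(data, cache, LognormalMixtureDFE(3.0, 4.0, 0.7), theta,
              FitOptions(starts=2, seed=0), fit_misid=False)
print({k: round(v, 3) for k, v in fit.params.items()})
```

prints (about 30 s, dominated by the cache build):

```
{'mu': 3.529, 'sigma': 5.001, 'w': 0.906}
```

The simulated exome carried ~27,600 segregating nonsynonymous sites
generated under `w = 0.9`; the fit recovers the marginal DFE
(`μ̂ = 3.53`, `σ̂ = 5.00` on the log-`γ` scale against a truth of 3.6 and
5.1) and the DFE correlation `ŵ = 0.906` — i.e. roughly 90% of new
mutations are estimated to have identical fitness effects in the two
populations. `examples/uncertainty_and_significance.py` continues this
analysis with Godambe standard errors and z-tests against `w = 1`.

A thin CLI mirrors the library for shell pipelines
(`jointdfe build-cache | fit-demo | fit-dfe | godambe | simulate |
project | misid-apply`); spectra are read and written in the dadi text
dialect.

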