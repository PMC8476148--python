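"""Robustness of the DFE correlation to model misspecification.

Fits a lognormal mixture (assuming additivity, h = 0.5) to noise-free
expected data generated with recessive mutations (h = 0.25) - the
marginal parameters mu and sigma absorb the bias while w stays accurate,
the pattern that makes w a reliable statistic.
Runtime: ~1 min (two selection caches).
"""

from jointdfe import (
    FitOptions,
    LognormalMixtureDFE,
    SampleConfig,
    ThetaConfig,
    build_cache,
    build_gamma_grid,
    expected_selected_afs,
    fit_dfe,
)
from jointdfe.simulate import DEFAULT_TRUTH_DEMO

sample = SampleConfig(20, 20)
grid = build_gamma_grid(25)
theta = ThetaConfig.from_theta_sel(13842.5)

cache_truth = build_cache(DEFAULT_TRUTH_DEMO, sample, grid, h=0.25)
cache_fit = build_cache(DEFAULT_TRUTH_DEMO, sample, grid, h=0.5)

print(f"{'w truth':>8} {'w hat':>8} {'mu hat':>8} {'sigma hat':>10}")
for w in (0.8, 0.9, 1.0):
    truth = LognormalMixtureDFE(3.6, 5.1, w)
    data = expected_selected_afs(cache_truth, truth, theta)
    res = fit_dfe(data, cache_fit, LognormalMixtureDFE(3.0, 4.0, 0.7),
                  theta, FitOptions(starts=2), fit_misid=False)
    print(f"{w:8.2f} {res.params['w']:8.3f} {res.params['mu']:8.3f} "
          f"{res.params['sigma']:10.3f}")
print("\nmu and sigma are biased away from (3.6, 5.1) by the wrong "
      "dominance assumption, but w tracks its truth within ~0.01-0.05.")
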