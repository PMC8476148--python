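"""Synthetic data generation and batch precision/robustness experiments.

The generator mirrors the study design used to validate joint-DFE
inference: expected joint spectra are computed under a known ("truth")
demographic model and joint DFE, observed data are drawn by independent
Poisson sampling of each unmasked AFS entry, and the full inference
pipeline (optional demographic fit, selection cache, DFE fit) is re-run
on each replicate.  Robustness scenarios fit deliberately misspecified
models to noise-free expected data, so any deviation of the estimates
from the truth is bias, not sampling noise.

Default study conditions
------------------------
* truth demography: human-like isolation-with-migration (IM) model with
  exponential growth and asymmetric migration;
* truth DFE: symmetric lognormal mixture with mu = 3.6, sigma = 5.1;
* nonsynonymous mutation rate theta_NS = 13842.5;
* sample sizes 20 + 20 chromosomes and a 25-point gamma grid, a
  scaled-down configuration that preserves the qualitative regime of the
  full-scale design (216/198 samples, 50-point grid) at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cache import SelectionCache, build_cache, build_gamma_grid
from .demography import DemographicModel, SelectionRegime
from .dfe import BivariateLognormalDFE, GammaMixtureDFE, LognormalMixtureDFE
from .diffusion import DEFAULT_ENGINE, EngineConfig, expected_joint_afs
from .inference import FitOptions, FitResult, fit_demography, fit_dfe, fitted_model
from .integrate_dfe import MisidParam, ThetaConfig, expected_selected_afs, misid_transform
from .spectrum import JointSpectrum, SampleConfig

#: human-like IM truth used throughout the simulation studies
DEFAULT_TRUTH_DEMO = DemographicModel(
    "IM", s_frac=0.8, nu1=2.5, nu2=3.0, T=0.15, m12=1.0, m21=0.8)

#: symmetric lognormal-mixture truth marginal
DEFAULT_TRUTH_DFE = LognormalMixtureDFE(mu=3.6, sigma=5.1, w=0.9)

#: nonsynonymous population-scaled mutation rate of the precision study
DEFAULT_THETA_NS = 13842.5

#: scaled-down defaults: 25-point cache, 20+20 chromosomes
DEFAULT_GRID_POINTS = 25
DEFAULT_SAMPLE = SampleConfig(20, 20)
FULL_SCALE_SAMPLE = SampleConfig(216, 198)
FULL_SCALE_GRID_POINTS = 50


def poisson_sample_afs(expected: JointSpectrum, seed: int) -> JointSpectrum:
    """Observed spectrum: independent Poisson draws per unmasked entry."""
    vals = expected.values
    if np.any(vals[~expected.mask] < 0) or np.any(~np.isfinite(vals[~expected.mask])):
        raise ValueError("expected spectrum must be finite and nonnegative")
    rng = np.random.default_rng(seed)
    draw = rng.poisson(np.where(expected.mask, 0.0, vals)).astype(float)
    out = expected.copy(values=draw, kind="observed")
    out.meta["seed"] = seed
    return out


@dataclass
class ExperimentSpec:
    """Configuration of one simulation experiment.

    The ``fit_*`` templates may deliberately differ from the truth to
    probe robustness; ``None`` means "fit the truth family/model".
    """

    truth_demo: DemographicModel = DEFAULT_TRUTH_DEMO
    truth_dfe: object = DEFAULT_TRUTH_DFE
    h_truth: float = 0.5
    sample: SampleConfig = DEFAULT_SAMPLE
    theta: ThetaConfig = field(
        default_factory=lambda: ThetaConfig.from_theta_sel(DEFAULT_THETA_NS))
    misid_truth: float = 0.0
    replicates: int = 10
    seed: int = 0
    grid_points: int = DEFAULT_GRID_POINTS
    gamma_bounds: tuple = (1e-4, 2000.0)
    fit_demo_template: DemographicModel | None = None
    fit_dfe_template: object = None
    refit_demography: bool = False
    engine: EngineConfig = DEFAULT_ENGINE
    fit_options: FitOptions = field(default_factory=lambda: FitOptions(starts=2))

    def replicate_seeds(self) -> list[int]:
        """Deterministic per-replicate seeds derived from the base seed."""
        ss = np.random.SeedSequence(self.seed)
        return [int(s) for s in
                ss.generate_state(max(self.replicates, 1)) >> 1]


def _truth_cache(spec: ExperimentSpec) -> SelectionCache:
    grid = build_gamma_grid(spec.grid_points, spec.gamma_bounds)
    return build_cache(spec.truth_demo, spec.sample, grid, h=spec.h_truth,
                       config=spec.engine)


def expected_selected_truth(spec: ExperimentSpec,
                            cache: SelectionCache | None = None
                            ) -> JointSpectrum:
    """Noise-free expected selected AFS under the truth of ``spec``."""
    cache = cache or _truth_cache(spec)
    F = expected_selected_afs(cache, spec.truth_dfe, spec.theta)
    if spec.misid_truth:
        F = misid_transform(F, spec.misid_truth)
    return F


def run_precision_experiment(spec: ExperimentSpec,
                             progress: bool = False) -> pd.DataFrame:
    """Per-replicate DFE estimates from Poisson-sampled data.

    Pipeline per replicate: expected AFS under the truth -> Poisson
    sample -> (optional) demographic refit on neutral data -> selection
    cache -> DFE fit.  Returns one row per replicate with the parameter
    estimates; failures are recorded, not fatal.
    """
    truth_cache = _truth_cache(spec)
    expected_sel = expected_selected_truth(spec, truth_cache)

    fit_template = spec.fit_dfe_template or spec.truth_dfe
    fit_demo = spec.fit_demo_template
    if spec.refit_demography and fit_demo is None:
        fit_demo = spec.truth_demo
    neutral_expected = None
    if spec.refit_demography:
        neutral_expected = truth_cache.neutral * spec.theta.theta_neu

    rows = []
    for r, rseed in enumerate(spec.replicate_seeds()):
        row = {"replicate": r, "seed": rseed}
        try:
            data = poisson_sample_afs(expected_sel, rseed)
            theta = spec.theta
            cache = truth_cache
            if spec.refit_demography:
                ndata = poisson_sample_afs(neutral_expected, rseed + 1)
                dres = fit_demography(ndata, fit_demo,
                                      replace(spec.fit_options, seed=rseed),
                                      engine=spec.engine,
                                      fit_misid=spec.misid_truth > 0)
                demo_hat = fitted_model(dres, fit_demo)
                grid = build_gamma_grid(spec.grid_points, spec.gamma_bounds)
                cache = build_cache(demo_hat, spec.sample, grid,
                                    config=spec.engine)
                theta = ThetaConfig(dres.params["theta_neu"], spec.theta.ratio_NS)
            res = fit_dfe(data, cache, fit_template, theta,
                          replace(spec.fit_options, seed=rseed),
                          fit_misid=spec.misid_truth > 0)
            row.update({k: v for k, v in res.params.items()})
            row["loglik"] = res.loglik
            row["converged"] = res.converged
        except Exception as exc:  # per-replicate failures are logged
            row["error"] = f"{type(exc).__name__}: {exc}"
            row["converged"] = False
        rows.append(row)
        if progress:
            print(f"replicate {r}: "
                  + ", ".join(f"{k}={v:.4g}" for k, v in row.items()
                              if isinstance(v, float)), flush=True)
    return pd.DataFrame(rows)


def summarize_precision(table: pd.DataFrame, truth: dict) -> pd.DataFrame:
    """Median and spread of each estimated parameter vs its truth."""
    rows = []
    ok = table[table.get("converged", True) == True]  # noqa: E712
    for name, true_val in truth.items():
        if name not in ok:
            continue
        est = ok[name].astype(float)
        rows.append({
            "param": name, "truth": true_val,
            "median": est.median(), "mean": est.mean(),
            "sd": est.std(ddof=1) if len(est) > 1 else 0.0,
            "n": len(est),
        })
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Robustness suite: noise-free data, deliberately misspecified fits
# ----------------------------------------------------------------------

def _fit_noise_free(spec: ExperimentSpec, fit_cache: SelectionCache,
                    theta: ThetaConfig, truth_cache: SelectionCache | None = None
                    ) -> FitResult:
    expected = expected_selected_truth(spec, truth_cache)
    template = spec.fit_dfe_template or LognormalMixtureDFE(3.0, 4.0, 0.7)
    return fit_dfe(expected, fit_cache, template, theta,
                   spec.fit_options, fit_misid=False)


def run_robustness_suite(specs: dict[str, ExperimentSpec],
                         progress: bool = False) -> pd.DataFrame:
    """Bias table: one row per scenario, with (truth, estimate) pairs.

    Each scenario fits a (possibly misspecified) lognormal mixture to the
    noise-free expected AFS under its truth.  Caches under the truth
    conditions (for data generation) and under the fitted conditions
    (h = 0.5, fitted or misspecified demography) are built per scenario
    and shared across its correlation sweep where possible.
    """
    rows = []
    cache_pool: dict[tuple, SelectionCache] = {}

    def get_cache(demo, sample, gp, gb, h, engine):
        key = (demo, sample.n1, sample.n2, gp, gb, h)
        if key not in cache_pool:
            grid = build_gamma_grid(gp, gb)
            cache_pool[key] = build_cache(demo, sample, grid, h=h,
                                          config=engine)
        return cache_pool[key]

    for name, spec in specs.items():
        if progress:
            print(f"scenario {name}", flush=True)
        truth_cache = get_cache(spec.truth_demo, spec.sample,
                                spec.grid_points, spec.gamma_bounds,
                                spec.h_truth, spec.engine)
        fit_demo = spec.fit_demo_template or spec.truth_demo
        theta = spec.theta
        if spec.fit_demo_template is not None:
            # misspecified demography: fit it to the noise-free neutral AFS
            ndata = truth_cache.neutral * spec.theta.theta_neu
            dres = fit_demography(ndata, fit_demo, spec.fit_options,
                                  engine=spec.engine, fit_misid=False)
            fit_demo = fitted_model(dres, fit_demo)
            theta = ThetaConfig(dres.params["theta_neu"], spec.theta.ratio_NS)
        fit_cache = get_cache(fit_demo, spec.sample, spec.grid_points,
                              spec.gamma_bounds, 0.5, spec.engine)
        res = _fit_noise_free(spec, fit_cache, theta, truth_cache)
        truth_corr = spec.truth_dfe.correlation()
        row = {"scenario": name,
               "w_truth": truth_corr,
               "w_hat": res.params.get("w", np.nan),
               "mu_hat": res.params.get("mu", np.nan),
               "sigma_hat": res.params.get("sigma", np.nan),
               "loglik": res.loglik,
               "converged": res.converged}
        if isinstance(spec.truth_dfe, LognormalMixtureDFE):
            row["mu_truth"] = spec.truth_dfe.mu
            row["sigma_truth"] = spec.truth_dfe.sigma
        rows.append(row)
        if progress:
            print(f"  w_truth={truth_corr:.3f} w_hat={row['w_hat']:.3f}",
                  flush=True)
    return pd.DataFrame(rows)


def dominance_scenarios(w_values=(0.8, 0.9, 1.0), h_values=(0.25, 0.75),
                        **kw) -> dict[str, ExperimentSpec]:
    """Truth simulated with dominant/recessive mutations, fit assuming h=0.5."""
    return {
        f"h={h}_w={w}": ExperimentSpec(
            truth_dfe=DEFAULT_TRUTH_DFE.with_params(w=w), h_truth=h, **kw)
        for h in h_values for w in w_values
    }


def gamma_truth_scenarios(w_values=(0.8, 0.9, 1.0), alpha=0.4, beta=1400.0,
                          **kw) -> dict[str, ExperimentSpec]:
    """Truth mixture with gamma marginals, fit with the lognormal mixture."""
    return {
        f"gamma_w={w}": ExperimentSpec(
            truth_dfe=GammaMixtureDFE(alpha=alpha, beta=beta, w=w), **kw)
        for w in w_values
    }


def bivariate_truth_scenarios(rho_values=(0.8, 0.9), asymmetric=False,
                              **kw) -> dict[str, ExperimentSpec]:
    """Truth bivariate lognormal (log-scale correlation rho), mixture fit."""
    if asymmetric:
        base = dict(mu1=3.6, sigma1=5.1, mu2=4.5, sigma2=6.8)
        tag = "asym"
    else:
        base = dict(mu1=3.6, sigma1=5.1, mu2=3.6, sigma2=5.1)
        tag = "sym"
    return {
        f"bivariate_{tag}_rho={r}": ExperimentSpec(
            truth_dfe=BivariateLognormalDFE(rho=r, **base), **kw)
        for r in rho_values
    }


def misspecified_demography_scenarios(w_values=(0.8, 0.9, 1.0),
                                      fit_model: str = "split_no_mig",
                                      **kw) -> dict[str, ExperimentSpec]:
    """IM truth with growth + asymmetric migration, simpler model fit."""
    if fit_model == "split_no_mig":
        template = DemographicModel("split_no_mig", nu1=2.0, nu2=2.0, T=0.1)
    elif fit_model == "split_mig_sym":
        template = DemographicModel("split_mig", nu1=2.0, nu2=2.0, T=0.1,
                                    m12=0.5, m21=0.5)
    else:
        raise ValueError(f"unknown misspecification {fit_model!r}")
    return {
        f"misdemo_{fit_model}_w={w}": ExperimentSpec(
            truth_dfe=DEFAULT_TRUTH_DFE.with_params(w=w),
            fit_demo_template=template, **kw)
        for w in w_values
    }
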