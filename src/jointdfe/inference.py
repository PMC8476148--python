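"""Composite-likelihood inference for demography and the joint DFE.

Entries of the joint AFS are modeled as independent Poisson variables
(a Poisson Random Field), giving the composite log-likelihood

    l = sum over unmasked (i,j) of  -lam_ij + S_ij log lam_ij - log S_ij!

Fitting is staged, as the cost of the selection cache dictates: the
demographic model is fit to the neutral (synonymous) spectrum with the
neutral mutation rate profiled analytically, then held fixed while the
DFE parameters are fit to the selected (nonsynonymous) spectrum with
``theta_sel`` fixed at a multiple of the fitted ``theta_neu``.

Because the composite likelihood ignores linkage, parameter uncertainty
uses the Godambe (sandwich) information from genomic-block bootstrap
spectra rather than the naive Fisher information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .cache import SelectionCache
from .demography import MODEL_PARAMS, PARAM_BOUNDS, DemographicModel, SelectionRegime
from .diffusion import DEFAULT_ENGINE, EngineConfig, expected_joint_afs
from .integrate_dfe import MisidParam, ThetaConfig, expected_selected_afs, misid_transform
from .spectrum import JointSpectrum, SpectrumError


class FitError(RuntimeError):
    pass


# ----------------------------------------------------------------------
# Poisson composite likelihood
# ----------------------------------------------------------------------

def poisson_loglik(model: JointSpectrum, data: JointSpectrum) -> float:
    """Poisson Random Field composite log-likelihood of ``data`` under ``model``."""
    if model.shape != data.shape:
        raise SpectrumError("model and data spectra have different shapes")
    mask = model.mask | data.mask
    lam = model.values[~mask]
    S = data.values[~mask]
    out = 0.0
    zero = lam <= 0
    if np.any(zero & (S > 0)):
        warnings.warn("model assigns zero expectation to observed entries; "
                      "log-likelihood is -inf", RuntimeWarning, stacklevel=2)
        return -np.inf
    ok = ~zero
    out = np.sum(-lam[ok] + S[ok] * np.log(lam[ok]) - gammaln(S[ok] + 1.0))
    return float(out)


# ----------------------------------------------------------------------
# Parameter transforms (unconstrained optimization space)
# ----------------------------------------------------------------------

_EPS = 1e-8


def _to_unconstrained(value: float, bounds: tuple[float, float]) -> float:
    lo, hi = bounds
    v = np.clip(value, lo + _EPS * max(1.0, abs(lo)), hi - _EPS * max(1.0, abs(hi)))
    if lo == 0.0 and hi == 1.0:
        return float(np.log(v / (1.0 - v)))          # logit
    if lo > 0 or (lo == 0.0 and not np.isfinite(hi)):
        return float(np.log(max(v, 1e-12)))          # log for positives
    if lo == 0.0:                                    # [0, hi] with hi finite
        frac = np.clip(v / hi, _EPS, 1 - _EPS)
        return float(np.log(frac / (1.0 - frac)))
    return float(v)


def _from_unconstrained(t: float, bounds: tuple[float, float]) -> float:
    lo, hi = bounds
    if lo == 0.0 and hi == 1.0:
        return float(1.0 / (1.0 + np.exp(-t)))
    if lo > 0 or (lo == 0.0 and not np.isfinite(hi)):
        return float(np.exp(t))
    if lo == 0.0:
        return float(hi / (1.0 + np.exp(-t)))
    return float(t)


def _jacobian(t: float, bounds: tuple[float, float]) -> float:
    """d(natural)/d(transformed) at transformed value t."""
    lo, hi = bounds
    if lo == 0.0 and hi == 1.0:
        s = 1.0 / (1.0 + np.exp(-t))
        return s * (1.0 - s)
    if lo > 0 or (lo == 0.0 and not np.isfinite(hi)):
        return np.exp(t)
    if lo == 0.0:
        s = 1.0 / (1.0 + np.exp(-t))
        return hi * s * (1.0 - s)
    return 1.0


#: optimization bounds for DFE and nuisance parameters (natural scale)
DFE_PARAM_BOUNDS = {
    "mu": (-10.0, 15.0),
    "sigma": (1e-2, 50.0),
    "w": (0.0, 1.0),
    "alpha": (1e-3, 10.0),
    "beta": (1e-2, 1e6),
    "mu1": (-10.0, 15.0),
    "sigma1": (1e-2, 50.0),
    "mu2": (-10.0, 15.0),
    "sigma2": (1e-2, 50.0),
    "rho": (0.0, 1.0),
    "p_misid": (0.0, 1.0),
}


@dataclass
class FitOptions:
    starts: int = 5
    perturb: float = 0.5        # sd of the perturbation in transformed space
    seed: int = 0
    maxiter: int = 400
    ftol: float = 1e-10
    # finite-difference step for the optimizer's gradient; must exceed the
    # solver's own discretization noise (the implicit step count changes
    # discretely with the parameters)
    grad_eps: float = 1e-6
    verbose: bool = False


@dataclass
class FitResult:
    params: dict
    loglik: float
    converged: bool
    starts: int
    seed: int
    diagnostics: dict = field(default_factory=dict)
    # private: loglik(params_dict, data, theta_scale) used for Godambe
    _loglik_fn: object = None

    def __post_init__(self) -> None:
        if self.converged and not np.isfinite(self.loglik):
            raise FitError("converged fit with non-finite log-likelihood")


def _optimize(objective, names, bounds, start_values, options: FitOptions):
    """Multi-start bounded local search in transformed parameter space."""
    rng = np.random.default_rng(options.seed)
    t0 = np.array([_to_unconstrained(start_values[k], bounds[k]) for k in names])
    best = None
    n_ok = 0
    for s in range(options.starts):
        t_start = t0 if s == 0 else t0 + rng.normal(0.0, options.perturb, t0.size)
        res = minimize(objective, t_start, method="L-BFGS-B",
                       options={"maxiter": options.maxiter,
                                "ftol": options.ftol,
                                "eps": options.grad_eps})
        if options.verbose:
            print(f"  start {s}: nll={res.fun:.6f} nit={res.nit}")
        if np.isfinite(res.fun):
            n_ok += 1
            if best is None or res.fun < best.fun - 1e-12 or (
                    abs(res.fun - best.fun) <= 1e-12
                    and tuple(res.x) < tuple(best.x)):
                # tie-break: lexicographically smallest transformed vector
                best = res
    if best is None:
        raise FitError("all optimization starts failed")
    return best, n_ok


# ----------------------------------------------------------------------
# Demographic fits
# ----------------------------------------------------------------------

def fit_demography(neutral_data: JointSpectrum, model: DemographicModel,
                   options: FitOptions | None = None,
                   engine: EngineConfig = DEFAULT_ENGINE,
                   fit_misid: bool = True,
                   fixed: dict | None = None) -> FitResult:
    """Maximum composite-likelihood demographic parameters.

    ``model`` provides the model id and the starting values of its free
    parameters.  ``theta_neu`` is profiled in closed form
    (``theta_hat = sum(data) / sum(model at theta=1)``); the neutral
    misidentification probability is a free parameter unless
    ``fit_misid=False``.  Reproducible given ``options.seed``.
    """
    options = options or FitOptions()
    fixed = dict(fixed or {})
    names = [p for p in MODEL_PARAMS[model.id] if p not in fixed]
    if fit_misid:
        names = names + ["p_misid"]
    bounds = {**PARAM_BOUNDS, "p_misid": (0.0, 1.0)}
    start = {p: getattr(model, p) for p in MODEL_PARAMS[model.id]}
    start["p_misid"] = 0.02
    mask = neutral_data.mask
    S_tot = neutral_data.total()

    def loglik_params(pdict: dict, data: JointSpectrum,
                      theta_scale: float = 1.0) -> float:
        demo = model.with_params(
            **{k: v for k, v in pdict.items() if k != "p_misid"}, **fixed)
        F = expected_joint_afs(demo, SelectionRegime(0.0, 0.0, 0.5),
                               neutral_data.sample, engine)
        F = misid_transform(F, pdict.get("p_misid", 0.0))
        denom = F.values[~mask].sum()
        theta_hat = data.values[~data.mask].sum() / denom
        return poisson_loglik(F * theta_hat, data), theta_hat

    cache_theta = {}

    def objective(t):
        pdict = {k: _from_unconstrained(tv, bounds[k]) for k, tv in zip(names, t)}
        try:
            ll, theta_hat = loglik_params(pdict, neutral_data)
        except Exception:
            return 1e12
        cache_theta["last"] = theta_hat
        return -ll if np.isfinite(ll) else 1e12

    best, n_ok = _optimize(objective, names, bounds, start, options)
    pdict = {k: _from_unconstrained(tv, bounds[k]) for k, tv in zip(names, best.x)}
    ll, theta_hat = loglik_params(pdict, neutral_data)
    result = FitResult(
        params={**{p: getattr(model, p) for p in MODEL_PARAMS[model.id]
                   if p in fixed}, **pdict, "theta_neu": theta_hat},
        loglik=ll, converged=bool(best.success and n_ok > 0),
        starts=options.starts, seed=options.seed,
        diagnostics={"n_successful_starts": n_ok, "model": model.id,
                     "optimizer": {"nit": int(best.nit),
                                   "message": str(best.message)},
                     "segregating_sites": S_tot},
    )
    result._loglik_fn = lambda pd, data, theta_scale=1.0: loglik_params(
        pd, data)[0]
    return result


def fitted_model(result: FitResult, template: DemographicModel
                 ) -> DemographicModel:
    """Build the DemographicModel from a demographic FitResult."""
    kw = {k: v for k, v in result.params.items()
          if k in MODEL_PARAMS[template.id]}
    return template.with_params(**kw)


# ----------------------------------------------------------------------
# DFE fits
# ----------------------------------------------------------------------

def fit_dfe(selected_data: JointSpectrum, cache: SelectionCache,
            dfe_template, theta: ThetaConfig,
            options: FitOptions | None = None,
            fit_misid: bool = True,
            fixed: dict | None = None) -> FitResult:
    """Maximum composite-likelihood joint-DFE parameters.

    The cache must have been built under the fitted demographic model;
    ``theta_sel`` is fixed through ``theta`` (never optimized).  The
    mixture weight ``w`` (or ``rho``) is constrained to its unit
    interval; boundary-pinned estimates are flagged in diagnostics.
    """
    options = options or FitOptions()
    fixed = dict(fixed or {})
    if selected_data.shape != cache.sample.shape:
        raise FitError("data sample sizes do not match the cache")
    names = [p for p in dfe_template.param_names if p not in fixed]
    if fit_misid:
        names = names + ["p_misid"]
    start = {p: getattr(dfe_template, p) for p in dfe_template.param_names}
    start["p_misid"] = 0.02

    def loglik_params(pdict: dict, data: JointSpectrum,
                      theta_scale: float = 1.0) -> float:
        dfe = dfe_template.with_params(
            **{k: v for k, v in pdict.items() if k != "p_misid"}, **fixed)
        th = ThetaConfig(theta_neu=theta.theta_neu * theta_scale,
                         ratio_NS=theta.ratio_NS)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model = expected_selected_afs(cache, dfe, th,
                                          pdict.get("p_misid", 0.0))
            return poisson_loglik(model, data)

    def objective(t):
        pdict = {k: _from_unconstrained(tv, DFE_PARAM_BOUNDS[k])
                 for k, tv in zip(names, t)}
        try:
            ll = loglik_params(pdict, selected_data)
        except Exception:
            return 1e12
        return -ll if np.isfinite(ll) else 1e12

    best, n_ok = _optimize(objective, names, DFE_PARAM_BOUNDS, start, options)
    pdict = {k: _from_unconstrained(tv, DFE_PARAM_BOUNDS[k])
             for k, tv in zip(names, best.x)}
    pinned = [k for k in names if k in ("w", "rho", "p_misid")
              and (pdict[k] < 1e-4 or pdict[k] > 1.0 - 1e-4)]
    result = FitResult(
        params={**{p: getattr(dfe_template, p) for p in fixed}, **pdict},
        loglik=loglik_params(pdict, selected_data),
        converged=bool(n_ok > 0), starts=options.starts, seed=options.seed,
        diagnostics={"n_successful_starts": n_ok,
                     "family": type(dfe_template).__name__,
                     "boundary_pinned": pinned,
                     "theta_sel": theta.theta_sel},
    )
    result._loglik_fn = loglik_params
    return result


# ----------------------------------------------------------------------
# Godambe (sandwich) uncertainty
# ----------------------------------------------------------------------

@dataclass
class BootstrapSet:
    """Bootstrap spectra (e.g. per-genomic-chunk resamples).

    ``theta_scale`` for each replicate defaults to the ratio of its
    number of segregating sites to the data's.
    """

    spectra: list
    theta_scale: np.ndarray | None = None

    def scales(self, data: JointSpectrum) -> np.ndarray:
        if self.theta_scale is not None:
            s = np.asarray(self.theta_scale, dtype=float)
        else:
            s = np.array([b.total() / data.total() for b in self.spectra])
        if np.any(s <= 0):
            raise FitError("bootstrap theta scales must be > 0")
        return s


def _fd_grad(f, t0, steps):
    g = np.zeros_like(t0)
    for k in range(t0.size):
        tp, tm = t0.copy(), t0.copy()
        tp[k] += steps[k]
        tm[k] -= steps[k]
        g[k] = (f(tp) - f(tm)) / (2.0 * steps[k])
    return g


def _fd_hess(f, t0, steps):
    n = t0.size
    H = np.zeros((n, n))
    f0 = f(t0)
    for k in range(n):
        for l in range(k, n):
            tpp, tpm, tmp, tmm = (t0.copy() for _ in range(4))
            tpp[[k, l]] += [steps[k], steps[l]]
            tmm[[k, l]] -= [steps[k], steps[l]]
            tpm[k] += steps[k]
            tpm[l] -= steps[l]
            tmp[k] -= steps[k]
            tmp[l] += steps[l]
            if k == l:
                tp, tm = t0.copy(), t0.copy()
                tp[k] += steps[k]
                tm[k] -= steps[k]
                H[k, k] = (f(tp) - 2.0 * f0 + f(tm)) / steps[k] ** 2
            else:
                H[k, l] = H[l, k] = (f(tpp) - f(tpm) - f(tmp) + f(tmm)) / (
                    4.0 * steps[k] * steps[l])
    return H


def godambe_se(fit: FitResult, data: JointSpectrum, boots: BootstrapSet,
               step: float = 1e-2, param_bounds: dict | None = None,
               cross_check: bool = True) -> dict:
    """Godambe-information standard errors for a converged fit.

    The sandwich variance ``H^-1 J H^-1`` is evaluated at the MLE in the
    transformed parameter space: ``H`` is the central-finite-difference
    Hessian of the composite log-likelihood on the original data and
    ``J`` the empirical covariance of bootstrap score vectors, each
    bootstrap's ``theta_sel`` scaled by its segregating-sites ratio.
    SEs are mapped to the natural scale with the transform Jacobian.
    """
    if fit._loglik_fn is None:
        raise FitError("fit carries no likelihood function handle")
    if not fit.converged:
        raise FitError("Godambe uncertainty requires a converged fit")
    bounds = param_bounds or DFE_PARAM_BOUNDS
    names = [k for k in fit.params if k in bounds]
    t_mle = np.array([_to_unconstrained(fit.params[k], bounds[k])
                      for k in names])
    scales = boots.scales(data)
    if len(boots.spectra) < 20:
        warnings.warn("fewer than 20 bootstrap spectra; Godambe variance "
                      "may be unstable", RuntimeWarning, stacklevel=2)

    def ll(t, d, sc=1.0):
        pdict = {k: _from_unconstrained(tv, bounds[k])
                 for k, tv in zip(names, t)}
        pdict.update({k: v for k, v in fit.params.items() if k not in names})
        return fit._loglik_fn(pdict, d, sc)

    def ses_for(stepsize):
        steps = np.maximum(np.abs(t_mle) * stepsize, stepsize)
        H = -_fd_hess(lambda t: ll(t, data), t_mle, steps)
        scores = np.array([
            _fd_grad(lambda t, b=b, s=s: ll(t, b, s), t_mle, steps)
            for b, s in zip(boots.spectra, scales)])
        J = np.cov(scores.T, bias=False)
        J = np.atleast_2d(J)
        try:
            Hinv = np.linalg.inv(H)
        except np.linalg.LinAlgError as exc:
            raise FitError("singular Hessian in Godambe computation") from exc
        cov_t = Hinv @ J @ Hinv
        jac = np.array([_jacobian(tv, bounds[k])
                        for k, tv in zip(names, t_mle)])
        var = np.clip(np.diag(cov_t), 0.0, None) * jac ** 2
        return np.sqrt(var), H, J

    ses, H, J = ses_for(step)
    result = {
        "params": names,
        "se": dict(zip(names, ses)),
        "se_1.96": {k: 1.96 * v for k, v in zip(names, ses)},
        "step": step,
        "degenerate": bool(np.allclose(J, 0.0)),
    }
    if result["degenerate"]:
        warnings.warn("zero score variance across bootstraps (identical "
                      "spectra?); SEs are zero", RuntimeWarning, stacklevel=2)
    if cross_check:
        ses2, _, _ = ses_for(step / 10.0)
        result["se_crosscheck"] = dict(zip(names, ses2))
        with np.errstate(divide="ignore", invalid="ignore"):
            shift = np.nanmax(np.abs(ses2 / np.where(ses == 0, np.nan, ses) - 1.0))
        if np.isfinite(shift) and shift > 0.2:
            warnings.warn(f"Godambe SEs shift by {shift:.0%} between step "
                          f"sizes {step} and {step / 10}; treat with caution",
                          RuntimeWarning, stacklevel=2)
        result["step_sensitivity"] = float(shift) if np.isfinite(shift) else 0.0
    return result


# ----------------------------------------------------------------------
# Significance and theta partitioning utilities
# ----------------------------------------------------------------------

def w_significance(estimates: list[tuple[float, float]]) -> dict:
    """Two-tailed z-tests of each (w_hat, SE) against w = 1, with BH-FDR.

    The family for the FDR adjustment is exactly the list passed in.
    """
    w_hat = np.array([e[0] for e in estimates], dtype=float)
    se = np.array([e[1] for e in estimates], dtype=float)
    if np.any(se <= 0):
        raise FitError("standard errors must be > 0 for z-tests")
    z = (w_hat - 1.0) / se
    p = 2.0 * norm.sf(np.abs(z))
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return {"z": z, "p": p, "p_fdr": p_adj}


@dataclass(frozen=True)
class MutationClassTable:
    """Per-mutation-type rates and SIFT-class site counts (12 types)."""

    u: np.ndarray   # mutation rate per type
    d: np.ndarray   # deleterious-class counts per type
    t: np.ndarray   # tolerated-class counts per type

    def __post_init__(self) -> None:
        for name in ("u", "d", "t"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        if not (self.u.shape == self.d.shape == self.t.shape):
            raise FitError("u, d, t must have identical shapes")
        if np.any(self.u <= 0):
            raise FitError("mutation rates must be > 0")
        if np.any(self.d < 0) or np.any(self.t < 0):
            raise FitError("counts must be >= 0")
        if np.all(self.d + self.t == 0):
            raise FitError("all-zero counts")


def partition_theta(theta_NS: float, table: MutationClassTable
                    ) -> tuple[float, float]:
    """Split theta_NS between deleterious and tolerated mutation classes.

    Rate-weighted proportions
    ``p_del = sum_i u_i d_i / sum_i u_i (d_i + t_i)`` (and analogously
    for tolerated), which sum to one by construction.
    """
    denom = np.sum(table.u * (table.d + table.t))
    p_del = np.sum(table.u * table.d) / denom
    p_tol = np.sum(table.u * table.t) / denom
    return theta_NS * p_del, theta_NS * p_tol
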