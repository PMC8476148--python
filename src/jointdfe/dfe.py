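"""Parametric joint distributions of fitness effects (DFEs).

A joint DFE is a probability distribution over pairs of population-scaled
selection coefficients ``(gamma1, gamma2)``, restricted here to the
deleterious quadrant (both negative).  Densities are parameterized by the
*magnitude* ``g = -gamma > 0``.

Three families are provided:

``LognormalMixtureDFE`` / ``GammaMixtureDFE``
    A mixture of a perfectly correlated component (``gamma1 = gamma2``,
    drawn from the marginal) with weight ``w`` and an independent
    component (independent draws from the same marginal) with weight
    ``1 - w``.  Because both components share the marginal, the
    correlation of the mixture equals ``w``, which is the "DFE
    correlation" statistic this package infers.

``BivariateLognormalDFE``
    ``(log g1, log g2)`` bivariate normal with means ``mu1, mu2``,
    standard deviations ``sigma1, sigma2`` and correlation ``rho``.
    ``rho`` is the correlation on the log scale; the correlation of the
    raw (lognormal-scale) coefficients differs from ``rho``, and this
    package always reports ``rho`` itself.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats


class DFEError(ValueError):
    """Invalid DFE parameters or out-of-domain evaluation."""


def _check_gamma_negative(gamma) -> np.ndarray:
    g = np.asarray(gamma, dtype=float)
    if np.any(g >= 0):
        raise DFEError("DFE densities are defined for gamma < 0 only")
    return -g


@dataclass(frozen=True)
class LognormalMixtureDFE:
    """Lognormal marginal: log(-gamma) ~ Normal(mu, sigma^2); weight w on
    the perfectly correlated component."""

    mu: float
    sigma: float
    w: float

    #: parameter names in canonical optimization order
    param_names = ("mu", "sigma", "w")

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise DFEError("sigma must be > 0")
        if not 0.0 <= self.w <= 1.0:
            raise DFEError("mixture weight w must be in [0, 1]")

    def _marginal(self):
        return stats.lognorm(s=self.sigma, scale=np.exp(self.mu))

    def marginal_pdf(self, gamma) -> np.ndarray:
        """Marginal density at gamma < 0 (per unit gamma)."""
        return self._marginal().pdf(_check_gamma_negative(gamma))

    def marginal_cdf_mag(self, g) -> np.ndarray:
        """P(|gamma| <= g)."""
        return self._marginal().cdf(np.asarray(g, dtype=float))

    def sample_pairs(self, n: int, rng) -> np.ndarray:
        """n pairs (gamma1, gamma2): correlated with prob w, else independent."""
        if n < 1:
            raise DFEError("n must be >= 1")
        corr = rng.random(n) < self.w
        g1 = self._marginal().rvs(size=n, random_state=rng)
        g2 = np.where(corr, g1, self._marginal().rvs(size=n, random_state=rng))
        return np.column_stack([-g1, -g2])

    def correlation(self) -> float:
        """The DFE correlation: for the mixture this is exactly w."""
        return self.w

    def with_params(self, **kw) -> "LognormalMixtureDFE":
        return replace(self, **kw)


@dataclass(frozen=True)
class GammaMixtureDFE:
    """Gamma marginal on |gamma| (shape alpha, scale beta); weight w on
    the perfectly correlated component."""

    alpha: float
    beta: float
    w: float

    param_names = ("alpha", "beta", "w")

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise DFEError("alpha and beta must be > 0")
        if not 0.0 <= self.w <= 1.0:
            raise DFEError("mixture weight w must be in [0, 1]")

    def _marginal(self):
        return stats.gamma(a=self.alpha, scale=self.beta)

    def marginal_pdf(self, gamma) -> np.ndarray:
        return self._marginal().pdf(_check_gamma_negative(gamma))

    def marginal_cdf_mag(self, g) -> np.ndarray:
        return self._marginal().cdf(np.asarray(g, dtype=float))

    def sample_pairs(self, n: int, rng) -> np.ndarray:
        if n < 1:
            raise DFEError("n must be >= 1")
        corr = rng.random(n) < self.w
        g1 = self._marginal().rvs(size=n, random_state=rng)
        g2 = np.where(corr, g1, self._marginal().rvs(size=n, random_state=rng))
        return np.column_stack([-g1, -g2])

    def correlation(self) -> float:
        return self.w

    def with_params(self, **kw) -> "GammaMixtureDFE":
        return replace(self, **kw)


@dataclass(frozen=True)
class BivariateLognormalDFE:
    """Bivariate lognormal over (|gamma1|, |gamma2|), log-scale correlation rho."""

    mu1: float
    sigma1: float
    mu2: float
    sigma2: float
    rho: float

    param_names = ("mu1", "sigma1", "mu2", "sigma2", "rho")

    def __post_init__(self) -> None:
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise DFEError("sigma1 and sigma2 must be > 0")
        if not -1.0 < self.rho < 1.0:
            raise DFEError("rho must be in (-1, 1)")

    def marginal_pdf(self, gamma, pop: int = 1) -> np.ndarray:
        mu, sig = (self.mu1, self.sigma1) if pop == 1 else (self.mu2, self.sigma2)
        return stats.lognorm(s=sig, scale=np.exp(mu)).pdf(_check_gamma_negative(gamma))

    def marginal_cdf_mag(self, g, pop: int = 1) -> np.ndarray:
        mu, sig = (self.mu1, self.sigma1) if pop == 1 else (self.mu2, self.sigma2)
        return stats.lognorm(s=sig, scale=np.exp(mu)).cdf(np.asarray(g, dtype=float))

    def joint_pdf(self, gamma1, gamma2) -> np.ndarray:
        """Joint density at (gamma1, gamma2), both < 0 (per unit gamma^2)."""
        g1 = _check_gamma_negative(gamma1)
        g2 = _check_gamma_negative(gamma2)
        z1 = (np.log(g1) - self.mu1) / self.sigma1
        z2 = (np.log(g2) - self.mu2) / self.sigma2
        r = self.rho
        norm = 1.0 / (2.0 * np.pi * self.sigma1 * self.sigma2
                      * g1 * g2 * np.sqrt(1.0 - r * r))
        expo = -(z1 * z1 - 2.0 * r * z1 * z2 + z2 * z2) / (2.0 * (1.0 - r * r))
        return norm * np.exp(expo)

    def rect_prob_mag(self, g1_lo, g1_hi, g2_lo, g2_hi) -> float:
        """P(g1_lo < |gamma1| <= g1_hi, g2_lo < |gamma2| <= g2_hi)."""
        mvn = stats.multivariate_normal(
            mean=[self.mu1, self.mu2],
            cov=[[self.sigma1 ** 2, self.rho * self.sigma1 * self.sigma2],
                 [self.rho * self.sigma1 * self.sigma2, self.sigma2 ** 2]])

        def Gc(a, b):
            if a <= 0 or b <= 0:
                return 0.0
            la = np.log(a) if np.isfinite(a) else np.inf
            lb = np.log(b) if np.isfinite(b) else np.inf
            return float(mvn.cdf([la, lb]))

        return max(Gc(g1_hi, g2_hi) - Gc(g1_lo, g2_hi) - Gc(g1_hi, g2_lo)
                   + Gc(g1_lo, g2_lo), 0.0)

    def sample_pairs(self, n: int, rng) -> np.ndarray:
        if n < 1:
            raise DFEError("n must be >= 1")
        cov = [[self.sigma1 ** 2, self.rho * self.sigma1 * self.sigma2],
               [self.rho * self.sigma1 * self.sigma2, self.sigma2 ** 2]]
        logs = rng.multivariate_normal([self.mu1, self.mu2], cov, size=n)
        return -np.exp(logs)

    def correlation(self) -> float:
        """Reported correlation: rho on the log scale (not the raw scale)."""
        return self.rho

    def with_params(self, **kw) -> "BivariateLognormalDFE":
        return replace(self, **kw)


DFEModel = LognormalMixtureDFE | GammaMixtureDFE | BivariateLognormalDFE

_FAMILIES = {
    "lognormal_mixture": LognormalMixtureDFE,
    "gamma_mixture": GammaMixtureDFE,
    "bivariate_lognormal": BivariateLognormalDFE,
}


def make_dfe(family: str, **params) -> DFEModel:
    """Construct a DFE model by family name (see ``_FAMILIES`` keys)."""
    try:
        cls = _FAMILIES[family]
    except KeyError:
        raise DFEError(f"unknown DFE family {family!r}; "
                       f"choose from {sorted(_FAMILIES)}") from None
    return cls(**params)


# module-level convenience wrappers matching the operation names used
# throughout the docs

def marginal_pdf(dfe: DFEModel, gamma) -> np.ndarray:
    return dfe.marginal_pdf(gamma)


def joint_pdf(dfe: BivariateLognormalDFE, gamma1, gamma2) -> np.ndarray:
    if not isinstance(dfe, BivariateLognormalDFE):
        raise DFEError("joint_pdf is defined for the bivariate lognormal; "
                       "mixture models have a singular diagonal component")
    return dfe.joint_pdf(gamma1, gamma2)


def sample_pairs(dfe: DFEModel, n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return dfe.sample_pairs(n, rng)


def dfe_correlation(dfe: DFEModel) -> float:
    return dfe.correlation()
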