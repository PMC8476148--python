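"""Discrete Wright--Fisher oracle for expected joint spectra.

An independent check on the diffusion engine: expected per-frequency
variant counts are propagated through explicit Wright--Fisher binomial
transition kernels on the full joint frequency state space, with mutation
influx at ``theta = 1``, then binomially downsampled to the requested
sample sizes.  Population-scaled parameters (gamma, T, M, nu) are
preserved under the rescaling to the simulation size ``N_sim``, so the
result converges to the diffusion solution as ``N_sim`` grows.

Within a generation both populations experience deterministic selection
and migration based on the *same* pre-drift joint state, then drift
independently; the update is therefore a joint (outer-product) kernel
over the state space, costing roughly ``(2N)^4`` per generation.  Only
small ``N_sim`` are tractable; a state-space guard enforces this.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.special import gammaln
from scipy.stats import binom

from .demography import DemographicModel, SelectionRegime
from .spectrum import JointSpectrum, SampleConfig

_MAX_STATES = 1 << 20  # refuse joint state spaces beyond ~1M entries


class OracleError(RuntimeError):
    pass


def _post_selection_freq(x, s: float, h: float):
    """Deterministic frequency change from viability selection.

    Genotype fitnesses 1, 1+2hs, 1+2s (ancestral hom / het / derived hom).
    """
    w2, w1 = 1.0 + 2.0 * s, 1.0 + 2.0 * h * s
    num = x * x * w2 + x * (1.0 - x) * w1
    den = x * x * w2 + 2.0 * x * (1.0 - x) * w1 + (1.0 - x) * (1.0 - x)
    return num / den


@njit(cache=True)
def _binom_window(n: int, p: float, lg: np.ndarray, row: np.ndarray):
    """Binomial pmf restricted to an ~8-sigma window; returns (kmin, kmax)."""
    if p <= 0.0:
        row[0] = 1.0
        return 0, 0
    if p >= 1.0:
        row[0] = 1.0
        return n, n
    sd = np.sqrt(n * p * (1.0 - p))
    kmin = max(0, int(n * p - 8.0 * sd - 2.0))
    kmax = min(n, int(n * p + 8.0 * sd + 3.0))
    lp, lq = np.log(p), np.log1p(-p)
    for k in range(kmin, kmax + 1):
        row[k - kmin] = np.exp(lg[n] - lg[k] - lg[n - k] + k * lp
                               + (n - k) * lq)
    return kmin, kmax


@njit(cache=True)
def _wf_generation(e, p1, p2, n1new, n2new, lg, cutoff):
    """Joint drift update: out[k1,k2] = sum_ij B(k1|p1_ij) B(k2|p2_ij) e_ij."""
    A, B = e.shape
    out = np.zeros((n1new + 1, n2new + 1))
    row1 = np.empty(n1new + 1)
    row2 = np.empty(n2new + 1)
    for i in range(A):
        for j in range(B):
            w = e[i, j]
            if w <= cutoff:
                continue
            k1min, k1max = _binom_window(n1new, p1[i, j], lg, row1)
            k2min, k2max = _binom_window(n2new, p2[i, j], lg, row2)
            for k1 in range(k1min, k1max + 1):
                r = row1[k1 - k1min] * w
                for k2 in range(k2min, k2max + 1):
                    out[k1, k2] += r * row2[k2 - k2min]
    return out


@njit(cache=True)
def _wf_generation_1d(e, p, n_new, lg):
    n_old = e.size - 1
    out = np.zeros(n_new + 1)
    row = np.empty(n_new + 1)
    for i in range(n_old + 1):
        w = e[i]
        if w <= 0.0:
            continue
        kmin, kmax = _binom_window(n_new, p[i], lg, row)
        for k in range(kmin, kmax + 1):
            out[k] += row[k - kmin] * w
    return out


def _equilibrium_counts(twoN: int, gamma: float, h: float, theta: float,
                        twoNa: float) -> np.ndarray:
    """Expected segregating-count vector at mutation-selection-drift balance."""
    s = gamma / twoNa
    x = np.arange(twoN + 1) / twoN
    xp = _post_selection_freq(x, s, h)
    i = np.arange(twoN + 1)
    P = binom.pmf(i[:, None], twoN, xp[None, :])  # P[i', i]
    Pint = P[1:twoN, 1:twoN]
    b = np.zeros(twoN - 1)
    b[0] = theta / 2.0 * (twoN / twoNa)  # influx nu/2 per generation
    e_int = np.linalg.solve(np.eye(twoN - 1) - Pint, b)
    e = np.zeros(twoN + 1)
    e[1:twoN] = e_int
    return e


def wright_fisher_oracle(demo: DemographicModel, sel: SelectionRegime,
                         sample: SampleConfig, N_sim: int,
                         theta: float = 1.0) -> JointSpectrum:
    """Expected joint sample AFS from the explicit Wright--Fisher chain.

    ``N_sim`` is the diploid ancestral population size of the rescaled
    chain; a relative size ``nu`` maps to ``round(2 * nu * N_sim)``
    chromosomes.  Final sampling to ``(n1, n2)`` is binomial.
    """
    twoNa = 2 * N_sim
    numax = max(demo.nu1, demo.nu2, demo.nu_pre, 1.0)
    lg = gammaln(np.arange(int(twoNa * numax) + 4) + 1.0)

    # ancestral equilibrium at size Na under gamma1
    e1 = _equilibrium_counts(twoNa, sel.gamma1, sel.h, theta, twoNa)
    pre = demo.pre_split_epoch
    twoN_anc = twoNa
    if pre is not None:
        nu_pre, T_pre = pre
        twoNpre = max(int(round(twoNa * nu_pre)), 4)
        s1 = sel.gamma1 / twoNa
        x = np.arange(twoN_anc + 1) / twoN_anc
        e1 = _wf_generation_1d(e1, _post_selection_freq(x, s1, sel.h), twoNpre, lg)
        xpre = np.arange(twoNpre + 1) / twoNpre
        p = _post_selection_freq(xpre, s1, sel.h)
        for _ in range(int(round(T_pre * twoNa))):
            e1 = _wf_generation_1d(e1, p, twoNpre, lg)
            e1[0] = 0.0
            e1[-1] = 0.0
            e1[1] += theta / 2.0 * nu_pre
        twoN_anc = twoNpre

    # split: binomial founder sampling at the initial daughter sizes
    nu10, nu20 = demo.initial_sizes()
    twoN1 = max(int(round(twoNa * nu10)), 4)
    twoN2 = max(int(round(twoNa * nu20)), 4)
    x_anc = np.arange(twoN_anc + 1) / twoN_anc
    B1 = binom.pmf(np.arange(twoN1 + 1)[None, :], twoN1, x_anc[:, None])
    B2 = binom.pmf(np.arange(twoN2 + 1)[None, :], twoN2, x_anc[:, None])
    e = (B1 * e1[:, None]).T @ B2  # (2N1+1, 2N2+1)

    # post-split generations
    T = demo.divergence_time
    gens = int(round(T * twoNa))
    M12, M21 = demo.migration_rates()
    s1 = sel.gamma1 / twoNa
    s2 = sel.gamma2 / twoNa
    m12 = M12 / twoNa
    m21 = M21 / twoNa
    for g in range(gens):
        t_now = min((g + 0.5) / twoNa, T)
        nu1, nu2 = demo.sizes_at(t_now)
        new1 = max(int(round(twoNa * nu1)), 4)
        new2 = max(int(round(twoNa * nu2)), 4)
        if (new1 + 1) * (new2 + 1) > _MAX_STATES:
            raise OracleError(
                f"joint state space {(new1 + 1) * (new2 + 1)} exceeds the "
                f"tractability guard; reduce N_sim"
            )
        A, B = e.shape
        x1 = np.repeat(np.arange(A) / (A - 1), B).reshape(A, B)
        x2 = np.tile(np.arange(B) / (B - 1), A).reshape(A, B)
        x1s = _post_selection_freq(x1, s1, sel.h)
        x2s = _post_selection_freq(x2, s2, sel.h)
        p1 = (1.0 - m12) * x1s + m12 * x2s
        p2 = (1.0 - m21) * x2s + m21 * x1s
        if M12 == 0.0 and M21 == 0.0:
            # no migration: the axes evolve independently -> matrix products
            T1 = binom.pmf(np.arange(new1 + 1)[:, None], new1, p1[:, 0][None, :])
            T2 = binom.pmf(np.arange(new2 + 1)[:, None], new2, p2[0, :][None, :])
            e = T1 @ e @ T2.T
        else:
            cutoff = max(e.max() * 1e-14, 0.0)
            e = _wf_generation(e, p1, p2, new1, new2, lg, cutoff)
        e[1, 0] += theta / 2.0 * nu1
        e[0, 1] += theta / 2.0 * nu2

    # binomial downsampling to the sample sizes
    A, B = e.shape
    D1 = binom.pmf(np.arange(sample.n1 + 1)[None, :], sample.n1,
                   (np.arange(A) / (A - 1))[:, None])
    D2 = binom.pmf(np.arange(sample.n2 + 1)[None, :], sample.n2,
                   (np.arange(B) / (B - 1))[:, None])
    F = D1.T @ e @ D2
    spec = JointSpectrum(F, sample, kind="expected")
    spec.meta.update(N_sim=N_sim, backend="wright-fisher")
    return spec
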