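"""Diffusion engine for expected joint allele frequency spectra.

Solves the two-population forward (Kolmogorov) diffusion for the density
``phi(x, y, t)`` of derived-allele frequencies under drift, selection with
dominance, migration, and time-varying population sizes, at mutation
influx ``theta = 1``.  The expected sample AFS is the integral of the
density against binomial sampling kernels.

Numerics
--------
* Phase-space grid on [0, 1] with tanh crowding toward the boundaries,
  where the equilibrium density has its 1/x singularity and where strong
  selection forms boundary layers.
* The flux is discretized in the product variable ``u = x(1-x) phi``:
  ``J = (1/2nu) [B(x) u - du/dx]`` with the bounded effective drift
  ``B = 2 nu M / (x(1-x))``.  Because ``u`` vanishes identically at
  ``x = 0, 1``, the absorbing boundaries are exact: fixed/lost density
  accumulates in the boundary cells and never diffuses back, while
  boundary rows still evolve along the free axis (a variant lost in one
  population keeps drifting in the other).
* Chang--Cooper exponential fitting of the interface value of ``u``:
  positivity preserving and exact for steady two-point problems, which
  keeps mutation--selection--drift equilibria accurate even for
  population-scaled coefficients of order 10^3.
* Fully implicit (backward Euler) time stepping with direction splitting,
  alternating the sweep order to cancel the leading splitting asymmetry.
* The computation runs on three grids of increasing resolution and is
  Richardson-extrapolated entrywise to zero grid spacing.

New mutations enter population ``i`` as a point mass flux at the lowest
interior frequency, calibrated against the discrete chain's absorption
probability so that the neutral substitution flux is exactly ``theta/2``
(reproducing the classical density ``theta * nu / x``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.linalg import solve_banded
from scipy.stats import binom

from .demography import DemographicModel, DemographyError, SelectionRegime
from .spectrum import JointSpectrum, SampleConfig


class EngineError(RuntimeError):
    """Solver failure, reported with the offending configuration."""


@dataclass(frozen=True)
class EngineConfig:
    """Numerical settings for the diffusion engine.

    pts
        Base number of phase-space grid points; the three extrapolation
        grids use ``pts``, ``pts + 10``, ``pts + 20``.  ``None`` chooses
        ``max(n1, n2) + 20``.
    crwd
        tanh crowding strength; larger packs more points near 0 and 1.
    dt_fac
        Target time step is ``dt_fac / pts``, further reduced when
        selection or migration is strong.
    min_steps / max_steps
        Caps on the number of implicit steps per epoch.
    """

    pts: int | None = None
    crwd: float = 4.0
    dt_fac: float = 0.2
    min_steps: int = 25
    max_steps: int = 400

    def pts_list(self, sample: SampleConfig) -> tuple[int, int, int]:
        base = self.pts if self.pts is not None else max(sample.n1, sample.n2) + 20
        base = max(base, 20)
        return (base, base + 10, base + 20)


DEFAULT_ENGINE = EngineConfig()


# ----------------------------------------------------------------------
# Grids and sampling kernels
# ----------------------------------------------------------------------

def phase_grid(pts: int, crwd: float = 4.0) -> np.ndarray:
    """Grid on [0, 1] with tanh crowding toward both boundaries."""
    u = np.linspace(0.0, 1.0, pts)
    x = 0.5 * (1.0 + np.tanh(crwd * (2.0 * u - 1.0)) / np.tanh(crwd))
    x[0], x[-1] = 0.0, 1.0
    return x


def _cell_widths(x: np.ndarray) -> np.ndarray:
    w = np.empty_like(x)
    w[1:-1] = 0.5 * (x[2:] - x[:-2])
    w[0] = 0.5 * (x[1] - x[0])
    w[-1] = 0.5 * (x[-1] - x[-2])
    return w


def _binom_kernel(x: np.ndarray, n: int) -> np.ndarray:
    """``K[g, i] = C(n, i) x_g^i (1 - x_g)^(n - i)``."""
    i = np.arange(n + 1)
    return binom.pmf(i[None, :], n, x[:, None])


# ----------------------------------------------------------------------
# Chang--Cooper coefficients in the product variable u = x(1-x) phi
# ----------------------------------------------------------------------

@njit(cache=True)
def _cc_delta(w: float) -> float:
    # upstream weighting: u_hat = delta u_j + (1 - delta) u_{j+1};
    # exact for the steady two-point problem u_{j+1}/u_j = exp(w)
    if abs(w) < 1e-8:
        return 0.5 + w / 12.0
    if w > 35.0:
        return 1.0 - 1.0 / w
    if w < -35.0:
        return -1.0 / w
    return 1.0 + 1.0 / np.expm1(w) - 1.0 / w


@njit(cache=True)
def _flux_coeffs(xh, hx, gamma, h, mig, yj, nu, p, q):
    """Interface flux J_{k+1/2} = p[k] u_k + q[k] u_{k+1}.

    Effective drift on u:  B = 2 nu M / (x(1-x)) with
    M = 2 gamma x(1-x)(h + (1-2h)x) + mig (y - x), so the selection part
    of B is bounded and only migration contributes a (integrable) 1/x
    factor.  p > 0 and q < 0 always, so boundary cells are pure sinks.
    """
    inv2nu = 1.0 / (2.0 * nu)
    for k in range(xh.size):
        xk = xh[k]
        V = xk * (1.0 - xk)
        B = (4.0 * nu * gamma * (h + (1.0 - 2.0 * h) * xk)
             + 2.0 * nu * mig * (yj - xk) / V)
        w = B * hx[k]
        d = _cc_delta(w)
        p[k] = inv2nu * (B * d + 1.0 / hx[k])
        q[k] = inv2nu * (B * (1.0 - d) - 1.0 / hx[k])


@njit(cache=True)
def _implicit_sweep(phi, x, xh, hx, wc, Vhat, y, dt, gamma, h, mig, nu):
    """One implicit step along axis 0 of ``phi`` for every column j.

    Interior nodes are advanced in u = x(1-x) phi by a Thomas solve; the
    two boundary cells of the swept axis absorb the implicit boundary
    fluxes (they receive mass, never emit it).
    """
    nx, ny = phi.shape
    p = np.empty(nx - 1)
    q = np.empty(nx - 1)
    cp = np.empty(nx - 2)
    dp = np.empty(nx - 2)
    for j in range(ny):
        _flux_coeffs(xh, hx, gamma, h, mig, y[j], nu, p, q)
        # unknowns u_1 .. u_{nx-2}; c_i = w_i / Vhat_i converts u to mass
        # row i: -dt p_{i-1} u_{i-1} + (c_i - dt (q_{i-1} - p_i)) u_i
        #        + dt q_i u_{i+1} = c_i u_i_old
        i = 1
        c = wc[i] / Vhat[i]
        diag = c - dt * (q[i - 1] - p[i])
        sup = dt * q[i]
        cp[0] = sup / diag
        dp[0] = c * Vhat[i] * phi[i, j] / diag
        for i in range(2, nx - 1):
            c = wc[i] / Vhat[i]
            sub = -dt * p[i - 1]
            diag = c - dt * (q[i - 1] - p[i])
            sup = dt * q[i]
            denom = diag - sub * cp[i - 2]
            cp[i - 1] = sup / denom
            dp[i - 1] = (c * Vhat[i] * phi[i, j] - sub * dp[i - 2]) / denom
        # back substitution
        u_next = dp[nx - 3]
        phi[nx - 2, j] = u_next / Vhat[nx - 2]
        for i in range(nx - 3, 0, -1):
            u_i = dp[i - 1] - cp[i - 1] * u_next
            phi[i, j] = u_i / Vhat[i]
            u_next = u_i
        # boundary cells absorb the implicit boundary fluxes
        u1 = phi[1, j] * Vhat[1]
        uK1 = phi[nx - 2, j] * Vhat[nx - 2]
        phi[0, j] += -dt * q[0] * u1 / wc[0]
        phi[nx - 1, j] += dt * p[nx - 2] * uK1 / wc[nx - 1]


def _steady_flux_coeffs(x: np.ndarray, gamma: float, h: float, nu: float):
    xh = 0.5 * (x[:-1] + x[1:])
    hx = np.diff(x)
    p = np.empty(x.size - 1)
    q = np.empty(x.size - 1)
    _flux_coeffs(xh, hx, gamma, h, 0.0, 0.0, nu, p, q)
    return p, q


# ----------------------------------------------------------------------
# 1D: influx calibration, equilibrium, pre-split epochs
# ----------------------------------------------------------------------

def _influx_rate(x: np.ndarray, theta: float) -> float:
    """Mutation influx mass rate at the first interior node.

    A point source at node 1 stands in for mutations entering at
    frequency 1/(2N) -> 0.  The rate is calibrated so that the *discrete*
    neutral chain carries a probability flux theta/2 toward fixation:
    ``R = theta / (2 u_1)`` with ``u_1`` the discrete probability of
    absorption at x = 1 starting from node 1 (continuum value ``x_1``).
    """
    p, q = _steady_flux_coeffs(x, 0.0, 0.5, 1.0)
    wc = _cell_widths(x)
    Vhat = x * (1.0 - x)
    K = x.size - 1
    n_int = K - 1
    # birth-death rates of the mass-transport chain
    up = p[1:K] * Vhat[1:K] / wc[1:K]
    dn = -q[0:K - 1] * Vhat[1:K] / wc[1:K]
    ab = np.zeros((3, n_int))
    ab[1, :] = -(up + dn)
    ab[0, 1:] = up[:-1]
    ab[2, :-1] = dn[1:]
    rhs = np.zeros(n_int)
    rhs[-1] = -up[-1]
    u_abs = solve_banded((1, 1), ab, rhs)
    return theta / (2.0 * u_abs[0])


def equilibrium_density_1d(x: np.ndarray, gamma: float, h: float,
                           nu: float = 1.0, theta: float = 1.0,
                           influx: float | None = None) -> np.ndarray:
    """Mutation--selection--drift equilibrium density on grid ``x``.

    Solves the steady flux-balance equations with absorbing boundaries and
    a calibrated point mutation influx at the first interior grid point.
    Returns the density with zero boundary values.
    """
    if not np.isfinite(gamma):
        raise EngineError("non-finite selection coefficient")
    if influx is None:
        influx = _influx_rate(x, theta)
    p, q = _steady_flux_coeffs(x, gamma, h, nu)
    Vhat = x * (1.0 - x)
    K = x.size - 1
    n_int = K - 1
    # -(J_{i-1/2} - J_{i+1/2}) = S_i  in the unknowns u_1..u_{K-1}
    ab = np.zeros((3, n_int))
    for row, i in enumerate(range(1, K)):
        ab[1, row] += -(q[i - 1] - p[i])
        if i >= 2:
            ab[2, row - 1] += -p[i - 1]
        if i <= K - 2:
            ab[0, row + 1] += q[i]
    rhs = np.zeros(n_int)
    rhs[0] = influx
    try:
        u_int = solve_banded((1, 1), ab, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise EngineError(f"steady-state solve failed at gamma={gamma}") from exc
    phi = np.zeros_like(x)
    phi[1:-1] = u_int / Vhat[1:-1]
    if np.any(~np.isfinite(phi)) or np.any(phi < -1e-9):
        raise EngineError(f"invalid equilibrium density at gamma={gamma}")
    return np.clip(phi, 0.0, None)


def _step_sizes(T: float, pts: int, rate_max: float,
                cfg: EngineConfig) -> np.ndarray:
    """Implicit-Euler step schedule, continuous in T.

    Fixed steps of the target size plus one remainder step that shrinks
    smoothly to zero, so the O(dt) time-stepping error varies continuously
    with the divergence time (an integer-only step count would make the
    likelihood a staircase in T and break finite-difference gradients).
    """
    dt_target = min(cfg.dt_fac / pts, 2.0 / (1.0 + abs(rate_max)))
    if T <= cfg.min_steps * dt_target:
        return np.full(cfg.min_steps, T / cfg.min_steps)
    if T >= cfg.max_steps * dt_target:
        return np.full(cfg.max_steps, T / cfg.max_steps)
    n = int(np.floor(T / dt_target))
    r = T - n * dt_target
    if r > 1e-12 * T:
        return np.concatenate([np.full(n, dt_target), [r]])
    return np.full(n, dt_target)


def _integrate_1d(phi: np.ndarray, x: np.ndarray, T: float, gamma: float,
                  h: float, nu: float, influx: float, cfg: EngineConfig) -> np.ndarray:
    """Implicit time integration of the 1D density (constant-size epoch)."""
    xh = 0.5 * (x[:-1] + x[1:])
    hx = np.diff(x)
    wc = _cell_widths(x)
    Vhat = x * (1.0 - x)
    col = np.ascontiguousarray(phi[:, None])
    y = np.zeros(1)
    for dt in _step_sizes(T, x.size, gamma, cfg):
        col[1, 0] += dt * influx / wc[1]
        _implicit_sweep(col, x, xh, hx, wc, Vhat, y, dt, gamma, h, 0.0, nu)
    col[0, 0] = 0.0
    col[-1, 0] = 0.0  # pre-split fixation/loss is not future polymorphism
    return col[:, 0]


# ----------------------------------------------------------------------
# 2D evolution
# ----------------------------------------------------------------------

def _diag_to_2d(phi1: np.ndarray, wc: np.ndarray) -> np.ndarray:
    """Place a 1D density on the diagonal of the 2D phase space."""
    phi = np.zeros((phi1.size, phi1.size))
    idx = np.arange(1, phi1.size - 1)
    phi[idx, idx] = phi1[idx] / wc[idx]
    return phi


def _reseed_boundaries(phi: np.ndarray, x: np.ndarray, wc: np.ndarray,
                       dt: float, m12: float, m21: float,
                       nu1: float, nu2: float, abs_prob: float) -> None:
    """Migration re-seeding of variants lost or fixed in one population.

    A variant absent from population 2 but at frequency x in population 1
    re-enters population 2 through migrants exactly like a mutation
    source with theta_eff = 2 nu2 m21 x (and symmetrically for fixed
    variants, with x -> 1 - x).  The boundary mass is therefore moved
    into the first interior node at the same calibrated rate used for
    mutation influx, theta_eff / (2 * abs_prob); the implicit sweep
    returns the non-establishing share to the boundary.  Without
    migration the boundaries stay strictly absorbing.
    """
    K = x.size - 1
    # pop-2 boundaries (rows y = 0 and y = 1), driven by m21
    if m21 > 0.0:
        rate_lost = nu2 * m21 * x / abs_prob
        esc = phi[:, 0] * wc[0] * -np.expm1(-rate_lost * dt)
        phi[:, 0] -= esc / wc[0]
        phi[:, 1] += esc / wc[1]
        rate_fixed = nu2 * m21 * (1.0 - x) / abs_prob
        esc = phi[:, K] * wc[K] * -np.expm1(-rate_fixed * dt)
        phi[:, K] -= esc / wc[K]
        phi[:, K - 1] += esc / wc[K - 1]
    # pop-1 boundaries (columns x = 0 and x = 1), driven by m12
    if m12 > 0.0:
        rate_lost = nu1 * m12 * x / abs_prob
        esc = phi[0, :] * wc[0] * -np.expm1(-rate_lost * dt)
        phi[0, :] -= esc / wc[0]
        phi[1, :] += esc / wc[1]
        rate_fixed = nu1 * m12 * (1.0 - x) / abs_prob
        esc = phi[K, :] * wc[K] * -np.expm1(-rate_fixed * dt)
        phi[K, :] -= esc / wc[K]
        phi[K - 1, :] += esc / wc[K - 1]


def _evolve_2d(phi: np.ndarray, x: np.ndarray, demo: DemographicModel,
               sel: SelectionRegime, influx: float, cfg: EngineConfig) -> np.ndarray:
    xh = 0.5 * (x[:-1] + x[1:])
    hx = np.diff(x)
    wc = _cell_widths(x)
    Vhat = x * (1.0 - x)
    T = demo.divergence_time
    if T <= 0:
        return phi
    m12, m21 = demo.migration_rates()
    # neutral absorption probability from node 1: converts a migrant (or
    # mutant) copy influx into the calibrated point-source mass rate
    abs_prob = 0.5 / _influx_rate(x, 1.0)
    rate = max(abs(sel.gamma1), abs(sel.gamma2), m12, m21)
    t_now = 0.0
    for k, dt in enumerate(_step_sizes(T, x.size, rate, cfg)):
        t_mid = t_now + 0.5 * dt
        t_now += dt
        nu1, nu2 = demo.sizes_at(t_mid)
        # mutation influx: new variants private to each population
        phi[1, 0] += dt * influx / (wc[1] * wc[0])
        phi[0, 1] += dt * influx / (wc[0] * wc[1])
        _reseed_boundaries(phi, x, wc, dt, m12, m21, nu1, nu2, abs_prob)
        # alternate sweep order to cancel the leading splitting asymmetry
        if k % 2 == 0:
            _implicit_sweep(phi, x, xh, hx, wc, Vhat, x, dt,
                            sel.gamma1, sel.h, m12, nu1)
            phiT = np.ascontiguousarray(phi.T)
            _implicit_sweep(phiT, x, xh, hx, wc, Vhat, x, dt,
                            sel.gamma2, sel.h, m21, nu2)
            phi = np.ascontiguousarray(phiT.T)
        else:
            phiT = np.ascontiguousarray(phi.T)
            _implicit_sweep(phiT, x, xh, hx, wc, Vhat, x, dt,
                            sel.gamma2, sel.h, m21, nu2)
            phi = np.ascontiguousarray(phiT.T)
            _implicit_sweep(phi, x, xh, hx, wc, Vhat, x, dt,
                            sel.gamma1, sel.h, m12, nu1)
    return phi


def _sample_2d(phi: np.ndarray, x: np.ndarray, sample: SampleConfig) -> np.ndarray:
    wc = _cell_widths(x)
    Kx = _binom_kernel(x, sample.n1) * wc[:, None]
    Ky = _binom_kernel(x, sample.n2) * wc[:, None]
    return Kx.T @ phi @ Ky


def _single_grid_afs(demo: DemographicModel, sel: SelectionRegime,
                     sample: SampleConfig, pts: int, cfg: EngineConfig,
                     theta: float = 1.0) -> np.ndarray:
    x = phase_grid(pts, cfg.crwd)
    wc = _cell_widths(x)
    influx = _influx_rate(x, theta)
    phi1 = equilibrium_density_1d(x, sel.gamma1, sel.h, nu=1.0, theta=theta,
                                  influx=influx)
    pre = demo.pre_split_epoch
    if pre is not None:
        nu_pre, T_pre = pre
        phi1 = _integrate_1d(phi1, x, T_pre, sel.gamma1, sel.h, nu_pre,
                             influx, cfg)
    phi = _diag_to_2d(phi1, wc)
    phi = _evolve_2d(phi, x, demo, sel, influx, cfg)
    return _sample_2d(phi, x, sample)


def _richardson(values: list[np.ndarray], deltas: list[float]) -> np.ndarray:
    """Polynomial extrapolation of per-entry values to delta -> 0."""
    out = np.zeros_like(values[0])
    for k, (vk, dk) in enumerate(zip(values, deltas)):
        coef = 1.0
        for l, dl in enumerate(deltas):
            if l != k:
                coef *= (0.0 - dl) / (dk - dl)
        out += coef * vk
    return out


# ----------------------------------------------------------------------
# Public API
# ----------------------------------------------------------------------

def expected_joint_afs(demo: DemographicModel, sel: SelectionRegime,
                       sample: SampleConfig,
                       config: EngineConfig = DEFAULT_ENGINE,
                       theta: float = 1.0) -> JointSpectrum:
    """Expected joint AFS ``F(gamma1, gamma2 | demo)`` at mutation rate theta.

    Deterministic given inputs and engine settings; corners masked.  The
    result is Richardson-extrapolated over three phase-space grids.
    """
    if not isinstance(demo, DemographicModel):
        raise DemographyError("demo must be a DemographicModel")
    pts_l = config.pts_list(sample)
    results, deltas = [], []
    for pts in pts_l:
        F = _single_grid_afs(demo, sel, sample, pts, config, theta)
        if np.any(~np.isfinite(F)):
            raise EngineError(
                f"solver produced non-finite entries at pts={pts}, "
                f"gamma=({sel.gamma1}, {sel.gamma2})"
            )
        results.append(F)
        deltas.append(phase_grid(pts, config.crwd)[1])
    F = _richardson(results, deltas)
    F = np.clip(F, 0.0, None)
    spec = JointSpectrum(F, sample, kind="expected")
    spec.meta.update(pts=pts_l, gamma=(sel.gamma1, sel.gamma2), h=sel.h,
                     demo=demo.param_dict() | {"id": demo.id}, theta=theta)
    return spec


def equilibrium_spectrum_1d(gamma: float, h: float, n: int,
                            config: EngineConfig = DEFAULT_ENGINE,
                            theta: float = 1.0) -> np.ndarray:
    """Expected 1D AFS (entries 1..n-1) at mutation--selection--drift equilibrium.

    For a neutral locus this is the classical ``theta / i``.
    """
    if n < 2:
        raise DemographyError(f"sample size n={n} must be >= 2")
    if not np.isfinite(gamma):
        raise DemographyError("gamma must be finite")
    base = config.pts if config.pts is not None else max(n + 40, 60)
    results, deltas = [], []
    for pts in (base, base + 20, base + 40):
        x = phase_grid(pts, config.crwd)
        phi = equilibrium_density_1d(x, gamma, h, theta=theta)
        wc = _cell_widths(x)
        K = _binom_kernel(x, n) * wc[:, None]
        results.append((K.T @ phi)[1:-1])
        deltas.append(x[1])
    return np.clip(_richardson(results, deltas), 0.0, None)
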