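"""Cache of expected spectra over a grid of selection-coefficient pairs.

Evaluating the DFE integral requires the expected joint AFS
``F(gamma1, gamma2)`` at many selection-coefficient pairs.  Because the
demographic parameters are held fixed during a DFE fit, these spectra are
precomputed once on a logarithmically spaced grid of gamma magnitudes
(the full-scale default is 50 points in [1e-4, 2000], i.e. 2,500
spectra) and reused for every likelihood evaluation.

The cache stores positive magnitudes; the implied selection coefficients
are ``-grid`` (deleterious-only).  ``spectra[i, j]`` is the spectrum at
``gamma1 = -grid[i], gamma2 = -grid[j]`` computed at ``theta = 1``, and
the diagonal doubles as the 1D cache for the perfectly correlated
mixture component.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .demography import DemographicModel, SelectionRegime
from .diffusion import DEFAULT_ENGINE, EngineConfig, EngineError, expected_joint_afs
from .spectrum import JointSpectrum, SampleConfig

_FORMAT_VERSION = 1


class CacheError(ValueError):
    pass


def build_gamma_grid(n_points: int, bounds: tuple[float, float] = (1e-4, 2000.0)
                     ) -> np.ndarray:
    """Strictly increasing, log-spaced gamma magnitudes.

    The endpoints equal the bounds exactly and the ratio of consecutive
    points is constant.
    """
    lo, hi = bounds
    if n_points < 2:
        raise CacheError("need at least 2 grid points")
    if not (0 < lo < hi):
        raise CacheError(f"invalid gamma bounds ({lo}, {hi})")
    return np.geomspace(lo, hi, n_points)


@dataclass
class SelectionCache:
    """Grid of expected spectra over ordered pairs of gamma magnitudes."""

    grid: np.ndarray
    spectra: np.ndarray        # (n_grid, n_grid, n1+1, n2+1), theta = 1
    neutral: JointSpectrum     # gamma1 = gamma2 = 0, theta = 1
    demo: DemographicModel
    sample: SampleConfig
    h: float = 0.5
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise CacheError("gamma grid must be strictly increasing")
        n = self.grid.size
        if self.spectra.shape != (n, n) + self.sample.shape:
            raise CacheError(
                f"spectra array shape {self.spectra.shape} inconsistent with "
                f"grid size {n} and sample {self.sample.shape}"
            )

    @property
    def n_spectra(self) -> int:
        return self.grid.size ** 2

    @property
    def mask(self) -> np.ndarray:
        return self.neutral.mask

    def spectrum_at(self, i: int, j: int) -> JointSpectrum:
        """The cached JointSpectrum at (gamma1, gamma2) = (-grid[i], -grid[j])."""
        return JointSpectrum(self.spectra[i, j].copy(), self.sample,
                             kind="expected")

    def diagonal(self) -> np.ndarray:
        """(n_grid, n1+1, n2+1) spectra along gamma1 = gamma2."""
        idx = np.arange(self.grid.size)
        return self.spectra[idx, idx]

    def check_demography(self, demo: DemographicModel) -> None:
        """Refuse use with a demographic model other than the one cached."""
        if demo != self.demo:
            raise CacheError(
                "cache was built under a different demographic model; "
                f"cached={self.demo}, requested={demo}"
            )

    # -- persistence -----------------------------------------------------
    def save(self, path: str | os.PathLike) -> None:
        """Write the cache as a single .npz container with a JSON header."""
        header = {
            "format_version": _FORMAT_VERSION,
            "demo": self.demo.param_dict() | {
                "id": self.demo.id, "growth": self.demo.growth,
                "s_frac": self.demo.s_frac, "nu_pre": self.demo.nu_pre,
                "T_pre": self.demo.T_pre,
            },
            "n1": self.sample.n1,
            "n2": self.sample.n2,
            "h": self.h,
            "meta": self.meta,
        }
        np.savez_compressed(
            path,
            header=json.dumps(header),
            grid=self.grid,
            spectra=self.spectra,
            neutral=self.neutral.values,
            mask=self.neutral.mask,
        )

    @classmethod
    def load(cls, path: str | os.PathLike) -> "SelectionCache":
        with np.load(path, allow_pickle=False) as z:
            header = json.loads(str(z["header"]))
            if header.get("format_version") != _FORMAT_VERSION:
                raise CacheError(f"unsupported cache format in {path}")
            demo_kw = dict(header["demo"])
            demo = DemographicModel(
                id=demo_kw.pop("id"), growth=demo_kw.pop("growth"), **demo_kw)
            sample = SampleConfig(header["n1"], header["n2"])
            neutral = JointSpectrum(z["neutral"], sample, mask=z["mask"],
                                    kind="neutral")
            return cls(grid=z["grid"], spectra=z["spectra"], neutral=neutral,
                       demo=demo, sample=sample, h=header["h"],
                       meta=header.get("meta", {}))


def build_cache(demo: DemographicModel, sample: SampleConfig,
                grid: np.ndarray, h: float = 0.5,
                config: EngineConfig = DEFAULT_ENGINE,
                progress: bool = False) -> SelectionCache:
    """Compute one expected spectrum per ordered pair of grid magnitudes.

    Results are independent of evaluation order; an engine failure aborts
    with the offending (gamma1, gamma2) pair reported.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0) or grid.size < 2:
        raise CacheError("grid must be strictly increasing with >= 2 points")
    n = grid.size
    neutral = expected_joint_afs(demo, SelectionRegime(0.0, 0.0, h), sample,
                                 config)
    neutral.kind = "neutral"
    spectra = np.empty((n, n) + sample.shape)
    for i in range(n):
        if progress:
            print(f"cache row {i + 1}/{n}", flush=True)
        for j in range(n):
            sel = SelectionRegime(-grid[i], -grid[j], h)
            try:
                spectra[i, j] = expected_joint_afs(demo, sel, sample,
                                                   config).values
            except EngineError as exc:
                raise EngineError(
                    f"engine failed at cache node gamma1=-{grid[i]}, "
                    f"gamma2=-{grid[j]}: {exc}"
                ) from exc
    cache = SelectionCache(grid=grid, spectra=spectra, neutral=neutral,
                           demo=demo, sample=sample, h=h)
    cache.meta.update(engine={"pts": config.pts, "crwd": config.crwd,
                              "dt_fac": config.dt_fac})
    return cache
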