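"""Two-population joint allele frequency spectra.

The joint AFS for samples of ``n1`` and ``n2`` chromosomes is an
``(n1+1) x (n2+1)`` matrix whose entry ``(i, j)`` counts (or gives the
expectation of) variants observed at derived-allele count ``i`` in
population 1 and ``j`` in population 2.  The absorbing corners ``(0, 0)``
and ``(n1, n2)`` carry no information about segregating variation and are
always masked; masked entries are excluded from every likelihood sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom


class SpectrumError(ValueError):
    """Raised for invalid spectra, sample sizes, or incompatible shapes."""


@dataclass(frozen=True)
class SampleConfig:
    """Haploid sample sizes for the two populations (each must be >= 2)."""

    n1: int
    n2: int

    def __post_init__(self) -> None:
        if int(self.n1) != self.n1 or int(self.n2) != self.n2:
            raise SpectrumError("sample sizes must be integers")
        if self.n1 < 2 or self.n2 < 2:
            raise SpectrumError(
                f"two-population spectra need n1, n2 >= 2, got ({self.n1}, {self.n2})"
            )
        object.__setattr__(self, "n1", int(self.n1))
        object.__setattr__(self, "n2", int(self.n2))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n1 + 1, self.n2 + 1)


def corner_mask(shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask that is True only at the two absorbing corners."""
    mask = np.zeros(shape, dtype=bool)
    mask[0, 0] = True
    mask[-1, -1] = True
    return mask


@dataclass
class JointSpectrum:
    """A joint AFS with an entry mask.

    Parameters
    ----------
    values
        ``(n1+1, n2+1)`` array of nonnegative expectations or counts.
    sample
        The haploid sample sizes; must match ``values.shape``.
    mask
        Boolean array, True = excluded.  The corners ``(0, 0)`` and
        ``(n1, n2)`` are forced to True on construction.
    kind
        One of ``neutral``, ``selected``, ``expected``, ``observed``.
    """

    values: np.ndarray
    sample: SampleConfig
    mask: np.ndarray | None = None
    kind: str = "expected"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.sample.shape:
            raise SpectrumError(
                f"values shape {self.values.shape} does not match sample "
                f"sizes {self.sample.shape}"
            )
        if self.mask is None:
            self.mask = corner_mask(self.values.shape)
        else:
            self.mask = np.asarray(self.mask, dtype=bool).copy()
            if self.mask.shape != self.values.shape:
                raise SpectrumError("mask shape does not match values")
            self.mask |= corner_mask(self.values.shape)
        if self.kind not in ("neutral", "selected", "expected", "observed"):
            raise SpectrumError(f"unknown spectrum kind {self.kind!r}")
        if np.any(~np.isfinite(self.values[~self.mask])):
            raise SpectrumError("non-finite unmasked entries")

    # -- basic accessors -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def unmasked(self) -> np.ndarray:
        """Flat array of the unmasked entries."""
        return self.values[~self.mask]

    def total(self) -> float:
        """Sum over unmasked entries (expected or observed segregating sites)."""
        return float(self.unmasked().sum())

    def copy(self, **updates) -> "JointSpectrum":
        kw = dict(
            values=self.values.copy(),
            sample=self.sample,
            mask=self.mask.copy(),
            kind=self.kind,
            meta=dict(self.meta),
        )
        kw.update(updates)
        return JointSpectrum(**kw)

    def __mul__(self, scalar: float) -> "JointSpectrum":
        return self.copy(values=self.values * float(scalar))

    __rmul__ = __mul__

    def __add__(self, other: "JointSpectrum") -> "JointSpectrum":
        self._check_compatible(other)
        return self.copy(values=self.values + other.values)

    def _check_compatible(self, other: "JointSpectrum") -> None:
        if self.shape != other.shape:
            raise SpectrumError("spectra have different shapes")
        if not np.array_equal(self.mask, other.mask):
            raise SpectrumError("spectra have different masks")


def _projection_matrix(n_from: int, n_to: int) -> np.ndarray:
    """Hypergeometric downsampling kernel along one axis.

    ``P[i, k]`` is the probability that a variant at derived count ``i`` of
    ``n_from`` appears at count ``k`` in a subsample of ``n_to`` drawn
    without replacement.
    """
    i = np.arange(n_from + 1)[:, None]
    k = np.arange(n_to + 1)[None, :]
    return hypergeom.pmf(k, n_from, i, n_to)


def project(spec: JointSpectrum, new_sample: SampleConfig) -> JointSpectrum:
    """Project a spectrum down to smaller sample sizes.

    Each entry's mass is redistributed by the exact hypergeometric sampling
    kernel independently on each axis.  Projection to the current sizes is
    the identity; upward projection is an error.
    """
    n1, n2 = spec.sample.n1, spec.sample.n2
    m1, m2 = new_sample.n1, new_sample.n2
    if m1 > n1 or m2 > n2:
        raise SpectrumError(
            f"cannot project ({n1},{n2}) upward to ({m1},{m2})"
        )
    if (m1, m2) == (n1, n2):
        return spec.copy()
    # Masked entries hold no information; drop their mass before projecting.
    vals = np.where(spec.mask, 0.0, spec.values)
    P1 = _projection_matrix(n1, m1)
    P2 = _projection_matrix(n2, m2)
    out = P1.T @ vals @ P2
    return JointSpectrum(out, new_sample, kind=spec.kind, meta=dict(spec.meta))
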