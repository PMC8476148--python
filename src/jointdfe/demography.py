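"""Two-population demographic models and selection regimes.

Units follow the diffusion convention the field uses for SFS work:

* population sizes are relative to the ancestral size ``N_a``;
* times are in units of ``2 N_a`` generations;
* migration rates are population-scaled, ``M = 2 N_a m`` (fraction ``m``
  of migrant lineages per generation);
* selection is population-scaled, ``gamma = 2 N_a s``, with diploid
  fitnesses 1, ``1 + 2hs``, ``1 + 2s`` for ancestral homozygote,
  heterozygote, and derived homozygote.

Model ids
---------
``equilibrium``
    No divergence: both samples drawn from one equilibrium population
    (implemented as a split of equal halves with T = 0).
``split_mig`` / ``split_no_mig``
    Ancestral population splits; daughters jump instantaneously to sizes
    ``nu1`` and ``nu2`` and exchange migrants at rates ``m12`` (into pop 1)
    and ``m21`` (into pop 2); ``split_no_mig`` forces both to zero.
``IM``
    Isolation-with-migration: the split assigns a fraction ``s_frac`` of
    the ancestral population to population 1, after which each population
    grows exponentially to its final size (``nu1``, ``nu2``) over time
    ``T``, with asymmetric migration.
``IM_pre``
    As ``IM``, but the ancestral population first changes instantaneously
    to size ``nu_pre`` for a duration ``T_pre`` before the split.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class DemographyError(ValueError):
    """Invalid demographic model or parameters."""


MODEL_IDS = ("equilibrium", "split_mig", "split_no_mig", "IM", "IM_pre")

#: Free parameters per model id, in canonical optimization order.
MODEL_PARAMS: dict[str, tuple[str, ...]] = {
    "equilibrium": (),
    "split_mig": ("nu1", "nu2", "T", "m12", "m21"),
    "split_no_mig": ("nu1", "nu2", "T"),
    "IM": ("s_frac", "nu1", "nu2", "T", "m12", "m21"),
    "IM_pre": ("nu_pre", "T_pre", "s_frac", "nu1", "nu2", "T", "m12", "m21"),
}

#: Optimization bounds (natural scale) per parameter name.
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "nu1": (1e-3, 100.0),
    "nu2": (1e-3, 100.0),
    "nu_pre": (1e-3, 100.0),
    "T": (1e-5, 5.0),
    "T_pre": (1e-5, 5.0),
    "m12": (0.0, 20.0),
    "m21": (0.0, 20.0),
    "s_frac": (0.01, 0.99),
}


@dataclass(frozen=True)
class DemographicModel:
    """A two-population demographic history.

    Only the parameters meaningful for ``id`` are consulted; the rest keep
    their defaults.  ``growth`` selects exponential vs instantaneous size
    change after the split for the IM-type models.
    """

    id: str
    nu1: float = 1.0
    nu2: float = 1.0
    T: float = 0.0
    m12: float = 0.0
    m21: float = 0.0
    s_frac: float = 0.5
    nu_pre: float = 1.0
    T_pre: float = 0.0
    growth: str = "exponential"

    def __post_init__(self) -> None:
        if self.id not in MODEL_IDS:
            raise DemographyError(f"unknown demographic model {self.id!r}")
        for name in ("nu1", "nu2", "nu_pre"):
            if getattr(self, name) <= 0:
                raise DemographyError(f"{name} must be > 0")
        for name in ("T", "T_pre", "m12", "m21"):
            if getattr(self, name) < 0:
                raise DemographyError(f"{name} must be >= 0")
        if not 0 < self.s_frac < 1:
            raise DemographyError("s_frac must be in (0, 1)")
        if self.growth not in ("exponential", "instantaneous"):
            raise DemographyError("growth must be exponential or instantaneous")

    # -- epoch description consumed by both engines ----------------------
    @property
    def divergence_time(self) -> float:
        return 0.0 if self.id == "equilibrium" else self.T

    @property
    def pre_split_epoch(self) -> tuple[float, float] | None:
        """(size, duration) of an ancestral size-change epoch, if any."""
        if self.id == "IM_pre" and self.T_pre > 0:
            return (self.nu_pre, self.T_pre)
        return None

    def initial_sizes(self) -> tuple[float, float]:
        """Relative sizes of the daughters immediately after the split."""
        anc = self.nu_pre if self.id == "IM_pre" else 1.0
        if self.id in ("IM", "IM_pre"):
            if self.growth == "instantaneous":
                return (self.nu1, self.nu2)
            return (self.s_frac * anc, (1.0 - self.s_frac) * anc)
        if self.id == "equilibrium":
            return (1.0, 1.0)
        return (self.nu1, self.nu2)

    def sizes_at(self, t: float) -> tuple[float, float]:
        """Relative sizes at time ``t`` after the split, ``0 <= t <= T``."""
        nu10, nu20 = self.initial_sizes()
        if self.id in ("IM", "IM_pre") and self.growth == "exponential" and self.T > 0:
            frac = min(max(t / self.T, 0.0), 1.0)
            return (
                nu10 * (self.nu1 / nu10) ** frac,
                nu20 * (self.nu2 / nu20) ** frac,
            )
        return (nu10, nu20) if self.id in ("IM", "IM_pre") else (self.nu1, self.nu2)

    def migration_rates(self) -> tuple[float, float]:
        if self.id in ("split_no_mig", "equilibrium"):
            return (0.0, 0.0)
        return (self.m12, self.m21)

    def free_param_names(self) -> tuple[str, ...]:
        return MODEL_PARAMS[self.id]

    def with_params(self, **params) -> "DemographicModel":
        return replace(self, **params)

    def param_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in MODEL_PARAMS[self.id]}


@dataclass(frozen=True)
class SelectionRegime:
    """Population-scaled selection (gamma = 2*Na*s) and dominance.

    ``gamma1`` acts in the ancestral population and in population 1 after
    the split; ``gamma2`` acts in population 2 from the split onward.
    Deleterious-only mode (the default) rejects positive gammas.
    """

    gamma1: float = 0.0
    gamma2: float = 0.0
    h: float = 0.5
    deleterious_only: bool = True

    def __post_init__(self) -> None:
        if not (np.isfinite(self.gamma1) and np.isfinite(self.gamma2)):
            raise DemographyError("selection coefficients must be finite")
        if not 0.0 <= self.h <= 1.0:
            raise DemographyError("dominance h must be in [0, 1]")
        if self.deleterious_only and (self.gamma1 > 0 or self.gamma2 > 0):
            raise DemographyError(
                "positive gamma in deleterious-only mode; pass "
                "deleterious_only=False to allow it"
            )

NEUTRAL = SelectionRegime(0.0, 0.0, 0.5)
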