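"""Domain types for lake food-web isotope analysis.

Units: all isotope values are per-mil (‰) deltas — δ13C vs VPDB, δ15N vs
atmospheric N2. Trophic positions and carbon-source proportions are
dimensionless. No unit conversion is performed anywhere in the package.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum


class Role(str, Enum):
    CONSUMER = "consumer"
    LITTORAL_BASELINE = "littoral_baseline"
    PELAGIC_BASELINE = "pelagic_baseline"


class Tissue(str, Enum):
    MUSCLE = "muscle"
    FIN = "fin"
    LIVER = "liver"
    WHOLE = "whole"


#: Plausible field ranges (per-mil); values outside trigger a warning, not an error.
D13C_PLAUSIBLE = (-50.0, 0.0)
D15N_PLAUSIBLE = (-10.0, 30.0)

#: The nine trophic-position variants, in canonical order.
TP_KEYS = (
    "tp1_lb",
    "tp1_p",
    "tp1_lbp",
    "tp2",
    "tp2_adj",
    "tp2_r",
    "tp2abs",
    "tp2abs_adj",
    "tp2abs_r",
)

#: The three littoral-carbon-use scalings, in canonical order.
LCU_KEYS = ("lcu", "lcu_adj", "lcu_r")


class DegenerateEndmembersError(ValueError):
    """Littoral and pelagic baseline δ13C means are equal: the two-source
    mixing model is undefined. Use a one-source trophic position with a
    pooled baseline instead."""


class DegenerateRangeError(ValueError):
    """All values in a collection are equal, so min-max rescaling is undefined."""


class ImplausibleIsotopeWarning(UserWarning):
    """Isotope value outside the plausible field range (soft check only)."""


@dataclass(frozen=True)
class IsotopeMeasurement:
    """One analyzed specimen: identity, grouping labels, and isotope values.

    ``season`` and ``stratum`` are unordered categorical labels (e.g. "may",
    "east"); ``stratum`` typically denotes a basin in spatially structured
    lakes.
    """

    specimen_id: str
    species: str
    role: Role
    tissue: Tissue
    season: str
    stratum: str
    d13c: float
    d15n: float
    length_mm: float | None = None

    def __post_init__(self):
        for name, value in (("d13c", self.d13c), ("d15n", self.d15n)):
            if not math.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value!r}")
        if self.length_mm is not None and self.length_mm <= 0:
            raise ValueError(f"length_mm must be positive, got {self.length_mm!r}")
        if not D13C_PLAUSIBLE[0] <= self.d13c <= D13C_PLAUSIBLE[1]:
            warnings.warn(
                f"specimen {self.specimen_id}: d13c {self.d13c} outside "
                f"plausible range {D13C_PLAUSIBLE}",
                ImplausibleIsotopeWarning,
                stacklevel=2,
            )
        if not D15N_PLAUSIBLE[0] <= self.d15n <= D15N_PLAUSIBLE[1]:
            warnings.warn(
                f"specimen {self.specimen_id}: d15n {self.d15n} outside "
                f"plausible range {D15N_PLAUSIBLE}",
                ImplausibleIsotopeWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class EndmemberSet:
    """Littoral and pelagic baseline means with assumed trophic positions.

    ``lambda_littoral`` / ``lambda_pelagic`` are the assumed trophic positions
    (λ) of the baseline taxa — e.g. 2 for a strict primary consumer, 2.25 for
    mayfly larvae, 2.5 for oligochaetes. ``scope`` records which (stratum,
    season) the set applies to; ``None`` in either slot means "pooled over
    that factor".
    """

    d13c_littoral: float
    d13c_pelagic: float
    d15n_littoral: float
    d15n_pelagic: float
    lambda_littoral: float = 2.0
    lambda_pelagic: float = 2.0
    n_littoral: int = 1
    n_pelagic: int = 1
    scope: tuple[str | None, str | None] = (None, None)

    def __post_init__(self):
        for name in ("d13c_littoral", "d13c_pelagic", "d15n_littoral", "d15n_pelagic"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.n_littoral < 1 or self.n_pelagic < 1:
            raise ValueError("endmember sample counts must be >= 1")
        if self.lambda_littoral < 1 or self.lambda_pelagic < 1:
            raise ValueError("baseline trophic positions (lambda) must be >= 1")

    @property
    def d13c_spread(self) -> float:
        return self.d13c_littoral - self.d13c_pelagic

    @property
    def lambdas_equal(self) -> bool:
        return self.lambda_littoral == self.lambda_pelagic


@dataclass(frozen=True)
class MetricConfig:
    """Knobs of the metric suite.

    delta_n : per-trophic-step δ15N enrichment (diet–tissue discrimination
        factor), conventionally 3.4 ‰ in freshwater food webs.
    lambda_default : assumed baseline trophic position for the one-source and
        equal-λ two-source equations.
    violation_threshold : fraction of a population outside [0, 1] above which
        min-max rescaled LCU is recommended over raw LCU (the "> 5 %" rule).
    rescale_scope : whether min-max rescaling pools all consumers in the
        system or operates within each stratum.
    """

    delta_n: float = 3.4
    lambda_default: float = 2.0
    violation_threshold: float = 0.05
    rescale_scope: str = "per_system"  # or "per_stratum"
    clip_bounds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        if self.delta_n <= 0:
            raise ValueError(f"delta_n must be positive, got {self.delta_n}")
        if not 0 < self.violation_threshold < 1:
            raise ValueError("violation_threshold must lie in (0, 1)")
        if self.rescale_scope not in ("per_system", "per_stratum"):
            raise ValueError(f"unknown rescale_scope {self.rescale_scope!r}")


@dataclass(frozen=True)
class MetricRecord:
    """Per-consumer littoral carbon use (three scalings) and the nine
    trophic-position variants."""

    specimen_id: str
    lcu: float
    lcu_adj: float
    lcu_r: float
    tp: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = set(TP_KEYS) - set(self.tp)
        if missing:
            raise ValueError(f"MetricRecord missing TP keys: {sorted(missing)}")


@dataclass(frozen=True)
class ViolationSummary:
    """Boundary-violation accounting for raw LCU within one population."""

    n_total: int
    n_above_1: int
    n_below_0: int
    pct_outside: float
    exceeds_threshold: bool

    @property
    def n_outside(self) -> int:
        return self.n_above_1 + self.n_below_0
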