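"""Core domain types for the national urban-forest carbon assessment.

The pipeline moves through four kinds of records: city-level assessment
summaries (plot-based model output: totals with sampling standard errors),
reconciliation units (province x ecozone strata carrying urban and canopy
area), carbon densities per unit canopy (stock in t C/ha of crown cover and
gross sequestration in t C/ha/yr), and the resulting per-RU carbon accounts.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from .errors import ValidationError

#: Net sequestration as a fraction of gross (biomass-decay emissions netted out).
DEFAULT_F_NET = 0.74
#: Mass ratio CO2:C, exactly 44/12.
CO2_PER_C = 44.0 / 12.0


class DensitySource(enum.Enum):
    """Provenance of a carbon density: pooled local data, a surrogate city, or
    managed-forest model constants."""

    POOLED = "pooled"
    PROXY_CITY = "proxy_city"
    FOREST_MODEL = "forest_model"


class UncertaintyClass(enum.Enum):
    """The three Monte-Carlo urban-area classes, in increasing uncertainty."""

    CITY_COVERED = "city_covered"
    PARTIAL = "partial"
    PROXY = "proxy"


@dataclass(frozen=True)
class CityAssessment:
    """One city's plot-based urban forest assessment summary.

    Standard errors reflect plot-sampling error of the totals; they may be
    absent (``None``) when the source report does not publish them.
    ``canopy_area_override`` carries a city's own canopy-cover estimate (ha)
    when the stratum canopy fraction should not be applied (used for the
    external surrogate city whose canopy came from satellite mapping).
    """

    name: str
    ru_id: int | None
    assessment_area: float  # ha
    n_plots: int
    carbon_storage_total: float  # t C
    carbon_storage_se: float | None  # t C
    seq_gross_total: float  # t C / yr
    seq_gross_se: float | None  # t C / yr
    external: bool = False
    canopy_area_override: float | None = None  # ha

    def __post_init__(self):
        for fname in (
            "assessment_area",
            "carbon_storage_total",
            "seq_gross_total",
        ):
            if getattr(self, fname) < 0:
                raise ValidationError(f"{self.name}: {fname} must be >= 0")
        for fname in ("carbon_storage_se", "seq_gross_se"):
            v = getattr(self, fname)
            if v is not None and v < 0:
                raise ValidationError(f"{self.name}: {fname} must be >= 0")
        if self.n_plots < 1:
            raise ValidationError(f"{self.name}: n_plots must be >= 1")
        if (
            self.canopy_area_override is not None
            and self.canopy_area_override > self.assessment_area
        ):
            raise ValidationError(
                f"{self.name}: canopy_area_override exceeds assessment_area"
            )


@dataclass(frozen=True)
class ReconciliationUnit:
    """One province x ecozone stratum with urban area and canopy cover."""

    ru_id: int
    name: str
    ecozone: str
    ru_area: float  # km2
    urban_area: float  # km2
    canopy_area: float  # km2
    canopy_fraction: float  # dimensionless, in [0, 1]
    uncertainty_class: UncertaintyClass | None = None

    #: printed-value rounding slack allowed on canopy_area/urban_area vs fraction
    CONSISTENCY_SLACK = 0.005

    def __post_init__(self):
        if not 0.0 <= self.canopy_fraction <= 1.0:
            raise ValidationError(f"RU {self.ru_id}: canopy_fraction not in [0,1]")
        if not self.canopy_area <= self.urban_area <= self.ru_area:
            raise ValidationError(
                f"RU {self.ru_id}: need canopy_area <= urban_area <= ru_area"
            )

    @property
    def urban_area_ha(self) -> float:
        return self.urban_area * 100.0

    @property
    def canopy_area_ha(self) -> float:
        return self.canopy_area * 100.0

    def canopy_consistent(self) -> bool:
        """Whether canopy_area/urban_area agrees with the printed fraction."""
        if self.urban_area == 0:
            return True
        return (
            abs(self.canopy_area / self.urban_area - self.canopy_fraction)
            <= self.CONSISTENCY_SLACK
        )


@dataclass(frozen=True)
class DensityPair:
    """Carbon per unit canopy: stock density and gross sequestration rate."""

    storage_density: float  # t C / ha canopy
    seq_rate: float  # t C / ha canopy / yr
    source: DensitySource = DensitySource.POOLED
    note: str = ""

    def __post_init__(self):
        if not (self.storage_density > 0 and self.seq_rate > 0):
            raise ValidationError("densities must be > 0")
        if not self.seq_rate < self.storage_density:
            raise ValidationError(
                "annual sequestration rate must be smaller than the stock density"
            )


@dataclass(frozen=True)
class BaselineRates:
    """Fixed-rate baseline: one national density and sequestration rate."""

    storage_density: float = 76.9  # t C / ha canopy
    seq_rate: float = 2.12  # t C / ha canopy / yr

    def __post_init__(self):
        if not (self.storage_density > 0 and self.seq_rate > 0):
            raise ValidationError("baseline rates must be > 0")


@dataclass(frozen=True)
class CarbonAccount:
    """Per-RU (or national) carbon account in kt.

    ``seq_net = f_net * seq_gross`` and ``co2_net = 44/12 * seq_net`` hold
    exactly by construction.
    """

    ru_id: int | None
    name: str
    storage: float  # kt C
    seq_gross: float  # kt C / yr
    seq_net: float  # kt C / yr
    co2_net: float  # kt CO2 / yr

    def __post_init__(self):
        for fname in ("storage", "seq_gross", "seq_net", "co2_net"):
            if getattr(self, fname) < 0:
                raise ValidationError(f"{self.name}: {fname} must be >= 0")


@dataclass(frozen=True)
class AccountingConfig:
    """Knobs of the stock/flux account.

    f_net: net:gross sequestration ratio (decay emissions netted out). The
    source text states 74%; its printed tables imply ~0.749-0.750, so the
    ratio is configurable rather than hard-coded.
    """

    f_net: float = DEFAULT_F_NET
    co2_ratio: float = CO2_PER_C
    report_precision: int = 1

    def __post_init__(self):
        if not 0 < self.f_net <= 1:
            raise ValidationError("f_net must be in (0, 1]")


@dataclass(frozen=True)
class PercentileBounds:
    """Monte-Carlo summary: mean and 2.5/97.5 percentiles of one output.

    ``rel_low``/``rel_high`` are relative deviations of the percentiles from
    the Monte-Carlo mean. When a deterministic central value is supplied the
    deviations relative to it are exposed as ``rel_low_det``/``rel_high_det``
    (the convention used when bounds are printed next to a deterministic
    account value).
    """

    mean: float
    p2_5: float
    p97_5: float
    deterministic: float | None = None

    @property
    def rel_low(self) -> float:
        return self.p2_5 / self.mean - 1.0

    @property
    def rel_high(self) -> float:
        return self.p97_5 / self.mean - 1.0

    @property
    def rel_low_det(self) -> float:
        ref = self.mean if self.deterministic is None else self.deterministic
        return self.p2_5 / ref - 1.0

    @property
    def rel_high_det(self) -> float:
        ref = self.mean if self.deterministic is None else self.deterministic
        return self.p97_5 / ref - 1.0


@dataclass
class RateDistribution:
    """Mixture of normal components describing one RU's carbon rate.

    Components are ``(label, weight, mean, sd)`` in density units (t/ha or
    t/ha/yr); weights sum to 1 within the RU.
    """

    ru_id: int
    quantity: str  # "storage" | "seq"
    uncertainty_class: UncertaintyClass
    components: list[tuple[str, float, float, float]] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.components:
            total = sum(w for _, w, _, _ in self.components)
            if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
                raise ValidationError(
                    f"RU {self.ru_id} {self.quantity}: weights sum to {total}, not 1"
                )
            for label, _, _, sd in self.components:
                if sd < 0:
                    raise ValidationError(
                        f"RU {self.ru_id} {self.quantity} component {label}: sd < 0"
                    )

    @property
    def mean(self) -> float:
        return sum(w * m for _, w, m, _ in self.components)
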