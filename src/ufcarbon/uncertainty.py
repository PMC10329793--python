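"""Three-class Monte Carlo propagation of inventory uncertainties.

Each reconciliation unit's urban area falls into one of three classes of
increasing uncertainty:

``CITY_COVERED``
    The fraction of an RU's urban area covered by city assessments.  Each
    covered city contributes a normal rate component with its own
    plot-sampling SE (converted to density units by its canopy area).
``PARTIAL``
    The remainder of an RU that contains assessed cities: a normal component
    centred on the RU's pooled city density with SD equal to the inter-city
    variability observed in the reference (Mixedwood Plains) RU.
``PROXY``
    RUs with no assessed city: a normal component centred on the assigned
    proxy density with SD combining (by default in quadrature) the proxy
    city's own SE, the inter-city SD, and the SD between all RU densities.
    Boreal RUs take managed-forest model constants; their SD is the inter-RU
    SD alone (the constants are not a sampled city).

Every iteration draws, per RU: a triangular urban-area factor (default
-10%/+33% around the mode), a canopy-cover perturbation (default 0.2%,
relative), a rate from the class mixture (negative draws truncated at zero,
truncation rate logged), and a multiplicative model factor (normal, mean 1,
default uncertainty 20% read as a 95% half-width, the inventory convention)
shared across RUs by default, since a common model bias moves all RUs
together.  Products follow the Tier-2 gain equation
and are summed nationally; 2.5/97.5 empirical percentiles (linear
interpolation on order statistics) give the bounds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .accounting import build_account
from .densities import city_canopy_area
from .errors import ConfigurationError, UFCarbonError, ValidationError
from .types import (
    AccountingConfig,
    CityAssessment,
    DensityPair,
    PercentileBounds,
    RateDistribution,
    ReconciliationUnit,
    UncertaintyClass,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class UncertaintyConfig:
    """Monte-Carlo settings.

    canopy_uncertainty semantics: "relative" perturbs canopy cover by a
    fraction of itself; "absolute" perturbs the cover fraction by the stated
    amount in cover points.  The source survey states 0.2% without a formula,
    so both are supported.
    """

    iterations: int = 10_000
    seed: int = 0
    model_uncertainty: float = 0.20
    model_semantics: str = "ci95"  # "ci95" (half-width of a 95% CI) | "sd"
    canopy_uncertainty: float = 0.002
    canopy_semantics: str = "relative"  # "relative" | "absolute"
    area_lower_rel: float = -0.10
    area_upper_rel: float = 0.33
    percentiles: tuple[float, float] = (2.5, 97.5)
    shared_model_factor: bool = True
    sd_combination: str = "quadrature"  # "quadrature" | "additive"
    include_rate_uncertainty: bool = True
    f_net: float = 0.74

    def __post_init__(self):
        if self.iterations < 2:
            raise ValidationError("iterations must be >= 2")
        if not self.area_lower_rel <= 0 <= self.area_upper_rel:
            raise ValidationError("triangular bounds must bracket the mode")
        if self.canopy_semantics not in ("relative", "absolute"):
            raise ValidationError("canopy_semantics must be relative|absolute")
        if self.sd_combination not in ("quadrature", "additive"):
            raise ValidationError("sd_combination must be quadrature|additive")
        if self.model_semantics not in ("ci95", "sd"):
            raise ValidationError("model_semantics must be ci95|sd")

    @property
    def model_sd(self) -> float:
        """SD of the multiplicative model factor.

        Inventory practice states uncertainties as half-widths of 95%
        confidence intervals, so the default reading divides the stated
        model uncertainty by 1.96; ``model_semantics="sd"`` uses it directly.
        """
        if self.model_semantics == "ci95":
            return self.model_uncertainty / 1.959963984540054
        return self.model_uncertainty

    @property
    def triangular_mean_factor(self) -> float:
        a, b = 1.0 + self.area_lower_rel, 1.0 + self.area_upper_rel
        return (a + 1.0 + b) / 3.0


@dataclass(frozen=True)
class Variability:
    """Inter-city and inter-RU SDs in density units (storage, seq)."""

    inter_city_storage: float
    inter_city_seq: float
    inter_ru_storage: float
    inter_ru_seq: float
    reference_ru: int | None = None


def classify_ru(
    ru: ReconciliationUnit, cities: list[CityAssessment]
) -> tuple[UncertaintyClass, dict[str, float]]:
    """Class and covered/partial weights for one RU.

    The covered weight is the summed city assessment area over the RU urban
    area, capped at 1 (with a warning) when assessments exceed the urban
    area definition.
    """
    in_ru = [c for c in cities if c.ru_id == ru.ru_id]
    if not in_ru:
        return UncertaintyClass.PROXY, {"covered": 0.0, "partial": 0.0}
    covered = sum(c.assessment_area for c in in_ru) / ru.urban_area_ha
    if covered > 1.0:
        log.warning(
            "RU %d: city assessment area exceeds urban area "
            "(coverage %.2f capped at 1)",
            ru.ru_id,
            covered,
        )
        covered = 1.0
    if covered >= 1.0:
        return UncertaintyClass.CITY_COVERED, {"covered": 1.0, "partial": 0.0}
    return UncertaintyClass.PARTIAL, {"covered": covered, "partial": 1.0 - covered}


def _city_density(
    city: CityAssessment,
    ru: ReconciliationUnit,
    quantity: str,
) -> tuple[float, float | None]:
    """(mean, sd) of one city's rate in density units (sd None if no SE)."""
    at = city_canopy_area(city, ru)
    if at <= 0:
        raise UFCarbonError(f"{city.name}: zero canopy area")
    if quantity == "storage":
        total, se = city.carbon_storage_total, city.carbon_storage_se
    else:
        total, se = city.seq_gross_total, city.seq_gross_se
    return total / at, (None if se is None else se / at)


def compute_variability(
    cities: list[CityAssessment],
    rus: list[ReconciliationUnit],
    ru_densities: dict[int, DensityPair],
    reference_ru: int | None = None,
) -> Variability:
    """Inter-city SD (reference RU's cities) and inter-RU SD (all RUs).

    The reference RU defaults to the one containing the most assessed cities
    (the Mixedwood Plains RU in the national tables).  With fewer than two
    cities the inter-city SD is zero.
    """
    ru_by_id = {ru.ru_id: ru for ru in rus}
    if reference_ru is None:
        counts: dict[int, int] = {}
        for c in cities:
            counts[c.ru_id] = counts.get(c.ru_id, 0) + 1
        reference_ru = max(counts, key=counts.get) if counts else None

    def _sd(values):
        return float(np.std(values, ddof=1)) if len(values) >= 2 else 0.0

    ref_cities = [c for c in cities if c.ru_id == reference_ru]
    ic_storage = _sd(
        [_city_density(c, ru_by_id[c.ru_id], "storage")[0] for c in ref_cities]
    )
    ic_seq = _sd([_city_density(c, ru_by_id[c.ru_id], "seq")[0] for c in ref_cities])
    ir_storage = _sd([ru_densities[ru.ru_id].storage_density for ru in rus])
    ir_seq = _sd([ru_densities[ru.ru_id].seq_rate for ru in rus])
    return Variability(
        inter_city_storage=ic_storage,
        inter_city_seq=ic_seq,
        inter_ru_storage=ir_storage,
        inter_ru_seq=ir_seq,
        reference_ru=reference_ru,
    )


def _combine(sds: list[float], how: str) -> float:
    if how == "additive":
        return float(sum(sds))
    return math.sqrt(sum(s * s for s in sds))


def default_proxy_city(
    ru: ReconciliationUnit,
    cities: list[CityAssessment],
    rus: list[ReconciliationUnit],
    ru_densities: dict[int, DensityPair],
) -> list[CityAssessment]:
    """Representative proxy cities for a PROXY RU (may be empty for boreal).

    The proxy is the largest assessed city (by assessment area) in the RU's
    own ecozone when one exists; for ecozones whose density was copied from a
    donor ecozone, all donor cities pool into the proxy.  Forest-model RUs
    have no proxy city.
    """
    ru_by_id = {r.ru_id: r for r in rus}
    same_zone = [c for c in cities if ru_by_id[c.ru_id].ecozone == ru.ecozone]
    if same_zone:
        return [max(same_zone, key=lambda c: c.assessment_area)]
    pair = ru_densities[ru.ru_id]
    if pair.note.startswith("copied from"):
        donor = pair.note.removeprefix("copied from ").strip()
        donor_cities = [c for c in cities if ru_by_id[c.ru_id].ecozone == donor]
        return donor_cities
    return []


def build_rate_distribution(
    ru: ReconciliationUnit,
    quantity: str,
    cities: list[CityAssessment],
    rus: list[ReconciliationUnit],
    ru_densities: dict[int, DensityPair],
    variability: Variability,
    config: UncertaintyConfig = UncertaintyConfig(),
) -> RateDistribution:
    """Normal-mixture rate distribution for one RU and quantity.

    The mixture mean equals the RU's assigned density, so a zero-uncertainty
    run reproduces the deterministic account exactly.
    """
    if quantity not in ("storage", "seq"):
        raise UFCarbonError("quantity must be 'storage' or 'seq'")
    ru_by_id = {r.ru_id: r for r in rus}
    assigned = ru_densities[ru.ru_id]
    mean_assigned = (
        assigned.storage_density if quantity == "storage" else assigned.seq_rate
    )
    ic = (
        variability.inter_city_storage
        if quantity == "storage"
        else variability.inter_city_seq
    )
    ir = (
        variability.inter_ru_storage
        if quantity == "storage"
        else variability.inter_ru_seq
    )
    klass, weights = classify_ru(ru, cities)
    components: list[tuple[str, float, float, float]] = []

    if klass is UncertaintyClass.PROXY:
        proxies = default_proxy_city(ru, cities, rus, ru_densities)
        if proxies:
            ats = [city_canopy_area(c, ru_by_id[c.ru_id]) for c in proxies]
            total_at = sum(ats)
            ses = [
                (c.carbon_storage_se if quantity == "storage" else c.seq_gross_se)
                for c in proxies
            ]
            if any(se is None for se in ses):
                proxy_se = _combine([ic, ir], config.sd_combination)
            else:
                proxy_se = math.sqrt(sum(se * se for se in ses)) / total_at
            sd = _combine([proxy_se, ic, ir], config.sd_combination)
        else:
            # managed-forest model constants: no city SE, no inter-city term
            sd = ir
        components.append(("proxy", 1.0, mean_assigned, sd))
    else:
        in_ru = [c for c in cities if c.ru_id == ru.ru_id]
        covered_w = weights["covered"]
        areas = [c.assessment_area for c in in_ru]
        total_area = sum(areas)
        for c, a in zip(in_ru, areas):
            m, sd_c = _city_density(c, ru_by_id[c.ru_id], quantity)
            if sd_c is None:
                sd_c = _combine([ic, ir], config.sd_combination)
            components.append((c.name, covered_w * a / total_area, m, sd_c))
        if weights["partial"] > 0:
            components.append(("partial", weights["partial"], mean_assigned, ic))
    dist = RateDistribution(
        ru_id=ru.ru_id,
        quantity=quantity,
        uncertainty_class=klass,
        components=components,
    )
    if not config.include_rate_uncertainty:
        dist.components = [(l, w, m, 0.0) for l, w, m, s in dist.components]
    return dist


@dataclass
class MonteCarloResult:
    """Percentile bounds per RU and nationally, plus diagnostics."""

    per_ru: dict[int, dict[str, PercentileBounds]]
    national: dict[str, PercentileBounds]
    truncation_rate: float
    config: UncertaintyConfig
    classes: dict[int, UncertaintyClass] = field(default_factory=dict)


_QUANTITIES = ("storage", "seq_gross", "seq_net", "co2_net")


def _draw_mixture(
    rng: np.random.Generator,
    dist: RateDistribution,
    n: int,
) -> tuple[np.ndarray, int]:
    """Weighted mixture draw (component sum), negatives truncated at 0."""
    out = np.zeros(n)
    truncated = 0
    for _, w, m, sd in dist.components:
        draws = rng.normal(m, sd, size=n) if sd > 0 else np.full(n, m)
        neg = draws < 0
        truncated += int(neg.sum())
        draws[neg] = 0.0
        out += w * draws
    return out, truncated


def run_monte_carlo(
    rus: list[ReconciliationUnit],
    cities: list[CityAssessment],
    ru_densities: dict[int, DensityPair],
    config: UncertaintyConfig = UncertaintyConfig(),
    variability: Variability | None = None,
) -> MonteCarloResult:
    """Propagate area, canopy, rate, and model uncertainty to bounds.

    Reproducible bit-for-bit for a fixed config (single numpy Generator,
    fixed draw order).
    """
    if variability is None:
        variability = compute_variability(cities, rus, ru_densities)
    missing = [ru.ru_id for ru in rus if ru.ru_id not in ru_densities]
    if missing:
        raise ConfigurationError(f"no density for RU(s) {missing}")

    n = config.iterations
    n_ru = len(rus)
    rng = np.random.default_rng(config.seed)
    acc_cfg = AccountingConfig(f_net=config.f_net)
    det_accounts, det_national = build_account(rus, ru_densities, acc_cfg)
    det_by_id = {a.ru_id: a for a in det_accounts}

    # area factors (triangular), canopy factors, model factors
    lo, hi = 1.0 + config.area_lower_rel, 1.0 + config.area_upper_rel
    if hi > lo:
        area_f = rng.triangular(lo, 1.0, hi, size=(n, n_ru))
    else:
        area_f = np.ones((n, n_ru))
    u = config.canopy_uncertainty
    if u > 0:
        if config.canopy_semantics == "relative":
            canopy_f = 1.0 + rng.normal(0.0, u, size=(n, n_ru))
        else:
            cf = np.array([ru.canopy_fraction for ru in rus])
            canopy_f = 1.0 + rng.normal(0.0, u, size=(n, n_ru)) / cf
        canopy_f = np.clip(canopy_f, 0.0, None)
    else:
        canopy_f = np.ones((n, n_ru))
    if config.model_sd > 0:
        if config.shared_model_factor:
            model_f = rng.normal(1.0, config.model_sd, size=(n, 1))
            model_f = np.broadcast_to(model_f, (n, n_ru))
        else:
            model_f = rng.normal(1.0, config.model_sd, size=(n, n_ru))
        model_f = np.clip(model_f, 0.0, None)
    else:
        model_f = np.ones((n, n_ru))

    storage_draws = np.empty((n, n_ru))
    gross_draws = np.empty((n, n_ru))
    truncated = 0
    total_rate_draws = 0
    classes = {}
    for j, ru in enumerate(rus):
        base = ru.canopy_area_ha / 1000.0  # kt per (t/ha)
        for quantity, target in (("storage", storage_draws), ("seq", gross_draws)):
            dist = build_rate_distribution(
                ru, quantity, cities, rus, ru_densities, variability, config
            )
            classes[ru.ru_id] = dist.uncertainty_class
            rates, n_trunc = _draw_mixture(rng, dist, n)
            truncated += n_trunc
            total_rate_draws += n * len(dist.components)
            target[:, j] = base * area_f[:, j] * canopy_f[:, j] * model_f[:, j] * rates

    lo_p, hi_p = config.percentiles

    def _bounds(draws: np.ndarray, det: float) -> PercentileBounds:
        return PercentileBounds(
            mean=float(draws.mean()),
            p2_5=float(np.percentile(draws, lo_p)),
            p97_5=float(np.percentile(draws, hi_p)),
            deterministic=det,
        )

    per_ru: dict[int, dict[str, PercentileBounds]] = {}
    for j, ru in enumerate(rus):
        det = det_by_id[ru.ru_id]
        per_ru[ru.ru_id] = {
            "storage": _bounds(storage_draws[:, j], det.storage),
            "seq_gross": _bounds(gross_draws[:, j], det.seq_gross),
            "seq_net": _bounds(config.f_net * gross_draws[:, j], det.seq_net),
            "co2_net": _bounds(
                config.f_net * (44.0 / 12.0) * gross_draws[:, j], det.co2_net
            ),
        }
    nat_storage = storage_draws.sum(axis=1)
    nat_gross = gross_draws.sum(axis=1)
    national = {
        "storage": _bounds(nat_storage, det_national.storage),
        "seq_gross": _bounds(nat_gross, det_national.seq_gross),
        "seq_net": _bounds(config.f_net * nat_gross, det_national.seq_net),
        "co2_net": _bounds(
            config.f_net * (44.0 / 12.0) * nat_gross, det_national.co2_net
        ),
    }
    trunc_rate = truncated / total_rate_draws if total_rate_draws else 0.0
    if trunc_rate > 0:
        log.info("negative rate draws truncated at zero: %.3f%%", 100 * trunc_rate)
    return MonteCarloResult(
        per_ru=per_ru,
        national=national,
        truncation_rate=trunc_rate,
        config=config,
        classes=classes,
    )


def zeroed(config: UncertaintyConfig) -> UncertaintyConfig:
    """A copy of ``config`` with every uncertainty source switched off."""
    return replace(
        config,
        model_uncertainty=0.0,
        canopy_uncertainty=0.0,
        area_lower_rel=0.0,
        area_upper_rel=0.0,
        include_rate_uncertainty=False,
    )
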