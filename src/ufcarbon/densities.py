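"""Derive ecozone carbon densities from city assessments and assign them to RUs.

A city's canopy area is its assessment area times the canopy fraction of the
reconciliation unit that contains it (or the city's own satellite-based
override).  Cities within an ecozone are pooled canopy-area-weighted:

    storage_density = sum(storage totals) / sum(city canopy areas)
    seq_rate        = sum(gross seq totals) / sum(city canopy areas)

which is the ratio estimator a stratified inventory uses; the unweighted mean
of per-city densities is available for sensitivity analysis.  Ecozones without
local data receive densities via rules: copy a neighbouring ecozone (Semiarid
<- Subhumid Prairies) or use managed-forest model constants (boreal ecozones,
40.0 t C/ha and 3.0 t C/ha/yr).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError, UFCarbonError
from .types import CityAssessment, DensityPair, DensitySource, ReconciliationUnit


@dataclass
class EcozoneDensityMap:
    """Carbon densities per ecozone with provenance notes."""

    densities: dict[str, DensityPair] = field(default_factory=dict)
    notes: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, ecozone: str) -> DensityPair:
        return self.densities[ecozone]

    def __contains__(self, ecozone: str) -> bool:
        return ecozone in self.densities

    def items(self):
        return self.densities.items()


def city_canopy_area(
    city: CityAssessment, ru: ReconciliationUnit | None = None
) -> float:
    """Canopy area (ha) of a city assessment.

    Uses the city's own canopy override when present, otherwise the canopy
    fraction of its reconciliation unit.
    """
    if city.canopy_area_override is not None:
        return city.canopy_area_override
    if ru is None:
        raise UFCarbonError(
            f"{city.name}: no reconciliation unit and no canopy override"
        )
    return city.assessment_area * ru.canopy_fraction


def pool_ecozone_density(
    cities: list[CityAssessment],
    ru_lookup: dict[int, ReconciliationUnit],
    *,
    method: str = "weighted",
) -> DensityPair:
    """Pool cities of one ecozone into a single density pair.

    ``method="weighted"`` (default) is canopy-area-weighted pooling;
    ``"unweighted"`` averages per-city densities.
    """
    if not cities:
        raise UFCarbonError("cannot pool an empty list of cities")
    areas = [city_canopy_area(c, ru_lookup.get(c.ru_id)) for c in cities]
    total_canopy = sum(areas)
    if total_canopy <= 0:
        raise UFCarbonError("pooled canopy area is zero")
    source = (
        DensitySource.PROXY_CITY
        if any(c.external for c in cities)
        else DensitySource.POOLED
    )
    if method == "weighted":
        storage = sum(c.carbon_storage_total for c in cities) / total_canopy
        seq = sum(c.seq_gross_total for c in cities) / total_canopy
    elif method == "unweighted":
        n = len(cities)
        storage = sum(c.carbon_storage_total / a for c, a in zip(cities, areas)) / n
        seq = sum(c.seq_gross_total / a for c, a in zip(cities, areas)) / n
    else:
        raise UFCarbonError(f"unknown pooling method {method!r}")
    return DensityPair(storage_density=storage, seq_rate=seq, source=source)


def derive_ecozone_densities(
    cities: list[CityAssessment],
    rus: list[ReconciliationUnit],
    rules: dict[str, dict],
    *,
    method: str = "weighted",
) -> EcozoneDensityMap:
    """Build the full ecozone density map: pooled values plus rule-based fills."""
    ru_lookup = {ru.ru_id: ru for ru in rus}
    by_ecozone: dict[str, list[CityAssessment]] = {}
    for city in cities:
        ru = ru_lookup.get(city.ru_id)
        if ru is None:
            raise ConfigurationError(
                f"{city.name}: ru_id {city.ru_id} not in the RU table"
            )
        by_ecozone.setdefault(ru.ecozone, []).append(city)

    out = EcozoneDensityMap()
    for ecozone, zone_cities in by_ecozone.items():
        pair = pool_ecozone_density(zone_cities, ru_lookup, method=method)
        out.densities[ecozone] = pair
        names = ", ".join(c.name for c in zone_cities)
        out.notes[ecozone] = (
            f"derived from external surrogate: {names}"
            if pair.source is DensitySource.PROXY_CITY
            else f"pooled from {names}"
        )

    # rule-based fills for ecozones without local data
    for ecozone, rule in rules.items():
        if ecozone in out:
            continue
        src = rule["source"]
        if src == "forest_model":
            out.densities[ecozone] = DensityPair(
                storage_density=rule["storage_density"],
                seq_rate=rule["seq_rate"],
                source=DensitySource.FOREST_MODEL,
                note="managed-forest model constants",
            )
            out.notes[ecozone] = "managed-forest model constants"
        elif src == "proxy_ecozone":
            donor = rule["proxy_ecozone"]
            if donor not in out:
                raise ConfigurationError(
                    f"{ecozone}: donor ecozone {donor!r} has no density"
                )
            d = out.densities[donor]
            out.densities[ecozone] = DensityPair(
                storage_density=d.storage_density,
                seq_rate=d.seq_rate,
                source=DensitySource.PROXY_CITY,
                note=f"copied from {donor}",
            )
            out.notes[ecozone] = f"copied from {donor}"
    return out


def assign_ru_densities(
    ecozone_map: EcozoneDensityMap | dict[str, DensityPair],
    rus: list[ReconciliationUnit],
) -> dict[int, DensityPair]:
    """Map every RU to its ecozone density; fail loudly on gaps."""
    densities = (
        ecozone_map.densities
        if isinstance(ecozone_map, EcozoneDensityMap)
        else ecozone_map
    )
    missing = [ru.ru_id for ru in rus if ru.ecozone not in densities]
    if missing:
        raise ConfigurationError(
            "no density rule covers RU(s) "
            + ", ".join(str(i) for i in sorted(missing))
        )
    return {ru.ru_id: densities[ru.ecozone] for ru in rus}
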