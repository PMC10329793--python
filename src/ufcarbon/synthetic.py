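"""Synthetic worlds with known ground truth for end-to-end testing.

The generator emulates the statistical structure of the national assessment
inputs: per-ecozone true carbon densities, per-RU canopy fractions, city
assessment summaries whose totals carry plot-sampling noise (relative SD
``cv/sqrt(n_plots)``) with the generating SD recorded as the published SE,
and boolean canopy rasters with a recorded realized cover fraction.

Defaults mirror the national study conditions: the 18-RU stratification with
its urban areas and canopy fractions, true densities equal to the derived
ecozone values, and a plot-noise coefficient of variation of 0.05 (the
fixture city SEs are 4-13% of their totals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .canopy import CANOPY, OTHER_URBAN, LandcoverGrid
from .densities import derive_ecozone_densities
from .errors import UFCarbonError
from .tables import load_city_table, load_ecozone_rules, load_ru_table
from .types import CityAssessment, DensityPair, ReconciliationUnit


@dataclass
class SyntheticWorld:
    """Ground truth: densities per ecozone, canopy fractions per RU."""

    rus: list[ReconciliationUnit]
    true_densities: dict[str, DensityPair]  # ecozone -> truth
    cv: float = 0.05  # plot-level noise, relative
    seed: int = 0
    noise: str = "normal"  # "normal" (truncated) | "lognormal"
    _rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self):
        if any(
            d.storage_density <= 0 or d.seq_rate <= 0
            for d in self.true_densities.values()
        ):
            raise UFCarbonError("true densities must be positive")
        self._rng = np.random.default_rng(self.seed)

    def ru_density(self, ru: ReconciliationUnit) -> DensityPair:
        return self.true_densities[ru.ecozone]


def make_world(seed: int = 0, cv: float = 0.05, noise: str = "normal") -> SyntheticWorld:
    """Default world: the national stratification with derived true densities."""
    rus = load_ru_table()
    cities = load_city_table()
    rules = load_ecozone_rules()
    zone_map = derive_ecozone_densities(cities, rus, rules)
    return SyntheticWorld(
        rus=rus, true_densities=dict(zone_map.densities), cv=cv, seed=seed, noise=noise
    )


def _noisy_total(
    rng: np.random.Generator, truth: float, rel_sd: float, noise: str
) -> float:
    if rel_sd == 0:
        return truth
    if noise == "lognormal":
        sigma = np.sqrt(np.log1p(rel_sd**2))
        return float(truth * rng.lognormal(-sigma**2 / 2.0, sigma))
    return float(max(0.0, truth * (1.0 + rng.normal(0.0, rel_sd))))


def generate_city(
    world: SyntheticWorld,
    ru: ReconciliationUnit,
    area_ha: float,
    n_plots: int,
    name: str | None = None,
    seed: int | None = None,
) -> CityAssessment:
    """One synthetic city assessment with truth-derived totals and SEs.

    The generating relative SD is ``cv / sqrt(n_plots)``; the reported SE is
    exactly that SD times the true total, mirroring how plot-sampling SEs
    accompany published totals.
    """
    if area_ha <= 0:
        raise UFCarbonError("area must be > 0")
    if n_plots < 1:
        raise UFCarbonError("n_plots must be >= 1")
    rng = world._rng if seed is None else np.random.default_rng(seed)
    truth = world.ru_density(ru)
    canopy_ha = area_ha * ru.canopy_fraction
    rel_sd = world.cv / np.sqrt(n_plots)
    storage_true = canopy_ha * truth.storage_density
    seq_true = canopy_ha * truth.seq_rate
    return CityAssessment(
        name=name or f"synth-{ru.ru_id}-{n_plots}",
        ru_id=ru.ru_id,
        assessment_area=area_ha,
        n_plots=n_plots,
        carbon_storage_total=_noisy_total(rng, storage_true, rel_sd, world.noise),
        carbon_storage_se=storage_true * rel_sd,
        seq_gross_total=_noisy_total(rng, seq_true, rel_sd, world.noise),
        seq_gross_se=seq_true * rel_sd,
    )


def generate_cities(
    world: SyntheticWorld,
    n_cities: int = 20,
    area_ha: float = 20_000.0,
    n_plots: int = 200,
) -> list[CityAssessment]:
    """Cities cycled across the world's RUs (each RU gets >= 1 as n grows)."""
    out = []
    for i in range(n_cities):
        ru = world.rus[i % len(world.rus)]
        out.append(
            generate_city(world, ru, area_ha, n_plots, name=f"synth-{i}-{ru.name}")
        )
    return out


def generate_raster(
    true_fraction: float,
    extent: tuple[int, int] = (500, 500),
    seed: int | None = None,
    resolution: float = 10.0,
    clustering: float = 0.0,
) -> tuple[LandcoverGrid, float]:
    """Boolean canopy raster (all-urban) with known realized cover.

    ``clustering=0`` draws pixelwise Bernoulli canopy; ``clustering > 0``
    smooths a noise field over that radius (pixels) and thresholds it at the
    exact count quantile, producing spatial blotches with the same marginal
    fraction but higher cell-level variance.  Returns the grid and the
    realized canopy fraction (the usable ground truth).
    """
    if not 0.0 <= true_fraction <= 1.0:
        raise UFCarbonError("true_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if clustering > 0:
        fieldv = ndimage.uniform_filter(
            rng.standard_normal(extent), size=int(2 * clustering + 1), mode="wrap"
        )
        k = int(round(true_fraction * fieldv.size))
        mask = np.zeros(extent, dtype=bool)
        if k > 0:
            thresh = np.partition(fieldv.ravel(), -k)[-k]
            mask = fieldv >= thresh
            # resolve threshold ties to hit the count exactly
            excess = int(mask.sum()) - k
            if excess > 0:
                ties = np.flatnonzero((fieldv == thresh).ravel())[:excess]
                mask.ravel()[ties] = False
    else:
        mask = rng.random(extent) < true_fraction
    data = np.where(mask, CANOPY, OTHER_URBAN)
    grid = LandcoverGrid(data=data, resolution=resolution)
    return grid, float(mask.mean())
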