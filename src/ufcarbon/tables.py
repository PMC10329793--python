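"""Readers and writers for the assessment tables.

The package ships four small CSV fixtures under ``_fixtures/``:

``ru_table.csv``
    The 18 reconciliation units (province x ecozone strata) with urban area,
    canopy area (km2) and canopy cover (%).
``city_table.csv``
    The 17 city assessment summaries (16 Canadian cities plus the external
    Seattle surrogate): assessment area (ha), plot count, total carbon
    storage and gross sequestration with plot-sampling standard errors.
    Seattle's SE columns are empty (not published) and its
    ``canopy_area_override_ha`` is back-calculated from the published RU-level
    results, since its satellite canopy estimate itself was never printed.
``ecozone_map.csv``
    How each of the nine urban ecozones obtains its carbon density: pooled
    from local city data, copied from a neighbouring ecozone, or fixed
    managed-forest model constants.
``table4_densities.csv``
    The published ecozone densities at printed (1-decimal) precision, for
    strict table replication.
``baseline.csv``
    The previous fixed-rate baseline (76.9 t C/ha; 2.12 t C/ha/yr).

Loaders validate schema and values and raise :class:`TableParseError` /
:class:`ValidationError` rather than returning partial results.  The
printed-value canopy consistency check (canopy_area/urban_area vs the printed
cover) is logged as a warning, because printed table values are rounded.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import TableParseError
from .types import (
    BaselineRates,
    CityAssessment,
    DensityPair,
    DensitySource,
    ReconciliationUnit,
)

log = logging.getLogger(__name__)

_FIXTURES = resources.files("ufcarbon") / "_fixtures"


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture CSV."""
    return Path(str(_FIXTURES / name))


def _read_csv(path, required: list[str], numeric: list[str], label: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise TableParseError(f"{label}: file is empty") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableParseError(f"{label}: missing column(s) {missing}")
    if df.empty:
        raise TableParseError(f"{label}: no data rows")
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise TableParseError(
                f"{label}: non-numeric cell {df.loc[bad[0], col]!r}",
                row=int(bad[0]),
                column=col,
            )
        df[col] = coerced
    return df


_RU_COLUMNS = [
    "ru_id",
    "name",
    "ecozone",
    "ru_area_km2",
    "urban_area_km2",
    "canopy_area_km2",
    "canopy_cover_pct",
]


def load_ru_table(path=None) -> list[ReconciliationUnit]:
    """Load reconciliation units from ``path`` (default: packaged fixture)."""
    src = path if path is not None else fixture_path("ru_table.csv")
    numeric = [c for c in _RU_COLUMNS if c.endswith(("_km2", "_pct", "_id"))]
    df = _read_csv(src, _RU_COLUMNS, numeric, "RU table")
    dup = df["ru_id"][df["ru_id"].duplicated()]
    if len(dup):
        raise TableParseError(
            f"RU table: duplicate ru_id {int(dup.iloc[0])}", column="ru_id"
        )
    units = []
    for _, row in df.iterrows():
        ru = ReconciliationUnit(
            ru_id=int(row["ru_id"]),
            name=str(row["name"]),
            ecozone=str(row["ecozone"]),
            ru_area=float(row["ru_area_km2"]),
            urban_area=float(row["urban_area_km2"]),
            canopy_area=float(row["canopy_area_km2"]),
            canopy_fraction=float(row["canopy_cover_pct"]) / 100.0,
        )
        if not ru.canopy_consistent():
            log.warning(
                "RU %d (%s): canopy_area/urban_area = %.4f differs from printed "
                "cover %.3f by more than %.3f (rounded source values)",
                ru.ru_id,
                ru.name,
                ru.canopy_area / ru.urban_area,
                ru.canopy_fraction,
                ru.CONSISTENCY_SLACK,
            )
        units.append(ru)
    return units


_CITY_COLUMNS = [
    "city",
    "ru_id",
    "external",
    "assessment_area_ha",
    "n_plots",
    "carbon_storage_t",
    "carbon_storage_se_t",
    "seq_gross_t_yr",
    "seq_gross_se_t_yr",
    "canopy_area_override_ha",
]


def load_city_table(path=None) -> list[CityAssessment]:
    """Load city assessment summaries (default: packaged fixture).

    Missing standard errors are recorded as absent (``None``), never as zero.
    """
    src = path if path is not None else fixture_path("city_table.csv")
    numeric = [
        "ru_id",
        "assessment_area_ha",
        "n_plots",
        "carbon_storage_t",
        "carbon_storage_se_t",
        "seq_gross_t_yr",
        "seq_gross_se_t_yr",
        "canopy_area_override_ha",
    ]
    df = _read_csv(src, _CITY_COLUMNS, numeric, "city table")

    def _opt(v):
        return None if pd.isna(v) else float(v)

    cities = []
    for _, row in df.iterrows():
        cities.append(
            CityAssessment(
                name=str(row["city"]),
                ru_id=None if pd.isna(row["ru_id"]) else int(row["ru_id"]),
                assessment_area=float(row["assessment_area_ha"]),
                n_plots=int(row["n_plots"]),
                carbon_storage_total=float(row["carbon_storage_t"]),
                carbon_storage_se=_opt(row["carbon_storage_se_t"]),
                seq_gross_total=float(row["seq_gross_t_yr"]),
                seq_gross_se=_opt(row["seq_gross_se_t_yr"]),
                external=bool(row["external"]),
                canopy_area_override=_opt(row["canopy_area_override_ha"]),
            )
        )
    return cities


def load_ecozone_rules(path=None) -> dict[str, dict]:
    """Load the ecozone density-source rules (default: packaged fixture)."""
    src = path if path is not None else fixture_path("ecozone_map.csv")
    df = _read_csv(
        src, ["ecozone", "source"], ["storage_density", "seq_rate"], "ecozone map"
    )
    rules = {}
    for _, row in df.iterrows():
        rule = {"source": str(row["source"])}
        if not pd.isna(row.get("proxy_ecozone")):
            rule["proxy_ecozone"] = str(row["proxy_ecozone"])
        if not pd.isna(row["storage_density"]):
            rule["storage_density"] = float(row["storage_density"])
            rule["seq_rate"] = float(row["seq_rate"])
        rules[str(row["ecozone"])] = rule
    return rules


def load_printed_densities(path=None) -> dict[str, DensityPair]:
    """Published ecozone densities at printed precision (strict replication)."""
    src = path if path is not None else fixture_path("table4_densities.csv")
    df = _read_csv(
        src, ["ecozone", "storage_density", "seq_rate"],
        ["storage_density", "seq_rate"], "printed densities",
    )
    out = {}
    for _, row in df.iterrows():
        out[str(row["ecozone"])] = DensityPair(
            storage_density=float(row["storage_density"]),
            seq_rate=float(row["seq_rate"]),
            source=DensitySource(str(row.get("source", "pooled"))),
            note=str(row["note"]) if not pd.isna(row.get("note")) else "",
        )
    return out


def load_baseline(path=None) -> BaselineRates:
    """Fixed-rate baseline densities (default: packaged fixture)."""
    src = path if path is not None else fixture_path("baseline.csv")
    df = _read_csv(
        src,
        ["storage_density_t_ha", "seq_rate_t_ha_yr"],
        ["storage_density_t_ha", "seq_rate_t_ha_yr"],
        "baseline",
    )
    row = df.iloc[0]
    return BaselineRates(
        storage_density=float(row["storage_density_t_ha"]),
        seq_rate=float(row["seq_rate_t_ha_yr"]),
    )
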