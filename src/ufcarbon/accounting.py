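"""Tier-2 gain-method carbon accounting per reconciliation unit.

The annual gain attributed to biomass increment is the product of activity
data and a country-specific rate: flux = canopy area (ha) x carbon rate per
unit canopy.  Applied with a stock density it yields the standing stock; with
a gross sequestration rate, the annual gross uptake.  Net sequestration nets
out biomass-decay emissions as a fixed fraction of gross (default 0.74) and
CO2 removals convert by the exact mass ratio 44/12.  National totals are the
exact column sums over RUs.  A fixed-rate baseline comparison reproduces the
difference against the previous single-density national assessment.
"""

from __future__ import annotations

import pandas as pd

from .errors import ConfigurationError, ValidationError
from .types import (
    AccountingConfig,
    BaselineRates,
    CarbonAccount,
    DensityPair,
    ReconciliationUnit,
)


def tier2_flux(canopy_area_ha: float, crw: float) -> float:
    """Gain-equation product, reported in kt (t C = ha x t/ha, then /1000).

    ``crw`` is a carbon rate per unit crown cover: a stock density (t C/ha)
    gives a stock in kt C, a gross rate (t C/ha/yr) gives a flux in kt C/yr.
    """
    if canopy_area_ha < 0:
        raise ValidationError("canopy area must be >= 0")
    if crw <= 0:
        raise ValidationError("carbon rate must be > 0")
    return canopy_area_ha * crw / 1000.0


def net_and_co2(
    gross: float, config: AccountingConfig = AccountingConfig()
) -> tuple[float, float]:
    """Net sequestration and CO2 removals from a gross flux (kt)."""
    if gross < 0:
        raise ValidationError("gross flux must be >= 0")
    net = config.f_net * gross
    return net, net * config.co2_ratio


def build_account(
    rus: list[ReconciliationUnit],
    ru_densities: dict[int, DensityPair],
    config: AccountingConfig = AccountingConfig(),
) -> tuple[list[CarbonAccount], CarbonAccount]:
    """Per-RU accounts plus the national total (exact column sum)."""
    accounts = []
    for ru in rus:
        try:
            d = ru_densities[ru.ru_id]
        except KeyError:
            raise ConfigurationError(f"no density for RU {ru.ru_id}") from None
        storage = tier2_flux(ru.canopy_area_ha, d.storage_density)
        gross = tier2_flux(ru.canopy_area_ha, d.seq_rate)
        net, co2 = net_and_co2(gross, config)
        accounts.append(
            CarbonAccount(
                ru_id=ru.ru_id,
                name=ru.name,
                storage=storage,
                seq_gross=gross,
                seq_net=net,
                co2_net=co2,
            )
        )
    national = CarbonAccount(
        ru_id=None,
        name="Canada",
        storage=sum(a.storage for a in accounts),
        seq_gross=sum(a.seq_gross for a in accounts),
        seq_net=sum(a.seq_net for a in accounts),
        co2_net=sum(a.co2_net for a in accounts),
    )
    return accounts, national


def baseline_comparison(
    rus: list[ReconciliationUnit],
    accounts: list[CarbonAccount],
    baseline: BaselineRates = BaselineRates(),
    config: AccountingConfig = AccountingConfig(),
) -> pd.DataFrame:
    """Differences (this assessment minus fixed-rate baseline), kt, per RU.

    The baseline applies one national stock density and gross rate to every
    RU's canopy area, with the same net and CO2 conversions.  Negative values
    mean this assessment is lower than the baseline.  The last row is the
    national total.
    """
    ru_by_id = {ru.ru_id: ru for ru in rus}
    rows = []
    for acc in accounts:
        ru = ru_by_id[acc.ru_id]
        base_storage = tier2_flux(ru.canopy_area_ha, baseline.storage_density)
        base_gross = tier2_flux(ru.canopy_area_ha, baseline.seq_rate)
        base_net, base_co2 = net_and_co2(base_gross, config)
        rows.append(
            {
                "ru_id": acc.ru_id,
                "name": acc.name,
                "d_storage": acc.storage - base_storage,
                "d_seq_gross": acc.seq_gross - base_gross,
                "d_seq_net": acc.seq_net - base_net,
                "d_co2_net": acc.co2_net - base_co2,
            }
        )
    df = pd.DataFrame(rows)
    cols = ["d_storage", "d_seq_gross", "d_seq_net", "d_co2_net"]
    total = pd.DataFrame([{"ru_id": pd.NA, "name": "Canada", **df[cols].sum()}])
    return pd.concat([df, total], ignore_index=True)


def account_frame(
    accounts: list[CarbonAccount],
    national: CarbonAccount,
    config: AccountingConfig = AccountingConfig(),
    *,
    rounded: bool = True,
) -> pd.DataFrame:
    """Tabular view of the account (kt, rounded at report time only)."""
    rows = [
        {
            "ru_id": a.ru_id,
            "name": a.name,
            "storage_kt": a.storage,
            "seq_gross_kt": a.seq_gross,
            "seq_net_kt": a.seq_net,
            "co2_net_kt": a.co2_net,
        }
        for a in [*accounts, national]
    ]
    df = pd.DataFrame(rows)
    df["ru_id"] = pd.array(df["ru_id"], dtype="Int64")
    if rounded:
        num = df.columns.drop(["ru_id", "name"])
        df[num] = df[num].round(config.report_precision)
    return df
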