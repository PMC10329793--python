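# ufcarbon

National urban-forest carbon accounting for greenhouse-gas inventories.

Urban trees are a managed carbon pool, but unlike commercial forests they
lack a coordinated national inventory. `ufcarbon` implements the assessment
procedure used to update the urban-forest portion of a national GHG
inventory's Settlements category: it turns a handful of city-level,
plot-based urban forest assessments (totals with sampling standard errors)
into regional carbon densities, scales them to province × ecozone strata
("reconciliation units", RUs) through canopy cover, and attaches a
Monte-Carlo uncertainty to every number it reports.

The package is aimed at inventory compilers and urban-forest researchers who
need the full chain — canopy sampling, density derivation, Tier-2
accounting, baseline comparison, uncertainty propagation — as tested,
reproducible code rather than a spreadsheet.

## Method

The core is the IPCC Tier-2 gain equation

    ΔC_G = A_T × C_RW

where `A_T` is the canopy cover area (ha) of a stratum and `C_RW` a carbon
rate per unit crown cover: a stock density (t C ha⁻¹) yields the standing
stock, a gross sequestration rate (t C ha⁻¹ yr⁻¹) the annual gross uptake.
Rates are derived per ecozone by canopy-area-weighted pooling of city
assessments,

    C_RW = Σ_c carbon_c / Σ_c (area_c × canopy_fraction_RU(c)),

with documented proxy rules for ecozones without local data (a surrogate
city for the temperate-rainforest coast, a neighbouring prairie ecozone for
the semiarid prairies, managed-forest model constants for boreal strata).
Net sequestration is a fixed fraction of gross (default 0.74, biomass-decay
emissions netted out) and CO₂ removals convert by exactly 44/12.

Uncertainty follows a three-class Monte Carlo: city-covered urban area uses
the published plot-sampling SEs; the remainder of assessed strata adds
inter-city variability; unassessed strata combine a proxy city's SE with
inter-city and inter-RU variability in quadrature. Urban-area activity data
get a triangular distribution (−10 %, mode, +33 %), canopy cover a 0.2 %
perturbation, and the assessment model a shared multiplicative factor with a
20 % uncertainty (read, per inventory convention, as a 95 % half-width).

A point-grid canopy sampler (1-km² cells, 25 % cell sampling, 55 evenly
spaced points per cell, urban-fraction and cloud QC rules) and a
synthetic-data generator (city assessments with known true densities,
landcover rasters with known cover) make every stage testable offline.

## Worked example

Derive ecozone densities from the packaged city table:

```sh
$ ufcarbon densities
ecozone,storage_density_t_ha,seq_rate_t_ha_yr,source,provenance
Atlantic maritime,61.6,3.4,pooled,pooled from Halifax
Mixedwood plains,57.8,2.4,pooled,"pooled from Ajax, Aurora, ..., Toronto"
Montane cordillera,22.6,1.4,pooled,pooled from Kelowna
Subhumid prairies,55.1,2.9,pooled,"pooled from Calgary, Edmonton"
Pacific maritime,97.3,6.9,proxy_city,derived from external surrogate: Seattle
Boreal plains,40.0,3.0,forest_model,managed-forest model constants
Semiarid prairies,55.1,2.9,proxy_city,copied from Subhumid prairies
...
```

Each row is carbon per hectare of tree cover: e.g. Atlantic-maritime urban
canopy holds 61.6 t C ha⁻¹ and takes up 3.4 t C ha⁻¹ yr⁻¹ gross.

Build the national account (here with the published 1-decimal densities):

```sh
$ ufcarbon account --use-printed-densities
ru_id,name,storage_kt,seq_gross_kt,seq_net_kt,co2_net_kt
1,BC Pacific maritime,7460.8,528.5,391.1,1434.1
2,BC Montane cordillera,307.4,19.0,14.1,51.7
...
,Canada,27294.0,1490.9,1103.3,4045.3
```

The national row says the assessed urban forest stores ≈27.3 Mt C and
sequesters ≈1.49 Mt C yr⁻¹ gross (≈1.10 Mt net, ≈4.05 Mt CO₂). The same
command also prints the difference against the previous fixed-rate baseline
(76.9 t C ha⁻¹; 2.12 t C ha⁻¹ yr⁻¹): storage comes out ≈6.7 Mt C *lower*
and gross sequestration ≈0.56 Mt C yr⁻¹ *higher* than the old national
constants implied.

Attach uncertainty bounds:

```sh
$ ufcarbon uncertainty --iterations 10000 --seed 1 | grep Canada
Canada,storage,29629.1678,19013.8855,42361.7177,-0.3583,0.4297
Canada,seq_gross,1620.6831,1131.0507,2207.2631,-0.3021,0.3619
...
```

Columns are mean, 2.5th and 97.5th percentile, and the relative deviations
of the percentiles from the mean: national gross sequestration carries
roughly (−30 %, +36 %) uncertainty at the default configuration. (The mean
sits above the deterministic account because the urban-area triangular
distribution is right-skewed: known urban area outside the analysed centres
can only add area.)

## Layout

- `src/ufcarbon/tables.py` — packaged fixture tables and validated loaders
- `src/ufcarbon/canopy.py` — point-grid canopy sampler with QC rules
- `src/ufcarbon/densities.py` — ecozone density derivation and proxy rules
- `src/ufcarbon/accounting.py` — Tier-2 account and baseline comparison
- `src/ufcarbon/uncertainty.py` — three-class Monte Carlo
- `src/ufcarbon/synthetic.py` — ground-truth generators
- `docs/methods.md` — model description, assumptions, and design choices
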