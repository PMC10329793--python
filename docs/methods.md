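# Methods

## Scope and data model

`ufcarbon` computes urban-forest carbon storage and gross/net sequestration
for a country stratified into reconciliation units (RUs, the intersection of
an ecozone with a provincial boundary; 18 such strata contain urban area in
the packaged tables). Inputs are (a) an RU table with urban area, canopy
area and canopy cover per stratum, (b) a table of city-level plot-based
assessment summaries — assessment area, plot count, total carbon storage and
gross sequestration with plot-sampling standard errors — and (c) a rule map
saying how each ecozone obtains its carbon density. City assessments are
consumed as published summaries; the plot-level assessment model that
produced them (allometry, growth adjustment, biomass-to-carbon factors) is
upstream of this package and out of scope.

The packaged city table includes one external surrogate city for the
temperate-rainforest coastal ecozone, whose published summary lacks standard
errors and whose canopy area comes from its own satellite estimate. That
canopy value was never published; the fixture ships 5,499 ha, a synthetic,
back-calculated value chosen for joint consistency with the published
RU-level storage (7,456.2 kt over 76,600 ha ⇒ 97.34 t ha⁻¹ ⇒
535,261 t / 97.34) and sequestration results, and it is flagged as
back-calculated in the fixture schema. A consequence worth knowing: the
derived coastal storage density prints as 97.3, whereas the published
density table prints 97.4 — the published tables are internally inconsistent
at the 0.1 % level and we follow the RU-level results, which carry more
significant digits.

## Density derivation

A city's canopy area is `assessment_area × canopy_fraction` of the RU
containing it (the stratum-level point-sampling estimate is deliberately
preferred over per-city field estimates, which are not consistently
available). Cities pool within an ecozone canopy-area-weighted:
`Σ carbon / Σ canopy_area`. This ratio estimator was chosen over the
unweighted mean of city densities because pooling is then invariant to
splitting a city into proportional parts and reduces the influence of small
assessments whose local canopy may deviate strongly from the stratum
fraction (the two prairie cities give 55.1 weighted vs 52.3 unweighted
t C ha⁻¹); the unweighted estimator remains available
(`pool_ecozone_density(..., method="unweighted")`).

Ecozones without local data are filled by rule: the semiarid prairies copy
the subhumid prairies; boreal ecozones take managed-forest model constants
(40.0 t C ha⁻¹, 3.0 t C ha⁻¹ yr⁻¹). Gaps fail loudly with the full list of
uncovered RUs. Densities are reported at one decimal but carried unrounded
into accounting; a `--use-printed-densities` switch forces the published
1-decimal values for strict table replication.

## Accounting

Per RU, stock and flux are `canopy_area_ha × rate / 1000` (kt). Net
sequestration is `f_net × gross` with `f_net` default 0.74; the published
tables imply a ratio of ~0.749–0.750 while the accompanying text states
74 %, so the ratio is a configuration field rather than a constant, and the
default follows the text. CO₂ converts by exactly 44/12 (kept as a rational
factor; unit conversions round-trip exactly in `convert_units(...,
exact=True)`). National totals are exact sums over RUs; rounding happens
only at report time (1 decimal). The baseline comparison applies one
national fixed density pair (default 76.9 t C ha⁻¹ and 2.12 t C ha⁻¹ yr⁻¹)
to every RU's canopy area with identical conversions and reports
differences.

## Canopy sampling

The point-grid sampler reproduces the survey design behind the RU canopy
fractions: a 1-km² cell grid, 25 % of cells drawn uniformly without
replacement, 55 points per selected cell on the rows × cols factorisation of
the point count closest to square (5 × 11 for 55) with half-spacing margins.
QC rules: cells with ≤ 25 % urban pixels are discarded before sampling
(strict inequality at the boundary), and cloud/distortion points are removed
before estimation — an all-discarded outcome is a no-data result, never a
zero. The estimator reports both a binomial SE (points treated as
independent Bernoulli draws) and a cluster SE from cell means. Points within
a cell are spatially structured, so the binomial SE is exactly calibrated
only when cover is homogeneous between cells (as in the iid synthetic
rasters used for the coverage tests); on blotchy rasters the cluster SE is
the honest one. Both conventions are reported because the source survey
states a single small canopy uncertainty without a formula.

## Monte Carlo uncertainty

Three classes of urban area, in increasing uncertainty:

1. **City-covered** fraction (`Σ assessment areas / urban area`, capped at
   1): one normal component per city, mean and SD from its published total
   and SE scaled to density units by its canopy area. Component weights are
   proportional to assessment area, which keeps the mixture mean exactly on
   the assigned pooled density — so a zero-uncertainty run collapses to the
   deterministic account bit-for-bit.
2. **Partial** remainder of assessed RUs: normal around the RU's pooled
   density with the inter-city SD observed among the twelve cities of the
   most densely assessed RU (sample SD of their individual densities,
   ~32.5 t C ha⁻¹ storage, ~1.22 t C ha⁻¹ yr⁻¹ sequestration).
3. **Proxy** RUs with no assessed city: normal around the assigned density
   with SD combining the proxy city's SE, the inter-city SD, and the SD
   across all 18 RU densities — in quadrature by default (independence
   assumption), additively behind a flag for sensitivity analysis. The
   representative proxy city is the largest assessment in the RU's own
   ecozone (coastal RU → the surrogate city, Atlantic RUs → the one Atlantic
   city, prairie proxies → the pooled prairie pair); boreal RUs centre on
   the forest-model constants and, having no proxy city, carry the inter-RU
   SD alone. The surrogate city publishes no SEs, so where its SE would
   enter, the inter-city/inter-RU quadrature substitutes.

Each iteration additionally draws, per RU, a triangular urban-area factor
(−10 % lower bound, mode at the estimate, +33 % upper bound — the analysed
population centres hold about two thirds of national urban area, so the
area outside the analysis bounds the upside), a canopy-cover perturbation
(0.2 %, interpreted as relative by default; absolute semantics available,
the source being ambiguous), and a multiplicative model factor, normal with
mean 1. The stated 20 % model uncertainty is read as the half-width of a
95 % interval (SD ≈ 0.102), the convention inventory uncertainty tables
use; a literal SD reading is available via `model_semantics="sd"`. The
model factor is shared across RUs by default (a common model bias moves all
strata together), which widens national bounds relative to independent
per-RU factors; both choices are exposed because the difference is material
(~8 percentage points on the national bounds). Negative rate draws are
truncated at zero and the truncation rate is logged (≈2 % of component
draws at the default configuration, concentrated in the widest proxy
strata).

Percentile bounds (2.5/97.5, linear interpolation on order statistics) are
reported per RU and nationally with relative deviations from the
Monte-Carlo mean; deviations from the deterministic account are also
exposed, since the right-skewed area distribution shifts the Monte-Carlo
mean ≈7.7 % above it. At the default 10,000 iterations national bounds are
stable to well under one percentage point against a 100,000-iteration run.
Per-stratum bounds for proxy RUs depend on the proxy-city assignment, which
the source tables do not publish; only the national bounds and the
proxy-wider-than-covered ordering should be read quantitatively.

## Synthetic data

The generator emulates the inputs' statistical structure, not their
ecology: true densities per ecozone, the packaged stratification and canopy
fractions, and city totals drawn as
`truth × (1 + e)`, `e ~ N(0, cv/√n_plots)` (truncated at zero; a lognormal
option keeps totals positive at high cv), with the generating SD published
as the SE. The default `cv = 0.05` matches the fixture cities, whose SEs
run 4–13 % of totals at 37–407 plots. Landcover rasters are pixelwise
Bernoulli canopy (optionally smoothed and thresholded at the exact count
quantile for spatial clustering with an unchanged marginal fraction), with
the realized fraction recorded as ground truth. What passing synthetic
tests show: the estimators are unbiased and calibrated under the stated
noise model. What they do not show: robustness to violations the generator
cannot produce — inter-city structural heterogeneity beyond the noise
model, canopy fractions that differ systematically between assessed cities
and their strata, or interpreter error in point labelling.

## Problem sizes used in the test suite

Deterministic stages run on the full 18-RU/17-city tables. Stochastic
checks use: 200 sampling seeds for estimator unbiasedness, 1,000 replicates
of ~1,100 points for CI coverage, 1,000 replicate synthetic cities for SE
calibration, 200 replicate single-stratum worlds (2,000 iterations each)
for interval calibration, and 10,000 vs 100,000 iterations for Monte-Carlo
convergence.

## Known limitations

- Dead organic matter, soils, and harvested wood products are outside the
  accounted pools; tree-mortality dynamics are not modelled.
- Ecozone pooling assumes urban forest structure varies across ecozones but
  not across provincial boundaries within one.
- The net:gross ratio ambiguity (0.74 text vs ~0.75 tables) propagates ~1 %
  into net and CO₂ figures.
- RU geometry is out of scope: strata are rows of a table, not polygons,
  and no geospatial joins are performed.
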