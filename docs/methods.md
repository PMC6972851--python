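# Methods

This note documents the models, conventions, and design choices behind
`beetox`, in the spirit of a statistical package's model documentation.

## Hazard model

Bee toxic load aggregates acute hazard, not risk: it counts the honey-bee
lethal doses represented by the insecticides applied in an area,
`Σ_ai Weight_ai / LD50_ai`, with weight in kg converted to µg (×10⁹) so the
quotient is a count of LD50s.  Contact and oral toxicity are treated as
separate axes throughout because the dominant exposure route cannot be
inferred from use data.  No environmental degradation, application-method,
or exposure modelling is attempted: half-lives depend strongly on the
matrix (soil vs. plant surface), and the use data carry no application
detail, so the metric is a hazard indicator, not a risk assessment.
Reporting divides by 10⁹ ("billions of bee LD50s"), which makes regional
per-hectare values land in the 0.01–20 range typical of published summaries.

## Consensus LD50 selection

Raw records are standardized (mg/bee ×1000 → µg/bee; Unicode µ tolerated)
and filtered to acute adult tests: exposure ≤ 4 days, contact or oral
route, adult bees, positive value in µg/bee.  Rows failing vocabulary or
value checks are rejected per-row with a logged reason, never an exception.
Conversions other than mg/bee→µg/bee (e.g., dietary ppm) are not attempted;
such records are dropped.

One value per compound × route is chosen by a strict ladder (tier recorded
in the output):

1. geometric mean of regulatory point estimates;
2. geometric mean of other-source point estimates;
3. regulatory unbounded estimates — minimum of "less than" bounds if any
   exist, else maximum of "greater than" bounds;
4. other-source unbounded estimates, same bound rule;
5. median of tier-1–4 consensus values within the compound's
   mode-of-action (IRAC) group;
6. median of tier-1–4 consensus values over all compounds.

Conventions where the procedure is underdetermined, fixed here once:
"less than" bounds take precedence within tiers 3–4 because an upper limit
on the LD50 is informative and hazard-conservative; medians of even-count
sets are arithmetic midpoints; duplicated records are not de-duplicated
before the geometric mean; tiers 5–6 operate on per-compound consensus
values, not raw records, since a group median most naturally refers to
compound-level toxicity.  If no compound anywhere has a tier-1–4 value the
global median is undefined and the procedure fails explicitly.

## Gap filling and imputation

- Use data: interior missing county-years are filled by linear
  interpolation independently for kg, contact load, and oral load.  Leading
  and trailing gaps take the nearest observed value (constant extension):
  linear extrapolation is undefined there, and extending a trend beyond the
  observed range would manufacture signal.  Counties that never report use
  are zero throughout.  Filled rows carry an `interpolated` flag.
- Census data: a withheld cell is replaced by the county's mean of that
  field over other census years, or zero when withheld everywhere.
  Imputation can break `treated ≤ cropland ≤ land`; violations are clamped
  down and flagged rather than propagated.

## Decomposition

Components are computed only at census years (land use is quinquennial;
intercensal interpolation of components is not attempted).  Extent is
reported against total land (`treated/land`) so that extent × intensity
reproduces per-land-ha load exactly; the cropland-based share is a separate
column.  Regional and national summaries are ratios of sums
(Σtreated/Σland, Σload/Σtreated, …), never means of county ratios, which
keeps the multiplicative identity and sum-consistency exact under
aggregation.  Aggregate potency is total load ÷ total kg
(weight-weighted).  Counties with zero treated area keep their per-land-ha
loads but have rate/intensity flagged undefined (NaN), never coerced to 0.

## Trend testing

Mann-Kendall with the tie-corrected variance
`[n(n−1)(2n+5) − Σ_t t(t−1)(2t+5)]/18` and tau-b.  A continuity correction
(|S| reduced by 1) is applied in the normal approximation — standard
practice for the short annual series (n = 16) this pipeline produces.
Exhaustive enumeration of the permutation null shows the approximation is
within 0.02 of the exact two-sided p for every achievable untied case at
n = 6–8 (worst 0.0171) and within 0.01 on a one-tie-group n = 6 example;
at n = 4–5 the worst-case discrepancy reaches 0.021–0.025 at extreme |S|,
so p-values for series that short should be read qualitatively.  Constant
series have undefined tau and are flagged.  Fold-changes are response
ratios end/start; non-positive baselines yield NaN (flagged), not ±inf.

## Clustering

Regional series are normalized to fold-change relative to the first year
(regions differ by orders of magnitude in absolute load; a region with zero
first-year load cannot be normalized and is excluded with a warning).  Ward
agglomeration uses the Lance–Williams recurrence on squared Euclidean
distances with leaf distances equal to plain Euclidean distance — the
"ward.D2" convention of the common reference implementations, against which
the tests cross-check.  Ties in the minimum merge distance are broken by
the lexicographically smallest node-id pair, making trees deterministic
given input order; permuting the input yields an isomorphic tree.

## Classification

`jenks_breaks` is the exact Fisher–Jenks dynamic program over distinct
values weighted by multiplicity (O(k·m²)), so tied values can never be
split across classes and the optimum matches exhaustive partition
enumeration.  The zero-centered variant for diverging change maps runs the
program separately on negative and non-negative values with a forced class
boundary at zero, allocating classes to each side in proportion to its
share of values (≥1 per side); one-signed input falls back to plain breaks
with a warning.  The default class count is 5.

## Synthetic scenario

The generator emulates the structure of the three real source-table
families — county pesticide-use estimates with dual low/high values,
quinquennial census land use with disclosure-withheld cells, and raw
toxicity extracts mixing sources, bounds, units, durations, and life
stages — without simulating pesticide fate, spatial autocorrelation, or
crop rotations.

Default conditions (all configurable): 90 counties in the nine Farm
Resource Regions, years 1997–2012 with census years 1997/2002/2007/2012;
county cropland log-normal around 1.2×10⁵ ha; national treated fraction of
cropland rising 15% → 26% while total cropland declines 12%; 5% of
county-years absent from use data and 10% of census cropland/treated cells
withheld; `kg_high = 1.5 × kg_low`; two urban counties with no agricultural
use at all; three "California-like" counties whose seed-applied
(neonicotinoid) use is absent from the use table.  The 12-compound catalog
uses true LD50s near published values (e.g., imidacloprid oral 0.0037
µg/bee, carbaryl contact 1.1 µg/bee) with organophosphates declining,
pyrethroids steady to rising, and neonicotinoids adopted from 2006 with
exponential growth concentrated in the Heartland and Northern Great Plains
(weight 1 there vs. 0.02 elsewhere); non-neonicotinoid compounds carry
weight 0.6 in those two regions, reflecting the lower foliar-insecticide
use of corn/soy-dominated cropland and keeping their baseline load small.

Two scalar parameters — the organophosphate end/start rate ratio and the
neonicotinoid adoption scale — are not fixed constants: the generator
solves the 2×2 linear system formed by the two endpoint-year load balances
so the planted national fold-changes equal the configured targets (9×
oral, 1× contact) exactly, for any seed.  This makes "the pipeline recovers
the planted truth" a sharp test.  The resulting regional structure plants
~50-fold oral increases in the two adopting regions and <5-fold elsewhere,
so the clustering root split has a known correct answer.

Toxicity records are planted so the consensus ladder can reproduce the true
LD50s exactly: regulatory point estimates are emitted at the true value
(σ = 0 by default, reflecting standardized regulatory protocols; the
log10-scale σ for other-source records is 0.3), the bounds-only compound's
largest "greater than" bound sits at its true value, and the records-free
compound's true LD50 coincides with its mode-of-action group median.  With
missingness disabled the full pipeline therefore reproduces the planted
fold-changes to numerical precision; with default missingness the residual
error is interpolation error only (typically < 3% on the national oral
fold).  What passing these tests does *not* show: robustness to biased or
heavy-tailed toxicity noise, spatially correlated missingness, or reporting
artifacts of the real databases — the synthetic tables are structurally,
not distributionally, faithful.

## Numerical conventions and edge cases

- All randomness flows from a single integer seed through one generator;
  identical configurations produce byte-identical outputs, and every
  pipeline output embeds a hash of the analytic configuration.
- Division guards: undefined ratios (zero treated area, zero kg, zero
  baselines) are NaN plus a flag, never 0 or ±inf.
- Internal identities (per-class sums vs. totals, extent × intensity vs.
  load/ha, engine vs. row-wise oracle) are tested at 1e-9 relative
  tolerance; consensus fixture values are exact.
- Problem sizes in tests and the acceptance script (90 counties × 16
  years × 12 compounds; exhaustive oracles at n ≤ 12 for breaks, n = 4 for
  Ward, n ≤ 8 for the permutation null) were chosen so each oracle is a
  complete enumeration while the full suite runs in seconds.

## Known limitations

- The pipeline emits classified county tables keyed by county id;
  cartography (joining to county geometries and rendering) is out of scope.
- Pastureland use, sub-county allocation, seed-treatment reconstruction for
  the California-like counties, and chronic/larval endpoints are not
  modelled.
- The Ward variant and class counts of published map figures vary across
  software; the conventions here (ward.D2, k = 5) are documented choices,
  not inferences about any particular study's software.
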