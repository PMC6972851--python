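# beetox — county-level bee toxic load

`beetox` is an analysis pipeline for **bee toxic load**: the total number of
honey-bee lethal doses represented by the agricultural insecticides applied
in an area.  Tracking kilograms of insecticide alone is misleading, because
active ingredients differ by orders of magnitude in potency toward insects;
weighting each compound's applied weight by its acute honey-bee LD50
produces a hazard-relevant aggregate that can be mapped and trended at the
county scale.  The package is aimed at landscape ecotoxicologists and
agro-environmental analysts who work with county pesticide-use estimates,
agricultural-census land use, and honey-bee toxicity databases.

## The model

For each county and year, separately for contact and oral toxicity,

    toxic load = Σ_ai  Weight_ai / LD50_ai

where *Weight* is kg of active ingredient applied (converted to µg, so the
sum counts bee LD50s) and *LD50* is the compound's consensus acute toxicity
in µg/bee.  Per hectare of county land, the load factors multiplicatively
into **extent** and **intensity**:

    load/ha = (cropland/land) × (treated/cropland) × (kg/treated) × (load/kg)
                 cropland frac   prop. treated      application rate  potency

The pipeline stages are:

1. **Consensus LD50s** — raw toxicity records are filtered to acute adult
   honey-bee tests (≤4 days, contact/oral, positive value standardizable to
   µg/bee) and reduced to one value per compound and route by a six-tier
   ladder: geometric mean of regulatory point estimates, then other point
   estimates, then regulatory and other unbounded (“<”/“>”) estimates, then
   the mode-of-action group median, then the global median.
2. **Toxic load** — Weight/LD50 summed per county-year with a per-class
   breakdown, using the conservative "low" weight estimate by default;
   missing county-years are linearly interpolated (edges extended, never
   extrapolated; counties never reporting use are zero).
3. **Decomposition** — census cells withheld for disclosure are imputed
   with the county mean over other census years (zero if always withheld),
   and the extent/intensity components above are computed for census years,
   with regional summaries as ratios of sums.
4. **Trends & fold-changes** — Mann-Kendall tests (tie-corrected tau-b,
   continuity-corrected normal p) and response ratios end/start (1 = no
   change, 3 = tripling, 0.3 = a 70% decline).
5. **Clustering** — regional load trajectories, normalized to fold-change
   relative to the first year, agglomerated with Ward's linkage on
   Euclidean distances.
6. **Classification** — exact Fisher–Jenks natural breaks for map classes,
   with a zero-centered variant for diverging change maps.

Because real county pesticide/census/toxicity extracts cannot ship with the
package, a first-class synthetic-data module generates the three source
tables with the structure the analysis assumes — dual low/high weight
estimates, withheld census cells, missing county-years, a compound-class
shift from organophosphates toward neonicotinoids/pyrethroids concentrated
in two of nine regions — together with a planted ground truth (exact
national fold-changes of 9× oral and 1× contact by default) used for
parameter-recovery tests.

## Worked example

```sh
python analysis/03_toxic_load.py --seed 0
python analysis/04_components.py --seed 0
```

prints, among other output,

```
1440 county-years (111 interpolated or zero-filled)
national contact fold-change 1997->2012: recovered 0.9953 (planted 1.0000, rel. error 0.47%)
national oral fold-change 1997->2012: recovered 8.7025 (planted 9.0000, rel. error 3.31%)
```

i.e., from the synthetic tables *with* missingness the pipeline recovers the
planted 9-fold oral increase within a few percent (it is exact when
missingness is disabled), and

```
               region  ...  oral_intensity_bil_per_treated_ha  oral_load_bil_per_ha
            Heartland  ...                             214.44                 15.89
Northern Great Plains  ...                             217.53                 21.30
        Contiguous US  ...                              55.94                  5.28
```

showing the two neonicotinoid-adopting regions dominating oral intensity
(billions of bee LD50s per treated hectare) by 2012.  The numbered scripts
under `analysis/` walk the full sequence: `01_simulate` … `08_sensitivity`
(trend tests, regional clustering whose root split isolates the two
high-increase regions, county map classes, and the low-vs-high estimate
comparison).  The same stages are available as a CLI:

```sh
beetox run-all --seed 0 --out results/run     # all stages + manifest
beetox sensitivity --seed 0 --out results/run
```

with an optional YAML scenario file (`--config configs/default_scenario.yaml`).

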