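# plankweave

Integration and taxonomic harmonization of multi-survey zooplankton
monitoring data.

## The problem

Long-term estuarine zooplankton monitoring is usually carried out by
several independent programs. Each publishes catch-per-unit-effort (CPUE,
individuals m⁻³) tables in its own dialect — wide or long layout, agency
species codes, its own units — and, critically, each counts organisms at
its own taxonomic resolution, which also changes through time as species
are added to identification lists or promoted from genus- to
species-level counting. A naive multi-survey analysis reads those
methodological differences as biology: a species "occurs" only where the
one survey that separates it happens to sample.

`plankweave` is a library (plus a thin CLI) for building an
analysis-ready integrated dataset out of such surveys:

* **standardize** — ingest per-survey tables from a declarative survey
  descriptor, resolve species codes, convert units, pivot to one long
  schema, replace false zeros (taxa not yet counted) with missing values
  while keeping true zeros for non-natives before their introduction
  year, and split into `environment.csv` / `zooplankton.csv` keyed by
  `SampleID`.
* **harmonize** — make taxonomic resolution comparable across surveys.
  In *community mode*, every category not counted by all surveys is
  summed, within each sample, up to the lowest-ranked ancestor whose
  "spp." bin every survey counts; the summed constituents are removed so
  no organism is counted twice; categories with no shared higher rank
  are dropped as orphans. In *taxa-of-interest mode*, summed "All X"
  groups are added while constituents are retained (double-counting by
  design; not for community analysis). A temporal correction reduces
  lists to their coarsest state over a year range, with a configurable
  time-lag that saves recently introduced species.
* **validate** — regress harmonized on raw per-sample total CPUE (slope,
  intercept, R²) and check exact per-sample equality after excluding
  dropped orphans: harmonization may move catch between categories but
  never create or destroy it.
* **enviro/counting** — PSS-78 conductivity→salinity with the
  low-salinity extension, flowmeter volumes (count × constant × mouth
  area), CPUE (count / subsample fraction / volume), carbon biomass from
  literature conversions, matched-gear undersampling flags, and
  Poisson counting-precision math (1.96·√n/n; counting 400 organisms
  gives ±10%).
* **simulate** — a synthetic multi-survey generator (lognormal latent
  densities, per-survey taxa-list censoring, species introductions,
  gear efficiencies, Poisson counting) with known ground truth, so the
  whole pipeline is testable offline.

## Worked example

Three simulated surveys count the genus *Tortanus*: one separates
*T. discaudatus* and *T. dextrilobatus* plus a residual *Tortanus* bin,
two lump everything into the bin. Harmonize for community analysis:

```python
import plankweave as pw

result = pw.simulate_program(pw.make_resolution_scenario("orphan", seed=4))
# ... standardize the survey tables (see examples/02_harmonize_community.py),
# then:
plan = pw.plan_community(result.taxa_lists, result.tree, surveys, "Meso")
harmonized = pw.apply_plan(catch, plan)
report = pw.validate_conservation(catch, harmonized, plan)
```

which prints:

```
input categories : ['Acartiella sinensis', 'Annelida', 'Tortanus',
                    'Tortanus dextrilobatus', 'Tortanus discaudatus']
output categories: ['Acartiella sinensis', 'Tortanus']
orphans dropped  : ['Annelida']
OLS harmonized~raw: slope=1.002997 intercept=-1.32 R2=0.998460
max relative delta after excluding drops: 1.77e-16
```

All *Tortanus* categories were rolled up to the genus (the rank every
survey counts) and the species rows removed; *Annelida*, counted by a
single survey with no shared higher category, was dropped with a recorded
reason. The regression departs from slope 1 / R² 1 only because of that
orphan; once its catch is excluded from both sides, per-sample totals
are identical to machine precision — the harmonization conserved catch
exactly. In taxa-of-interest mode the same sample instead keeps all the
detail (`examples/03_taxa_of_interest.py`):

```
               Taxname      CPUE
          All Tortanus 89.314465
              Tortanus 12.280739
Tortanus dextrilobatus 17.862893
  Tortanus discaudatus 59.170833
```

The `examples/` directory has one short script per capability; the same
pipeline is available from the shell via the `plankweave` CLI
(`simulate`, `integrate`, `community`, `taxa`, `salinity`, `flags`,
`precision`; exit codes 0/2/3 for ok / input error / validation failure).

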