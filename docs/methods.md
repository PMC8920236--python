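# Methods

## Data model

The integration works on two linked tables keyed by `SampleID`
(`"{Source} {Station} {ISO datetime} {SizeClass}"`, unique and
human-auditable): a sample-level environment table (station, datetime,
volume, water quality) and a long catch table with one CPUE
(individuals m⁻³) per sample × taxon/life-stage. Taxa live on a fixed
six-rank ladder (Phylum > Class > Order > Family > Genus > Species);
intermediate ranks are out of model. Life stages are opaque labels and
every (taxon, life stage) pair is an independent analysis unit, as is
each of the three gear size classes (Micro/Meso/Macro). Missing values
are serialized as literal `NA` in all CSVs.

Per-survey *taxa lists* record, for each survey × size class ×
category, the years it was counted (`start`/`end`, an optional `restart`
after a gap — the gap years are treated as not counted) and, for
non-natives, the introduction year.

### Zero vs. missing

A recorded CPUE of 0 in a year the survey did not count that category
means "unknown", not "absent": it becomes `NA`. The exception is a
non-native taxon before its introduction year, which was truly absent
and keeps 0. Nonzero values are never altered, and `NA` is never turned
back into 0.

## Taxonomic harmonization

"spp."/higher-rank categories are **other-bins**: within a survey they
exclude the lower taxa that survey counts separately. This is the key
semantic that makes rollups exact.

**Community mode** (exclusive). For each category not counted by every
survey, the target is the lowest rank whose ancestor bin (same life
stage) is on *every* survey's list. The output group at that ancestor
absorbs, per survey, the bin itself plus every category that rolls to
it; absorbed categories are removed from the output so nothing is
counted twice. Categories counted everywhere and absorbed by no group
are kept at full resolution; categories with no all-survey ancestor are
dropped with a recorded reason (orphans). Because kept categories are
excluded from every survey's bins *consistently*, this assignment is
exclusive without any post-hoc merging of nested groups: a non-universal
bin rolls up exactly like any other category. The planner is
deterministic, is applied per sample (data from different samples are
never aggregated), and is verified in the test suite against a naive
exhaustive search on random instances.

**Taxa-of-interest mode** (non-exclusive). For each requested taxon X,
an "All X" group sums every counted category in X's clade per survey,
and all constituents are retained. The plan is flagged non-exclusive;
on any sample the "All X" CPUE equals the community-mode group CPUE at
the same rank (a tested invariant).

**Group sums and missing values.** Within a sample, missing constituent
CPUEs are skipped (NA means unknown, not zero — turning it into zero
would silently destroy known catch) unless *all* constituents are
missing, in which case the group is missing. How the real pipelines
treat mixed 0/NA constituents is not documented anywhere we know of;
this choice is therefore exposed as `na_rule="ignore"|"propagate"` on
`apply_plan`.

**Temporal correction.** Over a requested year range, a category
survives only if counted in every year (the list's coarsest state);
introduced taxa first counted within `intro_lag` years of their
introduction survive from their first counted year (`intro_lag=inf`
retains all introduced taxa). The correction is applied *before* the
cross-survey plan when both are requested: coarsen in time, then across
surveys.

**Conservation validation.** Total CPUE per sample is computed for raw
and harmonized tables; an OLS with intercept (plain, unadjusted R²)
summarizes their agreement, and after crediting the catch of dropped
categories back, per-sample totals must agree to 1e-9 relative — the
orphans are the only legitimate source of difference.

## Physical quantities

**Salinity.** PSS-78 converts the conductivity ratio
R = C/C(35,15,0), C(35,15,0) = 42.914 mS cm⁻¹, through the rt(T) and
(for pressure > 0) Rp factors into practical salinity via the a/b
polynomials in √Rt; below S = 2 the low-salinity extension subtracts
the small-Rt correction so that S → 0 exactly at zero conductivity. The
polynomials are evaluated on the input temperature directly (they were
fitted on the 1968 temperature scale; the difference from ITS-90 is
below field-probe accuracy), valid −2..40 °C; values above S = 42 warn
but are returned. Field probes usually report *specific conductance*
normalized to 25 °C, so the default input convention rescales by
rt(T)/rt(25) before conversion; pass `input_type="in_situ"` for raw
conductivity at the measured temperature. The implementation is
vectorized; an independently transcribed scalar reference (with the
standard's own check values, including the defining point R=1, t=15 →
S=35) lives under `tests/reference/` and the two are compared on a grid
S∈[0.1,40] × T∈[5,30] to |ΔS| < 1e-3, including continuity across the
S = 2 boundary.

**Volume, CPUE, biomass.** Net volume = flowmeter count × flowmeter
constant (distance per count) × mouth area (m²); constants are
per-survey configuration since they are instrument-specific. CPUE =
organisms counted / subsample fraction / volume. Carbon biomass (µg C
m⁻³) = CPUE × per-individual literature carbon mass; taxa without a
literature value get *missing* biomass, never zero.

**Counting precision.** Assuming organisms land in aliquots as a
Poisson process, the relative 95% half-width of a count of n organisms
is 1.96·√n/n (≈ ±10% at the 400-organism protocol target; note 2/√400
is also exactly 10%, so the 2·CV and 95%-CI readings coincide at that
target). An exact chi-square Poisson interval is available as an
option. Protocol bounds: a 200–400 organisms ml⁻¹ dilution over 5–20
one-ml aliquots implies 1,000–8,000 organisms counted per sample.

**Flowmeter QC.** Volumes are flagged when |log v − median log v| >
3 × scaled MAD within a same-station (or same-date) group, or when
outside optional absolute bounds — the dispersion rule needs ≥ 3
values, the bounds catch singleton groups. Flagged volumes are replaced
by the mean of unflagged volumes in the group; with no donors the
volume is left missing and logged as un-imputable. Both the grouping
and the rule are configurable because published pipelines state the
imputation ("average from similar samples, same station or date") but
not the outlier criterion.

**Undersampling flags.** Restricted to station-dates sampled by both
gears, each taxon counted by both is totaled per gear and the ratio
(e.g. net/pump) compared to the band [θ, 1/θ], default θ = 0.75 — chosen
so a taxon whose net catch is 80% of the pump catch (the classic
near-equal case) is *not* flagged. Flagged records are marked, never
deleted.

**Sampling effort** is the mean number of samples per station per
month, averaged over the stations actually sampled that month (stations
never sampled in a period do not dilute the mean — this reading makes
"two samples per month at every sampled station" come out as effort
2.0), then averaged per year or per calendar month.

## Synthetic data generator

Each leaf taxon has a lognormal latent density, parameterized so the
configured `mean_density` *is* the distribution mean
(µ = ln m − σ²/2), with an optional mean-one seasonal modulation. Per
sample: a lognormal volume, censoring by the survey's taxa list for
that year (organisms of a leaf land in the lowest active category
covering it — the same bin semantics as the real surveys), gear
efficiency per taxon, and an enumerated count drawn
Poisson(density × volume × subsample fraction × efficiency), reported
as CPUE in each survey's dialect (long or coded-wide, m⁻³ or L⁻¹).
Introduced taxa have zero density before their introduction year and
record 0 when their category is active. One PRNG stream per run, with
per-survey substreams spawned deterministically, makes output
byte-identical for a fixed seed.

What it does *not* emulate: spatial structure and station effects,
cross-survey correlation of densities (each survey draws its own latent
field), overdispersed (contagious) plankton distributions, tides, or
realistic species parameterization. Passing recovery tests therefore
show the *pipeline arithmetic* is right, not that real surveys are this
well behaved.

Problem sizes: quantitative validation uses a two-survey calibration
program of ~1,560 samples (5 stations × 12 months × 13 years × 2
surveys) with σ = 0.25, which puts the Monte-Carlo error of a mean near
1% — appropriate for recovery checks at the few-percent level; planner
oracle comparisons use 200 random instances of ≤ 5 surveys × ≤ 40 taxa.

## Known limitations

* Only the six Linnean ranks; suborders/species complexes must be
  shoehorned or pre-mapped.
* Synonymy and external nomenclature services are out of scope; names
  must already be consistent across surveys.
* The conservation regression is diagnostic, not inferential — no
  uncertainty is attached to slope/R².
* Mysid length-based biomass regressions are not included; only
  per-individual literature carbon masses.
* The taxa-of-interest output deliberately double-counts; downstream
  code must respect the `exclusive=False` flag.
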