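# Methods

This note documents the statistical model behind `ffaconcord`, the choices
made where the procedure was genuinely open, and what the synthetic-data
studies do and do not establish.

## Standardization chain

**z-scores.** Every subject's concentration of analyte *j* is standardized
against a named reference population: `z = (x − mean_ref) / sd_ref`, sample
SD with ddof = 1. For humans the reference is the healthy-control (HC)
group; for each mouse cohort it is that cohort's own control group.
Analytes whose reference SD is zero (or with fewer than two non-missing
reference values) cannot be standardized and are dropped with a warning;
because radar polygons must be comparable across species, an analyte
dropped in either species is excluded from the shared panel.

**S-scores.** The fidelity statistic locates a standardized animal value
inside the patient cohort's z-score distribution:
`s = (z_animal − mean(z_patients)) / sd(z_patients)`. A defensible
alternative reading feeds the animal's *raw* concentration into the same
formula; raw mouse concentrations are not commensurable with human z-score
statistics, so the default standardizes the animal against its own species'
control group first, and the literal raw-value variant is available via
`sscore(..., animal_values="raw")` for auditability. The double
standardization cancels measurement units within each species: `s` is
invariant to any positive rescaling of raw concentrations applied
consistently within a species (a property test asserts this).

**AERC.** With *k* analytes at equal angular spacing θ = 2π/k and
non-negative radii r₁…r_k, the enclosed polygon area is
`0.5·sin(θ)·Σ rᵢ·rᵢ₊₁` (cyclic); this equals the Cartesian shoelace formula
applied to the polar vertices, and a 1,000-polygon oracle comparison holds
to 1e-10. Three facts shape its use:

* s-scores can be negative but radii cannot. The default transform is
  |s| — distance-from-patient-mean semantics, consistent with "closer to
  zero = closer to the patients". `shift_min` (per-animal) and `clip_zero`
  are provided; the transform used is recorded in every result.
* The area is **not** invariant to axis order. The default order is the
  canonical panel ordering (ascending carbon count, then double-bond
  count, then suffix); the order used is always emitted with the result.
* Group summaries report mean ± SEM with SEM = SD/√n, sample SD.

Models are ranked by mean AERC over treated animals (smaller = more
concordant), ties broken by mean |s|, then by name; both summaries are
always reported, and `rank_models(policy="mean_abs_s")` swaps the primary.

## Comparison layer

Each analyte is screened per group with Shapiro-Wilk (gate α = 0.05 per
group; Q-Q coordinates exported). If every group passes, a two-sided
unpaired t-test — Welch by default, pooled-variance Student available; if
any group fails or is untestable (n < 3 or constant), a two-sided
Mann-Whitney U: exact when both groups have n ≤ 8 and the pooled sample is
tie-free, otherwise the tie-corrected normal approximation without
continuity correction (this makes identical groups give exactly p = 1).
Direction is the sign of the difference of raw group means, matching
mean ± SEM reporting conventions. No multiple-testing correction is applied
by default across the ~26-analyte panel — mirroring common practice for
targeted panels read analyte-by-analyte — and Benjamini-Hochberg adjusted
p-values can be reported alongside
(`ComparisonPolicy(multiple_testing="benjamini_hochberg")`).

Contingency tables use Pearson chi-square **without** Yates continuity
correction (exposed as a flag); `contingency_consistency` flags printed
tables whose cells contradict their stated marginals rather than silently
fixing them. Kruskal-Wallis is tie-corrected with the chi-square
approximation; a one-way ANOVA is provided for completeness but the
reference pipeline does not route any comparison through it.

**Covariate adjustment** fits a pooled OLS of concentration on the
covariates (sex coded female = 1), and returns residuals re-centered at the
pooled mean, so group comparisons can be re-run on sex-adjusted values.
The adjustment is invariant to affine rescaling of covariates; a
rank-deficient design raises an error naming the collinear columns.

## Synthetic data generator

The generator emulates a targeted GC-MS FFA study: a 26-analyte panel with
log-normal concentrations (positive, spanning ~3 decades of µg/mL),
a multiplicative case effect on the median (fold changes in [0.55, 0.85]
for most analytes, 1 for a few — a general but uneven down-regulation),
human cohort sizes 88 control / 116 case, mouse cohorts of 6 + 6, sex ~
Bernoulli(0.62 female), age ~ N(14.7, 1.9) years, education ~ N(8.9, 1.9)
years, and a modest additive sex effect (0.12) on the log scale. Mouse
baselines are deliberately shifted and reshaped relative to human ones so
that the concordance statistics must cancel species scale, as they claim
to. A single integer seed drives all draws through spawned
`SeedSequence` sub-streams, so identical configs are bit-reproducible.

`simulate_concordance_scenario` plants a recoverable ground truth: each
model inherits a stated fraction ("fidelity") of the human fold-change
vector, the rest reverting to 1. The log-normal form is an assumption —
the real studies report only normality screening, not a generative model —
and the generator starts at quantified concentrations: no chromatograms,
instrument noise, batch effects, or missingness mechanisms. Passing
recovery tests therefore show the chain is correct and powerful **under
its own assumptions**, not that any particular real model ranking is
right.

Behavioral endpoints (forced-swim immobility clipped to the 240 s scoring
window, log-normal sucrose/water intakes, interaction-zone time) shift the
case group by a stated number of control SDs in the depressive direction;
they exercise the endpoint statistics and are not used by the concordance
chain.

## Method characterization

Two simulation studies (in `ffaconcord.studies`, re-run by
`scripts/acceptance.py`) characterize the analysis layer at the study's
own scale:

* **Type-I calibration** (10,000 replicates, n = 6/group, α = 0.05): on
  normal nulls the selector rejects at ≈ 0.043–0.049. On strongly skewed
  log-normal nulls it is **conservative** (≈ 0.032–0.036): at n = 6 the
  exact Mann-Whitney branch has discrete size 0.041, the Welch branch
  under-rejects on skewed data, and Shapiro-Wilk routes only about half of
  log-normal draws to the nonparametric branch. The conservatism shrinks
  as the skew does. This is the safe direction of miscalibration, but
  worth knowing when reading borderline p-values from n = 6 cohorts.

* **Ranking recovery** (200 replicates, fidelity 0.8 vs 0.2, uniform
  patient fold change, 6 mice/group): recovery is ≈ 0.90–0.93 at fold
  change 0.6 and exceeds 0.95 only for stronger effects (≈ 0.97 at fold
  0.4); with 12 mice/group it reaches ≈ 0.99 at fold 0.6. The limiting
  noise is the 6-animal control group behind the within-species
  z-standardization, which inflates each animal z's variance by roughly
  (1 + 1/6)·(5/3) ≈ 2. Single-study rankings from 6-animal cohorts with
  moderate effects should therefore be read as suggestive, not decisive.

## Numerical and degenerate-input conventions

* Sample SDs everywhere (ddof = 1); SEM = SD/√n.
* All-tied two-group data: p = 1, direction "none". Constant groups are
  "untestable" for normality and route nonparametric.
* Polygons need ≥ 3 axes; negative radii after transform are an internal
  error (invariant breach), not a user error.
* Missing data: analytes missing in > 20% of any group are dropped
  (logged); remaining missing values are excluded pairwise per analyte.
  Non-numeric concentration cells (e.g. "n.d.") become missing with a
  warning; negative concentrations are a hard input error.
* Analyte names normalize through a synonym dictionary to `C<carbons>:
  <bonds>[suffix]` shorthand; unknown names pass through verbatim with a
  warning. One published inconsistency is kept deliberately: the name
  "trans-9-octadecenoic acid" appears in circulation attached to the
  C18:2n6c shorthand (chemically a C18:1 isomer); the dictionary keys on
  the shorthand and keeps the name as a display synonym.
* Pipeline outputs are byte-deterministic for a fixed config + seed; the
  run manifest (config hash, seed, version) suffices to re-execute a run.

## Known limitations

* AERC depends on axis order and on the radius transform; both are
  reported with every result, but comparisons across studies require the
  same conventions.
* The S-score measures deviation from the patient **mean** profile; two
  models can tie on |s| while differing in the sign structure of their
  deviations. The per-analyte comparison table carries the signed detail.
* The generator's covariates are independent of group; confounded designs
  (e.g. sex imbalance between groups) can be simulated only by editing
  the covariate model per group outside the stock configs.
* Problem sizes in the shipped studies (10,000 calibration replicates,
  200 recovery replicates, 1,000 oracle polygons) were chosen to
  characterize the method at the study's own cohort scale while keeping
  a full run in the tens of seconds.
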