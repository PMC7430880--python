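# Methods

## Study design being modeled

Three experience groups perform simulator tasks and are scored on
task-specific performance metrics; a Likert questionnaire (1–5) collects
opinions in three domains per task. The analysis chain is: content
aggregation → construct screening → composite scoring → contrasting-groups
standard setting. Group labels are ordered novice < laparoscopic < robotic so
"expected direction of advantage" is well defined. The packaged fixtures
carry the study's group sizes (29/26/15 overall; 28/26/14 for Task 2, where
two participants lost performance data to a technical error) and per-group
mean/SD for every metric and Likert domain.

## Data model

Cohorts are long-format CSV (`participant_id,group,task,metric,value`) so
tasks may have different metric sets; Likert responses are
`participant_id,group,task,domain,item,score`. Metric values are stored as
reals even for counts — integrality is a property of the generator, not the
model. Participants missing a task's metrics are dropped *for that task
only*, never imputed. Each metric carries a registry entry with domain
(movement / safety / task-specific), unit, and benefit direction
(lower-better, higher-better, or ambiguous).

Two Task-3 metrics are registered as *ambiguous*: `distance_scope_and_tissue`
(experienced surgeons work closer to the tissue, but "closer" is not a
proficiency axis by itself) and `times_out_of_view` (experienced users move
the camera more, inflating the count). Ambiguous metrics are never selected
into a composite without an explicit override. Task-3
`precise_needle_passages` is registered lower-better: in that task passages
are redo-driven (the robotic-experienced group completes it with fewer
passages overall, 14.1 vs 15.3, and correspondingly fewer on-target passages,
10.3 vs 12.4), so fewer passages indicate proficiency; this orientation is
what makes the metric's inclusion in the Task-3 composite coherent with the
observed group ordering.

## Synthetic cohort generator

Every (task, metric, group) is emulated as `N(mean, sd)` truncated at zero,
with the *pre-truncation* location and scale set to the published values
(equivalent to rejection sampling of the untruncated normal). Count metrics
(units of `count` in the registry) are rounded to the nearest integer after
truncation. Likert scores are `round(clip(N(mean, sd), 1, 5))`; by default
each participant contributes one score per domain, so the group mean/SD of
participant domain means matches the fixture directly (the published tables
do not identify item-level variance).

Consequences of these choices:

* **Truncation bias.** For mean/sd ≳ 2.2 the bias is under the 2%/5%
  (mean/SD) recovery tolerance verified at n = 10⁴. Low-ratio count metrics
  (e.g. suture breakage at 0.6 ± 1.2) are biased upward — a documented
  property of the minimal nonnegativity fix, acceptable because such metrics
  enter the composite only through their pooled min–max range.
* **Normality is an assumption, not an inference.** Real times and path
  lengths are likely right-skewed; the published tables give only mean/SD, so
  the generator cannot (and does not try to) reproduce shape. Passing
  stochastic checks therefore shows the *pipeline* reproduces the published
  analysis under its own distributional model, not that the study data were
  normal.
* **No correlation structure** between metrics (none is published) and no
  modeling of the 20-minute task cap as censoring.
* **Seeding.** One global seed expands into independent substreams per
  (task, metric, group) via SHA-256 keying of a `SeedSequence`, so adding a
  metric never perturbs another's draws; cohort CSVs are byte-identical under
  a fixed seed. Synthetic demographics reproduce the study's expert split
  (7 of 15 robotic participants above 50 advanced procedures) to support the
  sub-expert re-screen.

## Screening

Pairwise contrasts are robotic-vs-novice, laparoscopic-vs-novice,
robotic-vs-laparoscopic, two-sided at α = 0.05 with no multiplicity
correction (matching the source analysis). On record-level data the
equal-variance choice is gated by a mean-centered Levene test at α = 0.05
(reject → Welch); this reproduces the printed p-values, which match the
pooled form where variances are similar (Task-1 total time L vs N, p = 0.047
under both forms) and the Welch form where they are not (Task-3 scope
distance R vs L, p = 0.001 under Welch only). Summary-statistic inputs
default to Welch, the conservative form. Shapiro–Wilk p-values are logged per
sample but non-gating — the published analysis reports t-tests throughout,
and the consequence of a failed normality check is otherwise unspecified.
When both samples are constant at the same value (possible for all-zero
synthetic count metrics) the contrast is reported as t = 0, p = 1 rather than
an error: no detectable difference.

Selection rule for the composite: significant robotic-vs-novice contrast AND
advantage (by group means under the metric's direction) with the robotic
group AND unambiguous direction, in registry order. Ties in means leave the
advantage undefined and the metric unselected. Explicit include/exclude
overrides handle judgment calls; the packaged default excludes
`needle_precision` from Task 2, whose printed composite omits it although its
robotic-vs-novice contrast is significant at record level (p = 0.042).

## Composite and standard setting

Min–max bounds are fitted on the pooled task cohort (all three groups), so
all participants share one 0–100 axis; per-group normalization would destroy
comparability. A zero-range metric raises an error rather than silently
contributing a constant. Values outside the fitted bounds (possible when a
map is reused on new data) are clipped. The composite is the weighted mean of
the normalized metrics (default weights 1); it is invariant to positive
affine rescaling of any raw metric, bounded in [0, 100], and permutation
invariant.

The contrasting-groups cutoff uses group Gaussians fitted by sample mean and
SD (ddof = 1) of the composites. With equal sigmas the cutoff is the midpoint
of the means; otherwise it is the root of the log-density quadratic lying
strictly between the means (the other root sits in a tail and is meaningless
as a standard). The crossing point equals the minimizer of theoretical
FP + FN — this equivalence is tested against a 1e-4 grid search over 500
random Gaussian pairs. A bounded numerical minimization of FP + FN guards
numerically degenerate quadratics. The pass rule is composite ≥ cutoff
(boundary passes); FP/FN definitions depend on this and are stated
accordingly. Pairs whose means are not ordered as expected (e.g. novices
outscoring laparoscopic participants) are flagged not-computable in the
three-group report instead of aborting.

The sensitivity sub-analysis formalizes "best/worst-case weighting" as
extremizing the standardized novice–robotic mean difference of the composite
over the weight simplex (SLSQP from the uniform point, every vertex, and
seeded Dirichlet starts; the uniform point always remains a candidate, so
best ≥ uniform ≥ worst by construction).

## Pipeline, reporting, problem sizes

`run_pipeline` executes content → screen → select → composite → standards per
task and renders JSON (schema-validated via pydantic on every run; the JSON
schema ships in `simvalid/data/report_schema.json`), Markdown laid out like
the published group tables, and per-task composite CSVs. Reports contain
seed, config hash and package version — no timestamps — and are
byte-identical under a fixed seed. `run_subgroup` re-runs the screen under a
demographic predicate (e.g. robotic participants with > 50 advanced
procedures, n = 7) and reports the selected-set delta against the full run.

Replicated checks use 20 synthetic cohorts at the study's group sizes (the
scale at which the published standards were set); calibration-style checks
use 400–2000 replicates and n = 10⁴ draws for moment recovery. The
acceptance script averages cutoffs over 20 replicate cohorts whose seeds
derive from a single CLI seed.

## Known limitations

* Normal location-scale emulation cannot reproduce skew, outliers or
  metric correlations of the real data; absolute FP/FN on synthetic cohorts
  are cleaner (often 0) than printed ones, and the theoretical total error of
  well-separated tasks is smaller than published, though the task ordering
  (Task 3 discriminating far worse than Tasks 1–2) is reproduced.
* Summary-only screening (Welch default) can flip borderline decisions
  relative to record-level gated tests (e.g. Task-3 `movements_left`,
  printed p = 0.060, Welch-from-summary p ≈ 0.04).
* The 20-minute task cap is a recorded limitation, not a censoring model.
* No bootstrap confidence interval on the cutoff and no borderline-group or
  Angoff standard-setting variants.
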