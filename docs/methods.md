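# Methods

## Data model

A screening cohort is a visit table: one row per mammogram with an AI risk
score in [0, 100], a BI-RADS assessment, the final (double-) reading recall
decision, histopathology truth, and a detection mode for cancers
(screen-detected; interval = diagnosed within 24 months of a negative
mammogram; missed = within 30 days). Dates are held at month resolution
because every derived quantity — screening intervals, interval windows,
lead times — is counted in whole months. BI-RADS is dichotomized with 1–2
negative and 0/3/4/5 positive (0 is incomplete and triggers workup).

## Threshold selection

ROC operating points are computed at every distinct observed score plus a
sentinel above the maximum, under the convention score ≥ threshold ⇒
positive. Youden's J = sens + spec − 1 is maximized exactly on integer
true-positive/true-negative counts (the objective `tp·n_neg + tn·n_pos` has
the same argmax and is free of floating-point ties); ties break toward the
lowest qualifying threshold, the sensitivity-favoring choice appropriate in
screening, and the tie-break rule is carried in the result. AUC is the
trapezoid-rule area, which on this threshold set equals the Mann–Whitney
concordance probability with ties counted half — a property the test suite
checks against an all-pairs oracle and against scikit-learn. The AUC
confidence interval is a percentile bootstrap (no stronger method is
justified by the data the package targets); replicates that draw a single
class are redrawn and logged.

## Triage

Green iff score ≤ 1: the vendor reports scores below 1 as low risk, and the
benchmark program's own wording uses both "below 1" and "lower than and
equal to 1"; since no fixture score lies exactly at 1 the choice is
inconsequential there, and ≤ is used uniformly. Red iff score ≥ the high
cut. A false negative is a cancer visit not categorized red (green or
yellow), matching the benchmark's 29/105 = 27.62% figure (5 green + 24
yellow).

## Prevalence-matching bootstrap

The retrieved benchmark cohort over-represents cancers, so simulated
cohorts keep every cancer visit exactly once and draw
`round(n_cancer/rate) − n_cancer` non-cancer visits uniformly with
replacement (105 cancers at 5.7/1000 → 18,421 visits, 18,316 of them
drawn). Resampling is at the visit level by default — the cohort statistic
of interest is per-mammogram — with a woman-level mode (whole non-cancer
women drawn with replacement, trimmed to the target count) available for
sensitivity analyses. Cohorts are streamed as index sets into the source
table, so 10,000 iterations use constant memory. Size rounding is
to-nearest (105/0.0057 = 18,421.05 → 18,421).

## Reading workflows

Reads per visit by scenario: double reading (`bmsp`) 2 for every visit —
third-reader arbitration is excluded from workload, making the baseline
exactly 2N; `s1` 1; `s2` 1 plus 1 per yellow; `s3` 0 for green, 1 for
yellow/red.

The benchmark data record only the final double-reading outcome, never
single-reader behavior, so AI-directed human reads need an explicit reader
model. `observed` replays the recorded recall flag; `flag_perfect` assumes
a human alerted by the AI flag detects every cancer in a yellow/red visit,
while non-cancer recalls still follow the recorded flags. Defaults:
`observed` for bmsp/s1 (their reads are not AI-directed), `flag_perfect`
for the AI-directed reads of s2/s3. Detection rules: bmsp = recorded;
s1 = human ∪ red; s2 = recorded ∪ red ∪ (yellow ∧ second read);
s3 = (human on yellow/red) ∪ red, red being auto-escalated. On the fixture
these yield 68 / 87 / 101 / 100 detected of 105. The 87 for s1 deliberately
differs from the benchmark's published 84: no stated reader assumption
reproduces 84 from the contingency table (the human ∪ red union gives 87),
so the package reports the derivable number rather than tuning an
unobservable single-reader sensitivity. For the same reason PPV1/NPV are
reported with an explicit recall definition — recall = human recall on the
visits the scenario reads, plus AI-red auto-escalation where defined; a
detected cancer is always recalled — and their published values are not
asserted anywhere.

Bootstrap aggregation uses the same resampled cohort for all scenarios in
an iteration (paired comparisons) and reports means and 2.5/97.5
percentiles. With deterministic reader models the cancer contribution is
constant and each iteration reduces to category tallies of the drawn
non-cancer visits, so 10,000 iterations run in seconds.

## Lead-time analysis

For each cancer patient the earliest prior visit scoring at/above the high
cut defines the lead time (months to diagnosis); using the earliest
qualifying prior maximizes the potential gain, and a latest-qualifying
variant exists behind `which="latest"`. Exact months are always retained;
for comparison with published summaries leads are also mapped to the
nearest of the reporting bins {6, 12, 24, 36, 48, 72}, ties to the smaller
bin. The packaged lead-time fixture encodes the published bin structure
(24 patients, 35 positive prior mammograms); the bins' arithmetic mean is
29.25 months, which is what the package reports on that fixture — the
benchmark's printed mean of 29.92 reflects unpublished exact visit
spacings (and its printed SD is internally inconsistent across sections),
so neither is used as an expected value.

## Synthetic cohorts

The generator emulates the benchmark's study conditions: biennial rounds
(24-month spacing, start month jittered within a year), a per-mammogram
cancer rate of 5.7/1000, per-class score distributions whose triage-band
masses equal the benchmark proportions (non-cancer 39.41/53.46/7.13%,
cancer 4.76/22.86/72.38%), the 68/29/8 detection-mode split with
`reader_detected` consistent with the mode, interval diagnoses 1–23 months
and missed diagnoses 1 month after the visit, and AI-positive earlier
visits planted for a 24/105 share of cancer patients at leads drawn from
the published bins.

Numerical choices:

- Within each triage band the score density is **uniform** — the data
  constrain only band masses, and the piecewise-uniform family is the
  least-informative member that keeps the Youden optimum at the configured
  high cut (J increases through yellow and decreases through red whenever
  the cancer class has more red and less yellow mass than the non-cancer
  class). The empirical Youden threshold on large samples therefore
  converges to the configured cut; the suite checks this at n = 100,000
  within 3 score points (the optimum is a kink, so the argmax converges
  slowly in the usual cube-root fashion).
- Cancer is assigned per visit at the configured rate; a woman exits
  screening after her cancer episode, which preserves the per-visit rate
  exactly in expectation and gives at most one episode per woman.
- Planted prior-positive visits are inserted as interim mammogram events
  when the drawn lead is off the biennial grid (real programs contain
  diagnostic visits between rounds), are clamped to the woman's first
  visit when the lead exceeds her history, and are skipped for women
  diagnosed at their first round — the realized planted share is thus the
  configured fraction times the probability of diagnosis after round 1.
- The realized count of patients with *any* AI-positive prior exceeds the
  planted share, because non-cancer scores land in the red band by chance
  (7.13% per prior visit under default masses). Tests that identify the
  planted mechanism therefore zero out the non-cancer red mass.
- One root seed drives five named `SeedSequence` streams (layout, cancer
  assignment, scores, detection modes, priors), so identical configs are
  bit-reproducible and components are independently testable.

What the generator does **not** emulate: tumor growth or score drift over
time, reader variability beyond the recorded labels, correlation between a
woman's successive scores, density/age structure, and non-cancer recall
behavior (a `noncancer_recall_rate` knob exists, default 0, because the
benchmark publishes no non-cancer recall data). Passing tests on synthetic
cohorts therefore validate the *accounting machinery* under the published
marginal structure, not the clinical performance of any AI system on real
images.

## Problem sizes and degenerate inputs

Fixture computations are exact and instantaneous; bootstrap aggregates use
10,000 iterations (the benchmark's own count) for headline numbers and a
few hundred iterations where a test only needs a law-of-large-numbers
check at 3 standard errors; synthetic recovery tests use 100,000 samples.
Degenerate inputs raise typed errors rather than returning silent NaNs:
single-class ROC input, zero-denominator metrics, cut-point order
violations, and a lead-time request on a history without a diagnosis
visit. An empty visit table yields an all-zero triage table; a patient
with no prior visits is simply absent from the lead-time summary.

## Known limitations

- Scenario results on the fixture inherit its category-midpoint scores;
  only category-level quantities are meaningful there.
- The reader models bracket, but cannot identify, true single-reader
  behavior; conclusions about s1 in particular are assumption-driven.
- PPV1/NPV depend on a recall definition the benchmark leaves implicit;
  the package states its own and makes no claim of matching published
  values.
- Woman-level bootstrap trims the last drawn woman's visits to hit the
  target size exactly, slightly biasing within-woman correlation at the
  boundary.
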