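# Methods

## The risk model

PERSEVERE is a classification-and-regression-tree (CART) model for 28-day
mortality in pediatric septic shock.  Its inputs are serum concentrations
of five stratification biomarkers measured within 24 h of presentation —
C-C chemokine ligand 3 (CCL3), interleukin-8 (IL8), heat shock protein
70 kDa 1B (HSPA1B), granzyme B (GZMB), matrix metalloproteinase-8 (MMP8),
all in pg/ml — plus age in decimal years.  The tree itself is *not*
re-derived here: it is consumed as fixed parameters (split rules and
terminal-node mortality probabilities) from a versioned YAML config, so a
recalibrated tree is a new config file, not a code change.

The updated 2014 model structure encoded in the default config has 6
biomarker-based decision rules, 1 age-based rule, 14 daughter nodes and 8
terminal nodes (TN1–TN8), with one biomarker (GZMB) reused on two
branches.  Terminal nodes fall into three bands: low risk (mortality
probability 0.000–0.025; TN2, TN4, TN7), intermediate (0.182–0.267; TN1,
TN3, TN5) and high (0.472–0.625; TN6, TN8).  **The numeric split
thresholds and the interior probabilities of the shipped config are
synthetic placeholders**: the published figure prints the exact values,
but they are not available in machine-readable form here, so the config
encodes the documented structure with physiologically plausible numbers.
Every statistic this package computes depends only on node membership and
node probabilities, never on the particular threshold values, and the
config file is the single place to drop in a verbatim transcription.

Conventions:

* Each split stores its inequality direction explicitly (`op: "<="` or
  `"<"`), making a figure transcription lossless.  With the default
  `"<="`, a value exactly at the threshold routes to the low child.
* Dichotomization uses a mortality-risk cut-off, default 0.025.  A
  probability exactly at the cut-off predicts survival, because the low
  band is inclusive of 0.025 and low-risk subjects are predicted
  survivors.
* Risk banding: low ⇔ p ≤ 0.025; intermediate ⇔ 0.025 < p < 0.40; high ⇔
  p ≥ 0.40.  The 0.40 boundary is an interior point between the printed
  intermediate (≤ 0.267) and high (≥ 0.472) ranges.
* Profiles with negative, non-finite or missing values are rejected, not
  imputed — classification requires a complete serum panel.

## Diagnostic statistics

From the 2×2 table of prediction vs outcome: sensitivity, specificity,
PPV, NPV as the usual cell ratios; likelihood ratios LR+ = sens/(1−spec)
and LR− = (1−sens)/spec.

Binomial proportions carry the **continuity-corrected Wilson score
interval** (Newcombe's method 4):

    L = [2np̂ + z² − 1 − z·√(z² − 2 − 1/n + 4p̂(nq̂ + 1))] / [2(n + z²)]
    U = [2np̂ + z² + 1 + z·√(z² + 2 − 1/n + 4p̂(nq̂ − 1))] / [2(n + z²)]

truncated to [0, 1], with L = 0 at k = 0 and U = 1 at k = n.  The
continuity-corrected form, not the plain Wilson interval, is what the
classic online score-method calculators implement; e.g. for 20/24 it
gives (0.62, 0.95) where plain Wilson gives (0.64, 0.93).

Likelihood-ratio CIs use the standard log method,
se(ln LR) = √(1/a − 1/(a+b) + 1/c − 1/(c+d)) with (a, c) the numerator
cells of the ratio.

The AUC is the tie-aware Mann–Whitney statistic (concordant pairs 1, tied
pairs ½, divided by n₁n₀) — with only eight distinct terminal
probabilities, ties are the norm, so the rank form matters.  Its CI uses
DeLong's placement-value variance estimator by default; Hanley–McNeil is
available by option.  Which method a given published interval used is
generally unknowable without patient-level data, which is why the choice
is an option rather than a constant.

Mean predicted mortality (the average assigned terminal probability) gets
a normal-approximation CI, mean ± z·SD/√n, truncated to [0, 1] — the
per-subject probabilities are bounded, so the CLT approximation is
comfortable at cohort sizes in the hundreds.

Zero-denominator statistics are reported as undefined by name, never
silently dropped.  Display rounding (whole percents, 1 decimal for LRs, 3
for AUC) is applied only in the text renderer; full precision is kept
internally.

## Net reclassification improvement

The baseline model is a univariable maximum-likelihood logistic
regression of 28-day mortality on the PRISM score, complete-case
(subjects without PRISM are excluded; no imputation).  A constant PRISM
column degenerates to the intercept-only fit (everyone gets the
prevalence); a non-converged fit (e.g. perfect separation) falls back to
a ridge-penalized fit with a warning.

The category-free NRI compares each subject's baseline risk with the
tree's terminal probability: "up" means strictly greater, ties count as
neither.  NRI = (P(up|event) − P(down|event)) + (P(down|nonevent) −
P(up|nonevent)), bounded in [−2, 2].  The SE is the asymptotic
multinomial form

    SE² = [p↑ᵉ + p↓ᵉ − (p↑ᵉ − p↓ᵉ)²]/n_events + [p↑ⁿ + p↓ⁿ − (p↓ⁿ − p↑ⁿ)²]/n_nonevents

with a two-sided normal test of NRI = 0.  A categorical variant over the
ordered low < intermediate < high strata is provided because the tree's
output is naturally three-stratum.  Under the null (new risks = baseline
plus symmetric noise, outcome independent of movement) the p-values are
uniform; the test suite verifies this to Monte-Carlo precision at 1000
replicates of n = 500.

## Clinical-course analysis

PICU free days = 28 − floor(length of stay), clamped to 0 for deaths
within 28 days or stays over 28 days; lengths of stay are floored so free
days are whole days.  Group contrasts use the two-sided Mann–Whitney
U-test — exact enumeration when both groups have ≤ 8 tie-free
observations, otherwise the normal approximation with tie and continuity
correction.  (Exhaustive enumeration at n = 8 vs 8 shows the two agree
within 0.011 everywhere and within 0.01 wherever the exact p < 0.25; the
worst case sits at the center of the null distribution.)  2×2 tables use
Fisher's exact test when any expected cell count is below 5 and the
continuity-corrected χ² otherwise.  "Organ-failure duration" is
operationalized as the day-7 persistence indicator (≥ 2 organ failures at
PICU day 7), the only duration variable with a published summary.
Quantile summaries use linearly interpolated 25th/75th percentiles.
False positives and true negatives are defined among survivors only:
predicted non-survivor vs predicted survivor.

## Synthetic cohorts

The generator emulates the *statistical structure* the evaluation
assumes, not septic-shock physiology:

* **Membership** is multinomial over a configured terminal-node occupancy,
  or exact integer counts.  The default emulation of the 182-subject
  validation cohort uses counts (TN1..TN8) = 20, 70, 8, 25, 13, 14, 28, 4
  — 123 subjects in low-risk nodes, 59 in intermediate/high.
* **Biomarkers/age** are uniform inside the terminal's admissible region
  (the intersection of ancestor split half-lines; unconstrained variables
  span 0 to 10× the variable's largest threshold, age 0–18 y).  Sampling
  stays strictly interior, so classification round-trips exactly.
  Uniform-in-cell suffices because every downstream statistic depends
  only on node membership.
* **Death** is Bernoulli per node, or — in deterministic-allocation mode —
  exactly round(n·p) deaths per node, which lets a configured cohort hit
  printed contingency counts exactly instead of their Bernoulli
  neighborhoods.  The default emulation allocates deaths
  (4, 3, 2, 0, 3, 8, 1, 3) across TN1..TN8: 4 in low-risk nodes, 20
  elsewhere, 24 total (13.2% mortality), giving TP 20 / FP 39 / TN 119 /
  FN 4.
* **PRISM** is outcome-conditional gamma, quartile-matched to the
  published survivor 11 (8–15) and non-survivor 19 (13–25) summaries:
  shapes/scales (4.8377, 2.4587) and (4.7290, 4.2228), rounded to integer
  scores.  Gamma because severity scores are non-negative and
  right-skewed.
* **Clinical course** is drawn conditional on stratum — deaths; low-risk
  survivors ("true negatives"); intermediate/high survivors ("false
  positives") — with gammas quartile-matched to stays of 4 (3–9) vs
  7 (4–13) days (deaths 4 (2–6), matching the published days-to-death),
  discrete organ-failure distributions with medians 1 (1–2) vs 3 (2–3),
  and day-7 persistence probabilities 0.10 vs 0.46.
* **Reproducibility**: one seed feeds named SeedSequence substreams per
  variable family (membership, biomarkers, deaths, PRISM, course, flags,
  order), so a config + seed yields a byte-identical CSV.

What the generator does *not* model: inter-biomarker correlation beyond
cell membership, realistic marginal biomarker distributions, longitudinal
physiology, site effects, or any association between biomarker values and
outcome *within* a terminal node.  Consequently, passing tests demonstrate
the correctness of the pipeline's arithmetic and its behavior under the
documented cohort structure — not the clinical performance of the model on
real patients, which only a real cohort can show.

## Problem sizes and numerical choices

The law-of-large-numbers recovery checks run at n = 50,000 subjects
(occupancy and node mortality within 3 binomial SE; PRISM via the
empirical CDF at the published medians), the NRI oracle comparison at
1,000 cohorts of n = 200, and the null-calibration at 1,000 replicates of
n = 500 — sizes at which the asymptotics under test are unambiguous while
the whole suite stays interactive.  The multi-seed false-positive
contrast check uses 10 cohorts at the published 119/39 group sizes; at
the configured shift the length-of-stay contrast has roughly 70% power
per cohort, so it is asserted as a majority-of-seeds property rather than
a single-draw p-value.

Tie-breaks and degenerate inputs: boundary values route to the low child
under `"<="`; empty cohorts, single-class outcome vectors, all-zero
tables and zero denominators raise or flag explicitly; contradictory
path constraints (an empty interval) are reported with the offending
variable and split.
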