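# Methods

This note documents the statistical procedures, the simulation model behind
the synthetic cohorts, the numerical choices, and the limitations of both.

## Cohort selection and birth-weight classification

A kitten enters the analysis if it has a recorded birth weight (Day 0) and a
known alive/dead status at 2 months (taken as a 60-day horizon). Selection is
a pure filter: retained and excluded records partition the input and the
operation is idempotent. Classification is per breed: birth weight strictly
below the breed's low-birth-weight threshold ⇒ LBW; a weight exactly at the
threshold is NBW. The threshold table is an input — deriving breed thresholds
is out of scope — and looking up a breed absent from the table is an error
rather than a silent default, since misclassification against the wrong
breed's threshold is worse than failing loudly. Kittens of unknown sex are
retained throughout; kittens dead with an unknown death day count toward
0–2-month mortality but are excluded from death-timing analyses and from the
survivor-conditioned model fits, where survival to the window start cannot be
verified for them.

## Growth rates and outlier screening

`GR x–y = 100·(w_y − w_x)/w_x` (percent of the Day-x weight). The five study
intervals are 0–1, 1–2, 0–2, 2–7 and 0–7 days; single-day rates cover Day
0→1 … 6→7. A rate exists only when both endpoint weights do. The chained
identity `(1 + GR 0–2/100) = (1 + GR 0–1/100)(1 + GR 1–2/100)` holds exactly
for complete profiles and is property-tested.

Outliers are screened in one species-level pass: for each of the five
intervals, Tukey fences `[Q25 − m·IQR, Q75 + m·IQR]` (default m = 1.5) are
computed on the pooled pre-exclusion distribution, and a kitten with any rate
strictly outside its interval's fences is dropped entirely. There is no
iterative re-fencing, and a missing rate never excludes. Values exactly on a
fence are inside (the rule is strict `<` / `>`).

Quantiles everywhere — fences and quartile breakpoints — use linear
interpolation between order statistics ("type 7", the numpy/R default); the
rule is configurable since nothing pins it down externally. Quartile groups
are assigned at species level with closed upper boundaries: group 1 iff
value ≤ Q1, group 2 iff Q1 < value ≤ Q2, etc., making assignment monotone in
the value.

Welch's t-test (Satterthwaite df, two-sided) compares LBW vs NBW per
interval; Cohen's d uses the pooled-SD convention with the conventional
bands |d| < 0.2 negligible, < 0.5 small, < 0.8 medium, ≥ 0.8 large.
Daily-rate comparisons are paired t-tests between consecutive days on
pairwise-complete kittens.

## Factorial mortality model and marginal means

For each of the windows Day 1→2 mo (with GR 0–1), Day 2→2 mo (GR 0–2) and
Day 7→2 mo (GR 0–7), death is modelled by a binomial GLM with logit link on
birth-weight category, growth-quartile group and their interaction —
a saturated 2×4 factorial, so fitted cell probabilities must equal the
empirical cell death fractions; this identity (to 1e-6) is the primary
correctness check of the fit. Deaths at exactly the window's start day count
as prior deaths and are excluded.

Fitting is IRLS on the cell-aggregated binomial counts (identical
coefficients to observation-level IRLS; verified against an independent GLM
implementation to 1e-6): deviance-change tolerance 1e-8, at most 25
iterations, half-stepping when a step increases deviance. An empty cell is a
rank-deficiency error naming the cell. A cell with empirical mortality 0 or 1
is *separation*: finite ML coefficients do not exist, the fit is flagged, the
affected cell logits are reported as ±∞ sentinels, and marginal means refuse
to run (the remedy is collapsing cells, not pretending at standard errors).

Estimated marginal means per cell are linear transforms of the coefficients
(for the saturated model, the cell logits themselves) with delta-method
standard errors; probability-scale means are the inverse logit of the
logit-scale means and are invariant to the reference-cell coding. All 28
pairwise contrasts are adjusted by Tukey's studentized-range method with
asymptotic df by default (the customary default of marginal-means software;
Bonferroni and Holm are available). The compact letter display uses the
insert-and-absorb algorithm, guaranteeing that cells sharing a letter are
never a significantly different pair.

Death timing uses the fixed bins 0–2, 3–21 and 22–60 days. Each period is
compared between categories by a 2×2 chi-square **without** continuity
correction, so the statistic is exactly Σ(O−E)²/E; at the death counts this
analysis is meant for (hundreds), the correction is immaterial, and the
uncorrected statistic is the transparent one.

Binomial CIs default to Wald (z·√(p(1−p)/n), clipped to [0, 100]%), with the
Wilson score interval available; percentages are rounded only at
presentation.

## Cost-sensitive alarm thresholds

The class imbalance (few deaths, many survivors) would let an unweighted tree
ignore deaths, so the 10:1 false-negative : false-positive cost matrix is
realized as *altered priors*: the death-class prior is the empirical prior
inflated by fn_cost/fp_cost and renormalized — the standard CART treatment of
a two-class loss matrix, equivalent to giving every death 10× a survivor's
weight in the Gini criterion. Trees are depth-1 because exactly one cutpoint
per growth rate per category is sought; depth is not a tuning dimension here.

Candidate cutpoints are midpoints between adjacent distinct sorted values;
children smaller than min_leaf (default 7, a conventional tree default) are
inadmissible; a split must strictly reduce the prior-weighted impurity;
criterion ties break toward the smallest cutpoint (a later candidate must
improve by more than 1e-10 to displace an earlier one, which also makes the
tie-break robust to cumulative-sum float noise). The scanning implementation
is property-tested against brute-force enumeration of the same criterion, and
against an independent reference tree (unit costs, and 10:1 costs via class
weights, which induce the same criterion).

Cross-validation: observations are split into 10 folds (stratified by
outcome by default, seeded); each fold's *training* side fits one stump; the
alarm threshold is the median of the 10 training-fold cutpoints (mean of the
middle pair). This is one of two readings of "median of the 10 values" —
the other would take values from a tuning path inside a single fit — and is
recorded as the implemented interpretation. Folds yielding no split are
excluded from the median with a warning; more than half failing aborts with
diagnostics.

Screening metrics are computed on the full per-category subset at the final
threshold with the at-risk rule `value < threshold` (a value equal to the
threshold is not at risk): Se = tp/(tp+fn), Sp = tn/(tn+fp), PPV = tp/(tp+fp),
NPV = tn/(tn+fn), mortality below/above as percentages, and the
multiplication term as their ratio. Thresholds are reported at full
precision; any rounding is presentational.

## Synthetic cohort model

The generator's defaults are the study conditions; they are set once and are
not tuning knobs.

* **Litters:** 1,223 litters (≈5,500 kittens); sizes `round(N(4.5, 1.5))`
  truncated at 1. Breeds are assigned per litter, uniformly across three
  synthetic breeds with birth weights N(85, 13), N(101, 14) and N(120, 16) g
  (spanning the plausible feline range of roughly 36–182 g; draws ≤30 g are
  redrawn). Each breed's LBW threshold sits at its 19.5th percentile, so LBW
  prevalence is ~19.5% by construction. No litter-level random effects are
  modelled, in weights or mortality — the downstream model has no litter
  term.
* **Growth:** `w(d+1) = w(d)·(1 + g_d/100)` with g_d i.i.d. Gaussian per
  category. Daily means/SDs are inverted in closed form from weekly GR 0–7
  targets — LBW 99.9 (SD 30.4), NBW 86.9 (SD 23) — giving daily LBW
  (10.40, 6.31) and NBW (9.35, 5.07), i.e. an overall daily mean near 9.5%.
  Independent increments cannot simultaneously match realistic *single-day*
  SDs (≈8–10, which imply day-to-day anticorrelation such as measurement
  noise) and the weekly SDs; the weekly moments win because the mortality
  model, the effect-size structure and the threshold analyses all operate on
  GR 0–7. Daily means are constant across days, so the generator does not
  emulate the empirical early-week deceleration of growth.
* **Mortality:** logit P(death) = baseline + shift·1[LBW] + slope·GR0–7
  (latent, i.e. the full-week growth the kitten would have had), slope −0.02
  per GR point. Baseline and shift are solved by Gauss–Hermite quadrature
  over the weekly-growth distribution so the marginal category rates are
  19.2% (LBW) and 4.4% (NBW) — ~7.4% overall and a ~4.4× ratio. A planted
  *step* alternative (risk_below/risk_above around a cutpoint on a named
  rate) replaces the logit model for parameter-recovery experiments.
* **Timing and missingness:** conditional on death, a period is drawn per
  category — LBW (0.50, 0.38, 0.12), NBW (0.35, 0.40, 0.25) over 0–2 / 3–21 /
  22–60 days, putting ≈80% of deaths in the neonatal period — and the day
  uniformly within it. Weights after the death day are never recorded; each
  weighing from Day 1 on is independently missing with probability 0.08,
  which reproduces per-interval sample sizes of roughly 80–90% of the cohort.

One root seed drives everything; litter-level sub-streams are spawned
deterministically, so cohorts are byte-identical under a fixed config.

**What passing tests on these cohorts does not show:** real kitten growth has
day-to-day measurement noise and autocorrelation, litter and maternal
effects, informative (not random) missingness, and mortality that depends on
more than one growth summary; recovery of a planted step demonstrates the
threshold machinery, not that real mortality is step-shaped. Calibration
checks demonstrate the generator hits its configured targets, not field
validity of those targets.

## Problem sizes

The default cohort is ~5,500 kittens; the parameter-recovery experiment uses
20 replicates of ~800 kittens (10-fold CV each); oracle-equivalence property
tests use random instances up to n = 500. The full test suite and the
acceptance script each run in well under a minute on one CPU.

## Known limitations

* Separated factorial cells stop the marginal-means stage; no Firth or
  Bayesian shrinkage fallback is provided.
* The chi-square period comparison has no exact-test fallback for tiny
  expected counts; it errors and says so.
* Cost sensitivity is limited to a 2-class loss ratio via altered priors;
  asymmetric per-observation costs and deeper trees are out of scope.
* The generator absorbs breeder interventions (supplemental feeding of small
  kittens) into the category growth distributions rather than modelling them
  as a process.
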