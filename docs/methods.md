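# Methods

This note records the statistical model behind `mlmfi`, the choices made
where the design was genuinely open, and what the synthetic cohort does
and does not establish.

## The analysis pipeline

1. **Cohort filter** — subjects aged 65–100 at baseline (inclusive on
   both ends), optionally one sex.
2. **Deficit ascertainment** — condition c is present for subject s iff
   s has ≥ 3 outpatient claim rows or ≥ 1 inpatient claim row with a
   code in c's ICD-9-CM family inside the baseline-year window.
   Implementation details that matter:
   * codes are normalized by stripping dots and upper-casing, then
     matched by string prefix; numeric prefixes must name at least the
     3-digit code family (the catalog loader rejects shorter ones), and
     V/E codes match literally;
   * claim rows are deduplicated on (subject, date, setting, normalized
     code) before counting, so a repeated identical row — including
     three same-day duplicates of one outpatient visit — cannot
     fabricate a deficit. Users whose data legitimately contain several
     identical same-day claims should be aware of this collapse;
   * subjects with no qualifying claims keep an all-zero row: they are
     the fit candidates, not missing data.
3. **Condition ranking** — mean decrease accuracy from a random forest:
   for each tree, out-of-bag accuracy minus OOB accuracy after permuting
   one condition's column, averaged over trees (unscaled, as in the
   classic randomForest importance). The per-tree OOB sets are
   recovered by replaying each tree's bootstrap draw
   (`RandomState(tree.random_state).randint(0, n, n)`), which the test
   suite verifies against `forest.oob_score_` bit-for-bit. Ties are
   broken by condition id so rankings are total and reproducible.
4. **Choosing k** — the forest is refit on the top-k conditions for
   every k in the grid (default: every k from 1 to p); model accuracy is
   out-of-bag classification accuracy; selected k = argmax, smallest k
   on ties. The full accuracy-vs-k trace is kept for plotting.
   The forest target is death during the full follow-up window by
   default; both the outcome and the horizon are configurable. No class
   reweighting is applied by default.
5. **Scoring** — ML-mFI = (count of selected conditions present) / k,
   so scores live exactly on {0, 1/k, …, 1}. A user-supplied expert
   condition list can be scored the same way as a comparator index
   (`index_kind="reference_mfi"`).
6. **Cut-point search** — see below.
7. **Survival evaluation** — KM + log-rank + Cox (unadjusted and
   age/sex-adjusted) per outcome × horizon, C-index per outcome.

## Distance and coverage indices

With four KM curves ordered fit → severe on a common monthly grid,

* D(t) = min{S_fit − S_mild, S_mild − S_mod, S_mod − S_sev} at t. The
  minimum (rather than, say, the mean gap) is what encodes "wide *and*
  balanced": D is large only when every adjacent pair is well separated.
  D < 0 flags crossed curves.
* C(t) = L_error / L_total, L_error = Σ over the four groups of the 95%
  CI length at t, L_total = S_fit(t) − S_severe(t). C is undefined
  (flagged, candidate infeasible) when L_total ≤ 0.

Criteria mapping: the max-min criterion is applied to D (maximize the
worst-time separation) and the min-max criterion to C (minimize the
worst-time relative error) — the only assignment consistent with
"larger D is better, smaller C is better". Both index formulas are
isolated behind single functions so alternatives can be swapped.

The search space is every ordered triple of candidate thresholds, where
candidates are midpoints between consecutive distinct observed score
values (the score lattice is finite, so this enumeration is exhaustive
up to equivalence of partitions). Hard feasibility constraints, checked
at every grid month (the grid runs from month 12 to month 96 by
default — dose order is demanded at any time after the first year over
an 8-year follow-up):

* every group ≥ max(30, 0.5% of n) subjects (both constants
  configurable);
* all three adjacent gaps strictly positive;
* adjacent 95% CIs disjoint (lower bound of the higher curve above the
  upper bound of the lower curve).

CI non-overlap is a hard constraint rather than a by-product of the
objective, because the target property of the final grouping is "no
overlaps between the survival curves" — encoding it as a constraint
makes the guarantee unconditional. When no candidate is feasible the
result names the violated constraint of the best-scoring infeasible
candidate instead of returning a partition silently.

## Survival conventions

* Time unit: months; dates are converted by exact day counts / 30.4375.
* Horizons (1/5/8 years) are applied as administrative censoring at
  12·h months with a separate model fit per horizon.
* Non-fatal outcomes censor at death; mortality does not.
* KM confidence intervals: Greenwood variance on the log(−log) scale,
  which keeps bounds inside [0, 1] (needed by the coverage index). The
  KM/Greenwood/CI computation is implemented in vectorized numpy
  because the cut-point search evaluates thousands of curve sets on the
  monthly grid; the test suite pins it against a brute-force
  product-limit oracle (1e-12) and against lifelines (1e-10).
* Cox models: lifelines `CoxPHFitter`, Efron tie handling (identical to
  Breslow when there are no ties). Group dummies with fit as reference;
  adjusted models add age (years) and male sex. A group with zero
  events is reported with a non-estimable flag rather than a spurious
  number. With very strong group effects the default Newton step can
  overshoot a perfectly finite maximum; the fitter retries with damped
  steps (0.25, then 0.1) before raising — estimates are unchanged when
  the default succeeds.
* Log-rank: lifelines k-sample test (dof = groups − 1); Harrell's C:
  lifelines concordance index over censoring-comparable pairs, ties at
  1/2. Both are pinned against hand/brute-force oracles in the tests.

## The synthetic cohort

Real claims panels of this kind are access-restricted, so the generator
produces cohorts with the structure the analysis assumes:

* latent frailty f = z + 0.02·(age − 82.5), z ~ N(0,1); age is drawn
  from five-year bands weighted like an insured elderly population
  (youngest bands dominate), sex ~ Bernoulli(0.502 female);
* condition presence: logit P(c) = logit(base_c) + 1.0·f, with
  per-condition baselines spread uniformly within ±60% of 0.10;
* 5 of 50 conditions are "informative": each multiplies the death,
  hospitalization and ICU hazards by 3 (log HR = log 3). The linear
  predictor adds 0.05·(age − 75), 0.3 for male sex and 0.3·z (the
  direct latent-frailty effect), and event times are exponential around
  baseline rates 0.04 / 0.12 / 0.05 events per person-year;
* claims: present conditions emit zero-truncated-Poisson(mean 4)
  outpatient rows and, with probability 0.15, one inpatient row — so
  the ≥3/≥1 rule misses a realistic fraction of true conditions; absent
  conditions emit 1–2 "rule-out" outpatient rows with probability 0.05,
  never enough to qualify;
* 5% of subjects are administratively censored uniformly before the
  8-year window ends; everyone else is censored at 8 years.

The prevalence and effect-size defaults were fixed once so that the
cohort actually exhibits the structure the method is built to detect —
a feasible, dose-ordered four-group partition at a few thousand
subjects, adjusted hazard ratios in the single-to-low-double-digit
range, and an 8-year death fraction near 0.45 — and are all exposed in
`SimulationConfig`.

What the generator does **not** emulate: realistic ICD-9 code frequency
distributions, correlated comorbidity clusters beyond the single latent
factor, enrollment churn, multi-year re-ascertainment, or competing
risks (latent event times are independent; censoring-at-death is applied
by the analysis layer, which owns that semantic). Subjects who would die
during the baseline year are not modeled — the generator emits only
subjects alive through baseline. Passing tests therefore show that the
pipeline recovers planted structure under its own model assumptions, not
that it would behave identically on real claims.

All draws flow from one root `numpy.random.Generator` in a fixed
order (ages, sex, latent frailty, prevalence baselines, condition
presence, informative-set choice, claim counts, claim dates/codes,
event times, censoring), so a config + seed determines every output
byte; the pipeline writes no timestamps into stage artifacts, making
end-to-end reruns byte-identical.

## Problem sizes

The shipped demonstration and verification runs use desk-scale cohorts
chosen as the package's own defaults: a 2000-subject demo (150-tree
forests, k grid stride 3; ~15 s), a 4000-subject selection-recovery run
and a 5000-subject dose-response run (300-tree forests, full k grid;
~90 s), and 200 replicates of 500 subjects for null calibration of the
Cox interval coverage. Forest sizes are configurable; the library
default is 500 trees.

## Known limitations

* "Model accuracy" is interpreted as out-of-bag classification
  accuracy; alternatives (held-out accuracy, AUC) are not implemented.
* The four-group count is fixed; a generalized g-group search is out of
  scope.
* No proportional-hazards diagnostics are run; HRs are reported as
  fitted.
* The importance measure inherits the known biases of permutation
  importance under correlated predictors; no debiasing is applied.
* Feasibility of the cut-point search depends on cohort size: below
  roughly two thousand subjects the CI-disjointness constraint is
  rarely satisfiable and the search reports infeasibility rather than
  forcing a partition.
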