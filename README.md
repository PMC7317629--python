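# mlmfi — machine-learning multimorbidity frailty index

`mlmfi` implements a data-driven, claims-based frailty index for older
adults, together with the survival-curve risk stratification that turns
the continuous index into four clinically ordered frailty groups. It is
aimed at epidemiologists and health-services researchers who work with
administrative claims (subject registry + outpatient/inpatient diagnosis
rows, ICD-9-CM coded) and want a fully automated, reproducible pipeline
from raw claims to hazard-ratio tables.

## The method

**Deficit ascertainment.** Under the cumulative-deficit model of aging,
a frailty index is the fraction of considered health deficits a person
has: FI = (number of deficits present) / (number considered), in [0, 1].
A diagnosis counts as a deficit in the baseline year only when it passes
the claims-validation convention used throughout Taiwanese
National-Health-Insurance research: **at least 3 outpatient claim
records or at least 1 inpatient claim record** whose code falls in the
condition's ICD-9-CM family.

**Condition selection.** Instead of an expert-curated item list, a
random-forest classifier predicts the adverse outcome (all-cause death
by default) from the binary deficit matrix, and conditions are ranked by
*mean decrease accuracy* — the drop in out-of-bag accuracy when a
condition's column is permuted, averaged over trees. For each candidate
count k the forest is refit on the top-k conditions; the selected k
maximizes out-of-bag accuracy (smallest k on ties). The ML-based index
is then ML-mFI = (selected conditions present) / k.

**Risk stratification.** Cut-points (c1, c2, c3) partition the score
into fit [0, c1), mild [c1, c2), moderate [c2, c3) and severe [c3, 1].
For the four Kaplan-Meier curves S_fit ≥ … ≥ S_severe evaluated
monthly, two indices drive the search:

* distance index D(t) = min over the three adjacent pairs of
  (S_upper(t) − S_lower(t)) — large only when all gaps are wide;
* coverage index C(t) = L_error(t) / L_total(t), with L_error the
  summed 95% CI lengths of the four curves and
  L_total = S_fit(t) − S_severe(t) — small when estimation error is
  small relative to the total spread.

The search enumerates all threshold triples on midpoints of consecutive
observed score values, discards candidates with an undersized group, a
non-positive adjacent gap or overlapping adjacent CIs at any month after
the first year, and among feasible candidates **maximizes min-over-t D**
(max-min), breaking ties by **minimizing max-over-t C** (min-max), then
lexicographically. The winning partition is guaranteed dose-ordered:
severe > moderate > mild > fit risk at every evaluated time.

**Evaluation.** Kaplan-Meier curves with Greenwood variance and
log(−log) CIs, k-group log-rank tests, Cox proportional-hazards HRs
(Efron ties; unadjusted and age/sex-adjusted; fit group as reference) at
1/5/8-year horizons, and Harrell's C. Non-fatal outcomes (unplanned
hospitalization, ICU admission) are censored at death.

Because real claims databases are access-restricted, the package ships a
synthetic cohort generator (`mlmfi.synthetic_cohort`) that emulates the
assumed data-generating structure — a latent frailty that raises both
condition prevalence and event hazards log-linearly — plus a
ground-truth ledger so selection and dose-response recovery can be
tested end to end.

## Worked example

```python
from mlmfi import (PipelineConfig, SimulationConfig, RFSettings, run_pipeline)

config = PipelineConfig(
    output_dir="demo_run",
    seed=42,
    simulation=SimulationConfig(n_subjects=2000, seed=42),
    rf=RFSettings(n_trees=150, seed=42),
    k_stride=3,
)
report = run_pipeline(config)
print(report.model.selected_k, report.stratification.cutpoints.as_tuple())
```

This simulates a 2000-subject cohort (50 candidate conditions, 5 truly
hazardous ones with per-condition HR 3), ascertains deficits, selects
conditions, scores, stratifies and evaluates. The run prints/persists:

```
selected_k: 10   OOB accuracy: 0.704
cut-points: (0.15, 0.25, 0.35)
group sizes: fit 1581, mild 238, moderate 105, severe 76
adjusted 8-year mortality HRs (fit = reference):
   group    hr  ci_low  ci_high
    mild  2.61    2.18     3.11
moderate  4.15    3.30     5.22
  severe 10.00    7.80    12.82
C-index (mortality): 0.672
```

Read: the forest kept 10 of 50 conditions (the 5 informative ones plus
correlates of the latent frailty); the cut-point search found a feasible
four-group partition whose KM curves stay strictly separated with
disjoint 95% CIs from month 12 to 96; adjusted mortality hazards rise
monotonically fit → severe; and the continuous score discriminates
8-year survival with C > 0.6. Artifacts (deficit matrix, model JSON,
scores, groups, HR table, KM curves, Markdown report) land in
`demo_run/`.

The same pipeline runs from the shell:

```bash
mlmfi run-all --config config.yaml --seed 42 --out demo_run
mlmfi stratified --config config.yaml --strata age   # per-age-band reruns
```

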