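# carealert

Symptom-distress analysis for caregiver e-alert trials: threshold scoring
of serial caregiver check-ins, bimonthly proportion indices, trapezoidal
AUC contrasts, and the full two-sample binomial inference battery, with a
seeded synthetic cohort generator standing in for raw trial data.

## The problem

In trials of e-alert systems for advanced-cancer care, a family caregiver
rates 10 patient symptoms (a modified Edmonton Symptom Assessment Scale)
on a 0–10 scale at weekly online check-ins.  A rating ≥ 7 is a *threshold
symptom*: severe enough that, in the intervention arm, the system pages
the clinical team.  The analysis questions are (1) whether threshold
symptoms are more likely to be rated lower at the next check-in (improved)
when clinicians are alerted, and (2) whether caregivers who know their
ratings page a clinician report fewer threshold symptoms in the first
place (response bias).  Raw data from the pooled pair of randomized trials
this package models were never deposited — only group-level count tables —
so the package pairs the published aggregates with a synthetic dyad cohort
generator that reproduces the structure of the raw streams (weekly
cadence, carry-forward ratings, attrition, arm-specific under-reporting).

It is written for biostatisticians and trialists who need a tested,
reproducible implementation of this scoring-and-inference pipeline, either
to reanalyze the published aggregates or to design similar monitoring
studies by simulation.

## The statistics

For two independent binomial samples x₁/n₁ and x₂/n₂ with p̂ᵢ = xᵢ/nᵢ:

* **Pooled Z test**: z = (p̂₁ − p̂₂)/√(p̄(1−p̄)(1/n₁ + 1/n₂)), p̄ = (x₁+x₂)/(n₁+n₂).
* **Unpooled Wald CI**: p̂₁ − p̂₂ ± z₁₋α/₂ √(p̂₁q̂₁/n₁ + p̂₂q̂₂/n₂).
* **Miettinen–Nurminen score CI**: the set of δ with |z(δ)| ≤ z₁₋α/₂,
  where z(δ) uses the MLE of (p₁, p₂) restricted to p₁ − p₂ = δ and the
  variance is inflated by N/(N−1); bounds by bracketed root search.
* **Chan–Zhang exact unconditional CI**: inversion of two one-sided exact
  tests (α/2 each) whose p-value is the supremum over the nuisance
  proportion of the exact tail probability of the MN score statistic,
  computed by full enumeration of the joint binomial outcome space.
* **Cohen's h**: |2 asin √p̂₁ − 2 asin √p̂₂|.
* **Two-group McNemar**: per arm, the net change d = (b − c)/N of paired
  threshold status between pretest and first check-in, with
  v = (b + c − (b−c)²/N)/N²; z = (d_alert − d_control)/√(v₁ + v₂).
* **AUC contrast**: trapezoidal area under each arm's bimonthly proportion
  trajectory, normalized to relative proportions r₁ + r₂ = 1 and compared
  by delegating (round(rᵢnᵢ), nᵢ) to the machinery above.

## Worked example

The headline published contrast — 235/443 improved threshold symptoms in
the alerted arm vs 332/1269 in the control arm:

```sh
$ carealert calc 235 443 332 1269 --method mn
{
  "x1": 235, "n1": 443, "x2": 332, "n2": 1269,
  "p1": 0.5304740406320542,
  "p2": 0.2616233254531127,
  "diff": 0.2688507151789415,
  "z": 10.351456886475983,
  "p_value": 4.1216547246635234e-25,
  "cohen_h": 0.5580898478598999,
  "alpha": 0.05,
  "ci_mn_low": 0.21622605887715382,
  "ci_mn_high": 0.3207526111211307
}
```

Alerted-arm threshold symptoms were improved at the next check-in 53.0% of
the time versus 26.2% in the control arm — a 26.9-point difference (95%
score CI 21.6 to 32.1 points, z = 10.35), effect size h = 0.56.

The numbered drivers under `analysis/` run the whole pipeline on a
simulated cohort and on the published aggregates:

```sh
$ python analysis/01_simulate_cohort.py --seed 1   # writes results/cohort.csv
$ python analysis/02_score_checkins.py             # bimonthly indices, alerts
$ python analysis/03_compare_proportions.py
published improved_of_threshold  p_alert=0.5305 p_control=0.2616 z= +10.35 p=4.12e-25 h=0.558 MN 95% CI [+0.216, +0.321]
published threshold_of_assessed  p_alert=0.0770 p_control=0.1440 z= -12.27 p=1.34e-34 h=0.216 MN 95% CI [-0.077, -0.057]
...
$ python analysis/04_auc_contrast.py               # trapezoidal AUC contrast
$ python analysis/05_response_bias.py              # pretest vs first check-in
```

In step 05 the simulated cohort shows the response-bias signature built
into its defaults: arms indistinguishable at pretest (h = 0.03) but fewer
alerted-arm threshold reports at the first online check-in (h = 0.18,
two-group McNemar z = 3.5).

## Layout

```
src/carealert/      library: cohort generator, scoring, inference, AUC,
                    pipeline, CLI, published count tables
analysis/           numbered narrative drivers (simulate → score → infer)
scripts/            acceptance recomputation
tests/              pytest suite incl. oracle and coverage checks
docs/methods.md     model, estimators, numerical choices, limitations
```
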