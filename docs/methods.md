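# Methods

This note records the models, estimators, numerical choices and known
limitations of the package.  Everything quantitative stated here is
computed by the test suite or the analysis drivers; nothing is asserted
from memory.

## 1. Synthetic cohort model

The generator emulates the raw material of a two-arm caregiver e-alert
trial.  Each dyad (patient + family caregiver) completes a pretest paper
survey at day 0 and is due an online check-in every
`checkin_interval_days` (default 7) days through `study_days` (default
365), rating `n_symptoms` = 10 symptoms on the integer 0–10 scale.

### Latent severity process

Per (dyad, symptom), latent severity follows a stationary Gaussian AR(1):

    x_t = μ + ρ (x_{t−1} − μ) + ε_t,
    ε_t ~ N(0, (1 − ρ²) σ² + τ²),
    x_0 ~ N(μ, σ),

with μ = `baseline_mean` (default 4.5), σ = `baseline_sd` (2.1),
ρ = `persistence` (0.8) and τ = `shock_sd` (0.5).  The innovation variance
is parametrized so that with τ = 0 the marginal stays exactly N(μ, σ²) at
every check-in; τ adds week-to-week reporting jitter on top.  The reported
rating is round-half-up of the latent value, clamped to {0, …, 10}
(`clip(floor(x + 0.5), 0, 10)`).  Rounding makes consecutive ratings
frequently identical, which is how carry-forward pre-populated forms
behave; a rating changes only when the latent severity moves by at least
one level.  With μ = 4.5, σ = 2.1, the discretized upper-tail mass at the
alert threshold (rating ≥ 7 ⇔ latent ≥ 6.5) is ≈ 0.17, matching the
published pretest threshold rate of about 17.5%.  The tail-mass identity
is verified against a quadrature oracle over the rounding/clamping map
(`tests/test_cohort.py`).

### Arm mechanisms

* **Allocation**: 1:1, dyads alternating CONTROL/ALERT before attrition.
* **Attrition**: geometric per-check-in hazard
  (`attrition_hazard_per_checkin`, default 0.011 ≈ 44% cumulative dropout
  over 52 check-ins, matching the roughly 117 → 65 decline in reporting
  caregivers per arm over 12 months).  A dropped dyad produces no further
  records.
* **Alert response**: after a *completed* check-in reports a symptom at
  ≥ 7, the next scheduled rating of that symptom is drawn conditionally:
  with probability `improvement_prob_given_alert` (ALERT arm, default
  0.53) or `improvement_prob_control` (CONTROL, 0.26) the reported rating
  is forced strictly lower, otherwise forced equal-or-higher.  The forcing
  is a truncated-normal draw of the latent value (inverse-CDF method), so
  the process stays coherent and the conditional improvement probability
  equals the parameter exactly — which is what makes the parameter-recovery
  acceptance check meaningful.  The defaults are the improvement
  proportions observed in the published totals.  Setting both
  probabilities to `None` disables the mechanism entirely and leaves the
  natural AR dynamics (used by the distributional oracle and the null
  calibration).  The mechanism is memoryless: it looks back exactly one
  scheduled check-in, mirroring the one-step horizon of the improvement
  definition.
* **Reporting bias** (ALERT arm, online only): a due check-in is completed
  with probability `bias_report_prob` (default 0.65, the ratio of the two
  arms' published symptom-report volumes 5750/8810), and latent severities
  are shifted by `bias_rating_shift` (default −0.6, which moves the
  discretized threshold mass from ≈ 0.17 to ≈ 0.11, the published
  first-check-in contrast) before rounding.  The pretest is never thinned
  or shifted: it was a paper survey not forwarded to clinicians, so any
  reluctance to alert could not yet operate.
* **Seeding**: one master seed; per-dyad substreams from
  `SeedSequence(seed, spawn_key=(crc32(dyad_id),))`, so cohorts are
  byte-identical across runs and stable under dyad reordering.

### What the generator emulates, and what it does not

It reproduces the *structure* the scoring layer assumes — cadence,
carry-forward, monotone attrition, the threshold-rate contrast between
arms, the improvement-probability contrast, and the pretest-vs-first-
check-in bias signature.  It does not reproduce several features of real
data, so passing tests certify the pipeline, not the world:

* **Absolute reporting volume.**  Control-arm caregivers here complete
  every due check-in; real caregivers completed roughly a quarter of due
  weekly check-ins (124 symptoms ≈ 12 check-ins/year per reporting
  caregiver in the published control arm).  Only the between-arm ratio is
  calibrated.
* **Threshold occupancy under forced transitions.**  Forcing threshold
  symptoms to improve with probability only 0.26 makes high states
  stickier than the natural mean-reverting dynamics, so the control arm's
  long-run threshold proportion rises above its pretest level (≈ 0.39 in
  the default simulated cohort vs 0.14 published).  The generator
  therefore reproduces the direction and ordering of the published
  contrasts, not their absolute levels.  This is an unavoidable
  consequence of pinning the conditional improvement probability, which
  the parameter-recovery criterion requires.
* One latent law shared by all 10 symptoms and all dyads; no symptom
  correlations, no clinic visits, medication changes, or clinician
  behaviour.

## 2. Scoring

* A symptom observation is *threshold* iff rating ≥ 7.
* It is *improved* iff the same symptom is rated strictly lower at the
  immediately following completed online check-in, regardless of the
  calendar gap; equal ratings are *same*; higher are *worsened*.  A
  missing symptom in a check-in is a data error (the instrument forces
  completion of all 10 items).
* The final observation of each (dyad, symptom) stream is *terminal*.
  Under the default `terminal_policy="include"` a terminal threshold
  observation stays in the threshold count and is tallied as unchanged;
  under `"exclude"` it leaves the threshold count and the improvement
  denominator.  Both readings of the published tables are defensible
  (their improvement denominators equal their threshold counts exactly,
  which suggests terminal observations were retained), hence the switch.
  The assessed count (10 per completed check-in) is never affected.
* Caregivers with fewer than two online check-ins contribute no
  comparison, so their online records are excluded; pretests are retained
  for the bias analysis.
* 2-month periods are fixed 61-day bins, period = ⌈day/61⌉ clamped to
  1–6; online check-ins after day 366 are discarded with a warning.  A
  threshold symptom belongs to the bin of its own check-in even when its
  follow-up rating falls in the next bin (the improvement definition is
  check-in-relative, not bin-relative).
* Aggregation is verified exactly against an independent pure-python
  recount over raw CSV rows on small cohorts, under both terminal
  policies.

## 3. Inference

* **Pooled Z / unpooled Wald**: textbook forms (README).  The pooled form
  reproduces the three published test statistics (10.35, −12.27, 0.696)
  and the unpooled form the published −.077/−.057 interval, which is how
  the otherwise-unlabelled published "Wald Z-test" was identified.
* **Miettinen–Nurminen**: restricted MLE via the closed-form cubic root
  (trigonometric solution), variance inflation N/(N−1), bounds by `brentq`
  to 1e−8 on [−1 + 1e−11, diff] and [diff, 1 − 1e−11].  Degenerate counts
  (x = 0 or x = n in both groups) still yield finite intervals.  Validated
  three ways: grid inversion at δ-step 1e−5 (agreement < 1e−4 on a
  50-table panel), direct numerical likelihood maximization (< 1e−7), and
  a loose external cross-check (statsmodels, 5e−3 — its inversion differs
  slightly and fails to bracket on some small tables).
* **Chan–Zhang**: two one-sided exact unconditional tests at α/2.  For a
  candidate δ the nuisance p₂ runs over a uniform open-interval grid of
  `grid_points` = 200 values of the δ-feasible range; tail probabilities
  sum the joint binomial pmf over outcomes whose MN score statistic at δ
  is at least as extreme as observed (tolerance 1e−9 on ties).  Bounds are
  located by a 0.01-step walk from the observed difference refined by
  bisection to 1e−4.  Enumeration is refused above n = 200 per group with
  a pointer to the MN interval.  Simulated coverage at n = 20 per arm
  never falls below nominal − 3 MC SE (by construction of the sup-p
  inversion), and the interval contains the MN interval on small tables.
* **Cohen's h** is reported as an absolute value, from unrounded
  proportions.
* **Two-group McNemar**: net-change statistic as in the README, positive
  z meaning the ALERT arm shifts more strongly toward fewer threshold
  reports at first check-in.  With one group empty it reduces to the
  one-sample net-change z.  The originally cited "multiple-sample McNemar"
  formulation is not recoverable from published sources (and the published
  Z = 6.910 "with 95% CI 6.50–7.29" — a CI on a Z statistic — cannot be
  reconstructed from published marginals), so this documented net-change
  difference form is used; its type-I error calibrates at α in simulation.
* Two-sided p-values throughout; α = 0.05 default; no multiplicity
  adjustment (none was applied in the source analyses).

## 4. AUC contrast

Trapezoidal AUC over bin midpoints at months 1, 3, 5, 7, 9, 11; periods
with zero denominator contribute no point.  Group AUCs are converted to
relative proportions and delegated to the proportion machinery with
effective n equal to each arm's total 12-month denominator — an explicit
approximation to the original (unpublished) proportional-difference
computation, matching the denominators of the totals-based tests.

**Calibration warning.**  The relative AUC is not a binomial proportion
over that effective n: under arm-label permutation of a generatively
neutral cohort the delegated z statistic has spread well above 1 (SD ≈ 2
even with serially independent ratings, larger with realistic
persistence), so the normal reference rejects far above α.  The z and
p-value are therefore reported as descriptive summaries; calibrated
inference for the AUC contrast should use the permutation distribution,
as the permutation test in `tests/test_auc.py` illustrates.  No published
AUC values exist to compare against, so this stage is validated by its
closed-form and symbolic-integration oracles and the permutation
properties only.

## 5. Test and simulation sizes

Chosen as the package's own defaults for a laptop-scale run: the
distributional oracle uses 500 dyads/arm × 4 weekly check-ins; MN coverage
1000 tables per proportion at n = 50; Chan–Zhang coverage 2000 tables at
n = 20 per arm with memoized p-values; parameter recovery 100 dyads/arm ×
20 seeds × 52 weeks; null calibration 500 replicates of 40 dyads/arm × 3
check-ins with persistence 0 (the pooled Z test presumes independent
observations; under the default serial correlation it is anticonservative
for cluster-correlated counts, a limitation shared with the original
totals-based analysis).

## 6. Known limitations

* The published improvement-contrast interval prints an upper bound of
  .320; unpooled Wald (.3212), MN (.3208) and the uninflated score
  interval (.3207) all round to .321, so that digit is not recoverable
  from the printed counts.  The corresponding check is left failing by
  design and documented there.
* Published Table-4 effect sizes for months 6, 8, 10 and the total do not
  recompute from their raw counts (e.g. month 6: 0.65 computed vs 0.60
  printed); the reproduction tests cover the entries that do.
* Totals-based binomial tests ignore within-dyad and within-symptom serial
  correlation and so overstate evidence on realistic (persistent) data;
  the package reproduces this analysis faithfully rather than replacing it
  with a cluster-robust one.
* The generator's single shared latent law is a deliberate simplification;
  see §1.
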