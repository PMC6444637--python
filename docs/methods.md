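# Methods

This note records the models, conventions, and numerical choices behind
`actiwear`, and what the synthetic experiments do and do not demonstrate.

## Time base and data model

Epochs are 0-based and all intervals half-open `[start, end)`; this keeps
every run-length computation free of off-by-one ambiguity. A series covers at
most one calendar day and never spans midnight — per-day processing is the
unit of every downstream summary, and runs of zeros touching the day
boundaries qualify for detection on their within-day length only. Diary
times are whole minutes (participants log to the minute); sub-minute diary
input is rejected at parse time. Time outside the diary's `[wake, bed)`
window is non-wear by definition, since the protocol has the device removed
overnight. Reintegration to a coarser epoch sums counts per block and drops
a trailing partial block rather than padding it — padding would fabricate
counts.

## Non-wear rules

Detection operates on counts per minute obtained by reintegration from the
native epoch, on the vertical axis by default (vector magnitude is a
configuration switch). The fixed rules flag maximal zero runs of at least
the window length. For the allowance rules the package adopts one reading of
an ambiguity the published descriptions leave open: **a qualifying span
starts and ends with zero minutes** — an interruption must interrupt zeros
on both sides, never begin or end a span. Tolerated interruption minutes
inside an accepted span are counted as non-wear (they lie inside the
interval), which matches the wear-time arithmetic of the cited algorithms.

* Troiano: span ≥ 60 min; interruption runs of ≤ 2 *consecutive* minutes,
  each minute with counts strictly between 0 and a ceiling (default
  100 cpm, configurable). A minute at or above the ceiling, or a third
  consecutive nonzero minute, breaks the span. Whether the original
  allowance is 2 consecutive or 2 total minutes per window is not
  documented; consecutive is the default and a total-budget variant
  (`interruption_mode="total"`) is provided.
* Choi: span ≥ 90 min; interruption runs of ≤ 2 consecutive nonzero minutes
  of any magnitude, absorbed only when ≥ 30 consecutive zero minutes
  immediately precede and follow them (flanks measured within the day).

Both are implemented by run-length encoding and local merging; the test
suite checks them minute-for-minute against independently written forward
exhaustive scans on thousands of randomized traces.

## Intensity classification and day reduction

Cut-points apply to 15-s vertical-axis epochs with inclusive upper bounds
(0–180 sedentary, 181–757 light, 758–1112 moderate, > 1112 vigorous);
minute-grid non-wear intervals are expanded to the 15-s grid by the exact
factor 4. Minutes are kept as exact multiples of 0.25 min until report
emission. Thresholds phrased as minima are inclusive: ≥ 600 wear min makes a
valid day, ≥ 60 MVPA min meets the guideline, ≥ 3 recorded days keeps a
subject. Per-day **non-wear period counts** are the *interior* detected
periods — intervals not touching the day boundaries — so that algorithm
counts are commensurable with the diary, whose count is the number of
daytime removals; the overnight block is off-schedule for both.

## Repeated-measures CCC

The two-method concordance model is

    Y_ijk = μ + s_i + m_j + d_k + (sm)_ij + (sd)_ik + e_ijk

with subject `s`, fixed method `m` (2 levels), day `d`, and random
interactions. Variance shared by the two methods at the same subject-day —
σ²_s + σ²_sd — is concordant; method-discordant variance is σ²_sm + σ²_e
plus the squared systematic shift, giving

    CCC = (σ²_s + σ²_sd) / (σ²_s + σ²_sd + σ²_sm + σ²_e + Δ²/2).

Placing the subject×day component in the numerator is what makes an
algorithm that reproduces the diary *day by day* score CCC = 1 even though
days vary; charging it to error would cap concordance below 1 for a perfect
comparator. The Δ²/2 term is exactly the penalty that makes the estimator
collapse to Lin's classical single-measure CCC when each subject contributes
one day (the k = 1 reduction is tested to 1e-6).

Estimation is ANOVA method of moments on the three-way decomposition
(the method×day and three-way interactions are pooled into the residual);
negative component estimates are truncated at zero. Unbalanced panels use
complete (subject, day) pairs, unweighted cell means, and a harmonic-mean
day count — adequate for near-balanced data, which is the intended use;
subjects with no complete pair are dropped with a warning. Confidence
intervals are percentile intervals from a subject-level nonparametric
bootstrap (default 1000 replicates, seeded); the estimator is vectorized
over bootstrap replicates so the 500-panel coverage study in the test suite
runs in seconds. Coverage of the nominal 95% interval is verified ≥ 85% at
20 subjects × 4 days.

## Other agreement statistics

Bland-Altman treats subject-days as independent pairs by default (the plots
pool all days); limits are bias ± 1.96 × SD of differences with the n−1
denominator. An optional repeated-measures correction rebuilds the SD from a
one-way ANOVA of differences by subject. Kappa point estimates come from
scikit-learn; the binary kappa carries a standard asymptotic CI, the
weighted kappa (linear weights `1 − |i−j|/(k−1)` by default, quadratic and
identity available) a seeded pair-bootstrap CI. Non-wear period counts are
capped into the ordinal categories {0, 1, 2, 3, 4, 5+} before the weighted
kappa. Valid-day proportions are compared with Pearson's chi-square on the
2×2 table (1 df, no continuity correction); a zero expected cell raises an
error that recommends an exact or corrected test. Mean per-rule differences
from the diary are reported with subject-level bootstrap CIs; no mixed-model
inference is attempted.

## Synthetic cohorts

The generator emulates the validation design: `n_subjects = 77`,
`days_per_subject = 4`, 15-s epochs. Wake and bed times are truncated
normals (~08:10 ± 40 min on, ~21:05 ± 40 min off, whole minutes), giving
roughly 12.5 h of scheduled wear. Daily removals are drawn over {0, 1, 2, 3}
with probabilities (0.507, 0.425, 0.052, 0.016) — the observed diary
frequencies of the emulated protocol — with lognormal durations (median
40 min, σ_log 0.6, clipped to [5, 240] min) placed with 30-min wear gaps;
infeasible schedules are resampled and error after bounded retries.

Wear-time counts follow a semi-Markov bout model over five states —
motionless sedentary (exact zeros), fidgeting sedentary (1–180 counts/15 s),
light (181–757), moderate (758–1112), vigorous (1113–3000) — with lognormal
dwell times (defaults: median 10, 8, 5, 3, 1.5 min). Lognormal dwells were
chosen over i.i.d. epochs because the misclassification phenomenon under
study requires autocorrelated stillness: long zero runs must arise *inside*
wear time. Counts are uniform within each band because band membership, not
count magnitude, drives every downstream statistic. The transition matrix
was set once so the diary-referenced cohort means sit in the realistic youth
range (~70% of wear sedentary, ~8–9% MVPA, ~745 wear min/day). Secondary
axes are emitted as noisy fractions of the vertical axis, co-zero with it.

Two named regimes bracket the difficulty of the detection problem:

* **easy** (`SimulationConfig.easy_regime()`): every removal ≥ 90 min, bed
  no later than 22:24 so the evening off-body segment also reaches 90 min,
  no motionless state, no artifacts. Every wear minute is then nonzero and
  every zero run is true non-wear ≥ 90 min, so *all seven rules must recover
  ground-truth non-wear exactly* — the 90-min floor on day-edge segments is
  part of the regime definition, since the Choi rule cannot certify a
  shorter terminal segment.
* **hard** (`SimulationConfig.hard_regime()`): motionless bouts with
  lognormal dwell of median 25 min truncated to 12–45 min and sticky
  still↔fidget transitions. Short zero windows then flag still sitting as
  non-wear, sedentary estimates increase strictly with window length, and
  the 10-min rule shows the worst diary concordance.

Optional 1–2-min handling artifacts are injected inside true non-wear at a
configurable rate per hour, at least 30 min from run boundaries and from
each other, with counts below 100 cpm — the configuration under which the
Troiano and Choi allowances absorb them while plain zero windows are split.
Diary reporting noise (minutes, default 0 — the emulated protocol
synchronized watches to the device) is available for sensitivity studies.
Randomness is keyed by `(seed, subject, day)`, so cohorts are reproducible
and per-subject streams are stable under cohort-size changes.

**What passing tests show — and do not.** The generator reproduces the
*structure* that makes non-wear detection hard (autocorrelated stillness,
removals, diurnal scheduling), not the physiology of any real cohort: no
device noise floor, no partial-wear fidgeting at removal boundaries, no
demographic covariates, uniform in-band count magnitudes. Exact recovery in
the easy regime and the bias gradient in the hard regime validate the
algorithms and the agreement machinery, not any claim about which rule is
best for real children.

## Problem sizes and runtime

The test suite simulates full 77 × 4 cohorts for the recovery and
bias-direction checks, 10 × 4 cohorts for structural invariants, 1000
randomized traces (≤ 200 min) for oracle equivalence, and 500 panels for
bootstrap coverage; the whole suite runs in well under a minute on one CPU.
`scripts/acceptance.py` uses the full default cohort with 500 bootstrap
replicates per interval.

## Known limitations

* Proprietary device formats (AGD/GT3X binaries) and device calibration are
  out of scope; input is delimited epoch text.
* The CCC estimator is method-of-moments, not REML; for severely unbalanced
  panels the harmonic-mean approximation is crude.
* Bland-Altman defaults ignore within-subject correlation (by design, to
  pool all days as the validation plots do); the corrected variant is an
  option, not the default.
* The simulator draws each day independently — no within-subject activity
  phenotype beyond the shared schedule distributions, so between-subject
  variance in the synthetic cohort is lower than in real panels.
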