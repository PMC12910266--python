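# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limits of what the test suite demonstrates.

## Engagement definitions

A watch day is **active** when post-artifact valid wear reaches the
threshold (default 6 h; the comparison is inclusive, `>= 360` minutes, and
a 1 h variant reproduces the laxer wear summary). A survey day is active
when the daily stress measure was completed. Engagement rate is active
days over the **observed span** — day 0 through the participant's last
recorded day, capped at the 180-day horizon. Days inside the span with no
record count as nonactive for rates; for smoothing they are treated as
missing and excluded from the window mean, so silent gaps are not imputed
as zeros before the periodogram. The denominators question (observed span
vs fixed 180 days) is genuinely open in studies of this kind; both are
supported and observed-span is the default, which is also what lets the
generator's planted adherence means coexist with heavy dropout.

The centered 7-day rolling mean truncates its window at the series edges
(keeping series length stable for the FFT stage) rather than dropping edge
days. Watch–survey coupling is the Pearson correlation of the two smoothed
series on their day overlap; a constant series makes the correlation
undefined and it is reported as missing with a warning — never coerced
to 0.

Welch's two-sample *t* statistic, Satterthwaite degrees of freedom and the
two-sided *p* are computed from the closed-form summary statistics (scipy
supplies the *t* distribution); `scipy.stats.ttest_ind(equal_var=False)`
serves as an independent cross-check in the tests. When both groups are
constant and equal the test reports t=0, p=1 rather than 0/0.

## Retention survival analysis

Day states follow a two-pass rule: nonactive days are provisional exits,
downgraded to `inactive` when any later day is active, so only the
terminal nonactive run remains `exit`. The event time is the **first day
of the terminal exit run**: "sustained exit" begins when activity stops.
The series is interpreted on the horizon grid — a participant who stops
producing records has disengaged (exit), not been censored — and an exit
run starting at or after day 180 is censored at 180, as is a fully active
horizon. A never-active participant is a day-0 event. Dropout in the
generator is absorbing, but the classifier handles re-entry (an optional
generator re-entry probability exists purely to stress-test it).

Kaplan–Meier estimation and the k-sample log-rank test are delegated to
lifelines; a brute-force hypergeometric O−E oracle and hand product-limit
fixtures validate them in the tests. The median 95% CI inverts the
log-log survival confidence band (Brookmeyer–Crowley style), chosen
because it is the standard approach when no method is otherwise specified;
quartile times use the first time the survival curve falls to the target
level, and unreached quantiles are reported as missing.

The recovered Kaplan–Meier median sits ~2 days below the planted dropout
median because the exit run starts at the last active day + 1, which
precedes the dropout day by the expected length of a short nonactive tail
(≈(1−p)/p days at daily adherence p). A single-replicate KM median at
n=200/group has a sampling SD of roughly 13 days (adults), so the
recovery check compares the Monte-Carlo center across 100 replicate
cohorts to the planted medians (±10 days) and requires log-rank
significance in ≥80% of replicates.

## Periodogram

Each smoothed series is detrended by subtracting the mean of its
non-missing values; missing entries are then zero-filled (unbiased under
MCAR — an explicit assumption) and a real-input FFT yields magnitudes at
periods `N/k` days, `k = 1..N/2`, zero frequency excluded. Dominant
periods are the three largest magnitudes, ties broken toward the longer
period. The grid is discrete: a planted off-grid period is recovered as
the nearest `N/k` bin, and tests only ever assert within-one-bin
recovery. Series shorter than 28 days (two cycles of the shortest
reportable period) are excluded from cohort histograms. Because the
periodogram runs on the 7-day-smoothed series, high-frequency content is
attenuated by the smoother's low-pass response; sub-weekly peaks are
therefore not interpretable and the reported band focuses on 1-5 weeks.

## Pre-scan additive model

Eligibility mirrors the intended cohort: at least 2 scans, each preceded
by ≥300 h of wear in a look-back window. A 300 h requirement cannot fit in
the 3-day (72 h) modeling window, so the look-back is a separate, longer
lead-in — 30 days by default, configurable and recorded in the manifest.

Per event, minute rows in the half-open window `[scan − 3 d, scan)` carry
the response `time_to_scan` in minutes (scan timestamp = midnight of the
scan day unless supplied). Preprocessing: chained-equation imputation
(scikit-learn IterativeImputer: mean-fill initialization, 10 iterations,
linear Bayesian-ridge regressors, single imputation, seeded and
deterministic) with the per-minute missingness fraction (imputed channels
/ 5, values in {0, .2, …, 1}) recorded **before** imputation and observed
values guaranteed untouched; events with a fully missing channel or a
channel under 20% observed are excluded with the reason logged. EDA and
HRV are natural-log transformed (strictly positive by contract) to remove
right skew, then all five channels are z-scored within the event; a
constant channel is dropped with a warning. Circadian detrending is
deliberately not applied.

The model is a Gaussian additive model with one cubic B-spline smooth per
feature (20 basis functions on equally spaced knots, second-order
difference penalty), no interactions. "Default hyperparameters" are pinned
here rather than inherited from any external tool: a single smoothing
parameter shared across terms, selected by the profiled Gaussian REML
criterion on a fixed log-spaced grid (10⁻²…10⁸, 16 points). Basis columns
are centered on the training sample so each smooth has exactly zero mean
over the training rows and the intercept equals the response mean;
predictions clamp features to the training range. The implementation is
validated against R mgcv (P-spline basis, REML) on a shared fixture.
Per-term smoothing parameters were considered and rejected: the grid
search becomes combinatorial with no benefit demonstrable at these data
sizes.

Partial dependence for a feature is the intercept plus its centered
smooth on a 100-point grid over the observed range — exact for an
additive model, no Monte-Carlo averaging needed. Cross-validation is
row-wise shuffled 5-fold, refitting the model (including smoothing
selection) per fold. Within-person PDP similarity is the Pearson
correlation of two events' smooths re-evaluated on the intersection of
their feature ranges; disjoint ranges or constant curves give a missing
value.

A caution on shape recovery: with feature noise, the true conditional
mean E[time | feature] is an attenuated version of the inverse planted
map, and at high noise its central curvature can legitimately flip sign.
Recovery tests therefore compare the PDP to a brute-force binned
conditional-mean oracle simulated from the planted law (400k draws), and
the curvature-sign check runs at low noise where the inverse map governs.

## Instrument scoring and alerts

PHQ-9 (9 items 0-3), GAD-7 (7 items 0-3), PSS-4 (4 items 0-4, items 2 and
3 reverse-scored x→4−x), PROMIS SRI short form (8 items 1-5) reported as
the **raw sum** — the group means in this setting (~16-23) are consistent
with raw short-form sums, and no T-score lookup table ships, so the
conversion hook is disabled. Incomplete responses are excluded and logged,
never prorated. The PHQ-9 item-9 alert fires on any positive response
(value ≥1); the alert log is audit-complete — exactly one row per
positive response — and alerting is a non-blocking side channel with no
clinical routing simulated. Group comparisons aggregate to one mean total
per participant per instrument before testing, so n is participants,
never responses (no pseudo-replication).

## Synthetic cohort generator

The generator's defaults are the study conditions: 9 children / 36 adults
(26/36 adult carriers, 44%/29% cancer history, all children carriers —
child non-carriers are generatable via config to probe confounding),
180-day horizon, 14-day check-in cycle.

- **Wear.** Daily wear probability = group base (adult 0.81, child 0.56)
  × normalized exponential decay (half-life 180 d) × (1 + 0.15·sin) cycle.
  The scale is solved by bisection so the **clipped** profile's mean equals
  the base exactly — early-follow-up saturation at probability 1 would
  otherwise bias the planted group gap. Worn days draw total hours from
  truncated normals (17.6±3.1 / 15.7±2.9 h); non-worn days are
  zero-inflated sub-threshold wear. The sleep share (~25%, capped at the
  8 h 23:00-07:00 window) is generated directly: sleep labels are an
  input to the analysis, not an inference.
- **Dropout.** Absorbing geometric hazards solved from target medians
  (153 d adults, 77 d children); records simply stop.
- **Surveys.** Completion probability p_s(d) + c·(w_d − p_w(d)), clipped:
  mean-preserving in the survey marginal (bases 0.65/0.51) while coupling
  completion to same-day watch activity (c = 0.7). Stress level is
  ordinal 0-3 with planted mass on "very stressed" (0.363 child / 0.143
  adult).
- **Instruments.** Biweekly batteries; totals are draws from a normal
  censored to the instrument range, with the latent mean solved (by
  bisection on the censored-normal expectation) so the **realized** mean
  hits the planted value (PHQ-9 10.0±5.2 vs 4.2±4.4; PROMIS SRI 22.7±5.9
  vs 16.5±5.5). Item allocation spreads the total across items; PHQ-9
  item 9 stays 0 except for alerter participants (prevalence 0.11), who
  get exactly one positive item-9 response.
- **Physiology.** Minute samples only on worn minutes (a contiguous block
  per day) and only within 35 days before a scan — wide enough for the
  30-day eligibility look-back plus the 3-day window; simulating every
  minute of the horizon would generate millions of rows with no consumer.
  Channels are individual baselines plus a smooth pre-scan effect
  (per-channel shape: EDA quadratic, HR/HRV linear, respiration sigmoid,
  temperature flat; HRV and temperature fall under stress) active in the
  3-day window, with effects from overlapping windows summed. EDA and HRV
  are built on the log scale (lognormal baselines, strictly positive).
  Values go missing independently at 10%, inflated by +10% inside the
  pre-scan window — missing-not-at-random by construction, which is what
  the missingness-fraction feature is meant to detect.

What the generator does **not** emulate: circadian structure, raw 64 Hz
signal processing or wear artifacts (valid minutes are post-exclusion by
contract), tumor biology, family clustering of participants, and survey
response styles. Passing recovery tests therefore show the pipeline is
correct and well-calibrated under its stated assumptions — not that real
cohorts satisfy those assumptions.

## Determinism and problem sizes

All randomness flows from one seed through a `SeedSequence` spawn tree
(one stream per participant), so fixed seeds give byte-identical CSVs.
Recovery checks run at n=200/group (engagement, scores), 100 replicate
cohorts (retention), 4,320 rows/event with 400k-draw oracles (GAM), and
50-100 seeds (imputation) — sizes at which each planted effect's
sampling error is small relative to its tolerance while the whole suite
stays desk-scale.
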