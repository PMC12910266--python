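# scanwear

Analysis pipeline for wearable digital-health studies in hereditary-cancer
surveillance cohorts — engagement, retention, periodicity, psychosocial
scores and pre-scan physiology — paired with a synthetic cohort generator
that plants a known ground truth for every quantity the pipeline estimates.

## The problem

Families affected by Li-Fraumeni syndrome (a germline *TP53* cancer
predisposition) live with lifelong imaging surveillance and the
anticipatory stress that precedes each scan ("scanxiety"). Digital health
tools — a medical-grade smartwatch plus app-based daily stress surveys and
periodic questionnaires — can monitor both engagement and well-being
between clinic visits. Analyzing such data raises a bundle of recurring
questions this package answers with tested, replayable code:

- **Engagement.** What fraction of days did each participant wear the watch
  at least 6 h, or complete the daily stress survey? Do adults and children
  (or *TP53* carriers vs non-carriers, cancer survivors vs unaffected)
  differ? Group contrasts use two-sample Welch *t* tests (Satterthwaite
  degrees of freedom, two-sided *p*).
- **Retention.** Each observed day is `active` or nonactive; nonactive days
  later followed by activity are `inactive` (temporary disengagement) and
  the terminal nonactive run is the `exit`. The survival event is the first
  day of that terminal run within a 180-day horizon; later exits are
  censored. Kaplan–Meier curves (with median, IQR and a median 95% CI from
  the log-log survival band) and log-rank tests compare strata.
- **Periodicity.** Smoothed (centered 7-day mean) engagement series are
  mean-detrended and Fourier-transformed; the top-3 spectral magnitudes at
  periods `N/k` days expose engagement cycles such as the biweekly
  check-in-call rhythm.
- **Psychosocial state.** PHQ-9, GAD-7, PSS-4 (items 2-3 reverse-scored)
  and PROMIS Sleep-Related Impairment (raw sum) are scored per response;
  any positive PHQ-9 item 9 (self-harm) emits an audit-complete alert row.
- **Scanxiety.** For each surveillance scan with enough preceding wear,
  minute-level physiology (log EDA, heart rate, log HRV, respiratory rate,
  skin temperature, each z-scored, plus a per-minute missingness fraction)
  from the 3 days before the scan is regressed on minutes-to-scan with a
  Gaussian additive model: one penalized cubic B-spline smooth per feature,
  no interactions, smoothing selected by REML over a log-spaced grid.
  Missing values are imputed by chained equations (MICE) before modeling;
  model quality is 5-fold cross-validated MSE, and fitted smooths are
  summarized as partial-dependence curves whose within-person similarity
  across scans is a Pearson correlation on the shared feature range.

Because real cohorts of this kind are small and not redistributable, the
package ships a generator (`scanwear.cohort`) whose configuration *is* the
ground truth: planted adherence means and decay, a 14-day check-in cycle,
geometric dropout hazards implying target retention medians, watch–survey
coupling, instrument-score group differences, alert prevalence and smooth
pre-scan physiological signatures. Every analysis stage is validated by
recovering these planted values.

## Worked example

```python
from scanwear import CohortConfig, simulate_cohort
from scanwear.engagement import wear_time_summary
from scanwear.retention import survival_records, km_fit, log_rank

cohort = simulate_cohort(CohortConfig(seed=1))   # 9 children, 36 adults, 180 d
table = wear_time_summary(cohort.daily, cohort.participants)
print(table[["level", "n", "pct_days_worn_mean", "total_h_mean"]].round(1).to_string(index=False))

records = survival_records(cohort.daily, cohort.participants, modality="watch")
for level, grp in records.groupby("age_group"):
    km = km_fit(grp)
    print(f"{level}: median retention {km.median:.0f} d (IQR {km.iqr[0]:.0f}-{km.iqr[1]:.0f})")
chi2, df, p = log_rank(records, "age_group")
print(f"log-rank chi2={chi2:.2f} (df={df}), p={p:.3f}")
```

prints

```
level  n  pct_days_worn_mean  total_h_mean
child  9                68.2          15.7
adult 35                88.1          17.7
adult: median retention 123 d (IQR 50-nan)
child: median retention 74 d (IQR 29-95)
log-rank chi2=4.11 (df=1), p=0.043
```

Adults wear the watch on a larger share of their observed days and stay in
the study longer; at this cohort size the Kaplan–Meier medians are noisy
(the adult upper IQR bound is not reached, printed as `nan`), yet the
log-rank test already separates the groups. Hours-per-worn-day recover the
planted 17.6 h (adults) and 15.7 h (children).

The same analyses run from the shell, staged over plain CSV files:

```bash
scanwear simulate --out data --seed 1          # 5 CSVs + config sidecar
scanwear retention --data data --out results   # survival_records.csv, km_curves.csv, ...
scanwear all --out run1 --seed 1               # every stage + report.md + manifest.json
```

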