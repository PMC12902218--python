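# icmeval

Evaluation framework for insertable cardiac monitor (ICM) atrial-fibrillation
detection, measured against multi-day Holter annotations, with a 1-D CNN
false-positive triage stage.

## The problem

An ICM continuously monitors the heart and logs detected AF episodes as
`(start, end)` intervals plus a short electrogram (EGM) snippet per episode. A
simultaneously worn Holter provides gold-standard rhythm annotations: AF
intervals, atrial tachycardia / flutter (AT/AFL), and uninterpretable
segments. Judging how well the ICM detects AF against that reference raises
several distinct questions, and this package answers each of them:

- **Episode-based accuracy** — of the true AF *events* (≥ 2 min on the
  unclipped annotation), how many did the device detect (sensitivity)? Of the
  device's logged *episodes*, how many overlap true AF (positive predictive
  value, PPV)? Events and episodes have different denominators, so both are
  tracked. Three estimators are reported: **gross** (pool all counts),
  **patient-average** (mean of per-patient proportions), and **GEE**
  (intercept-only logistic generalized estimating equation with exchangeable
  working correlation and robust variance — the principled way to get a
  population estimate with per-patient clustering).
- **Duration-based accuracy** — second-by-second agreement computed by exact
  interval algebra (no sampling grid): TP/FP/TN/FN durations inside an
  "analyzable" mask that removes uninterpretable ECG and AT/AFL time.
- **Patient-based accuracy** — the 2×2 table of "has true AF" vs "has any
  retained detection", with exact (Clopper–Pearson) confidence intervals.
- **AF-burden agreement** — per-patient burden (% of analyzable time in AF)
  from both sources, compared with Pearson correlation and Bland–Altman
  bias / 95 % limits of agreement.
- **False-positive triage** — a small 1-D convolutional network scores each
  episode's EGM snippet; episodes below an operating threshold chosen to lose
  *zero* true positives on validation are discarded, and every metric family
  is recomputed post-filter.

Because real paired ICM/Holter recordings are not distributable, the package
includes a **synthetic cohort generator**: per-patient ground-truth AF
timelines, imperfect device detections (misses, boundary jitter, clustered
false positives with labelled causes), exclusion segments, per-patient clock
offsets between the two time bases, and phenomenological EGM snippets whose
rhythm classes (true AF, sinus arrhythmia, ectopy, noise) are separable by
morphology and RR-interval statistics. A clock-alignment module recovers the
injected offsets by overlap maximization before any metric is computed.

## Worked example

The episode- and patient-level formulas are small enough to verify by hand.
Given these counts — 39 patients with true AF, all with at least one detection;
80 of 96 patients without AF had no detection; 1256 device episodes of which
1004 were true and 252 false; the classifier retained all 1004 true episodes
plus 69 false ones —

```bash
icmeval verify-example
```

prints:

```
patient_sensitivity          computed  100.0  expected  100.0  ok
patient_specificity          computed   83.3  expected   83.3  ok
patient_ppv                  computed   70.9  expected   70.9  ok
patient_npv                  computed  100.0  expected  100.0  ok
episode_gross_ppv_pre_ai     computed   79.9  expected   79.9  ok
episode_gross_ppv_post_ai    computed   93.6  expected   93.6  ok
fp_reduction                 computed   72.6  expected   72.6  ok
```

e.g. gross PPV pre-filter = 1004 / (1004 + 252) = 79.9 %, post-filter =
1004 / (1004 + 69) = 93.6 %, and the false-positive reduction =
(252 − 69) / 252 = 72.6 %.

## Quick start (library)

```python
from icmeval import alignment, evaluation as ev
from icmeval.synthetic import CohortConfig, generate_cohort

cohort = generate_cohort(CohortConfig(n_patients=30, seed=1))
synced = [alignment.apply_sync(log, alignment.estimate_offset(log, tr))
          for log, tr in zip(cohort.icm_logs, cohort.tracks)]
results = [ev.match_episodes(log, tr)
           for log, tr in zip(synced, cohort.tracks)]
for m in ev.episode_metrics(results):
    print(m.name, m.estimator, m.pct, (m.ci_low, m.ci_high))
```

Or run everything (simulate → align → train CNN → classify → evaluate →
report) in one command:

```bash
icmeval run --seed 1 --outdir out/
# -> out/report.json, annotations.csv, icm_episodes_synced.csv, manifest.json, run.log
```

Runs are deterministic: the same seed yields a byte-identical `report.json`.

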