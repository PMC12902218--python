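# Methods

This note documents the statistical model, the synthetic-data generator, the
numerical choices, and the known limitations of `icmeval`. Every empirical
number quoted here is computed by the test suite or the analysis scripts;
nothing is asserted beyond what the code demonstrates.

## 1. Data model

All rhythm information is represented as half-open intervals `[start, end)` in
float seconds on a per-patient clock.

- **Holter annotation track** (`annotation_io.AnnotationTrack`): a recording
  span plus labelled events — `AF`, `ATFL` (atrial tachycardia / flutter),
  `UNINTERPRETABLE`, `OTHER`. Events are validated (inside the span, positive
  duration, known labels) and stored sorted.
- **ICM episode log** (`annotation_io.IcmEpisodeLog`): device-detected
  episodes with optional EGM snippet reference, classifier score, retention
  flag, and (for synthetic data) the simulated false-positive cause.
- Interval arithmetic (`icmeval.intervals`) is exact: union, intersection,
  subtraction, and clipping are two-pointer sweeps over sorted endpoint lists.
  No sampling grid is involved, so confusion durations carry no discretization
  error; the tests verify agreement with a 0.1 s per-sample oracle and exact
  conservation `tp + fp + tn + fn = mask duration` to 1e-6 s.

## 2. Assessment rules

- **Analyzable mask**: recording span minus `UNINTERPRETABLE` and `ATFL` time.
  Uninterpretable ECG cannot adjudicate the device, and AT/AFL is neither a
  true positive nor a clean true negative for an AF detector, so both are
  excluded from assessment rather than counted against either side.
- **True AF events**: annotated AF intervals intersected with the mask, but
  the ≥ 2 min minimum-duration rule is applied to the *unclipped* annotation —
  an event is a real event even if part of it falls in masked time.
- **Episode matching**: a device episode overlapping any true AF (within the
  mask) is a true positive; one overlapping no AF is a false positive; one
  lying entirely outside the mask is *excluded* (not penalized). A true event
  is detected if any retained device episode overlaps it. Events and episodes
  are deliberately not forced into one-to-one correspondence: one long device
  episode may cover several events, and several episodes may tile one event —
  hence the separate sensitivity (event) and PPV (episode) denominators.

## 3. Estimators and uncertainty

Detections cluster within patients, so three estimators are reported for each
episode-level proportion:

- **Gross**: pool numerators and denominators over patients. Efficient but its
  naive binomial CI understates variance under clustering; we report
  Clopper–Pearson (default) or Wilson intervals on the pooled counts as a
  descriptive reference.
- **Patient-average**: mean of per-patient proportions (patients with empty
  denominators dropped), CI = mean ± 1.96·sd/√m. Weights every patient
  equally regardless of episode count.
- **GEE**: intercept-only logistic generalized estimating equation with an
  exchangeable working correlation and robust (sandwich) variance, fit with
  `statsmodels`. This is the population-averaged estimate with honest
  clustering-aware uncertainty. When the data are degenerate (every trial a
  success or every trial a failure) the logistic intercept diverges; the code
  then falls back to the pooled proportion with an exact binomial CI and says
  so in the estimate's `note`. The test suite contains an independent
  closed-form IRLS implementation of the same model and checks agreement with
  `statsmodels` to 1e-4.

Patient-level (2×2) metrics use exact Clopper–Pearson intervals. Burden
agreement follows Bland–Altman: bias = mean(ICM − Holter), 95 % limits of
agreement = bias ± 1.96·sd (sample sd, ddof = 1), with Pearson r alongside;
the burden denominator is analyzable-mask time, not the raw span.

## 4. Clock alignment

ICM and Holter run on independent clocks. `alignment.estimate_offset` finds
the shift (applied to ICM times) that maximizes total overlap between device
episodes and annotated AF: a coarse grid over ±120 s at 0.5 s steps, then
golden-section refinement around the best cell; ties resolve to the smallest
|offset|. Quality = overlapped fraction of total episode duration. Patients
with no episodes or no annotated AF get a flagged no-op estimate — for them no
within-patient signal exists to estimate an offset, which is also true of the
real measurement problem. The generator injects known offsets; tests verify
recovery within one grid step, including under boundary jitter (≥ 95/100
Monte-Carlo replicates).

## 5. Synthetic cohort generator

`synthetic.generate_cohort` produces ground truth and an imperfect device view
of it. Defaults (all configurable via `CohortConfig`) describe a cohort of 135
patients wearing a Holter 3–7 days:

| parameter | default | rationale |
|---|---|---|
| `prob_af_patient` | 39/135 | AF prevalence matching the evaluation setting |
| `episodes_per_af_patient_law` | zero-truncated NB, mean ≈ 13.4 | heavy-tailed episode counts; ~1000 true episodes per ~39 AF patients |
| `episode_duration_law` | lognormal(ln 2400, 1.1), truncated ≥ 120 s | spans minutes-to-days episodes; free choice, not fit to data |
| `miss_prob` | 0.006 | per-episode miss probability giving episode sensitivity ≈ 99.4 % |
| `boundary_jitter_sd` | 20 s | device episode boundaries disagree with annotations by seconds-to-minutes |
| `fp_rate_per_day` | 0.31 | ≈ 250 false episodes per cohort |
| `fp_rate_dispersion` | 0.08 | gamma-mixed per-patient FP rate (mean 1); false positives concentrate in few patients, so most non-AF patients stay clean (patient specificity ≈ 83 % at n = 135) rather than nearly all being contaminated as a homogeneous Poisson process would imply |
| `fp_cause_mix` | (0.384, 0.313, 0.298), normalized | sinus arrhythmia / ectopy / noise as false-positive causes |
| `uninterpretable_frac`, `atfl_frac` | 0.02, 0.01 | exclusion segments exercising the mask rules |
| `clock_offset_range` | ± 60 s | per-patient uniform clock offset |

Per-patient RNGs are spawned from a `SeedSequence`, so cohorts are
reproducible and patients independent. Event times are rounded to 1 ms.
Detected boundaries are jittered, re-truncated to ≥ 120 s and clipped to the
span; false positives are rejection-sampled outside true AF (a detection
during real AF is by definition true). An optional duration-dependent miss
model (logistic in log-duration) is available instead of the constant
`miss_prob`.

**EGM snippets** are phenomenological, not electrophysiological: 90 s at
64 Hz, QRS complexes as Gaussian-derivative wavelets on rhythm-specific RR
processes — irregular gamma RR (CV 0.28) plus 4–9 Hz fibrillatory baseline for
true AF; 0.25 Hz respiratory RR modulation with P waves for sinus arrhythmia;
premature beats with compensatory pauses for ectopy; motion bursts and
baseline wander for noise. The classes are separable by morphology and RR
statistics (the tests show an RR-variability discriminant alone reaches
AUROC > 0.9), which is what the classifier stage needs; the generator does
*not* emulate real subcutaneous EGM morphology, device sensing behavior, or
pathology beyond these four classes.

## 6. False-positive classifier

A 1-D CNN scores each episode's EGM snippet, implemented directly on NumPy
(convolution via im2col + BLAS matmul) with gradient-checked backpropagation:
Conv–ReLU–BatchNorm–Dropout blocks with max-pooling, global average pooling,
dense head, single sigmoid logit. Training uses focal loss
(γ = 2, α = 0.25) — with γ = 0, α = 0.5 it reduces exactly to ½ × binary
cross-entropy, which the tests check to 1e-10 — and Adam, in float32, fully
deterministic under a fixed seed. Default desk scale: 4 blocks, filters
(8, 8, 16, 16), kernel 9, 2× input downsampling, 12 epochs on 480 snippets
(~20 s CPU, validation AUROC 1.0).

Train/validation splitting is by *patient*, never by snippet, to avoid
leakage. The operating threshold follows a zero-true-positive-loss policy: the
largest threshold retaining every validation true positive, minus half the gap
to the nearest validation false score below it (the midpoint makes the margin
robust out of sample; a brute-force scan in the tests confirms no admissible
threshold rejects more false positives). At apply time, episodes whose snippet
is missing or unreadable are retained (fail-safe for sensitivity) and the
error is reported. Because the filter can only remove episodes, PPV and
specificity cannot decrease; sensitivity is unchanged as long as no true
episode scores below threshold — the acceptance tests verify bit-identical
sensitivity on a full synthetic cohort.

## 7. Numerical choices

- All interval arithmetic in float64 seconds; CNN arithmetic in float32.
- Percentages printed to 1 decimal; raw proportions kept at full precision in
  `report.json`, which is written with sorted keys so equal-seed runs are
  byte-identical (timings go to `run.log` only).
- Clopper–Pearson via the Beta quantile (`statsmodels proportion_confint`,
  `method="beta"`); GEE via `statsmodels` as described above.

## 8. Limitations

- The generator's distributional forms (lognormal durations, gamma RR,
  negative-binomial episode counts, gamma FP dispersion) are plausible shapes
  chosen for coverage of the evaluation logic, not fits to clinical data.
  Cohort-level metric values depend on these choices and should not be read as
  device performance claims.
- Clock alignment needs within-patient AF overlap; patients without detections
  or without annotated AF keep a zero offset (flagged). Linear drift is
  supported in `apply_sync` but not estimated.
- The EGM synthesizer covers four rhythm classes only; classifier performance
  on it upper-bounds nothing about real electrograms.
- GEE with few clusters (small cohorts) relies on asymptotics; the degenerate
  fallback intervals are exact but ignore clustering (there is no variance to
  cluster when every outcome is identical).
- AT/AFL is excluded, not evaluated; the framework measures AF detection only.
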