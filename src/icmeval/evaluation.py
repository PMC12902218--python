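"""AF-detection performance metrics.

Three metric families, computed against the core-lab-style annotation under
the study's exclusion rules (uninterpretable ECG and AT/AFL time are removed
from assessment):

* **episode-based** — proportions over discrete events/episodes: sensitivity
  (true AF events overlapped by at least one device episode) and PPV (device
  episodes overlapping annotated AF), each as a *gross* pooled estimate, an
  unweighted *patient-average*, and a cluster-robust *GEE* estimate;
* **duration-based** — the interval-overlap confusion durations tp/fp/tn/fn
  within the analyzable mask, giving sensitivity, specificity, PPV, NPV and
  accuracy over time;
* **patient-based (diagnostic)** — the 2×2 table of patients by true AF
  presence vs any device detection.

Matching rule: any positive overlap (> 0 s by default) between a device
episode and a true AF event counts as a match; events and episodes keep
their own denominators (one event detected by three episodes is one detected
event and three true-positive episodes).  A device episode lying entirely
outside the analyzable mask is excluded, not counted as false positive.
Undefined ratios (zero denominators) propagate as explicit undefined
estimates, never as 0 or 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.special import expit
from statsmodels.stats.proportion import proportion_confint

from . import intervals as iv
from .annotation_io import AnnotationTrack, IcmEpisodeLog, MIN_EPISODE_S


# ---------------------------------------------------------------------------
# Masks and true events
# ---------------------------------------------------------------------------

@dataclass
class AnalyzableMask:
    """Per-patient time eligible for AF assessment (exclusions removed)."""

    patient_id: str
    intervals: list[tuple[float, float]]

    @property
    def total_s(self) -> float:
        return iv.total(self.intervals)


def build_mask(track: AnnotationTrack) -> AnalyzableMask:
    """Recording span minus uninterpretable and AT/AFL intervals."""
    excluded = iv.union(track.intervals("UNINTERPRETABLE"), track.intervals("ATFL"))
    return AnalyzableMask(track.patient_id, iv.subtract([track.recording_span], excluded))


@dataclass
class TrueEvent:
    """One annotated AF event with its mask-clipped segments."""

    event_id: str
    start_s: float
    end_s: float
    clipped: list[tuple[float, float]]

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def true_af_events(
    track: AnnotationTrack,
    mask: AnalyzableMask | None = None,
    min_duration_s: float = MIN_EPISODE_S,
) -> list[TrueEvent]:
    """Annotated AF events eligible as truth.

    The duration threshold applies to the *annotated* (unclipped) event; the
    clipped segments (which may be several, if exclusions cut the event) are
    what detection is assessed against.  Events whose clipped remnant is
    empty are dropped — they lie entirely in excluded time and cannot be
    assessed.
    """
    if mask is None:
        mask = build_mask(track)
    out = []
    for k, (s, e) in enumerate(track.intervals("AF")):
        if e - s < min_duration_s - 1e-9:
            continue
        clipped = iv.intersect([(s, e)], mask.intervals)
        if not clipped:
            continue
        out.append(TrueEvent(f"T{k + 1:04d}", s, e, clipped))
    return out


# ---------------------------------------------------------------------------
# Episode matching
# ---------------------------------------------------------------------------

TRUE_POSITIVE = "true_positive"
FALSE_POSITIVE = "false_positive"
EXCLUDED = "excluded"


@dataclass
class EpisodeStatus:
    episode_id: str
    status: str  # true_positive | false_positive | excluded
    matched_event_ids: list[str] = field(default_factory=list)
    duration_s: float = 0.0
    cause_label: Optional[str] = None


@dataclass
class EpisodeMatchResult:
    patient_id: str
    true_events: list[TrueEvent]
    detected_event_ids: set[str]
    episodes: list[EpisodeStatus]

    @property
    def n_true(self) -> int:
        return len(self.true_events)

    @property
    def n_detected(self) -> int:
        return len(self.detected_event_ids)

    @property
    def n_tp(self) -> int:
        return sum(1 for e in self.episodes if e.status == TRUE_POSITIVE)

    @property
    def n_fp(self) -> int:
        return sum(1 for e in self.episodes if e.status == FALSE_POSITIVE)

    @property
    def has_true_af(self) -> bool:
        return self.n_true > 0

    @property
    def has_detection(self) -> bool:
        return any(e.status != EXCLUDED for e in self.episodes)


def filter_retained(icm_log: IcmEpisodeLog) -> IcmEpisodeLog:
    """Keep only episodes the classifier retained (missing decision = retained)."""
    return IcmEpisodeLog(
        icm_log.patient_id,
        [ep for ep in icm_log.episodes if ep.ai_retained is not False],
    )


def match_episodes(
    icm_log_synced: IcmEpisodeLog,
    track: AnnotationTrack,
    min_overlap_s: float = 0.0,
    min_event_duration_s: float = MIN_EPISODE_S,
) -> EpisodeMatchResult:
    """Classify every device episode and mark every true event detected/missed.

    Episode status: *true_positive* if its mask-clipped interval overlaps any
    true AF event by more than ``min_overlap_s``; *excluded* if it lies
    entirely outside the analyzable mask; *false_positive* otherwise.  A true
    event is detected iff at least one episode overlaps it.
    """
    mask = build_mask(track)
    events = true_af_events(track, mask, min_event_duration_s)
    detected: set[str] = set()
    statuses: list[EpisodeStatus] = []
    for ep in icm_log_synced.episodes:
        clipped = iv.intersect([(ep.start_s, ep.end_s)], mask.intervals)
        if not clipped:
            statuses.append(EpisodeStatus(ep.episode_id, EXCLUDED,
                                          duration_s=ep.duration_s,
                                          cause_label=ep.cause_label))
            continue
        matched = [
            ev.event_id
            for ev in events
            if iv.overlap_length(clipped, ev.clipped) > max(min_overlap_s, 0.0)
        ]
        if matched:
            detected.update(matched)
            statuses.append(EpisodeStatus(ep.episode_id, TRUE_POSITIVE, matched,
                                          ep.duration_s, ep.cause_label))
        else:
            statuses.append(EpisodeStatus(ep.episode_id, FALSE_POSITIVE, [],
                                          ep.duration_s, ep.cause_label))
    return EpisodeMatchResult(track.patient_id, events, detected, statuses)


# ---------------------------------------------------------------------------
# Metric estimates
# ---------------------------------------------------------------------------

@dataclass
class MetricEstimate:
    name: str
    estimator: str  # gross | patient_average | gee
    point: Optional[float]
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    undefined: bool = False
    note: str = ""

    @property
    def pct(self) -> Optional[float]:
        return None if self.point is None else 100.0 * self.point


def ci_proportion(k: int, n: int, method: str = "clopper-pearson") -> tuple[float, float]:
    """95% CI for a binomial proportion (Clopper–Pearson exact or Wilson)."""
    if n <= 0:
        raise ValueError("n must be positive")
    sm_method = {"clopper-pearson": "beta", "wilson": "wilson"}[method]
    lo, hi = proportion_confint(k, n, alpha=0.05, method=sm_method)
    return float(lo), float(hi)


def _gross(name: str, k: int, n: int, ci_method: str) -> MetricEstimate:
    if n == 0:
        return MetricEstimate(name, "gross", None, undefined=True, note="zero denominator")
    lo, hi = ci_proportion(k, n, ci_method)
    return MetricEstimate(name, "gross", k / n, lo, hi)


def _patient_average(name: str, pairs: Sequence[tuple[int, int]]) -> MetricEstimate:
    """Unweighted mean of per-patient proportions (patients with trials > 0)."""
    props = [k / n for k, n in pairs if n > 0]
    if not props:
        return MetricEstimate(name, "patient_average", None, undefined=True,
                              note="no patient with a defined denominator")
    m = len(props)
    mean = float(np.mean(props))
    if m < 2:
        return MetricEstimate(name, "patient_average", mean, note="single patient; no CI")
    se = float(np.std(props, ddof=1)) / np.sqrt(m)
    lo = max(0.0, mean - 1.96 * se)
    hi = min(1.0, mean + 1.96 * se)
    return MetricEstimate(name, "patient_average", mean, lo, hi)


def gee_proportion(
    successes: Sequence[int], trials: Sequence[int], name: str = "proportion"
) -> MetricEstimate:
    """Cluster-adjusted proportion via intercept-only logistic GEE.

    Clusters are patients; the working correlation is exchangeable and the
    95% CI comes from the robust (sandwich) standard error on the logit
    scale, back-transformed.  Degenerate data (all successes or all
    failures, where the logit is infinite) falls back to the pooled
    proportion with an exact binomial CI, with a warning.
    """
    successes = [int(k) for k in successes]
    trials = [int(n) for n in trials]
    if len(successes) != len(trials):
        raise ValueError("successes and trials must have equal length")
    pairs = [(k, n) for k, n in zip(successes, trials) if n > 0]
    if len(pairs) < 2:
        if not pairs:
            return MetricEstimate(name, "gee", None, undefined=True,
                                  note="no cluster with trials")
        k, n = pairs[0]
        lo, hi = ci_proportion(k, n)
        return MetricEstimate(name, "gee", k / n, lo, hi, note="single cluster; exact CI")
    K = sum(k for k, _ in pairs)
    N = sum(n for _, n in pairs)
    if K == 0 or K == N:
        warnings.warn(f"{name}: all-{'success' if K else 'failure'} data; "
                      "GEE logit degenerate, falling back to exact binomial CI")
        lo, hi = ci_proportion(K, N)
        return MetricEstimate(name, "gee", K / N, lo, hi,
                              note="degenerate (all same outcome); exact binomial CI")

    import statsmodels.api as sm

    y = np.concatenate([
        np.concatenate([np.ones(k), np.zeros(n - k)]) for k, n in pairs
    ])
    groups = np.concatenate([np.full(n, i) for i, (_, n) in enumerate(pairs)])
    X = np.ones((len(y), 1))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GEE(y, X, groups=groups, family=sm.families.Binomial(),
                           cov_struct=sm.cov_struct.Exchangeable())
            res = model.fit()
        b = float(res.params[0])
        se = float(res.bse[0])
        if not np.isfinite(b) or not np.isfinite(se):
            raise ValueError("non-finite GEE estimate")
    except Exception as exc:
        warnings.warn(f"{name}: GEE failed ({exc}); falling back to gross + exact CI")
        lo, hi = ci_proportion(K, N)
        return MetricEstimate(name, "gee", K / N, lo, hi, note="gee fallback: gross + exact CI")
    return MetricEstimate(name, "gee", float(expit(b)),
                          float(expit(b - 1.96 * se)), float(expit(b + 1.96 * se)))


def episode_metrics(
    results: Iterable[EpisodeMatchResult], ci_method: str = "clopper-pearson"
) -> list[MetricEstimate]:
    """Episode-based sensitivity and PPV: gross, patient-average and GEE."""
    results = list(results)
    if not results:
        raise ValueError("need at least one patient")
    sens_pairs = [(r.n_detected, r.n_true) for r in results]
    ppv_pairs = [(r.n_tp, r.n_tp + r.n_fp) for r in results]
    out = []
    for name, pairs in (("episode_sensitivity", sens_pairs), ("episode_ppv", ppv_pairs)):
        K = sum(k for k, _ in pairs)
        N = sum(n for _, n in pairs)
        out.append(_gross(name, K, N, ci_method))
        out.append(_patient_average(name, pairs))
        est = gee_proportion([k for k, _ in pairs], [n for _, n in pairs], name)
        out.append(est)
    return out


# ---------------------------------------------------------------------------
# Duration-based metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionDurations:
    """Per-patient overlap durations within the analyzable mask, seconds."""

    patient_id: str
    tp_s: float
    fp_s: float
    tn_s: float
    fn_s: float

    @property
    def mask_s(self) -> float:
        return self.tp_s + self.fp_s + self.tn_s + self.fn_s


def confusion_durations(
    icm_log_synced: IcmEpisodeLog, track: AnnotationTrack
) -> ConfusionDurations:
    """Interval-overlap confusion: tp=|ICM∩AF|, fp=|ICM∖AF|, fn=|AF∖ICM|,
    tn=|mask∖(ICM∪AF)|, all restricted to the analyzable mask."""
    mask = build_mask(track)
    af = iv.intersect(track.intervals("AF"), mask.intervals)
    icm = iv.intersect(
        [(ep.start_s, ep.end_s) for ep in icm_log_synced.episodes], mask.intervals
    )
    tp = iv.overlap_length(icm, af)
    fp = iv.total(iv.subtract(icm, af))
    fn = iv.total(iv.subtract(af, icm))
    tn = iv.total(iv.subtract(mask.intervals, iv.union(icm, af)))
    return ConfusionDurations(track.patient_id, tp, fp, tn, fn)


_DURATION_METRICS = {
    "duration_sensitivity": lambda c: (c.tp_s, c.tp_s + c.fn_s),
    "duration_specificity": lambda c: (c.tn_s, c.tn_s + c.fp_s),
    "duration_ppv": lambda c: (c.tp_s, c.tp_s + c.fp_s),
    "duration_npv": lambda c: (c.tn_s, c.tn_s + c.fn_s),
    "duration_accuracy": lambda c: (c.tp_s + c.tn_s, c.mask_s),
}


def duration_metrics_from_confusion(
    confusions: Iterable[ConfusionDurations],
) -> list[MetricEstimate]:
    """Cohort-level duration metrics, pooling seconds across patients."""
    cs = list(confusions)
    pooled = ConfusionDurations(
        "pooled",
        sum(c.tp_s for c in cs),
        sum(c.fp_s for c in cs),
        sum(c.tn_s for c in cs),
        sum(c.fn_s for c in cs),
    )
    out = []
    for name, f in _DURATION_METRICS.items():
        num, den = f(pooled)
        if den <= 0:
            out.append(MetricEstimate(name, "gross", None, undefined=True,
                                      note="zero denominator"))
        else:
            out.append(MetricEstimate(name, "gross", num / den))
    return out


def duration_metrics(
    icm_log_synced: IcmEpisodeLog, track: AnnotationTrack
) -> tuple[ConfusionDurations, list[MetricEstimate]]:
    """Single-patient confusion durations and the five derived metrics."""
    c = confusion_durations(icm_log_synced, track)
    return c, duration_metrics_from_confusion([c])


# ---------------------------------------------------------------------------
# Patient-based (diagnostic) metrics
# ---------------------------------------------------------------------------

def patient_diagnostics(results: Iterable[EpisodeMatchResult]) -> list[MetricEstimate]:
    """2×2 patient classification: truth = any true AF event; device = any
    non-excluded episode.  Returns sensitivity, specificity, PPV, NPV."""
    tp = tn = fp = fn = 0
    for r in results:
        if r.has_true_af:
            tp += r.has_detection
            fn += not r.has_detection
        else:
            fp += r.has_detection
            tn += not r.has_detection
    return patient_metrics_from_counts(tp, fp, tn, fn)


def patient_metrics_from_counts(
    tp: int, fp: int, tn: int, fn: int
) -> list[MetricEstimate]:
    table = {
        "patient_sensitivity": (tp, tp + fn),
        "patient_specificity": (tn, tn + fp),
        "patient_ppv": (tp, tp + fp),
        "patient_npv": (tn, tn + fn),
    }
    out = []
    for name, (k, n) in table.items():
        if n == 0:
            out.append(MetricEstimate(name, "gross", None, undefined=True,
                                      note="zero denominator"))
        else:
            lo, hi = ci_proportion(k, n)
            out.append(MetricEstimate(name, "gross", k / n, lo, hi))
    return out


# ---------------------------------------------------------------------------
# PPV by episode-duration threshold
# ---------------------------------------------------------------------------

DEFAULT_DURATION_THRESHOLDS_S = (120.0, 600.0, 3600.0, 86400.0)


def ppv_by_duration(
    results: Iterable[EpisodeMatchResult],
    thresholds_s: Sequence[float] = DEFAULT_DURATION_THRESHOLDS_S,
) -> list[dict]:
    """Gross episode PPV restricted to device episodes of at least each
    duration threshold (default 2 min / 10 min / 1 h / 24 h)."""
    eps = [e for r in results for e in r.episodes if e.status != EXCLUDED]
    out = []
    for thr in thresholds_s:
        sel = [e for e in eps if e.duration_s >= thr - 1e-9]
        n_tp = sum(1 for e in sel if e.status == TRUE_POSITIVE)
        n = len(sel)
        out.append({
            "threshold_s": float(thr),
            "n_tp": n_tp,
            "n_episodes": n,
            "ppv": (n_tp / n) if n else None,
        })
    return out
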