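"""Synthetic cohort generator.

Emulates the structure of a prospective ICM-vs-Holter AF detection study:
~135 patients wear a 3–7-day Holter while an insertable cardiac monitor
(ICM) logs AF episodes of >= 2 minutes.  A core-lab-style annotation track
carries the true AF intervals plus atrial-tachycardia/flutter (ATFL) and
uninterpretable segments; the device log carries the true episodes minus
Bernoulli misses, with jittered boundaries, on its own (offset, possibly
drifting) clock, plus Poisson false-positive episodes attributed to sinus
arrhythmia, ectopy or noise.  Every logged episode carries a synthesized
electrogram (EGM) snippet: 30 s pre-trigger + 60 s post-trigger of a
QRS-wavelet train whose RR-interval process depends on the rhythm.

All times are half-open ``[start, end)`` seconds on the per-patient Holter
clock (the device log is then shifted to the ICM clock), rounded to 1 ms.
Identical config + seed gives a bit-identical cohort.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import intervals as iv
from .annotation_io import AnnotationTrack, IcmEpisode, IcmEpisodeLog, MIN_EPISODE_S

RHYTHM_LABELS = ("true_af", "sinus_arrhythmia", "ectopy", "noise")
FP_CAUSES = ("sinus_arrhythmia", "ectopy", "noise")

#: device EGM storage window around the detection trigger, seconds
PRETRIGGER_S = 30.0
POSTTRIGGER_S = 60.0


class ConfigError(ValueError):
    pass


def _round_ms(x: float) -> float:
    return round(float(x), 3)


@dataclass
class CohortConfig:
    """Generator parameters.

    Defaults emulate the study conditions: 135 patients, 3–7-day
    recordings, AF in ~29% of patients averaging ~13 episodes each,
    episode miss probability 0.6% (gross episode sensitivity ~99.4%),
    ~0.31 false episodes per patient-day split ~38/31/30% between sinus
    arrhythmia, ectopy and noise, and an unknown ICM clock offset within
    ±60 s.  Episode durations follow a truncated lognormal; the true
    duration distribution is not published, so the law here is a
    documented free choice (see docs/methods.md).
    """

    n_patients: int = 135
    recording_days_range: tuple[float, float] = (3.0, 7.0)
    prob_af_patient: float = 39.0 / 135.0
    #: (log-mean, log-sd) of lognormal episode duration in seconds, truncated >= 120 s
    episode_duration_law: tuple[float, float] = (math.log(600.0), 2.0)
    #: ("fixed", n) | ("poisson", mean) | ("nbinom", mean, dispersion); zero-truncated
    episodes_per_af_patient_law: tuple = ("nbinom", 13.4, 1.5)
    miss_prob: float = 0.006
    #: optional (intercept, slope-per-log-second) logistic miss model; overrides
    #: miss_prob when set (real devices miss short episodes more often)
    duration_dependent_miss: Optional[tuple[float, float]] = None
    boundary_jitter_sd: float = 2.0
    fp_rate_per_day: float = 0.31
    #: gamma shape of the per-patient multiplier on fp_rate_per_day (mean 1).
    #: Small values concentrate false episodes in a few arrhythmia-prone
    #: patients, as observed clinically, so most patients stay detection-free;
    #: None gives a homogeneous Poisson rate.
    fp_rate_dispersion: Optional[float] = 0.08
    fp_cause_mix: tuple[float, float, float] = (0.384, 0.313, 0.298)
    #: (log-mean, log-sd) of lognormal false-episode duration, truncated >= 120 s;
    #: false episodes skew short, which is what makes PPV rise with duration cutoffs
    fp_duration_law: tuple[float, float] = (math.log(150.0), 0.35)
    uninterpretable_frac: float = 0.02
    atfl_frac: float = 0.01
    #: by default uninterpretable segments avoid true AF so the 2-minute truth
    #: definition stays clean; enable to exercise the mask-clipping rules
    allow_uninterpretable_in_af: bool = False
    clock_offset_range: tuple[float, float] = (-60.0, 60.0)
    clock_drift_ppm: float = 0.0
    egm_sample_rate: float = 64.0
    synthesize_egms: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        probs = {
            "prob_af_patient": self.prob_af_patient,
            "miss_prob": self.miss_prob,
            "uninterpretable_frac": self.uninterpretable_frac,
            "atfl_frac": self.atfl_frac,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        if any(w < 0 for w in self.fp_cause_mix) or sum(self.fp_cause_mix) <= 0:
            raise ConfigError("fp_cause_mix must be non-negative with positive sum")
        # normalize the cause mix (printed study percentages sum to 99.5%)
        s = float(sum(self.fp_cause_mix))
        self.fp_cause_mix = tuple(float(w) / s for w in self.fp_cause_mix)
        if self.recording_days_range[0] <= 0 or (
            self.recording_days_range[1] < self.recording_days_range[0]
        ):
            raise ConfigError("bad recording_days_range")
        if self.fp_rate_per_day < 0 or self.boundary_jitter_sd < 0:
            raise ConfigError("rates and jitter must be non-negative")
        if self.fp_rate_dispersion is not None and self.fp_rate_dispersion <= 0:
            raise ConfigError("fp_rate_dispersion must be positive or None")
        mu, sd = self.episode_duration_law
        if sd < 0:
            raise ConfigError("episode_duration_law sd must be >= 0")
        # reject configs whose expected AF time cannot fit in the recording
        mean_eps = self._mean_episode_count()
        mean_dur = math.exp(mu + sd * sd / 2.0)
        mean_span = (
            0.5 * (self.recording_days_range[0] + self.recording_days_range[1]) * 86400.0
        )
        if mean_eps * max(mean_dur, MIN_EPISODE_S) > mean_span:
            raise ConfigError(
                "expected AF time per patient exceeds the recording span: "
                f"{mean_eps:.1f} episodes x {mean_dur:.0f} s > {mean_span:.0f} s"
            )

    def _mean_episode_count(self) -> float:
        law = self.episodes_per_af_patient_law
        if law[0] == "fixed":
            return float(law[1])
        return float(law[1])  # poisson / nbinom parameterized by mean

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruthTimeline:
    """True rhythm timeline for one patient, on the Holter clock."""

    patient_id: str
    recording_span: tuple[float, float]
    af_intervals: list[tuple[float, float]]
    atfl_intervals: list[tuple[float, float]] = field(default_factory=list)

    @property
    def total_af_s(self) -> float:
        return iv.total(self.af_intervals)


@dataclass
class EgmSnippet:
    """Device-stored electrogram around one detection trigger."""

    samples: np.ndarray
    sample_rate: float
    rhythm_label: str
    pretrigger_s: float = PRETRIGGER_S
    posttrigger_s: float = POSTTRIGGER_S

    @property
    def duration_s(self) -> float:
        return self.pretrigger_s + self.posttrigger_s


@dataclass
class SyntheticCohort:
    """Everything `generate_cohort` produces, keyed consistently by patient."""

    config: CohortConfig
    timelines: list[GroundTruthTimeline]
    tracks: list[AnnotationTrack]
    icm_logs: list[IcmEpisodeLog]
    #: (patient_id, episode_id) -> EgmSnippet (empty when synthesize_egms=False)
    egms: dict[tuple[str, str], EgmSnippet]
    #: per-patient clock offset actually injected: icm_time = holter_time - offset
    true_offsets: dict[str, float]

    @property
    def spans(self) -> dict[str, tuple[float, float]]:
        return {t.patient_id: t.recording_span for t in self.tracks}


# ---------------------------------------------------------------------------
# EGM synthesis
# ---------------------------------------------------------------------------

def _qrs_wavelet(sample_rate: float) -> np.ndarray:
    """Biphasic QRS-like wavelet (~120 ms support): Gaussian first derivative."""
    half = max(int(round(0.06 * sample_rate)), 2)
    t = np.arange(-half, half + 1) / sample_rate
    sigma = 0.012
    w = -(t / sigma) * np.exp(-0.5 * (t / sigma) ** 2)
    return w / np.max(np.abs(w))


def _rr_sequence(rhythm_label: str, duration_s: float, rng: np.random.Generator) -> np.ndarray:
    """Beat times (s from snippet start) for the rhythm-dependent RR process."""
    n_max = int(duration_s / 0.25) + 8
    if rhythm_label == "true_af":
        # irregularly irregular: iid gamma RR, CV ~0.28, no periodic modulation
        mean, cv = 0.75, 0.28
        shape = 1.0 / cv**2
        rr = rng.gamma(shape, mean / shape, size=n_max)
        rr = np.clip(rr, 0.28, 2.2)
    elif rhythm_label == "sinus_arrhythmia":
        # regular mean with slow (respiratory, ~0.25 Hz) sinusoidal modulation
        mean = 0.85
        rr = np.empty(n_max)
        t = rng.uniform(0.0, 4.0)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        for i in range(n_max):
            rr[i] = mean * (1.0 + 0.13 * np.sin(2.0 * np.pi * 0.25 * t + phase))
            rr[i] += rng.normal(0.0, 0.008)
            t += rr[i]
        rr = np.clip(rr, 0.4, 1.6)
    elif rhythm_label == "ectopy":
        # regular base rhythm with premature beats + compensatory pauses
        mean = 0.8
        rr = mean + rng.normal(0.0, 0.012, size=n_max)
        i = 1
        while i < n_max - 1:
            if rng.random() < 0.16:
                rr[i] *= 0.55      # premature coupling interval
                rr[i + 1] *= 1.45  # compensatory pause
                i += 2
            else:
                i += 1
        rr = np.clip(rr, 0.3, 1.8)
    elif rhythm_label == "noise":
        mean = 0.8
        rr = np.clip(mean + rng.normal(0.0, 0.015, size=n_max), 0.4, 1.6)
    else:
        raise ValueError(f"unknown rhythm_label {rhythm_label!r}")
    beats = np.cumsum(rr) + rng.uniform(0.0, float(rr[0]))
    return beats[beats < duration_s]


def synthesize_egm(
    rhythm_label: str,
    duration_s: float = PRETRIGGER_S + POSTTRIGGER_S,
    sample_rate: float = 64.0,
    seed: int | np.random.Generator = 0,
) -> EgmSnippet:
    """Synthesize one phenomenological EGM snippet.

    The waveform is a train of QRS-like wavelets placed at beat times drawn
    from a rhythm-dependent RR point process, plus a rhythm-dependent
    baseline: AF carries irregular fibrillatory (f-wave) activity and no
    P waves; organized rhythms carry a small P bump per beat; the noise
    class adds broadband noise bursts and baseline wander on top of an
    organized rhythm.  This is class-separable morphology/rhythm structure,
    not an electrophysiological simulation.
    """
    if rhythm_label not in RHYTHM_LABELS:
        raise ValueError(f"unknown rhythm_label {rhythm_label!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    x = np.zeros(n)

    beats = _rr_sequence(rhythm_label, duration_s, rng)
    qrs = _qrs_wavelet(sample_rate)
    half = (len(qrs) - 1) // 2
    amp = 1.0 + rng.normal(0.0, 0.05, size=len(beats))
    for bt, a in zip(beats, amp):
        c = int(round(bt * sample_rate))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        x[lo:hi] += a * qrs[half - (c - lo): half + (hi - c)]

    if rhythm_label == "true_af":
        # fibrillatory baseline: narrowband 4–9 Hz activity with drifting phase
        f = rng.uniform(4.0, 9.0)
        phase = np.cumsum(rng.normal(0.0, 0.35, size=n))
        x += 0.16 * np.sin(2.0 * np.pi * f * t + phase)
    else:
        # small P-wave bump ~160 ms before each QRS
        p_half = max(int(round(0.05 * sample_rate)), 1)
        tp = np.arange(-p_half, p_half + 1) / sample_rate
        p = 0.14 * np.exp(-0.5 * (tp / 0.025) ** 2)
        for bt in beats:
            c = int(round((bt - 0.16) * sample_rate))
            lo, hi = max(0, c - p_half), min(n, c + p_half + 1)
            if hi > lo:
                x[lo:hi] += p[p_half - (c - lo): p_half + (hi - c)]

    if rhythm_label == "noise":
        # broadband bursts at roughly QRS amplitude plus baseline wander
        n_bursts = rng.integers(3, 8)
        for _ in range(n_bursts):
            b0 = rng.uniform(0.0, duration_s - 4.0)
            blen = rng.uniform(2.0, 8.0)
            m = (t >= b0) & (t < b0 + blen)
            x[m] += rng.normal(0.0, 0.8, size=int(m.sum()))
        x += 0.5 * np.sin(2.0 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi))

    x += rng.normal(0.0, 0.03, size=n)  # sensor noise floor
    return EgmSnippet(samples=x, sample_rate=sample_rate, rhythm_label=rhythm_label)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _draw_episode_count(law: tuple, rng: np.random.Generator) -> int:
    kind = law[0]
    if kind == "fixed":
        return max(int(law[1]), 1)
    if kind == "poisson":
        for _ in range(1000):
            k = int(rng.poisson(float(law[1])))
            if k >= 1:
                return k
        return 1
    if kind == "nbinom":
        mean, disp = float(law[1]), float(law[2])
        for _ in range(1000):
            lam = rng.gamma(disp, mean / disp)
            k = int(rng.poisson(lam))
            if k >= 1:
                return k
        return 1
    raise ConfigError(f"unknown episode-count law {law!r}")


def _draw_truncated_lognormal(
    law: tuple[float, float], lo: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    mu, sd = law
    out = np.empty(size)
    filled = 0
    while filled < size:
        cand = rng.lognormal(mu, sd, size=size - filled)
        cand = cand[cand >= lo]
        out[filled: filled + len(cand)] = cand
        filled += len(cand)
    return out


def _place_disjoint(
    durations: np.ndarray, span: float, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Place episodes of given durations disjointly in [0, span).

    Gaps are a random Dirichlet split of the free time, so episode positions
    are exchangeable.  Longest episodes are dropped if the total cannot fit
    in 85% of the span.
    """
    durations = np.sort(durations)[::-1]
    while len(durations) and durations.sum() > 0.85 * span:
        durations = durations[1:]
    if len(durations) == 0:
        return []
    durations = rng.permutation(durations)
    free = span - durations.sum()
    gaps = rng.dirichlet(np.ones(len(durations) + 1)) * free
    out = []
    cur = 0.0
    for g, d in zip(gaps[:-1], durations):
        s = _round_ms(cur + g)
        e = _round_ms(s + d)
        out.append((s, e))
        cur = e
    return out


def _place_in_free_time(
    total_target: float,
    n_pieces: int,
    free: list[tuple[float, float]],
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    """Place ~n_pieces disjoint intervals of total length ~total_target inside free time."""
    out: list[tuple[float, float]] = []
    if total_target <= 0 or n_pieces <= 0:
        return out
    piece = total_target / n_pieces
    for _ in range(n_pieces):
        lens = np.array([e - s for s, e in free])
        ok = lens > piece
        if not ok.any():
            break
        w = np.where(ok, lens, 0.0)
        idx = rng.choice(len(free), p=w / w.sum())
        s0, e0 = free[idx]
        start = _round_ms(rng.uniform(s0, e0 - piece))
        end = _round_ms(start + piece)
        if end <= start:
            continue
        out.append((start, end))
        free = iv.subtract(free, [(start, end)])
        if not free:
            break
    return iv.normalize(out)


def _miss_probability(cfg: CohortConfig, duration_s: float) -> float:
    if cfg.duration_dependent_miss is None:
        return cfg.miss_prob
    b0, b1 = cfg.duration_dependent_miss
    z = b0 + b1 * math.log(duration_s)
    return 1.0 / (1.0 + math.exp(-z))


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate one synthetic cohort (deterministic in config.seed)."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    patient_seeds = ss.spawn(config.n_patients)

    timelines: list[GroundTruthTimeline] = []
    tracks: list[AnnotationTrack] = []
    logs: list[IcmEpisodeLog] = []
    egms: dict[tuple[str, str], EgmSnippet] = {}
    true_offsets: dict[str, float] = {}

    for i in range(config.n_patients):
        rng = np.random.default_rng(patient_seeds[i])
        pid = f"P{i + 1:03d}"
        span_s = _round_ms(rng.uniform(*config.recording_days_range) * 86400.0)
        span = (0.0, span_s)

        # --- ground truth AF ---
        af: list[tuple[float, float]] = []
        if rng.random() < config.prob_af_patient:
            n_ep = _draw_episode_count(config.episodes_per_af_patient_law, rng)
            durs = _draw_truncated_lognormal(
                config.episode_duration_law, MIN_EPISODE_S + 0.01, n_ep, rng
            )
            durs = np.minimum(durs, 0.8 * span_s)
            af = _place_disjoint(durs, span_s, rng)

        # --- exclusion segments on the annotation track ---
        free = iv.subtract([span], af) if not config.allow_uninterpretable_in_af else [span]
        atfl = _place_in_free_time(
            config.atfl_frac * span_s, int(rng.integers(1, 4)), free, rng
        )
        free2 = iv.subtract(free, atfl)
        unint = _place_in_free_time(
            config.uninterpretable_frac * span_s, int(rng.integers(3, 8)), free2, rng
        )

        events = (
            [("AF", s, e) for s, e in af]
            + [("ATFL", s, e) for s, e in atfl]
            + [("UNINTERPRETABLE", s, e) for s, e in unint]
        )
        timelines.append(GroundTruthTimeline(pid, span, af, atfl))
        tracks.append(AnnotationTrack(pid, span, events))

        # --- device detections ---
        detected: list[tuple[float, float, str]] = []  # (start, end, cause)
        for s, e in af:
            if rng.random() < _miss_probability(config, e - s):
                continue
            js = max(s + rng.normal(0.0, config.boundary_jitter_sd), 0.0)
            je = e + rng.normal(0.0, config.boundary_jitter_sd)
            if je - js < MIN_EPISODE_S:  # device still reports >= 2 min
                je = js + MIN_EPISODE_S
            if je > span_s:
                je = span_s
                js = min(js, je - MIN_EPISODE_S)
            detected.append((_round_ms(js), _round_ms(je), "true_af"))

        fp_mult = 1.0
        if config.fp_rate_dispersion is not None:
            k = config.fp_rate_dispersion
            fp_mult = rng.gamma(k, 1.0 / k)
        n_fp = int(rng.poisson(fp_mult * config.fp_rate_per_day * span_s / 86400.0))
        fp_free = iv.subtract([span], af)
        for _ in range(n_fp):
            d = float(
                _draw_truncated_lognormal(config.fp_duration_law, MIN_EPISODE_S, 1, rng)[0]
            )
            cause = FP_CAUSES[int(rng.choice(3, p=config.fp_cause_mix))]
            # false episodes occur outside true AF (a detection during real AF
            # is, by definition, a true detection)
            for _try in range(200):
                lens = np.array([e0 - s0 for s0, e0 in fp_free])
                ok = lens > d
                if not ok.any():
                    break
                w = np.where(ok, lens, 0.0)
                idx = rng.choice(len(fp_free), p=w / w.sum())
                s0, e0 = fp_free[idx]
                start = _round_ms(rng.uniform(s0, e0 - d))
                end = _round_ms(start + d)
                if end - start >= MIN_EPISODE_S:
                    detected.append((start, end, cause))
                    fp_free = iv.subtract(fp_free, [(start, end)])
                    break

        detected.sort()
        offset = _round_ms(rng.uniform(*config.clock_offset_range))
        true_offsets[pid] = offset
        drift = config.clock_drift_ppm * 1e-6

        episodes = []
        for k, (s, e, cause) in enumerate(detected):
            # ICM clock runs behind the Holter clock by `offset`, plus drift
            icm_s = _round_ms(s - offset + drift * s)
            icm_e = _round_ms(e - offset + drift * e)
            eid = f"E{k + 1:04d}"
            ep = IcmEpisode(
                episode_id=eid, start_s=icm_s, end_s=icm_e, cause_label=cause
            )
            episodes.append(ep)
            if config.synthesize_egms:
                egms[(pid, eid)] = synthesize_egm(
                    cause, sample_rate=config.egm_sample_rate, seed=rng
                )
        logs.append(IcmEpisodeLog(pid, episodes))

    return SyntheticCohort(config, timelines, tracks, logs, egms, true_offsets)
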