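"""Event-stream artifacts and their on-disk formats.

Two artifacts drive the whole evaluation:

* an **annotation track** — the gold-standard Holter annotation for one
  patient: labelled half-open intervals of AF, atrial tachycardia/flutter
  (ATFL), uninterpretable ECG, or other rhythms;
* an **ICM episode log** — the device-detected AF episodes for one patient,
  each at least 2 minutes long, each optionally carrying a pointer to its
  stored electrogram snippet and a classifier score/decision.

Both are serialized as plain UTF-8 CSV (RFC 4180, '.' decimal).  Times are
written with full float precision so that write→read is the identity.
Electrogram arrays live in separate per-episode files so the event CSVs stay
small.  A ``manifest.json`` ties a cohort together: patient ids, recording
spans, file paths and an echo of the generator config.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .intervals import Interval

ANNOTATION_LABELS = ("AF", "ATFL", "UNINTERPRETABLE", "OTHER")

#: minimum programmed episode duration, seconds (device detects AF >= 2 min)
MIN_EPISODE_S = 120.0


class ParseError(ValueError):
    """A malformed row in an input file (message names the line)."""


class ValidationError(ValueError):
    """A structurally valid file whose content violates an invariant."""


@dataclass
class AnnotationTrack:
    """Gold-standard labelled intervals for one Holter recording."""

    patient_id: str
    recording_span: Interval
    events: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(
            [(str(l), float(s), float(e)) for l, s, e in self.events],
            key=lambda ev: (ev[1], ev[2], ev[0]),
        )
        self.validate()

    def validate(self) -> None:
        lo, hi = self.recording_span
        if not hi > lo:
            raise ValidationError(f"{self.patient_id}: empty recording span")
        last_end: dict[str, float] = {}
        for label, s, e in self.events:
            if label not in ANNOTATION_LABELS:
                raise ValidationError(f"{self.patient_id}: unknown label {label!r}")
            if not e > s:
                raise ValidationError(f"{self.patient_id}: empty event [{s}, {e})")
            if s < lo or e > hi:
                raise ValidationError(
                    f"{self.patient_id}: event [{s}, {e}) outside span [{lo}, {hi})"
                )
            if label in last_end and s < last_end[label]:
                raise ValidationError(
                    f"{self.patient_id}: overlapping {label} events at {s}"
                )
            last_end[label] = e

    def intervals(self, label: str) -> list[Interval]:
        return [(s, e) for l, s, e in self.events if l == label]


@dataclass
class IcmEpisode:
    """One device-detected AF interval on the ICM clock."""

    episode_id: str
    start_s: float
    end_s: float
    egm_path: Optional[str] = None
    ai_score: Optional[float] = None
    ai_retained: Optional[bool] = None
    cause_label: Optional[str] = None  # ground-truth cause, synthetic cohorts only

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class IcmEpisodeLog:
    """All device-detected episodes for one patient, sorted by start."""

    patient_id: str
    episodes: list[IcmEpisode] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.episodes = sorted(self.episodes, key=lambda ep: (ep.start_s, ep.end_s))

    def validate(self, min_duration_s: float | None = MIN_EPISODE_S) -> None:
        if min_duration_s is None:
            return
        for ep in self.episodes:
            if ep.duration_s < min_duration_s - 1e-9:
                raise ValidationError(
                    f"{self.patient_id}/{ep.episode_id}: duration "
                    f"{ep.duration_s:.3f} s < {min_duration_s:g} s"
                )


# ---------------------------------------------------------------------------
# CSV serialization
# ---------------------------------------------------------------------------

def _read_csv(path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype={"patient_id": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


def write_annotation_tracks(tracks: list[AnnotationTrack], path) -> None:
    rows = [
        {"patient_id": t.patient_id, "label": l, "start_s": s, "end_s": e}
        for t in tracks
        for l, s, e in t.events
    ]
    df = pd.DataFrame(rows, columns=["patient_id", "label", "start_s", "end_s"])
    df.to_csv(path, index=False)


def write_annotation_track(track: AnnotationTrack, path) -> None:
    write_annotation_tracks([track], path)


def read_annotation_tracks(
    path, spans: dict[str, Interval]
) -> dict[str, AnnotationTrack]:
    """Read a (possibly multi-patient) annotations CSV.

    ``spans`` maps patient_id -> recording span; the CSV itself carries only
    events, so spans come from the manifest (or the caller).  Patients in
    ``spans`` with no event rows get an empty track.
    """
    df = _read_csv(path, ["patient_id", "label", "start_s", "end_s"])
    for i, row in df.iterrows():
        try:
            float(row["start_s"]), float(row["end_s"])
        except (TypeError, ValueError):
            raise ParseError(f"{path}: line {i + 2}: non-numeric time") from None
    out: dict[str, AnnotationTrack] = {}
    for pid, span in spans.items():
        sub = df[df["patient_id"] == pid]
        events = [
            (str(r.label), float(r.start_s), float(r.end_s))
            for r in sub.itertuples()
        ]
        out[pid] = AnnotationTrack(pid, (float(span[0]), float(span[1])), events)
    unknown = set(df["patient_id"]) - set(spans)
    if unknown:
        raise ValidationError(f"{path}: patients without a recording span: {sorted(unknown)}")
    return out


def read_annotation_track(
    path, recording_span: Interval | None = None
) -> AnnotationTrack:
    """Read a single-patient annotations CSV.

    Without an explicit ``recording_span`` the span is taken as
    ``[0, max end)`` — adequate for ad-hoc files; cohort reads should go
    through the manifest, which records the true spans.
    """
    df = _read_csv(path, ["patient_id", "label", "start_s", "end_s"])
    pids = df["patient_id"].unique()
    if len(pids) != 1:
        raise ValidationError(f"{path}: expected one patient, found {len(pids)}")
    pid = str(pids[0])
    if recording_span is None:
        recording_span = (0.0, float(df["end_s"].astype(float).max()))
    return read_annotation_tracks(path, {pid: recording_span})[pid]


_ICM_COLS = [
    "patient_id", "episode_id", "start_s", "end_s",
    "egm_path", "ai_score", "ai_retained", "cause_label",
]


def write_icm_logs(logs: list[IcmEpisodeLog], path) -> None:
    rows = []
    for log in logs:
        for ep in log.episodes:
            rows.append({
                "patient_id": log.patient_id,
                "episode_id": ep.episode_id,
                "start_s": ep.start_s,
                "end_s": ep.end_s,
                "egm_path": ep.egm_path if ep.egm_path is not None else "",
                "ai_score": ep.ai_score if ep.ai_score is not None else "",
                "ai_retained": {True: "true", False: "false", None: ""}[ep.ai_retained],
                "cause_label": ep.cause_label if ep.cause_label is not None else "",
            })
    pd.DataFrame(rows, columns=_ICM_COLS).to_csv(path, index=False)


def write_icm_log(log: IcmEpisodeLog, path) -> None:
    write_icm_logs([log], path)


def read_icm_logs(
    path, min_duration_s: float | None = MIN_EPISODE_S
) -> dict[str, IcmEpisodeLog]:
    """Read a (possibly multi-patient) ICM episode CSV.

    ``min_duration_s=None`` disables the >=2-minute validation, for
    threshold experiments.
    """
    df = _read_csv(path, ["patient_id", "episode_id", "start_s", "end_s"])
    for c in ("egm_path", "ai_score", "ai_retained", "cause_label"):
        if c not in df.columns:
            df[c] = ""
    out: dict[str, IcmEpisodeLog] = {}
    for i, r in enumerate(df.itertuples()):
        try:
            start, end = float(r.start_s), float(r.end_s)
        except (TypeError, ValueError):
            raise ParseError(f"{path}: line {i + 2}: non-numeric time") from None

        def _opt(v):
            return None if (pd.isna(v) or v == "") else v

        retained = _opt(r.ai_retained)
        if retained is not None:
            retained = {"true": True, "false": False}.get(str(retained).lower())
            if retained is None:
                raise ParseError(f"{path}: line {i + 2}: bad ai_retained value")
        score = _opt(r.ai_score)
        ep = IcmEpisode(
            episode_id=str(r.episode_id),
            start_s=start,
            end_s=end,
            egm_path=_opt(r.egm_path) and str(r.egm_path),
            ai_score=None if score is None else float(score),
            ai_retained=retained,
            cause_label=_opt(r.cause_label) and str(r.cause_label),
        )
        out.setdefault(str(r.patient_id), IcmEpisodeLog(str(r.patient_id), [])).episodes.append(ep)
    for log in out.values():
        log.episodes.sort(key=lambda ep: (ep.start_s, ep.end_s))
        log.validate(min_duration_s)
    return out


def read_icm_log(path, min_duration_s: float | None = MIN_EPISODE_S) -> IcmEpisodeLog:
    logs = read_icm_logs(path, min_duration_s)
    if len(logs) != 1:
        raise ValidationError(f"{path}: expected one patient, found {len(logs)}")
    return next(iter(logs.values()))


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def write_manifest(path, spans: dict[str, Interval], files: dict[str, str],
                   config: dict | None = None) -> None:
    doc = {
        "patients": [
            {"patient_id": pid, "recording_span": [span[0], span[1]]}
            for pid, span in sorted(spans.items())
        ],
        "files": files,
        "config": config or {},
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_manifest(path) -> tuple[dict[str, Interval], dict[str, str], dict]:
    doc = json.loads(Path(path).read_text())
    spans = {
        p["patient_id"]: (float(p["recording_span"][0]), float(p["recording_span"][1]))
        for p in doc["patients"]
    }
    return spans, doc.get("files", {}), doc.get("config", {})


def dataclass_to_dict(obj) -> dict:
    return dataclasses.asdict(obj)
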