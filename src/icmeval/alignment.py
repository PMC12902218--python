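"""ICM–Holter clock synchronization.

The device logs episodes on its own clock, which is offset (and may drift)
relative to the Holter recorder.  The study design this emulates resolved
the discrepancy by manually synchronizing one detected episode beat-by-beat
to the Holter trace and shifting the rest; here the synchronization point is
found automatically by maximizing the total overlap between the shifted
device episodes and the annotated AF intervals over a grid of candidate
offsets, refined by golden-section search around the grid optimum.

Convention: ``offset_s`` is the number of seconds to ADD to ICM timestamps
to land on the Holter clock.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from . import intervals as iv
from .annotation_io import AnnotationTrack, IcmEpisodeLog


@dataclass
class SyncEstimate:
    patient_id: str
    offset_s: float
    drift_ppm: float = 0.0
    quality: float = 0.0  # achieved overlap / total ICM episode duration
    note: str = ""        # "", "no_af", or "empty_log"


def _total_overlap(icm: list[tuple[float, float]], af, offset: float) -> float:
    return iv.overlap_length([(s + offset, e + offset) for s, e in icm], af)


def _golden_max(f, lo: float, hi: float, tol: float = 1e-3) -> float:
    """Golden-section maximization of a unimodal-enough scalar function."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def estimate_offset(
    icm_log: IcmEpisodeLog,
    track: AnnotationTrack,
    search_window_s: float = 120.0,
    step_s: float = 0.5,
) -> SyncEstimate:
    """Estimate the offset to add to ICM times for one patient.

    Grid search over ``[-search_window_s, +search_window_s]`` at ``step_s``
    resolution on the total ICM∩AF overlap, ties broken toward the smallest
    |offset|, then golden-section refinement within one grid step.  The
    quality score is the achieved overlap divided by the total logged
    episode duration (1.0 = every logged second lands on annotated AF).
    """
    if search_window_s <= 0 or step_s <= 0:
        raise ValueError("search window and step must be positive")
    pid = track.patient_id
    icm = [(ep.start_s, ep.end_s) for ep in icm_log.episodes]
    if not icm:
        warnings.warn(f"{pid}: empty ICM log; returning no-op sync estimate")
        return SyncEstimate(pid, 0.0, 0.0, 0.0, note="empty_log")
    af = track.intervals("AF")
    total_icm = iv.total(icm)
    if not af:
        return SyncEstimate(pid, 0.0, 0.0, 0.0, note="no_af")

    offsets = np.arange(-search_window_s, search_window_s + step_s / 2, step_s)
    best_o, best_v = 0.0, -1.0
    for o in offsets:
        v = _total_overlap(icm, af, float(o))
        if v > best_v + 1e-12 or (abs(v - best_v) <= 1e-12 and abs(o) < abs(best_o)):
            best_o, best_v = float(o), v
    if best_v <= 0.0:
        return SyncEstimate(pid, 0.0, 0.0, 0.0, note="no_af")

    refined = _golden_max(
        lambda o: _total_overlap(icm, af, o), best_o - step_s, best_o + step_s
    )
    if _total_overlap(icm, af, refined) < best_v:
        refined = best_o
    quality = _total_overlap(icm, af, refined) / total_icm
    return SyncEstimate(pid, float(refined), 0.0, float(quality))


def apply_sync(icm_log: IcmEpisodeLog, sync: SyncEstimate) -> IcmEpisodeLog:
    """Shift every episode onto the Holter clock.

    Each boundary t becomes ``t + offset_s + drift_ppm*1e-6*t``; for zero
    drift, episode durations are preserved exactly.
    """
    d = sync.drift_ppm * 1e-6

    def shift(t: float) -> float:
        return t + sync.offset_s + d * t

    eps = [
        replace(ep, start_s=shift(ep.start_s), end_s=shift(ep.end_s))
        for ep in icm_log.episodes
    ]
    return IcmEpisodeLog(icm_log.patient_id, eps)
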