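"""AF-burden agreement between device and Holter.

AF burden is the percentage of analyzable monitored time spent in AF.  Both
burdens use the analyzable mask as denominator (consistent with the
exclusion rule that removes uninterpretable and AT/AFL time from
assessment).  Agreement across patients is summarized by the Pearson
correlation and a Bland–Altman analysis of the differences d = ICM − Holter:
bias = mean(d), 95% limits of agreement = bias ± 1.96·sd(d) (sample sd).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy import stats

from . import intervals as iv
from .annotation_io import AnnotationTrack, IcmEpisodeLog
from .evaluation import build_mask


@dataclass
class BurdenPair:
    patient_id: str
    holter_burden_pct: Optional[float]
    icm_burden_pct: Optional[float]

    @property
    def defined(self) -> bool:
        return self.holter_burden_pct is not None


@dataclass
class BurdenAgreement:
    pearson_r: Optional[float]
    bias_pct: float
    loa_low_pct: float
    loa_high_pct: float
    n: int
    note: str = ""


def compute_burdens(icm_log_synced: IcmEpisodeLog, track: AnnotationTrack) -> BurdenPair:
    """Holter and ICM AF burden (% of analyzable time) for one patient."""
    mask = build_mask(track)
    m = mask.total_s
    if m <= 0:
        return BurdenPair(track.patient_id, None, None)
    af = iv.intersect(track.intervals("AF"), mask.intervals)
    icm = iv.intersect(
        [(ep.start_s, ep.end_s) for ep in icm_log_synced.episodes], mask.intervals
    )
    return BurdenPair(
        track.patient_id,
        100.0 * iv.total(af) / m,
        100.0 * iv.total(icm) / m,
    )


def agreement(pairs: Iterable[BurdenPair]) -> BurdenAgreement:
    """Pearson correlation and Bland–Altman summary over patients."""
    pairs = [p for p in pairs if p.defined]
    if len(pairs) < 3:
        raise ValueError("need at least 3 patients with a defined burden")
    h = np.array([p.holter_burden_pct for p in pairs])
    c = np.array([p.icm_burden_pct for p in pairs])
    d = c - h
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    note = ""
    if np.std(h) == 0 or np.std(c) == 0:
        r = None
        note = "zero variance; correlation undefined"
    else:
        r = float(stats.pearsonr(h, c).statistic)
    return BurdenAgreement(
        pearson_r=r,
        bias_pct=bias,
        loa_low_pct=bias - 1.96 * sd,
        loa_high_pct=bias + 1.96 * sd,
        n=len(pairs),
        note=note,
    )
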