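"""Shared constants and helpers for the numbered analysis scripts.

All scripts operate on the same seeded synthetic cohort so their outputs
compose into one coherent analysis. Regeneration is deterministic and cheap,
so each script rebuilds what it needs rather than passing large intermediates
around; only small result tables are written under results/.
"""

from pathlib import Path

from icmeval import alignment
from icmeval.synthetic import CohortConfig, generate_cohort

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

SEED = 20240901
COHORT_N = 30


def get_cohort(synthesize_egms: bool = True):
    cfg = CohortConfig(n_patients=COHORT_N, seed=SEED,
                       synthesize_egms=synthesize_egms)
    return generate_cohort(cfg)


def get_synced(cohort):
    """Estimate per-patient clock offsets and return synced logs + estimates."""
    synced, estimates = [], []
    for log, track in zip(cohort.icm_logs, cohort.tracks):
        est = alignment.estimate_offset(log, track)
        synced.append(alignment.apply_sync(log, est))
        estimates.append(est)
    return synced, estimates


def metric_rows(estimates):
    """Flatten MetricEstimate objects into table rows."""
    return [
        {
            "metric": m.name,
            "estimator": m.estimator,
            "point": m.point,
            "pct": None if m.pct is None else round(m.pct, 1),
            "ci_low": m.ci_low,
            "ci_high": m.ci_high,
            "note": m.note if not m.undefined else (m.note or "undefined"),
        }
        for m in estimates
    ]
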