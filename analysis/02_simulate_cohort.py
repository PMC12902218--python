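"""Generate the seeded synthetic cohort used by the remaining scripts.

Writes the raw cohort (Holter annotation tracks, ICM episode logs, manifest)
under scratch/cohort/ and a per-patient summary table to
results/cohort_summary.csv.
"""

import pandas as pd

from common import RESULTS, SCRATCH, get_cohort
from icmeval import annotation_io
from icmeval.intervals import total


def main():
    cohort = get_cohort(synthesize_egms=False)

    outdir = SCRATCH / "cohort"
    outdir.mkdir(parents=True, exist_ok=True)
    annotation_io.write_annotation_tracks(cohort.tracks, outdir / "annotations.csv")
    annotation_io.write_icm_logs(cohort.icm_logs, outdir / "icm_episodes.csv")
    annotation_io.write_manifest(
        outdir / "manifest.json", cohort.spans,
        {"annotations": "annotations.csv", "icm": "icm_episodes.csv"},
        cohort.config.to_dict(),
    )

    rows = []
    for track, log, tl in zip(cohort.tracks, cohort.icm_logs, cohort.timelines):
        span_d = (track.recording_span[1] - track.recording_span[0]) / 86400.0
        rows.append({
            "patient_id": track.patient_id,
            "span_days": round(span_d, 2),
            "n_true_af_episodes": len(tl.af_intervals),
            "true_af_hours": round(total(tl.af_intervals) / 3600.0, 2),
            "n_icm_episodes": len(log.episodes),
            "true_clock_offset_s": cohort.true_offsets[track.patient_id],
        })
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "cohort_summary.csv", index=False)
    print(df.to_string(index=False))
    print(f"\n{len(df)} patients; "
          f"{int((df.n_true_af_episodes > 0).sum())} with true AF; "
          f"{int(df.n_icm_episodes.sum())} ICM-detected episodes total")
    print(f"raw cohort written to {outdir}")


if __name__ == "__main__":
    main()
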