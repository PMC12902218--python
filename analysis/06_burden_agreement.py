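"""Per-patient AF-burden agreement between ICM and Holter (Bland–Altman).

Computes each patient's AF burden (% of analyzable time in AF) from the
Holter annotations and from the synced ICM log, then the Pearson correlation,
bias and 95% limits of agreement of the differences.

Outputs: results/burden_pairs.csv, results/burden_agreement.json.
"""

import json

import pandas as pd

from common import RESULTS, get_cohort, get_synced
from icmeval import burden


def main():
    cohort = get_cohort(synthesize_egms=False)
    synced, _ = get_synced(cohort)

    pairs = [burden.compute_burdens(log, tr)
             for log, tr in zip(synced, cohort.tracks)]
    agree = burden.agreement(pairs)

    df = pd.DataFrame([
        {
            "patient_id": p.patient_id,
            "holter_burden_pct": p.holter_burden_pct,
            "icm_burden_pct": p.icm_burden_pct,
            "difference_pct": (None if not p.defined
                               else p.icm_burden_pct - p.holter_burden_pct),
        }
        for p in pairs
    ])
    summary = {
        "n": agree.n,
        "pearson_r": agree.pearson_r,
        "bias_pct": agree.bias_pct,
        "loa_low_pct": agree.loa_low_pct,
        "loa_high_pct": agree.loa_high_pct,
        "note": agree.note,
    }

    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "burden_pairs.csv", index=False)
    (RESULTS / "burden_agreement.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")

    print(df.to_string(index=False))
    print(json.dumps(summary, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
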