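"""Apply the trained classifier as an episode filter and re-evaluate.

Scores every synced ICM episode's EGM snippet with the model trained by
04_train_classifier.py, drops episodes below the operating threshold, and
recomputes all metric families. Also reports the false-positive rejection
rate broken down by simulated cause.

Outputs: results/post_ai_metrics.csv, results/fp_rejection_by_cause.csv.
"""

import pandas as pd

from common import RESULTS, SCRATCH, get_cohort, get_synced, metric_rows
from icmeval import evaluation as ev
from icmeval.classifier import classify_log, load_classifier
from icmeval.pipeline import fp_rejection_by_cause


def main():
    cohort = get_cohort(synthesize_egms=True)
    synced, _ = get_synced(cohort)
    model = load_classifier(SCRATCH / "model")

    classified, errors = [], []
    for log in synced:
        new_log, errs = classify_log(log, model, cohort.egms)
        classified.append(new_log)
        errors.extend(errs)
    post = [ev.filter_retained(log) for log in classified]

    results = [ev.match_episodes(log, tr)
               for log, tr in zip(post, cohort.tracks)]
    confusions = [ev.confusion_durations(log, tr)
                  for log, tr in zip(post, cohort.tracks)]
    metrics = (ev.patient_diagnostics(results)
               + ev.episode_metrics(results)
               + ev.duration_metrics_from_confusion(confusions))
    metrics_df = pd.DataFrame(metric_rows(metrics))

    rejection = fp_rejection_by_cause(synced, classified, cohort.tracks)
    rej_df = pd.DataFrame(
        [{"cause": k, **v} for k, v in rejection["by_cause"].items()]
        + [{"cause": "all", **rejection["overall"]}]
    )

    RESULTS.mkdir(exist_ok=True)
    metrics_df.to_csv(RESULTS / "post_ai_metrics.csv", index=False)
    rej_df.to_csv(RESULTS / "fp_rejection_by_cause.csv", index=False)

    print(f"classify errors: {len(errors)}")
    print(metrics_df.to_string(index=False))
    print(rej_df.to_string(index=False))


if __name__ == "__main__":
    main()
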