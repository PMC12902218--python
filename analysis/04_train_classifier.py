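"""Train the 1-D CNN false-positive rejection model on synthetic EGM snippets.

Builds a labelled training set (true-AF snippets vs the three false-positive
causes), trains with a patient-level split and focal loss, selects the
operating threshold under the zero-true-positive-loss policy, and saves the
model to scratch/model/ for the next script.

Outputs: results/classifier_training.csv (per-epoch history),
results/classifier_validation.json (split sizes, AUROC, threshold).
"""

import json

import pandas as pd

from common import RESULTS, SCRATCH, SEED
from icmeval.classifier import ClassifierConfig, save_classifier, train
from icmeval.pipeline import make_training_set


def main():
    snippets, labels, pids = make_training_set(480, sample_rate=64,
                                               seed=SEED + 2)
    cfg = ClassifierConfig(seed=SEED + 1)
    trained = train(snippets, labels, pids, cfg)

    save_classifier(trained, SCRATCH / "model")

    hist = pd.DataFrame(trained.history)
    RESULTS.mkdir(exist_ok=True)
    hist.to_csv(RESULTS / "classifier_training.csv", index=False)
    summary = {
        **trained.validation_summary,
        "operating_threshold": trained.operating_threshold,
    }
    (RESULTS / "classifier_validation.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")

    print(hist.to_string(index=False))
    print(json.dumps(summary, indent=2, sort_keys=True))
    print(f"model saved to {SCRATCH / 'model'}")


if __name__ == "__main__":
    main()
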