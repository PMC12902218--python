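import numpy as np
import pytest
from hypothesis import settings

from icmeval.classifier import ClassifierConfig, train
from icmeval.pipeline import make_training_set
from icmeval.synthetic import CohortConfig, generate_cohort

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-patient cohort with EGMs, default error modes."""
    return generate_cohort(CohortConfig(n_patients=30, seed=5))


@pytest.fixture(scope="session")
def clean_cohort():
    """Error-free cohort: no misses, no false positives, perfect clocks."""
    cfg = CohortConfig(
        n_patients=10, prob_af_patient=1.0, miss_prob=0.0, fp_rate_per_day=0.0,
        boundary_jitter_sd=0.0, clock_offset_range=(0.0, 0.0),
        uninterpretable_frac=0.0, atfl_frac=0.0, synthesize_egms=False, seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def trained_classifier():
    """One CNN trained on a separable synthetic corpus, reused across tests."""
    snippets, labels, pids = make_training_set(480, 64.0, seed=2)
    return train(snippets, labels, pids, ClassifierConfig(seed=1))


def random_track_and_log(rng: np.random.Generator, span_s: float = 7200.0):
    """A random annotation track + device log for oracle comparisons.

    Intervals are drawn freely (not via the cohort generator) so the interval
    algebra is exercised on adversarial layouts: overlapping device episodes
    vs AF, exclusions cutting through both, etc.
    """
    from icmeval.annotation_io import AnnotationTrack, IcmEpisode, IcmEpisodeLog

    def random_intervals(n, min_len, max_len):
        out = []
        for _ in range(n):
            start = rng.uniform(0, span_s - max_len)
            out.append((round(start, 1), round(start + rng.uniform(min_len, max_len), 1)))
        return out

    events = []
    af = []
    cur = rng.uniform(0, 600)
    for _ in range(rng.integers(0, 5)):
        dur = rng.uniform(120, 900)
        if cur + dur > span_s:
            break
        af.append((round(cur, 1), round(cur + dur, 1)))
        cur += dur + rng.uniform(60, 1200)
    events += [("AF", s, e) for s, e in af]
    for s, e in random_intervals(rng.integers(0, 3), 30, 400):
        events.append(("UNINTERPRETABLE", s, e))
    atfl = []
    for s, e in random_intervals(rng.integers(0, 2), 60, 500):
        if all(e <= s2 or s >= e2 for _, s2, e2 in events if _ == "ATFL"):
            atfl.append((s, e))
    events += [("ATFL", s, e) for s, e in atfl]
    # drop overlapping same-label rows (track validation requires disjoint)
    from icmeval import intervals as iv

    clean_events = []
    for label in {"AF", "UNINTERPRETABLE", "ATFL"}:
        ivs = iv.normalize([(s, e) for l, s, e in events if l == label])
        clean_events += [(label, s, e) for s, e in ivs]
    track = AnnotationTrack("PX", (0.0, span_s), clean_events)

    eps = []
    for k, (s, e) in enumerate(random_intervals(rng.integers(1, 8), 120, 1200)):
        eps.append(IcmEpisode(f"E{k}", s, min(e, span_s)))
    return track, IcmEpisodeLog("PX", eps)
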