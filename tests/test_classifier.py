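"""CNN episode-classifier tests: loss closed forms, architecture contracts,
threshold policy against a brute-force scan, and the filter semantics."""

import dataclasses

import numpy as np
import pytest

from icmeval.annotation_io import IcmEpisode, IcmEpisodeLog
from icmeval.classifier import (
    ClassifierConfig, ClassifierConfigError, build_model, classify_log,
    load_classifier, prepare_inputs, save_classifier, select_threshold, train,
)
from icmeval.cnn import focal_loss, focal_loss_grad_logit, sigmoid
from icmeval.synthetic import synthesize_egm


def _small_cfg(**kw):
    defaults = dict(
        n_conv_blocks=2, filters_per_block=(4, 8), kernel_size=5,
        dropout_per_block=(0.0, 0.1), pool_every=1, dense_units=(8,),
        input_downsample=4, epochs=2, seed=0,
    )
    defaults.update(kw)
    return ClassifierConfig(**defaults)


class TestFocalLoss:
    def test_reduces_to_half_bce_when_gamma_zero(self):
        """γ=0, α=0.5 gives exactly half the binary cross-entropy."""
        rng = np.random.default_rng(1)
        p = rng.uniform(0.01, 0.99, 10)
        y = rng.integers(0, 2, 10).astype(float)
        fl = focal_loss(p, y, gamma=0.0, alpha=0.5)
        bce = -(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert np.max(np.abs(fl - 0.5 * bce)) < 1e-10

    def test_vanishes_on_perfect_predictions(self):
        y = np.array([1.0, 0.0])
        p = np.array([1.0 - 1e-9, 1e-9])
        assert focal_loss(p, y, 2.0, 0.25).max() < 1e-6

    def test_gradient_matches_numerical(self):
        rng = np.random.default_rng(2)
        z = rng.normal(0, 2, 20)
        y = rng.integers(0, 2, 20).astype(float)
        for gamma, alpha in [(0.0, 0.5), (2.0, 0.25), (1.0, 0.7)]:
            g = focal_loss_grad_logit(sigmoid(z), y, gamma, alpha)
            eps = 1e-6
            num = (focal_loss(sigmoid(z + eps), y, gamma, alpha)
                   - focal_loss(sigmoid(z - eps), y, gamma, alpha)) / (2 * eps)
            assert np.max(np.abs(g - num)) < 1e-5

    def test_downweights_easy_examples(self):
        # a well-classified positive contributes far less with gamma=2
        easy = focal_loss(np.array([0.95]), np.array([1.0]), 2.0, 0.5)
        hard = focal_loss(np.array([0.55]), np.array([1.0]), 2.0, 0.5)
        bce_ratio = np.log(0.55) / np.log(0.95)
        assert hard / easy > bce_ratio  # modulating factor sharpens the contrast


class TestConfigAndBuild:
    def test_non_monotone_filters_rejected(self):
        with pytest.raises(ClassifierConfigError, match="non-decreasing"):
            _small_cfg(filters_per_block=(8, 4))

    def test_non_monotone_dropout_rejected(self):
        with pytest.raises(ClassifierConfigError, match="non-decreasing"):
            _small_cfg(dropout_per_block=(0.3, 0.1))

    def test_excessive_pooling_rejected(self):
        cfg = ClassifierConfig(
            n_conv_blocks=6, filters_per_block=(4,) * 6, kernel_size=3,
            dropout_per_block=(0.0,) * 6, pool_every=1, input_downsample=1,
        )
        with pytest.raises(ClassifierConfigError, match="pooling"):
            build_model(cfg, 64)

    def test_same_seed_identical_initial_params(self):
        cfg = _small_cfg()
        a = build_model(cfg, 256).state_dict()
        b = build_model(cfg, 256).state_dict()
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_forward_scalar_output_any_batch(self):
        cfg = _small_cfg()
        net = build_model(cfg, 128)
        for n in (1, 3, 7):
            z = net.forward(np.zeros((n, 1, 128), np.float32))
            p = sigmoid(z)
            assert z.shape == (n,)
            assert np.all((p > 0) & (p < 1)) and np.all(np.isfinite(p))


class TestThresholdPolicy:
    def test_separable_clouds(self):
        scores = np.array([0.9, 0.95, 0.99, 0.1, 0.2, 0.3])
        labels = np.array([1, 1, 1, 0, 0, 0])
        t = select_threshold(scores, labels, _small_cfg())
        assert 0.3 < t <= 0.9
        assert (scores[labels == 1] >= t).all()
        assert (scores[labels == 0] < t).all()

    def test_identical_scores_retain_everything(self):
        scores = np.full(6, 0.7)
        labels = np.array([1, 1, 1, 0, 0, 0])
        t = select_threshold(scores, labels, _small_cfg())
        assert (scores >= t).all()  # 0 rejection

    def test_matches_brute_force_scan(self):
        """No candidate threshold rejects more falses at zero true loss."""
        rng = np.random.default_rng(5)
        scores = np.concatenate([rng.uniform(0.4, 1.0, 30), rng.uniform(0.0, 0.7, 30)])
        labels = np.concatenate([np.ones(30), np.zeros(30)])
        t = select_threshold(scores, labels, _small_cfg())
        pos, neg = scores[labels == 1], scores[labels == 0]
        assert (pos >= t).all()
        best = max((neg < c).sum() for c in np.r_[scores, 0.0, 1.0]
                   if (pos >= c).all())
        assert (neg < t).sum() == best

    def test_fixed_policy(self):
        cfg = _small_cfg(threshold_policy="fixed", fixed_threshold=0.42)
        assert select_threshold(np.array([0.9]), np.array([1]), cfg) == 0.42


class TestTraining:
    def test_single_class_rejected(self):
        snips = [synthesize_egm("true_af", seed=s) for s in range(4)]
        with pytest.raises(ValueError, match="both classes"):
            train(snips, [1, 1, 1, 1], ["A", "A", "B", "B"], _small_cfg())

    def test_patient_split_has_no_leakage_and_learns(self, trained_classifier):
        s = trained_classifier.validation_summary
        assert s["n_train"] + s["n_val"] == 480
        assert s["val_auroc"] >= 0.95
        assert s["val_tp_retained"] == s["val_tp_total"]  # zero-TP-loss policy
        # loss decreased over training
        hist = trained_classifier.history
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]

    def test_training_determinism(self):
        snips = ([synthesize_egm("true_af", seed=s) for s in range(12)]
                 + [synthesize_egm("noise", seed=100 + s) for s in range(12)])
        labels = [1] * 12 + [0] * 12
        pids = [f"P{i % 6}" for i in range(24)]
        cfg = _small_cfg(epochs=1)
        t1 = train(snips, labels, pids, cfg)
        t2 = train(snips, labels, pids, cfg)
        assert t1.operating_threshold == t2.operating_threshold
        s1, s2 = t1.net.state_dict(), t2.net.state_dict()
        assert all(np.array_equal(s1[k], s2[k]) for k in s1)


class TestClassifyLog:
    def _log_and_egms(self, n=4):
        eps, egms = [], {}
        for i in range(n):
            eid = f"E{i}"
            eps.append(IcmEpisode(eid, 1000.0 * i, 1000.0 * i + 200.0))
            rhythm = "true_af" if i % 2 == 0 else "noise"
            egms[("P1", eid)] = synthesize_egm(rhythm, seed=i)
        return IcmEpisodeLog("P1", eps), egms

    def test_threshold_zero_retains_all(self, trained_classifier):
        log, egms = self._log_and_egms()
        t = dataclasses.replace(trained_classifier, operating_threshold=0.0)
        out, errors = classify_log(log, t, egms)
        assert errors == []
        assert all(ep.ai_retained for ep in out.episodes)
        # boundaries untouched
        assert [(e.start_s, e.end_s) for e in out.episodes] == \
            [(e.start_s, e.end_s) for e in log.episodes]

    def test_threshold_above_one_rejects_all(self, trained_classifier):
        log, egms = self._log_and_egms()
        t = dataclasses.replace(trained_classifier, operating_threshold=1.0 + 1e-9)
        out, _ = classify_log(log, t, egms)
        assert not any(ep.ai_retained for ep in out.episodes)

    def test_missing_snippet_failsafe_retained(self, trained_classifier):
        log, egms = self._log_and_egms()
        del egms[("P1", "E1")]
        out, errors = classify_log(log, trained_classifier, egms)
        assert len(errors) == 1 and "E1" in errors[0]
        ep = {e.episode_id: e for e in out.episodes}["E1"]
        assert ep.ai_retained is True and ep.ai_score is None

    def test_separates_true_from_false_snippets(self, trained_classifier):
        log, egms = self._log_and_egms(8)
        out, _ = classify_log(log, trained_classifier, egms)
        for ep in out.episodes:
            expected = int(ep.episode_id[1:]) % 2 == 0
            assert ep.ai_retained is expected


def test_save_load_roundtrip(tmp_path, trained_classifier):
    save_classifier(trained_classifier, tmp_path / "model")
    back = load_classifier(tmp_path / "model")
    assert back.operating_threshold == trained_classifier.operating_threshold
    x = [synthesize_egm("true_af", seed=99), synthesize_egm("ectopy", seed=98)]
    assert np.allclose(back.score(x), trained_classifier.score(x))


def test_prepare_inputs_normalizes_and_downsamples():
    snip = synthesize_egm("true_af", seed=0)
    x = prepare_inputs([snip], downsample=2)
    assert x.shape == (1, 1, 90 * 64 // 2)
    assert abs(float(x.mean())) < 1e-5
    assert float(x.std()) == pytest.approx(1.0, abs=1e-3)
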