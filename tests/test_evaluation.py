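"""Metric-family tests: hand-worked interval arithmetic, a per-sample
discretization oracle, clustered (GEE) estimation against an independent
solver, and the exclusion/undefined rules."""

import numpy as np
import pytest
from scipy import stats

from conftest import random_track_and_log
from icmeval import evaluation as ev
from icmeval.annotation_io import AnnotationTrack, IcmEpisode, IcmEpisodeLog


def _track(span, events):
    return AnnotationTrack("P1", span, events)


def _log(eps):
    return IcmEpisodeLog("P1", [IcmEpisode(f"E{i}", s, e) for i, (s, e) in enumerate(eps)])


class TestMask:
    def test_no_exclusions_full_span(self):
        m = ev.build_mask(_track((0.0, 1000.0), [("AF", 0.0, 300.0)]))
        assert m.intervals == [(0.0, 1000.0)]

    def test_overlapping_exclusions_merged(self):
        m = ev.build_mask(_track((0.0, 1000.0), [
            ("UNINTERPRETABLE", 100.0, 200.0), ("ATFL", 150.0, 300.0),
        ]))
        assert m.intervals == [(0.0, 100.0), (300.0, 1000.0)]
        assert m.total_s == 800.0

    def test_exclusions_covering_span_gives_empty_mask(self):
        track = _track((0.0, 500.0), [("UNINTERPRETABLE", 0.0, 500.0)])
        m = ev.build_mask(track)
        assert m.intervals == [] and m.total_s == 0.0
        _, metrics = ev.duration_metrics(_log([]), track)
        assert all(x.undefined for x in metrics)


class TestTrueEvents:
    def test_short_event_excluded(self):
        evs = ev.true_af_events(_track((0.0, 1000.0), [("AF", 0.0, 119.0)]))
        assert evs == []

    def test_simple_event_retained(self):
        evs = ev.true_af_events(_track((0.0, 1000.0), [("AF", 0.0, 300.0)]))
        assert len(evs) == 1 and evs[0].clipped == [(0.0, 300.0)]

    def test_clipped_event_keeps_one_id_two_segments(self):
        track = _track((0.0, 1000.0), [
            ("AF", 0.0, 300.0), ("UNINTERPRETABLE", 100.0, 200.0),
        ])
        evs = ev.true_af_events(track)
        assert len(evs) == 1
        assert evs[0].clipped == [(0.0, 100.0), (200.0, 300.0)]

    def test_threshold_applies_to_annotation_not_clip(self):
        # 150 s annotated event whose visible remnant is only 40 s: still truth
        track = _track((0.0, 1000.0), [
            ("AF", 0.0, 150.0), ("UNINTERPRETABLE", 40.0, 150.0),
        ])
        evs = ev.true_af_events(track)
        assert len(evs) == 1 and evs[0].clipped == [(0.0, 40.0)]

    def test_event_fully_in_excluded_time_dropped(self):
        track = _track((0.0, 1000.0), [
            ("AF", 100.0, 300.0), ("ATFL", 100.0, 300.0),
        ])
        assert ev.true_af_events(track) == []


class TestMatchEpisodes:
    def test_partial_overlap_is_tp(self):
        res = ev.match_episodes(_log([(100.0, 400.0)]),
                                _track((0.0, 2000.0), [("AF", 350.0, 900.0)]))
        assert res.episodes[0].status == ev.TRUE_POSITIVE
        assert res.n_detected == 1

    def test_episode_inside_atfl_excluded_not_fp(self):
        res = ev.match_episodes(
            _log([(200.0, 400.0)]),
            _track((0.0, 2000.0), [("ATFL", 100.0, 500.0)]),
        )
        assert res.episodes[0].status == ev.EXCLUDED
        assert res.n_fp == 0

    def test_hand_enumerated_cohort(self):
        """5 true events, 4 detected, one spurious episode: sens 4/5, PPV 4/5."""
        af = [(i * 1000.0, i * 1000.0 + 300.0) for i in range(5)]
        track = _track((0.0, 10000.0), [("AF", s, e) for s, e in af])
        icm = [(s + 50.0, e + 50.0) for s, e in af[:4]] + [(8000.0, 8200.0)]
        res = ev.match_episodes(_log(icm), track)
        assert (res.n_detected, res.n_true) == (4, 5)
        assert (res.n_tp, res.n_fp) == (4, 1)

    def test_multiple_episodes_one_event(self):
        """Three episodes on one event: 1 detected event, 3 TP episodes."""
        track = _track((0.0, 5000.0), [("AF", 0.0, 2000.0)])
        res = ev.match_episodes(_log([(0.0, 400.0), (600.0, 900.0), (1500.0, 1700.0)]),
                                track)
        assert res.n_detected == 1 and res.n_tp == 3

    def test_min_overlap_option(self):
        track = _track((0.0, 5000.0), [("AF", 0.0, 1000.0)])
        log = _log([(990.0, 1200.0)])  # 10 s overlap
        assert ev.match_episodes(log, track).episodes[0].status == ev.TRUE_POSITIVE
        res = ev.match_episodes(log, track, min_overlap_s=30.0)
        assert res.episodes[0].status == ev.FALSE_POSITIVE


def _result(pid, n_true, n_det, n_tp, n_fp):
    evs = [ev.TrueEvent(f"T{i}", 0, 200, [(0, 200)]) for i in range(n_true)]
    eps = [ev.EpisodeStatus(f"E{i}", ev.TRUE_POSITIVE, ["T0"], 200.0)
           for i in range(n_tp)]
    eps += [ev.EpisodeStatus(f"F{i}", ev.FALSE_POSITIVE, [], 150.0)
            for i in range(n_fp)]
    return ev.EpisodeMatchResult(pid, evs, {f"T{i}" for i in range(n_det)}, eps)


class TestEpisodeMetrics:
    def test_pooled_ppv_matches_hand_value(self):
        """1004 true + 252 false detections pool to gross PPV 0.799."""
        results = [_result("P1", 500, 500, 1004, 252)]
        m = {(x.name, x.estimator): x for x in ev.episode_metrics(results)}
        assert m[("episode_ppv", "gross")].point == pytest.approx(1004 / 1256)
        assert round(m[("episode_ppv", "gross")].pct, 1) == 79.9

    def test_perfect_single_patient(self):
        results = [_result("P1", 3, 3, 3, 0)]
        for x in ev.episode_metrics(results):
            if not x.undefined:
                assert x.point == pytest.approx(1.0)

    def test_gross_vs_patient_average(self):
        """Per-patient PPV 1/2 and 9/10: gross 10/12, patient average 0.7."""
        results = [_result("A", 1, 1, 1, 1), _result("B", 9, 9, 9, 1)]
        m = {(x.name, x.estimator): x for x in ev.episode_metrics(results)}
        assert m[("episode_ppv", "gross")].point == pytest.approx(10 / 12)
        assert m[("episode_ppv", "patient_average")].point == pytest.approx(0.7)

    def test_zero_denominator_flagged_undefined(self):
        results = [_result("A", 0, 0, 0, 0)]
        m = {(x.name, x.estimator): x for x in ev.episode_metrics(results)}
        assert m[("episode_sensitivity", "gross")].undefined
        assert m[("episode_sensitivity", "gross")].point is None


class TestDurationMetrics:
    def test_hand_interval_arithmetic(self):
        """mask 1000 s, AF [0,400), ICM [100,500): tp=300 fp=100 fn=100 tn=500."""
        track = _track((0.0, 1000.0), [("AF", 0.0, 400.0)])
        c, metrics = ev.duration_metrics(_log([(100.0, 500.0)]), track)
        assert (c.tp_s, c.fp_s, c.fn_s, c.tn_s) == (300.0, 100.0, 100.0, 500.0)
        m = {x.name: x.point for x in metrics}
        assert m["duration_sensitivity"] == pytest.approx(0.75)
        assert m["duration_specificity"] == pytest.approx(5 / 6)
        assert m["duration_ppv"] == pytest.approx(0.75)
        assert m["duration_npv"] == pytest.approx(5 / 6)
        assert m["duration_accuracy"] == pytest.approx(0.8)

    def test_identity_gives_all_ones(self, clean_cohort):
        cs = [ev.confusion_durations(l, t)
              for l, t in zip(clean_cohort.icm_logs, clean_cohort.tracks)]
        for x in ev.duration_metrics_from_confusion(cs):
            assert x.point == pytest.approx(1.0)

    def test_no_af_no_icm_degenerate(self):
        track = _track((0.0, 1000.0), [])
        _, metrics = ev.duration_metrics(_log([]), track)
        m = {x.name: x for x in metrics}
        assert m["duration_specificity"].point == pytest.approx(1.0)
        assert m["duration_sensitivity"].undefined

    def test_conservation_over_random_patients(self):
        """tp+fp+tn+fn equals the mask duration to 1e-6 s, always."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            track, log = random_track_and_log(rng)
            c = ev.confusion_durations(log, track)
            mask = ev.build_mask(track)
            assert c.mask_s == pytest.approx(mask.total_s, abs=1e-6)

    def test_matches_discretization_oracle(self):
        """Interval-algebra confusion agrees with a 0.1 s per-sample count."""
        rng = np.random.default_rng(7)
        dt = 0.1
        for _ in range(100):
            track, log = random_track_and_log(rng, span_s=3600.0)
            c = ev.confusion_durations(log, track)
            t = (np.arange(int(3600 / dt)) + 0.5) * dt

            def member(ivs):
                m = np.zeros(len(t), bool)
                for s, e in ivs:
                    m |= (t >= s) & (t < e)
                return m

            mask = member(ev.build_mask(track).intervals)
            af = member(track.intervals("AF")) & mask
            icm = member([(e.start_s, e.end_s) for e in log.episodes]) & mask
            n_bounds = 2 * (len(track.events) + len(log.episodes) + 1)
            tol = 0.2 * n_bounds
            assert abs(c.tp_s - (af & icm).sum() * dt) <= tol
            assert abs(c.fp_s - (~af & icm & mask).sum() * dt) <= tol
            assert abs(c.fn_s - (af & ~icm).sum() * dt) <= tol
            assert abs(c.tn_s - (mask & ~af & ~icm).sum() * dt) <= tol


class TestPatientDiagnostics:
    def test_three_patient_enumeration(self):
        """TP-patient, TN-patient, FP-patient: sens 1, spec 1/2, PPV 1/2, NPV 1."""
        results = [
            _result("TP", 2, 2, 2, 0),
            _result("TN", 0, 0, 0, 0),
            _result("FP", 0, 0, 0, 3),
        ]
        m = {x.name: x.point for x in ev.patient_diagnostics(results)}
        assert m == {
            "patient_sensitivity": 1.0, "patient_specificity": 0.5,
            "patient_ppv": 0.5, "patient_npv": 1.0,
        }

    def test_study_counts(self):
        """39/39 AF patients detected, 80/96 clean: 100/83.3/70.9/100."""
        m = {x.name: round(x.pct, 1)
             for x in ev.patient_metrics_from_counts(39, 16, 80, 0)}
        assert m == {
            "patient_sensitivity": 100.0, "patient_specificity": 83.3,
            "patient_ppv": 70.9, "patient_npv": 100.0,
        }

    def test_all_af_free_sensitivity_undefined(self):
        results = [_result("A", 0, 0, 0, 0), _result("B", 0, 0, 0, 0)]
        m = {x.name: x for x in ev.patient_diagnostics(results)}
        assert m["patient_specificity"].point == pytest.approx(1.0)
        assert m["patient_sensitivity"].undefined


class TestCiProportion:
    def test_boundary_cases(self):
        assert ev.ci_proportion(10, 10)[1] == pytest.approx(1.0)
        assert ev.ci_proportion(0, 10)[0] == pytest.approx(0.0)

    def test_matches_beta_quantile_oracle(self):
        lo, hi = ev.ci_proportion(8, 10)
        assert lo == pytest.approx(stats.beta.ppf(0.025, 8, 3), abs=1e-6)
        assert hi == pytest.approx(stats.beta.ppf(0.975, 9, 2), abs=1e-6)
        assert (round(lo, 4), round(hi, 4)) == (0.4439, 0.9748)

    def test_wilson_variant(self):
        lo, hi = ev.ci_proportion(8, 10, method="wilson")
        assert 0.0 < lo < 0.8 < hi < 1.0


def _gee_oracle(ks, ns, tol=1e-12, max_iter=500):
    """Independent intercept-only exchangeable-GEE solver.

    Closed-form weighted-mean update for the marginal proportion (the
    exchangeable inverse collapses to cluster weights 1/(1+(n-1)a)),
    interleaved with the moment estimator of the working correlation.
    """
    ks = np.asarray(ks, float)
    ns = np.asarray(ns, float)
    mu, a = ks.sum() / ns.sum(), 0.0
    for _ in range(max_iter):
        w = 1.0 / (1.0 + (ns - 1.0) * a)
        mu_new = (w * ks).sum() / (w * ns).sum()
        v = mu_new * (1.0 - mu_new)
        ssr = (ks * (1 - mu_new) ** 2 + (ns - ks) * mu_new**2) / v
        s = (ks - ns * mu_new) / np.sqrt(v)
        nobs = ns.sum()
        scale = ssr.sum() / (nobs - 1.0)
        pair_sum = ((s**2 - ssr) / 2.0).sum() / scale
        npairs = (ns * (ns - 1.0) / 2.0).sum()
        a_new = pair_sum / (npairs - 1.0)
        if abs(mu_new - mu) < tol and abs(a_new - a) < tol:
            return mu_new
        mu, a = mu_new, a_new
    return mu


class TestGeeProportion:
    def test_singleton_clusters_equal_gross(self):
        ks = [1, 0, 1, 1, 0, 1, 0, 1]
        est = ev.gee_proportion(ks, [1] * 8)
        assert est.point == pytest.approx(sum(ks) / 8, abs=1e-6)

    def test_matches_independent_solver(self):
        """Point estimate equals the hand-rolled GEE solver on 20 random
        clustered datasets (max |difference| < 1e-4)."""
        rng = np.random.default_rng(11)
        worst = 0.0
        for _ in range(20):
            m = int(rng.integers(5, 15))
            ns = rng.integers(1, 30, size=m)
            p = rng.uniform(0.15, 0.85, size=m)  # cluster heterogeneity
            ks = rng.binomial(ns, p)
            if ks.sum() in (0, ns.sum()):
                continue
            est = ev.gee_proportion(ks.tolist(), ns.tolist())
            worst = max(worst, abs(est.point - _gee_oracle(ks, ns)))
        assert worst < 1e-4

    def test_degenerate_all_success_falls_back(self):
        with pytest.warns(UserWarning, match="degenerate"):
            est = ev.gee_proportion([5, 3, 2], [5, 3, 2])
        assert est.point == pytest.approx(1.0)
        assert "degenerate" in est.note
        assert est.ci_high == pytest.approx(1.0)

    def test_ci_width_near_binomial_when_independent(self):
        """With zero intra-cluster correlation the GEE CI is about as wide as
        the binomial CI (mean width ratio within 10% over 100 replicates)."""
        rng = np.random.default_rng(42)
        ratios = []
        for _ in range(100):
            ns = np.full(40, 5)
            ks = rng.binomial(ns, 0.3)
            if ks.sum() in (0, ns.sum()):
                continue
            gee = ev.gee_proportion(ks.tolist(), ns.tolist())
            lo, hi = ev.ci_proportion(int(ks.sum()), int(ns.sum()), "wilson")
            ratios.append((gee.ci_high - gee.ci_low) / (hi - lo))
        assert abs(np.mean(ratios) - 1.0) < 0.1


class TestPpvByDuration:
    def test_threshold_below_all_equals_overall(self):
        results = [_result("A", 5, 5, 8, 2)]
        table = ev.ppv_by_duration(results, thresholds_s=(0.0,))
        assert table[0]["ppv"] == pytest.approx(0.8)

    def test_short_fps_make_ppv_nondecreasing(self, small_cohort):
        from icmeval import alignment

        results = []
        for log, tr in zip(small_cohort.icm_logs, small_cohort.tracks):
            est = alignment.estimate_offset(log, tr)
            results.append(ev.match_episodes(alignment.apply_sync(log, est), tr))
        table = ev.ppv_by_duration(results)
        vals = [row["ppv"] for row in table if row["ppv"] is not None]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_empty_stratum_undefined(self):
        results = [_result("A", 1, 1, 1, 0)]
        table = ev.ppv_by_duration(results, thresholds_s=(1e9,))
        assert table[0]["ppv"] is None


def test_filter_monotonicity_removing_fps(small_cohort):
    """Removing only false-positive episodes never decreases PPV or
    specificity and never changes sensitivity."""
    from icmeval import alignment
    from icmeval.annotation_io import IcmEpisodeLog

    rng = np.random.default_rng(3)
    synced, tracks = [], []
    for log, tr in zip(small_cohort.icm_logs, small_cohort.tracks):
        est = alignment.estimate_offset(log, tr)
        synced.append(alignment.apply_sync(log, est))
        tracks.append(tr)
    pre = [ev.match_episodes(l, t) for l, t in zip(synced, tracks)]
    # drop a random subset of FP episodes only
    post_logs = []
    for log, res in zip(synced, pre):
        fps = {e.episode_id for e in res.episodes if e.status == ev.FALSE_POSITIVE}
        drop = {eid for eid in fps if rng.random() < 0.7}
        post_logs.append(IcmEpisodeLog(
            log.patient_id, [ep for ep in log.episodes if ep.episode_id not in drop]
        ))
    post = [ev.match_episodes(l, t) for l, t in zip(post_logs, tracks)]

    def metric(results, name, est="gross"):
        vals = {(x.name, x.estimator): x for x in ev.episode_metrics(results)}
        return vals[(name, est)].point

    assert metric(post, "episode_sensitivity") == metric(pre, "episode_sensitivity")
    assert metric(post, "episode_ppv") >= metric(pre, "episode_ppv")
    pre_d = ev.duration_metrics_from_confusion(
        [ev.confusion_durations(l, t) for l, t in zip(synced, tracks)])
    post_d = ev.duration_metrics_from_confusion(
        [ev.confusion_durations(l, t) for l, t in zip(post_logs, tracks)])
    pre_m = {x.name: x.point for x in pre_d}
    post_m = {x.name: x.point for x in post_d}
    assert post_m["duration_specificity"] >= pre_m["duration_specificity"]
    assert post_m["duration_sensitivity"] == pytest.approx(pre_m["duration_sensitivity"])
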