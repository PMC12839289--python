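"""Window metrics, ROC, alarm persistence logic and event-level accounting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spikeseiz import (
    AlarmEvent,
    PredictionStream,
    benchmark_latency,
    build_hybrid_snn,
    detect_alarms,
    detection_latency,
    false_alarm_rates,
    replay,
    roc_auc,
    window_metrics,
)
from spikeseiz.streaming import persistence_times
from spikeseiz.synthetic import generate_background
from spikeseiz.windowing import segment, windows_for_record, zscore


def make_stream(binary, step=0.25, win=0.5, rid="r"):
    probs = np.asarray(binary, dtype=float)
    starts = np.arange(len(probs)) * step
    return PredictionStream(rid, starts, probs, step, win)


def brute_force_alarms(binary, k):
    """Independent run-scanner: maximal runs of ones with length >= k."""
    runs = []
    start = None
    for i, v in enumerate(list(binary) + [0]):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start >= k:
                runs.append((start, i - 1))
            start = None
    return runs


class TestWindowMetrics:
    def test_perfect(self):
        m = window_metrics([1, 0, 1], [1, 0, 1])
        assert m["accuracy"] == 1 and m["error_rate"] == 0 and m["f1"] == 1

    def test_hand_counts(self):
        y = [1] * 10 + [0] * 10
        p = [1] * 9 + [0] + [1] + [0] * 9
        m = window_metrics(p, y)
        assert m["precision"] == pytest.approx(0.9)
        assert m["recall"] == pytest.approx(0.9)
        assert m["f1"] == pytest.approx(0.9)
        assert (m["tp"], m["fp"], m["fn"], m["tn"]) == (9, 1, 1, 9)

    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=2))
    @settings(max_examples=50, deadline=None)
    def test_f1_is_harmonic_mean(self, pairs):
        p = [a for a, _ in pairs]
        y = [b for _, b in pairs]
        m = window_metrics(p, y)
        if m["precision"] + m["recall"] > 0:
            hm = 2 * m["precision"] * m["recall"] / (m["precision"] + m["recall"])
            assert m["f1"] == pytest.approx(hm)
        assert m["error_rate"] == pytest.approx(1 - m["accuracy"])


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_pairwise_oracle_with_ties(self):
        assert roc_auc([0.2, 0.6, 0.6, 0.9], [0, 0, 1, 1]) == pytest.approx(0.875)

    def test_null_distribution(self, rng):
        probs = rng.random(10_000)
        labels = rng.integers(0, 2, 10_000)
        assert roc_auc(probs, labels) == pytest.approx(0.5, abs=0.02)

    def test_matches_brute_force_pair_count(self, rng):
        probs = rng.random(60).round(1)  # force ties
        labels = rng.integers(0, 2, 60)
        pos, neg = probs[labels == 1], probs[labels == 0]
        pairs = [(1.0 if p > n else 0.5 if p == n else 0.0) for p in pos for n in neg]
        assert roc_auc(probs, labels) == pytest.approx(np.mean(pairs))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestDetectAlarms:
    @pytest.mark.parametrize("n_pos,n_alarms", [(9, 0), (10, 1), (25, 1)])
    def test_single_run_threshold(self, n_pos, n_alarms):
        stream = make_stream([0] * 3 + [1] * n_pos + [0] * 3)
        assert len(detect_alarms(stream, 0.5, k=10)) == n_alarms

    def test_two_runs_separated_by_one_negative(self):
        stream = make_stream([1] * 12 + [0] + [1] * 12)
        assert len(detect_alarms(stream, 0.5, k=10)) == 2

    def test_event_geometry(self):
        stream = make_stream([0] * 4 + [1] * 12 + [0] * 4)
        (ev,) = detect_alarms(stream, 0.5, k=10)
        assert ev.start_s == pytest.approx(4 * 0.25)
        assert ev.end_s == pytest.approx(15 * 0.25 + 0.5)
        assert ev.n_windows == 12
        assert ev.trigger_s == pytest.approx((4 + 9) * 0.25 + 0.5)

    @given(st.integers(0, 2**31 - 1), st.sampled_from([1, 2, 10, 39]))
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_run_scan_oracle(self, seed, k):
        r = np.random.default_rng(seed)
        binary = (r.random(r.integers(1, 90)) < 0.5).astype(int)
        stream = make_stream(binary)
        got = [(round(ev.start_s / 0.25), ev.n_windows) for ev in
               detect_alarms(stream, 0.5, k=k)]
        want = [(a, b - a + 1) for a, b in brute_force_alarms(binary, k)]
        assert got == want


class TestFalseAlarmRates:
    def test_zero_alarm_rates(self):
        out = false_alarm_rates([], [], 1.0)
        assert out["fa_per_day"] == 24 * out["fa_per_hour"] == 0

    @pytest.mark.parametrize("fa_h,fa_d", [(0.034, 0.82), (0.026, 0.62)])
    def test_per_day_display_conversion(self, fa_h, fa_d):
        assert round(24 * fa_h, 2) == pytest.approx(fa_d)

    def test_three_false_alarms_in_a_day(self):
        alarms = [AlarmEvent(i * 1000.0, i * 1000.0 + 5, 12, i * 1000.0 + 3)
                  for i in range(3)]
        out = false_alarm_rates(alarms, [], total_hours=24.0)
        assert out["fa_per_hour"] == pytest.approx(0.125)
        assert out["fa_per_day"] == pytest.approx(3.0)

    def test_overlapping_alarm_is_true(self):
        alarms = [AlarmEvent(100.0, 110.0, 40, 102.75)]
        out = false_alarm_rates(alarms, [(105.0, 120.0)], total_hours=1.0)
        assert out["n_false"] == 0 and alarms[0].is_false is False

    def test_exact_day_hour_identity(self, rng):
        alarms = [AlarmEvent(s, s + 4, 11, s + 2) for s in
                  rng.uniform(0, 3000, 7)]
        out = false_alarm_rates(alarms, [(50.0, 60.0)], total_hours=rng.uniform(1, 20))
        assert out["fa_per_day"] == pytest.approx(24 * out["fa_per_hour"], rel=1e-12)


class TestDetectionLatency:
    def test_alarm_at_onset(self):
        alarms = [AlarmEvent(100.0, 130.0, 120, 100.0)]
        assert detection_latency(alarms, [(100.0, 130.0)]) == [0.0]

    def test_no_alarms_all_missed(self):
        assert detection_latency([], [(10.0, 20.0), (50.0, 70.0)]) == [None, None]

    def test_perfect_stream_from_onset_gives_2_75_s(self):
        # positives exactly from onset: k=10, step 0.25, win 0.5
        onset = 5.0
        n = 100
        starts = np.arange(n) * 0.25
        probs = (starts >= onset).astype(float)
        stream = PredictionStream("r", starts, probs)
        alarms = detect_alarms(stream, 0.5, k=10)
        (lat,) = detection_latency(alarms, [(onset, onset + 10)])
        assert lat == pytest.approx(9 * 0.25 + 0.5)  # 2.75 s

    def test_pre_onset_run_floors_at_zero(self):
        alarms = [AlarmEvent(80.0, 130.0, 200, 82.75)]
        (lat,) = detection_latency(alarms, [(90.0, 120.0)])
        assert lat == 0.0

    def test_persistence_time_readings(self):
        t = persistence_times()
        assert t["persistence_time"] == pytest.approx(2.5)
        assert t["span_time"] == pytest.approx(2.75)


class _StubModel:
    """Constant-output model for replay plumbing tests."""

    def __init__(self):
        self.training = False

    def eval(self):
        self.training = False
        return self

    def train(self):
        self.training = True
        return self

    def __call__(self, x):
        from spikeseiz._autograd import Tensor
        B = x.shape[0]
        logits = np.zeros((B, 2))
        logits[:, 1] = x.data.mean(axis=(1, 2))  # monotone in window activity
        return Tensor(logits)


class TestReplay:
    def test_decision_count_formula(self):
        rec = generate_background(C=1, duration_s=600, fs=256, seed=0)
        stream = replay(_StubModel(), zscore(rec), coder="delta_sigma")
        assert stream.probs.size == (600 * 256 - 128) // 64 + 1
        assert stream.step_s == pytest.approx(0.25)

    def test_causality_under_truncation(self):
        rec = zscore(generate_background(C=1, duration_s=60, fs=256, seed=1))
        full = replay(_StubModel(), rec, coder="delta_sigma")
        import dataclasses
        short = dataclasses.replace(rec, data=rec.data[:, : 30 * 256])
        part = replay(_StubModel(), short, coder="delta_sigma")
        n = part.probs.size
        np.testing.assert_allclose(full.probs[:n], part.probs, atol=1e-12)

    def test_too_short_record_empty_stream(self):
        rec = generate_background(C=1, duration_s=0.4, fs=256, seed=0)
        stream = replay(_StubModel(), rec, coder="delta_sigma")
        assert stream.probs.size == 0

    def test_replay_deterministic(self):
        rec = zscore(generate_background(C=2, duration_s=30, fs=256, seed=2))
        a = replay(_StubModel(), rec, coder="hybrid")
        b = replay(_StubModel(), rec, coder="hybrid")
        np.testing.assert_array_equal(a.probs, b.probs)

    def test_natural_prevalence_preserved(self, small_cohort, small_cohort_spec):
        """The fraction of positive windows in replayed records matches the
        generator's prevalence within +-30 % relative."""
        pos = tot = 0
        for rec in small_cohort:
            wins = windows_for_record(rec)
            pos += sum(w.label for w in wins)
            tot += len(wins)
        frac = pos / tot
        prev = small_cohort_spec.seizure_prevalence
        assert abs(frac - prev) / prev <= 0.35  # window quantization adds slack


class TestOracleClassifierStreaming:
    def test_zero_false_alarms_and_full_detection(self, small_cohort):
        """Probability = true window label => no false alarms, every seizure found."""
        for rec in small_cohort:
            wins = windows_for_record(rec)
            stream = PredictionStream(
                rec.record_id,
                np.array([w.start_sample for w in wins]) / rec.fs,
                np.array([float(w.label) for w in wins]),
            )
            alarms = detect_alarms(stream, 0.5, k=10)
            fa = false_alarm_rates(alarms, rec.ictal_intervals, rec.duration_s / 3600)
            assert fa["n_false"] == 0
            lats = detection_latency(alarms, rec.ictal_intervals)
            assert all(l is not None for l in lats)
            for l in lats:
                assert 0.0 <= l <= 2.75 + 1e-9


class TestBenchmark:
    def test_positive_finite_latency(self, rng):
        m = build_hybrid_snn().eval()
        batch = (rng.random((8, 46, 128)) < 0.2).astype(float)
        ms = benchmark_latency(m, batch, repetitions=2)
        assert np.isfinite(ms) and ms > 0
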