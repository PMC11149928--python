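"""SWR detection rules, per-event features, summaries and normalization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ripplepac import (
    ContractError,
    DetectionParams,
    RippleEvent,
    detect_events,
    event_features,
    merge_events,
    normalize_to_baseline,
    summarize_trial,
)
from conftest import random_z_envelope
from reference_detector import naive_detect

FS = 1000.0


def env(spans, n=1000, level=4.0):
    """Envelope with supra-threshold runs at the given sample spans."""
    z = np.zeros(n)
    for lo, hi in spans:
        z[lo:hi] = level
    return z


class TestDetectionRules:
    def test_all_zero_envelope_yields_nothing(self):
        assert detect_events(np.zeros(1000), fs=FS) == []

    def test_30ms_run_yields_one_event_with_exact_features(self):
        events = detect_events(env([(100, 130)]), fs=FS)
        assert len(events) == 1
        ev = events[0]
        assert ev.start_s == pytest.approx(0.100)
        assert ev.end_s == pytest.approx(0.130)
        assert ev.duration_ms == pytest.approx(30.0)
        assert ev.peak_z == 4.0
        assert ev.integral_z == pytest.approx(120.0)

    def test_10ms_run_below_minimum_duration(self):
        assert detect_events(env([(100, 110)]), fs=FS) == []

    def test_runs_10ms_apart_merge_into_one(self):
        events = detect_events(env([(100, 120), (130, 150)]), fs=FS)
        assert len(events) == 1
        assert events[0].start_s == pytest.approx(0.100)
        assert events[0].end_s == pytest.approx(0.150)

    def test_runs_20ms_apart_stay_separate(self):
        events = detect_events(env([(100, 120), (140, 160)]), fs=FS)
        assert len(events) == 2

    def test_exact_threshold_does_not_trigger(self):
        # 'exceeding three standard deviations' is strict
        z = np.zeros(1000)
        z[100:150] = 3.0
        assert detect_events(z, fs=FS) == []

    def test_sub15ms_pair_merging_above_minimum_counts(self):
        # two 10 ms runs, 10 ms apart: merged span 30 ms passes the filter
        events = detect_events(env([(100, 110), (120, 130)]), fs=FS)
        assert len(events) == 1
        assert events[0].duration_ms == pytest.approx(30.0)

    def test_boundary_extension_below_threshold(self):
        z = np.zeros(1000)
        z[95:100] = 2.0  # above boundary, below threshold
        z[100:130] = 4.0
        z[130:140] = 2.0
        params = DetectionParams(boundary_sd=1.0)
        events = detect_events(z, params, fs=FS)
        assert len(events) == 1
        assert events[0].start_s == pytest.approx(0.095)
        assert events[0].end_s == pytest.approx(0.140)

    def test_missing_fs_rejected(self):
        with pytest.raises(ContractError):
            detect_events(env([(100, 130)]))


class TestEventFeatures:
    def test_rectangle(self):
        ev = event_features(env([(0, 30)], level=5.0), (0, 30), fs=FS)
        assert ev.peak_z == 5.0
        assert ev.integral_z == pytest.approx(150.0)

    def test_triangular_ramp_exact_discrete_sum(self):
        ramp = np.concatenate([np.linspace(0, 6, 16), np.linspace(6, 0, 16)[1:]])
        ev = event_features(ramp, (0, 31), fs=FS)
        assert ev.peak_z == 6.0
        assert ev.integral_z == pytest.approx(math.fsum(ramp))

    def test_single_sample_interval(self):
        z = np.zeros(100)
        z[10] = 4.0
        ev = event_features(z, (10, 11), fs=FS)
        assert ev.duration_ms == pytest.approx(1.0)
        assert ev.integral_z == 4.0

    def test_empty_interval_rejected(self):
        with pytest.raises(ContractError):
            event_features(np.zeros(100), (10, 10), fs=FS)


class TestMerging:
    def test_empty(self):
        assert merge_events([], 15.0) == []

    def test_pair_within_gap(self):
        a = event_features(env([(0, 20)]), (0, 20), fs=FS)
        b = event_features(env([(30, 50)]), (30, 50), fs=FS)
        merged = merge_events([a, b], 15.0)
        assert len(merged) == 1
        assert merged[0].start_s == 0.0
        assert merged[0].end_s == pytest.approx(0.050)

    def test_transitive_chain(self):
        z = env([(0, 10), (20, 30), (40, 50)])
        events = [event_features(z, iv, fs=FS) for iv in [(0, 10), (20, 30), (40, 50)]]
        merged = merge_events(events, 15.0, z_env=z, fs=FS)
        assert len(merged) == 1
        assert merged[0].end_s == pytest.approx(0.050)

    def test_unsorted_rejected(self):
        z = env([(0, 20), (100, 120)])
        events = [event_features(z, iv, fs=FS) for iv in [(100, 120), (0, 20)]]
        with pytest.raises(ContractError):
            merge_events(events, 15.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_idempotent(self, seed):
        z = random_z_envelope(np.random.default_rng(seed), n_max=3000)
        events = detect_events(z, fs=FS)
        once = merge_events(events, 15.0, z_env=z, fs=FS)
        twice = merge_events(once, 15.0, z_env=z, fs=FS)
        assert once == twice


class TestMonotonicity:
    @pytest.mark.parametrize("seed", range(5))
    def test_raising_threshold_refines_detections(self, seed):
        # Raising the threshold shrinks the supra-threshold support, and
        # every event found at the higher threshold falls inside the support
        # of a lower-threshold detection.  (The raw event COUNT is not
        # monotone: lowering the threshold can bridge the valley between two
        # events and fuse them into one.)
        z = random_z_envelope(np.random.default_rng(seed), n_max=5000)
        supports = []
        for th in [2.0, 3.0, 4.0, 5.0]:
            events = detect_events(z, DetectionParams(threshold_sd=th), fs=FS)
            supports.append([(ev.start_s, ev.end_s) for ev in events])
            assert all(ev.peak_z > th for ev in events)
        for low, high in zip(supports, supports[1:]):
            for s, e in high:
                assert any(ls <= s and e <= le for ls, le in low)

    @pytest.mark.parametrize("seed", range(5))
    def test_raising_merge_gap_never_adds_events(self, seed):
        z = random_z_envelope(np.random.default_rng(seed), n_max=5000)
        counts = [
            len(detect_events(z, DetectionParams(merge_gap_ms=g), fs=FS))
            for g in [0.0, 5.0, 15.0, 50.0]
        ]
        assert counts == sorted(counts, reverse=True)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(50))
    def test_matches_naive_reference(self, seed):
        rng = np.random.default_rng(seed)
        z = random_z_envelope(rng, n_max=2000)
        params = DetectionParams(
            threshold_sd=3.0,
            min_duration_ms=float(rng.choice([5.0, 15.0, 25.0])),
            merge_gap_ms=float(rng.choice([0.0, 15.0, 30.0])),
            boundary_sd=float(rng.choice([1.0, 2.0, 3.0])),
        )
        fast = detect_events(z, params, fs=FS)
        slow = naive_detect(
            list(z),
            FS,
            threshold_sd=params.threshold_sd,
            min_duration_ms=params.min_duration_ms,
            merge_gap_ms=params.merge_gap_ms,
            boundary_sd=params.boundary_sd,
        )
        assert len(fast) == len(slow)
        for ev, (s, e, peak, integral) in zip(fast, slow):
            assert round(ev.start_s * FS) == s
            assert round(ev.end_s * FS) == e
            assert ev.peak_z == peak
            assert ev.integral_z == pytest.approx(integral, rel=1e-12)


class TestSummaries:
    def test_rate_uses_full_trial_duration(self):
        z = env([(i * 1000, i * 1000 + 30) for i in range(10)], n=300_000)
        events = detect_events(z, fs=FS)
        summary = summarize_trial(events, trial_duration_s=300.0)
        assert summary.n_events == 10
        assert summary.rate_hz == pytest.approx(10 / 300.0)

    def test_empty_trial_flagged(self):
        summary = summarize_trial([], trial_duration_s=180.0)
        assert summary.rate_hz == 0.0
        assert not summary.means_defined
        assert math.isnan(summary.mean_integral)

    def test_mean_integral(self):
        z = np.zeros(1000)
        z[100:120] = 5.0  # integral 100
        z[500:520] = 7.0  # integral 140
        events = detect_events(z, fs=FS)
        summary = summarize_trial(events, trial_duration_s=1.0)
        assert summary.mean_integral == pytest.approx(120.0)

    def test_normalization_identity(self):
        z = env([(100, 130)])
        s = summarize_trial(detect_events(z, fs=FS), 1.0)
        norm = normalize_to_baseline(s, s)
        for feature, value in norm.ratios.items():
            assert value == pytest.approx(1.0), feature

    def test_normalization_ratio(self):
        a = summarize_trial(detect_events(env([(100, 130), (500, 530)]), fs=FS), 1.0)
        b = summarize_trial(detect_events(env([(100, 130)]), fs=FS), 1.0)
        assert normalize_to_baseline(a, b)["rate_hz"] == pytest.approx(2.0)

    def test_zero_baseline_flagged_not_dropped(self):
        stim = summarize_trial(detect_events(env([(100, 130)]), fs=FS), 1.0)
        base = summarize_trial([], 1.0)
        norm = normalize_to_baseline(stim, base)
        assert math.isnan(norm["rate_hz"])
        assert "rate_hz" in norm.flagged

    def test_channel_mismatch_rejected(self):
        a = summarize_trial([], 1.0, channel_id="ch0")
        b = summarize_trial([], 1.0, channel_id="ch1")
        with pytest.raises(ContractError):
            normalize_to_baseline(a, b)
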