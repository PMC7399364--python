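"""Spike/burst/PSD feature extraction against constructed-signal oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dcnlearn import features as ft
from dcnlearn import sigproc
from dcnlearn import synthgen as sg

FS = 10000.0
WIN = ft.FeatureWindow(0.0, 1000.0)
ABS_THR = ft.ThresholdSpec(absolute_uV=5.0, wlen_ms=20.0)


def bump_trace(events, n=10000, half_width=20):
    """Triangular bumps of given (sample, height); prominence == height."""
    x = np.zeros(n)
    for center, height in events:
        for k in range(-half_width, half_width + 1):
            x[center + k] = max(x[center + k], height * (1 - abs(k) / half_width))
    return sigproc.TimeSeries(x, FS)


class TestDetectSpikes:
    def test_injected_prominences_recovered_exactly(self):
        x = bump_trace([(2000, 10.0), (5000, 20.0), (8000, 30.0)])
        events = ft.detect_spikes(x, WIN, ABS_THR)
        assert len(events) == 3
        assert np.mean([e.prominence for e in events]) == pytest.approx(20.0)

    def test_flat_trace_has_no_events(self):
        x = sigproc.TimeSeries(np.zeros(10000), FS)
        assert ft.detect_spikes(x, WIN, ABS_THR) == []

    def test_triangular_peak_width_is_half_base(self):
        # A symmetric triangle of base width w has half-prominence width w/2.
        half_width = 40  # base = 80 samples = 8 ms
        x = bump_trace([(5000, 10.0)], half_width=half_width)
        (event,) = ft.detect_spikes(x, WIN, ABS_THR)
        assert event.width == pytest.approx(half_width / FS * 1000.0, rel=0.05)

    def test_empty_window_rejected(self):
        x = sigproc.TimeSeries(np.zeros(10000), FS)
        with pytest.raises(ValueError):
            ft.detect_spikes(x, ft.FeatureWindow(0.0, 0.01), ABS_THR)

    def test_event_times_are_absolute_sample_indices(self):
        x = bump_trace([(6000, 15.0)])
        events = ft.detect_spikes(x, ft.FeatureWindow(500.0, 200.0), ABS_THR)
        assert [e.time for e in events] == [6000]


class TestHFFeatures:
    def test_rectified_constant_integral(self):
        x = sigproc.TimeSeries(np.full(10000, 4.0), FS)
        out = ft.hf_features(x, WIN, ABS_THR)
        assert out["hf_integral"] == pytest.approx(4.0 * 1.0)  # c * T

    def test_injected_spikes_count_and_amplitude(self):
        x = bump_trace([(2000, 10.0), (5000, 20.0), (8000, 30.0)])
        out = ft.hf_features(x, WIN, ABS_THR)
        assert out["hf_spike_count"] == 3
        assert out["hf_spike_amplitude"] == pytest.approx(20.0)

    def test_zero_trace_zero_features(self):
        x = sigproc.TimeSeries(np.zeros(10000), FS)
        out = ft.hf_features(x, WIN, ABS_THR)
        assert all(v == 0.0 for v in out.values())

    def test_added_spike_increments_count_and_integral(self):
        x1 = bump_trace([(2000, 10.0)])
        x2 = bump_trace([(2000, 10.0), (7000, 12.0)])
        o1 = ft.hf_features(x1, WIN, ABS_THR)
        o2 = ft.hf_features(x2, WIN, ABS_THR)
        assert o2["hf_spike_count"] == o1["hf_spike_count"] + 1
        assert o2["hf_integral"] > o1["hf_integral"]


class TestLFFeatures:
    # Bursts are ~40 ms wide, so the prominence locality window must
    # exceed the burst base width.
    BURST_THR = ft.ThresholdSpec(absolute_uV=4.0, wlen_ms=200.0)

    def test_two_burst_oracle(self):
        env = bump_trace([(3000, 5.0), (7000, 7.0)], half_width=200)
        out = ft.lf_features(env, WIN, self.BURST_THR)
        assert out["lf_burst_count"] == 2
        assert out["lf_max_burst_amplitude"] == pytest.approx(7.0)
        assert out["lf_mean_burst_amplitude"] == pytest.approx(6.0)
        assert out["lf_sum_burst_amplitudes"] == pytest.approx(12.0)

    def test_flat_envelope_zero_features(self):
        env = sigproc.TimeSeries(np.zeros(10000), FS)
        out = ft.lf_features(env, WIN, self.BURST_THR)
        assert all(v == 0.0 for v in out.values())

    def test_single_burst_sum_equals_max_equals_mean(self):
        env = bump_trace([(5000, 9.0)], half_width=200)
        out = ft.lf_features(env, WIN, self.BURST_THR)
        assert (
            out["lf_sum_burst_amplitudes"]
            == out["lf_max_burst_amplitude"]
            == out["lf_mean_burst_amplitude"]
        )


class TestPSDFeatures:
    def test_700_hz_tone_maximizes_600_1000_band(self, rng):
        t = np.arange(10000) / FS
        x = sigproc.TimeSeries(
            8.0 * np.sin(2 * np.pi * 700.0 * t) + rng.normal(0, 0.3, 10000), FS
        )
        out = ft.psd_features(x, WIN)
        hf_vals = [out[f] for f in ft.HF_PSD_FEATURES]
        assert int(np.argmax(hf_vals)) == 1

    def test_10_hz_oscillation_beats_40_80_band(self, rng):
        t = np.arange(10000) / FS
        x = sigproc.TimeSeries(
            5.0 * np.sin(2 * np.pi * 10.0 * t) + rng.normal(0, 0.3, 10000), FS
        )
        out = ft.psd_features(x, WIN)
        assert out["lf_psd_8_13"] > out["lf_psd_40_80"]

    def test_zero_trace_all_zero(self):
        out = ft.psd_features(sigproc.TimeSeries(np.zeros(10000), FS), WIN)
        assert len(out) == 13
        assert all(v < 1e-12 for v in out.values())

    def test_matches_band_peak_psd_per_band(self, rng):
        x = sigproc.TimeSeries(rng.normal(0, 1, 10000), FS)
        out = ft.psd_features(x, WIN)
        for name in ("hf_psd_200_600", "lf_psd_13_40"):
            lo, hi = (float(v) for v in name.split("_")[-2:])
            assert out[name] == pytest.approx(
                sigproc.band_peak_psd(x, WIN, (lo, hi)), rel=1e-9
            )


class TestBattery:
    def test_exactly_22_features_in_four_categories(self):
        assert len(ft.ALL_FEATURES) == 22
        sizes = {c: len(v) for c, v in ft.FEATURE_CATEGORIES.items()}
        assert sizes == {"HF": 4, "LF": 5, "HF_PSD": 8, "LF_PSD": 5}

    def test_full_battery_gives_154_columns(self):
        assert len(ft.feature_columns(ft.ALL_FEATURES)) == 154

    def test_single_feature_gives_7_columns(self):
        assert len(ft.feature_columns(["hf_spike_count"])) == 7


@pytest.fixture(scope="module")
def tiny_dataset():
    sched = sg.TrialSchedule(trials_per_set=1, sets=1)
    config = sg.GeneratorConfig.desk(schedule=sched)
    return sg.generate_animal(config, 0, 11)


class TestExtractFeatureTable:
    def test_full_battery_shape_and_density(self, tiny_dataset):
        table = ft.extract_feature_table(tiny_dataset, WIN)
        assert table.shape == (16, 5 + 154)
        assert not table.isna().any().any()

    def test_single_feature_has_7_columns(self, tiny_dataset):
        table = ft.extract_feature_table(tiny_dataset, WIN, ["hf_integral"])
        assert table.shape == (16, 5 + 7)

    def test_empty_subset_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="empty"):
            ft.extract_feature_table(tiny_dataset, WIN, [])

    def test_window_longer_than_trial_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="spans only"):
            ft.extract_feature_table(
                tiny_dataset, ft.FeatureWindow(0.0, 6000.0), ["hf_integral"]
            )

    def test_csv_round_trip(self, tiny_dataset, tmp_path):
        table = ft.extract_feature_table(tiny_dataset, WIN, ["hf_spike_count"])
        path = tmp_path / "features.csv"
        ft.write_feature_table(table, path)
        back = ft.read_feature_table(path)
        pd.testing.assert_frame_equal(table, back)

    def test_prefiltered_matches_direct(self, tiny_dataset):
        subset = ["hf_spike_count", "lf_burst_count", "hf_psd_200_600"]
        direct = ft.extract_feature_table(tiny_dataset, WIN, subset)
        cached = ft.extract_feature_table(
            ft.prefilter_dataset(tiny_dataset, subset), WIN, subset
        )
        pd.testing.assert_frame_equal(direct, cached)


class TestScaleEquivariance:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_amplitude_scales_counts_invariant(self, k):
        x = bump_trace([(2000, 10.0), (5000, 20.0), (8000, 30.0)])
        scaled = sigproc.TimeSeries(x.samples * k, FS)
        thr = ft.ThresholdSpec(absolute_uV=5.0 * k, wlen_ms=20.0)
        base = ft.hf_features(x, WIN, ABS_THR)
        out = ft.hf_features(scaled, WIN, thr)
        assert out["hf_spike_count"] == base["hf_spike_count"]
        assert out["hf_spike_amplitude"] == pytest.approx(
            k * base["hf_spike_amplitude"], rel=1e-9
        )
        assert out["hf_integral"] == pytest.approx(k * base["hf_integral"], rel=1e-9)

    def test_psd_scales_quadratically(self, rng):
        x = sigproc.TimeSeries(rng.normal(0, 1, 10000), FS)
        k = 3.0
        scaled = sigproc.TimeSeries(x.samples * k, FS)
        a = ft.psd_features(x, WIN)
        b = ft.psd_features(scaled, WIN)
        for name in ft.HF_PSD_FEATURES:
            assert b[name] == pytest.approx(k**2 * a[name], rel=1e-9)


class TestWindowContainment:
    def test_windowed_features_equal_sliced_trace(self):
        # Features from window W of a long trace equal features from the
        # standalone slice (detection is purely local to the window).
        rng = np.random.default_rng(3)
        long = bump_trace([(2500, 12.0), (3500, 25.0)], n=20000)
        noisy = sigproc.TimeSeries(long.samples + rng.normal(0, 0.1, 20000), FS)
        w = ft.FeatureWindow(200.0, 400.0)  # samples 2000..6000
        sliced = sigproc.TimeSeries(noisy.samples[2000:6000], FS)
        full_w = ft.FeatureWindow(0.0, 400.0)
        a = ft.hf_features(noisy, w, ABS_THR)
        b = ft.hf_features(sliced, full_w, ABS_THR)
        for key in a:
            assert a[key] == pytest.approx(b[key], rel=1e-6)
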