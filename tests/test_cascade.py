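import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glowcurve_qc.cascade import (
    RuleCascadeClassifier,
    classify,
    classify_class_a,
    classify_class_b,
    classify_class_c,
    classify_class_d,
    detect_spikes,
    smoothen,
)
from glowcurve_qc.datamodel import EXCLUSIVE_LABELS, GlowCurve, Label, PipelineConfig
from glowcurve_qc.simulate import AnomalySpec, inject_anomaly

from _oracles import spike_scan_bruteforce
from conftest import flat_curve


class TestDetectSpikes:
    def test_flat_curve_has_no_spikes(self):
        assert detect_spikes(GlowCurve(flat_curve()), 50).count == 0

    def test_single_channel_spike(self):
        report = detect_spikes(GlowCurve(flat_curve(overrides={50: 200})), 50)
        assert report.positions == (49,)
        assert report.channels == (50,)

    def test_two_channel_spike_counts_once(self):
        report = detect_spikes(GlowCurve(flat_curve(overrides={50: 200, 51: 200})), 50)
        assert report.positions == (49,)
        assert set(report.channels) == {50, 51}

    def test_positions_strictly_increasing_in_range(self):
        rng = np.random.default_rng(5)
        report = detect_spikes(GlowCurve(rng.uniform(1, 100, 200)), 50)
        pos = np.array(report.raw_positions)
        assert np.all(np.diff(pos) > 0)
        assert pos.size == 0 or (pos.min() >= 1 and pos.max() <= 197)

    def test_matches_bruteforce_scan_on_random_curves(self):
        rng = np.random.default_rng(17)
        for k in range(1000):
            if k % 2:
                y = rng.uniform(0, 100, 200)
            else:
                y = 50 + 40 * np.sin(np.arange(200) / rng.uniform(2, 20)) + rng.normal(0, 10, 200)
                y = np.clip(y, 0, None)
            s = float(rng.uniform(5, 100))
            assert list(detect_spikes(GlowCurve(y), s).raw_positions) == spike_scan_bruteforce(y, s)


class TestClassD:
    @pytest.mark.parametrize("count, n_spikes, expected", [(4, 3, True), (3, 3, False), (0, 3, False)])
    def test_strictly_more_than_nspikes(self, count, n_spikes, expected):
        y = flat_curve()
        for c in range(20, 20 + 5 * count, 5):
            y[c - 1] = 500
        report = detect_spikes(GlowCurve(y), 50)
        assert report.count == count
        assert classify_class_d(report, n_spikes) is expected


class TestSmoothen:
    def test_spike_free_curve_is_identity(self):
        gc = GlowCurve(flat_curve())
        assert smoothen(gc, detect_spikes(gc, 50)) == gc

    def test_single_spike_interpolated(self):
        gc = GlowCurve(flat_curve(overrides={50: 200}))
        sm = smoothen(gc, detect_spikes(gc, 50))
        assert sm.ch(50) == 100.0
        mask = np.ones(200, bool)
        mask[49] = False
        assert np.array_equal(sm.channels[mask], gc.channels[mask])

    def test_two_channel_spike_interpolated(self):
        gc = GlowCurve(flat_curve(overrides={50: 200, 51: 200}))
        sm = smoothen(gc, detect_spikes(gc, 50))
        assert sm.ch(50) == 100.0 and sm.ch(51) == 100.0

    def test_idempotent_when_fully_removed(self):
        rng = np.random.default_rng(3)
        y = 100 + 10 * rng.standard_normal(200)
        for c in (40, 90, 150):
            y[c - 1] = 400
        gc = GlowCurve(np.clip(y, 0, None))
        once = smoothen(gc, detect_spikes(gc, 50))
        twice = smoothen(once, detect_spikes(once, 50))
        assert twice == once


def peak_curve(center=95, height=1000.0, low_avg=0.0, high_avg=0.0, width=3):
    """Construction helper: localized peak plus flat pedestals in the
    default class-A windows (1..40 low, 160..200 high)."""
    y = np.zeros(200)
    y[center - width - 1 : center + width] = height / 2
    y[center - 1] = height
    y[0:40] += low_avg
    y[159:200] += high_avg
    return GlowCurve(y)


class TestClassA:
    CFG = PipelineConfig(MinBgdHeight=10, MaxBgdHeight=50)

    def test_high_window_in_band_is_a_high(self):
        gc = peak_curve(high_avg=150)  # 100 < 150 < 500
        assert classify_class_a(gc, self.CFG) == frozenset({Label.A_HIGH})

    def test_both_windows_in_band_is_dual_a(self):
        gc = peak_curve(low_avg=150, high_avg=150)
        assert classify_class_a(gc, self.CFG) == frozenset({Label.A_LOW, Label.A_HIGH})

    def test_peak_out_of_place_gives_none(self):
        gc = peak_curve(center=120, high_avg=150)
        assert classify_class_a(gc, self.CFG) == frozenset()

    def test_band_bounds_are_strict(self):
        assert classify_class_a(peak_curve(high_avg=100), self.CFG) == frozenset()  # == min bound
        assert classify_class_a(peak_curve(high_avg=500), self.CFG) == frozenset()  # == max bound


class TestClassC:
    @pytest.mark.parametrize("center, expected", [(120, Label.C_HIGH), (70, Label.C_LOW), (95, None), (105, None), (85, None)])
    def test_shift_classification(self, center, expected):
        assert classify_class_c(peak_curve(center=center), 10) is expected


class TestClassB:
    def test_rectangular_curve_is_wide(self, config):
        # near-constant plateau with its maximum at channel 95: the window
        # average is essentially the maximum, far above WideAvgVal
        gc = GlowCurve(flat_curve(100.0, overrides={95: 101}))
        assert classify_class_b(gc, config) is Label.B_WIDE

    def test_near_delta_curve_is_narrow(self, config):
        y = np.zeros(200)
        y[94] = 1000.0
        y[93] = y[95] = 400.0
        assert classify_class_b(GlowCurve(y), config) is Label.B_NARROW

    def test_default_normal_curve_is_neither(self, noiseless_normal, config):
        assert classify_class_b(noiseless_normal, config) is None

    def test_peak_out_of_place_gives_none(self, config):
        y = np.zeros(200)
        y[119] = 1000.0
        assert classify_class_b(GlowCurve(y), config) is None


class TestCascade:
    def test_spikes_preempt_shifted_peak(self, config):
        y = np.zeros(200)
        y[119] = 1000.0  # shifted peak
        y[118] = y[120] = 300.0
        for c in (30, 40, 50, 60, 70):
            y[c - 1] = 200.0  # 5 isolated spikes on zero baseline
        res = classify(GlowCurve(y), config)
        assert res.labels == frozenset({Label.D})

    def test_unclassifiable_curve_falls_to_e(self, noiseless_normal, config):
        res = classify(noiseless_normal, config)
        assert res.labels == frozenset({Label.E})

    def test_injected_a_low_recovered(self, noiseless_normal, config):
        gc = inject_anomaly(noiseless_normal, AnomalySpec(label=Label.A_LOW), seed=0)
        assert classify(gc, config).labels == frozenset({Label.A_LOW})

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_exclusivity_on_random_curves(self, seed):
        rng = np.random.default_rng(seed)
        y = np.clip(rng.normal(50, 30, 200), 0, None)
        labels = classify(GlowCurve(y), PipelineConfig()).labels
        assert len(labels & EXCLUSIVE_LABELS) <= 1
        if labels & EXCLUSIVE_LABELS:
            assert not labels - EXCLUSIVE_LABELS


class TestRuleCascadeClassifier:
    def test_fit_validates_config(self):
        clf = RuleCascadeClassifier(PipelineConfig(MinBgdHeight=90, MaxBgdHeight=50))
        with pytest.raises(ValueError, match="MinBgdHeight"):
            clf.fit()

    def test_predict_maps_curves_to_labels(self, noiseless_normal, config):
        clf = RuleCascadeClassifier(config).fit()
        curves = [
            inject_anomaly(noiseless_normal, AnomalySpec(label=Label.C_HIGH), seed=0),
            inject_anomaly(noiseless_normal, AnomalySpec(label=Label.D), seed=0),
        ]
        assert list(clf.predict(curves)) == ["C_HIGH", "D"]

    def test_sklearn_param_interface(self):
        clf = RuleCascadeClassifier()
        params = clf.get_params()
        assert "config" in params
        clf.set_params(config=PipelineConfig(NSpikes=5))
        assert clf.config.NSpikes == 5
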