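"""Breathing metrics: segmentation, tidal volume, excursion, errors, tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from respiromech import (
    BreathSegmentation,
    amplitude_error,
    displacement_volume_correlation,
    excursions,
    normalize_cycles,
    nrmse,
    paired_ratio_test,
    segment_breaths,
    tidal_volumes,
)


class TestSegmentation:
    def test_sinusoid_flow_boundaries_spaced_one_period(self):
        T, fs = 4.0, 100.0
        t = np.arange(0, 20, 1 / fs)
        seg = segment_breaths(np.sin(2 * np.pi * t / T), "flow", 1 / fs, T)
        spacing = np.diff(seg.boundaries)
        assert np.all(np.abs(spacing - T * fs) <= 1)

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError, match="no complete cycle"):
            segment_breaths(np.ones(500), "flow", 0.01, 4.0)

    def test_invariant_to_noise_below_hysteresis_band(self):
        T, fs = 4.0, 100.0
        t = np.arange(0, 20, 1 / fs)
        clean = np.sin(2 * np.pi * t / T)
        rng = np.random.default_rng(0)
        noisy = clean + rng.uniform(-0.005, 0.005, t.size)  # band is +/-0.02
        a = segment_breaths(clean, "flow", 1 / fs, T)
        b = segment_breaths(noisy, "flow", 1 / fs, T)
        assert a.boundaries.size == b.boundaries.size
        assert np.max(np.abs(a.boundaries - b.boundaries)) <= 1

    def test_displacement_minima_segmentation(self):
        T, fs = 5.0, 50.0
        t = np.arange(0, 25, 1 / fs)
        seg = segment_breaths(-np.cos(2 * np.pi * t / T), "displacement", 1 / fs, T)
        spacing = np.diff(seg.boundaries)
        assert np.all(np.abs(spacing - T * fs) <= 2)

    def test_segmentation_requires_increasing_boundaries(self):
        with pytest.raises(ValueError):
            BreathSegmentation(np.array([10, 5]))


class TestTidalVolume:
    def test_zero_flow_gives_zero(self):
        seg = BreathSegmentation(np.array([0, 100, 200]))
        vt = tidal_volumes(np.zeros(201), seg, 0.01)
        np.testing.assert_array_equal(vt, [0.0, 0.0])

    def test_half_sine_inspiration_closed_form(self):
        A, tau, fs = 0.5, 1.5, 200.0
        t = np.arange(0, 4.0, 1 / fs)
        flow = np.where(t < tau, A * np.sin(np.pi * t / tau), -0.1)
        seg = BreathSegmentation(np.array([0, t.size - 1]))
        vt = tidal_volumes(flow, seg, 1 / fs)
        assert vt[0] == pytest.approx(2 * A * tau / np.pi, rel=1e-3)

    def test_bad_dt_rejected(self):
        with pytest.raises(ValueError):
            tidal_volumes(np.zeros(10), BreathSegmentation(np.array([0, 5])), 0.0)


class TestExcursion:
    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        trace = rng.normal(size=300)
        seg = BreathSegmentation(np.array([0, 150, 299]))
        np.testing.assert_allclose(excursions(trace, seg), excursions(trace + 5.0, seg))


class TestNormalizeCycles:
    def test_identical_cycles_average_to_one_cycle(self):
        cycle = np.sin(2 * np.pi * np.arange(100) / 100)
        trace = np.tile(cycle, 4)
        seg = BreathSegmentation(np.array([0, 100, 200, 300]))
        avg = normalize_cycles(trace, seg)
        single = np.interp(np.arange(20) / 20 * 100, np.arange(400), trace)
        assert avg.shape == (20,)
        np.testing.assert_allclose(avg, single, atol=1e-12)

    def test_antiphase_cycles_cancel(self):
        cycle = np.sin(2 * np.pi * np.arange(80) / 80)
        trace = np.concatenate([cycle, -cycle])
        seg = BreathSegmentation(np.array([0, 80, 160]))
        avg = normalize_cycles(trace, seg, n_points=20, n_cycles=2)
        np.testing.assert_allclose(avg, 0.0, atol=1e-9)

    def test_too_few_cycles_rejected(self):
        seg = BreathSegmentation(np.array([0, 50]))
        with pytest.raises(ValueError):
            normalize_cycles(np.zeros(51), seg, n_cycles=3)


class TestErrorMeasures:
    def test_amplitude_error_examples(self):
        assert amplitude_error(1.0, 1.0) == 0.0
        assert amplitude_error(1.07, 1.0) == pytest.approx(7.0)
        assert amplitude_error(0.93, 1.0) == pytest.approx(amplitude_error(1.07, 1.0))
        with pytest.raises(ValueError):
            amplitude_error(1.0, 0.0)

    def test_nrmse_identical_and_offset(self):
        obs = np.sin(np.linspace(0, 6, 200))
        assert nrmse(obs, obs) == 0.0
        assert nrmse(obs + 0.1, obs) == pytest.approx(100 * 0.1 / np.ptp(obs))

    @given(k=st.floats(0.1, 100.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_nrmse_scale_invariance(self, k):
        obs = np.sin(np.linspace(0, 6, 100))
        sim = obs + 0.05 * np.cos(np.linspace(0, 6, 100))
        assert nrmse(k * sim, k * obs) == pytest.approx(nrmse(sim, obs), rel=1e-9)

    def test_nrmse_flat_observation_rejected(self):
        with pytest.raises(ValueError):
            nrmse(np.zeros(10), np.ones(10))


class TestCorrelation:
    def test_proportional_pairs(self):
        pairs = [(x, 2.5 * x) for x in (1.0, 2.0, 3.0, 4.0)]
        assert displacement_volume_correlation(pairs)["r"] == pytest.approx(1.0)

    def test_linear_model_monte_carlo(self):
        rng = np.random.default_rng(0)
        exc = rng.uniform(1.0, 4.0, 100)
        vt = 0.7 * exc + rng.normal(0, 0.2, 100)
        res = displacement_volume_correlation(np.column_stack([exc, vt]))
        assert res["r"] > 0.9 and res["p"] < 1e-6

    def test_coordinate_swap_symmetry(self):
        rng = np.random.default_rng(2)
        pairs = rng.normal(size=(10, 2))
        a = displacement_volume_correlation(pairs)
        b = displacement_volume_correlation(pairs[:, ::-1])
        assert a["r"] == pytest.approx(b["r"])

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            displacement_volume_correlation([(1, 2), (3, 4)])
        with pytest.raises(ValueError):
            displacement_volume_correlation([(1, 2), (1, 3), (1, 4)])


class TestPairedComparison:
    def test_exact_doubling(self):
        spont = np.array([1.0, 1.2, 0.9, 1.1])
        res = paired_ratio_test(spont, 2 * spont)
        assert res.ratio_means == pytest.approx(2.0)
        assert res.mean_of_ratios == pytest.approx(2.0)
        assert res.p_value < 0.2  # n=4 limits attainable significance

    def test_null_case(self):
        x = np.array([1.0, 2.0, 3.0])
        res = paired_ratio_test(x, x)
        assert res.ratio_means == pytest.approx(1.0)
        assert res.p_value == 1.0

    def test_cohort_of_eight_reaches_significance(self):
        spont = np.linspace(0.8, 1.5, 8)
        res = paired_ratio_test(spont, spont * 1.9)
        assert res.p_value < 0.05

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_ratio_test([1.0, 2.0], [1.0])


class TestSamplingRateInvariance:
    def test_measures_agree_between_50_and_200_hz(self):
        T = 4.0
        for fs_pair in ((50.0, 200.0),):
            results = []
            for fs in fs_pair:
                t = np.arange(0, 5 * T, 1 / fs)
                disp = 1.2 * np.sin(np.pi * t / T) ** 2
                flow = 0.6 * np.sin(2 * np.pi * t / T)
                seg_d = segment_breaths(disp, "displacement", 1 / fs, T)
                seg_f = segment_breaths(flow, "flow", 1 / fs, T)
                results.append(
                    (np.mean(excursions(disp, seg_d)),
                     np.mean(tidal_volumes(flow, seg_f, 1 / fs)))
                )
            (e50, v50), (e200, v200) = results
            assert e50 == pytest.approx(e200, rel=0.01)
            assert v50 == pytest.approx(v200, rel=0.01)
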