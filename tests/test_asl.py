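"""Perfusion quantification: difference maps, calibration, SNR, QC metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wmperf.asl import (
    ASLKineticParams,
    ASLTimeSeries,
    calibrate_m0,
    cbf_scale,
    cbf_variance,
    kinetic_factor,
    mean_relative_displacement,
    pairwise_differences,
    qc_exclude_low_gm_cbf,
    quantify_cbf,
    roi_snr,
    significant_signal,
    snr_map,
)
from wmperf.image import ImageVolume


def _series(control, label, **kw):
    """Build a 1-voxel time series from lists of control/label values."""
    vols = np.empty((1, 1, 1, 2 * len(control)))
    vols[0, 0, 0, 0::2] = control
    vols[0, 0, 0, 1::2] = label
    return ASLTimeSeries(vols, **kw)


class TestPairwiseDifferences:
    def test_two_point_mean_and_variance(self):
        ts = _series([10.0, 10.0], [7.0, 5.0])  # differences 3, 5
        dm, dvar, n = pairwise_differences(ts)
        assert n == 2
        assert dm.data[0, 0, 0] == 4.0
        assert dvar.data[0, 0, 0] == 2.0

    def test_constant_series_is_zero(self):
        ts = _series([5.0] * 4, [5.0] * 4)
        dm, dvar, _ = pairwise_differences(ts)
        assert np.all(dm.data == 0) and np.all(dvar.data == 0)

    def test_matches_bruteforce_loop(self, rng):
        vols = rng.normal(size=(4, 3, 2, 10))
        ts = ASLTimeSeries(vols)
        dm, dvar, n = pairwise_differences(ts)
        diffs = np.stack([vols[..., 2 * i] - vols[..., 2 * i + 1] for i in range(5)], -1)
        assert np.allclose(dm.data, diffs.mean(axis=-1), atol=1e-12)
        assert np.allclose(dvar.data, diffs.var(axis=-1, ddof=1), atol=1e-12)

    def test_single_pair_variance_undefined(self):
        with pytest.raises(ValueError):
            pairwise_differences(_series([1.0], [0.0]))


class TestM0Calibration:
    def test_uniform_map_linear_in_factor(self):
        m0 = ImageVolume(np.full((4, 4, 4), 250.0))
        mask = np.zeros((4, 4, 4), bool)
        mask[1:3, 1:3, 1:3] = True
        assert calibrate_m0(m0, mask, conversion_factor=2.0) == pytest.approx(500.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            calibrate_m0(ImageVolume(np.ones((4, 4, 4))), np.zeros((4, 4, 4), bool))

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            calibrate_m0(ImageVolume(np.zeros((4, 4, 4))), np.ones((4, 4, 4), bool))


class TestKineticModel:
    def test_scale_factor_matches_two_exponential_evaluation(self):
        # independent evaluation of 1/(e^{-1100/1650} - e^{-2820/1650})
        want = 1.0 / (math.exp(-1100.0 / 1650.0) - math.exp(-2820.0 / 1650.0))
        assert abs(kinetic_factor(ASLKineticParams()) - want) < 1e-12
        assert abs(want - 3.0085) < 1e-3

    def test_factor_increases_with_delay(self):
        p = ASLKineticParams()
        vals = [kinetic_factor(p, s) for s in range(5)]  # +45 ms per slice
        assert np.all(np.diff(vals) > 0)

    @given(
        t1b=st.floats(500, 3000),
        tau=st.floats(200, 4000),
        omega=st.floats(200, 4000),
    )
    @settings(max_examples=100, deadline=None)
    def test_factor_finite_positive(self, t1b, tau, omega):
        p = ASLKineticParams(t1_blood_ms=t1b, tau_ms=tau, omega_ms=omega)
        k = kinetic_factor(p)
        assert np.isfinite(k) and k > 0

    def test_zero_delta_m_gives_zero_cbf(self):
        dm = ImageVolume(np.zeros((3, 3, 3)))
        cbf = quantify_cbf(dm, 1000.0, ASLKineticParams())
        assert np.all(cbf.data == 0)

    def test_linearity_in_delta_m_and_inverse_m0(self, rng):
        dm = ImageVolume(rng.normal(size=(4, 4, 4)))
        p = ASLKineticParams()
        c1 = quantify_cbf(dm, 1000.0, p).data
        c2 = quantify_cbf(dm.copy_with(3.0 * dm.data), 1000.0, p).data
        c3 = quantify_cbf(dm, 2000.0, p).data
        assert np.allclose(c2, 3.0 * c1, atol=1e-12)
        assert np.allclose(c3, 0.5 * c1, atol=1e-12)

    def test_slice_dependent_delay_applied(self):
        dm = ImageVolume(np.ones((2, 2, 3)))
        p = ASLKineticParams(slice_time_increment_ms=45.0)
        cbf = quantify_cbf(dm, 1000.0, p, slice_axis=2)
        for z in range(3):
            expected = cbf_scale(p, 1000.0, z)
            assert np.allclose(cbf.data[..., z], expected)


class TestVarianceAndSNR:
    def test_zero_variance_propagates_to_zero(self):
        v = ImageVolume(np.zeros((3, 3, 3)))
        out = cbf_variance(v, 10, 1000.0, ASLKineticParams())
        assert np.all(out.data == 0)

    def test_quadratic_scaling_in_m0(self, rng):
        v = ImageVolume(rng.uniform(0.1, 2.0, size=(4, 4, 4)))
        p = ASLKineticParams()
        a = cbf_variance(v, 10, 1000.0, p).data
        b = cbf_variance(v, 10, 2000.0, p).data
        assert np.allclose(b, a / 4.0, atol=1e-12)

    def test_monte_carlo_sd_matches_delta_method(self, rng):
        p = ASLKineticParams()
        m0, sigma, n_draws = 1000.0, 2.5, 10000
        dm_true = 3.0
        draws = dm_true + rng.normal(scale=sigma, size=n_draws)
        cbf_draws = [
            quantify_cbf(ImageVolume(np.full((1, 1, 1), d)), m0, p).data[0, 0, 0]
            for d in draws[:200]
        ]
        # vectorized equivalent for the full sample
        scale = cbf_scale(p, m0, 0)
        cbf_all = scale * draws
        predicted = np.sqrt(
            cbf_variance(ImageVolume(np.full((1, 1, 1), sigma**2)), 1, m0, p).data[0, 0, 0]
        )
        assert abs(np.std(cbf_all) - predicted) / predicted < 0.03
        assert np.allclose(cbf_draws, cbf_all[:200], atol=1e-9)

    def test_snr_reference_value(self):
        cbf = ImageVolume(np.full((2, 2, 2), 20.0))
        var = ImageVolume(np.full((2, 2, 2), 100.0))
        snr = snr_map(cbf, var, n_pairs=100)
        assert np.allclose(snr.data, 20.0)

    def test_snr_scales_with_sqrt_pairs(self):
        cbf = ImageVolume(np.full((2, 2, 2), 20.0))
        var = ImageVolume(np.full((2, 2, 2), 100.0))
        a = snr_map(cbf, var, 50).data
        b = snr_map(cbf, var, 200).data
        assert np.allclose(b, 2.0 * a)

    def test_infinite_snr_excluded_from_roi_mean(self):
        cbf = ImageVolume(np.array([[[20.0, 10.0]]]))
        var = ImageVolume(np.array([[[0.0, 25.0]]]))
        snr = snr_map(cbf, var, 4)
        assert np.isinf(snr.data[0, 0, 0])
        assert roi_snr(snr, np.ones((1, 1, 2), bool)) == pytest.approx(4.0)

    def test_wm_snr_below_gm_snr_on_synthetic_subject(self, anatomy):
        from wmperf.pipeline import PipelineConfig, run_cohort_analysis
        from wmperf.synthetic import CohortConfig

        cfg = PipelineConfig(
            cohort=CohortConfig(n_subjects=3, seed=4), seed=4,
        )
        ana = run_cohort_analysis(cfg, upto="quantify")
        gm = ana.masks.gm_mask.data.astype(bool)
        wm = ana.masks.wm_mask.data.astype(bool)
        snr = ana.perfusion[0]["snr"]
        assert roi_snr(snr, wm) < roi_snr(snr, gm)


class TestSignificantSignal:
    def test_noiseless_positive_signal_fully_detected(self):
        vols = np.zeros((2, 2, 2, 12))
        vols[..., 0::2] = 10.0
        vols[..., 1::2] = 8.0
        ts = ASLTimeSeries(vols)
        _, frac = significant_signal(ts, np.ones((2, 2, 2), bool), n_perm=200, seed=0)
        assert frac == 1.0

    def test_null_attains_nominal_level(self, rng):
        vols = rng.normal(size=(16, 16, 8, 40))
        ts = ASLTimeSeries(vols)
        _, frac = significant_signal(
            ts, np.ones((16, 16, 8), bool), alpha=0.05, n_perm=499, seed=7
        )
        assert abs(frac - 0.05) < 0.02

    def test_fraction_grows_with_averages(self, anatomy):
        from wmperf.synthetic import CohortConfig, build_true_cbf, make_asl_timeseries, make_cohort

        cfg = CohortConfig(n_subjects=3, noise_sd_asl=8.0, seed=6)
        subs, _ = make_cohort(anatomy, cfg)
        s = subs[0]
        build_true_cbf(anatomy, s, cfg)
        wm = anatomy.pve_wm.data >= 0.7
        fracs = []
        for n_pairs in (50, 200):
            s.n_pairs = n_pairs
            s.motion_trace = None
            ts = make_asl_timeseries(anatomy, s, ASLKineticParams(), cfg, seed=31)
            _, frac = significant_signal(ts, wm, n_perm=300, seed=8)
            fracs.append(frac)
        assert fracs[1] >= fracs[0]

    def test_empty_mask_rejected(self):
        ts = ASLTimeSeries(np.zeros((2, 2, 2, 12)))
        with pytest.raises(ValueError):
            significant_signal(ts, np.zeros((2, 2, 2), bool))


class TestMotionAndQC:
    def test_zero_trace_gives_zero_mrd(self):
        assert mean_relative_displacement(np.zeros((10, 6))) == 0.0

    def test_single_axis_translation_jump(self):
        trace = np.zeros((2, 6))
        trace[1, 0] = 3.0
        assert mean_relative_displacement(trace) == pytest.approx(3.0)

    def test_matches_independent_recomputation(self, rng):
        trace = np.cumsum(rng.normal(scale=0.05, size=(30, 6)), axis=0)
        got = mean_relative_displacement(trace, rotation_radius_mm=50.0)
        # scripted recomputation
        steps = []
        for t in range(1, 30):
            d = trace[t] - trace[t - 1]
            steps.append(
                math.sqrt(
                    d[0] ** 2 + d[1] ** 2 + d[2] ** 2
                    + (50 * d[3]) ** 2 + (50 * d[4]) ** 2 + (50 * d[5]) ** 2
                )
            )
        assert abs(got - np.mean(steps)) < 1e-12

    def test_exclusion_is_strictly_below_threshold(self):
        kept, excl = qc_exclude_low_gm_cbf({"a": 37.9, "b": 38.0, "c": 50.0})
        assert excl == ["a"] and set(kept) == {"b", "c"}

    def test_no_exclusion_when_all_pass(self):
        kept, excl = qc_exclude_low_gm_cbf({"a": 38.0, "b": 60.0})
        assert excl == [] and len(kept) == 2

    def test_planted_low_perfusion_subjects_detected(self, anatomy):
        from wmperf.pipeline import PipelineConfig, run_cohort_analysis
        from wmperf.synthetic import CohortConfig

        cfg = PipelineConfig(
            cohort=CohortConfig(n_subjects=12, n_low_gm_cbf=3, seed=8), seed=8,
        )
        ana = run_cohort_analysis(cfg, upto="quantify")
        excluded = set(ana.qc[ana.qc.excluded].subject_id)
        planted = {s.subject_id for i, s in enumerate(ana.subjects) if i < 3}
        assert excluded == planted
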