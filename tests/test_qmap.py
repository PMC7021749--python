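"""T1 / ADC fitting and the pCASL perfusion model, against independent oracles."""

import numpy as np
import pytest

from renalquant import (ASLConstants, ASLSet, DWISeries, MOLLISeries,
                        TissueParams, fit_adc_map, fit_t1_map,
                        forward_asl_signal, perfusion_map, simulate_asl_set,
                        simulate_dwi_series, simulate_molli_series)
from renalquant.phantom import CORTEX, MEDULLA, PELVIS, ground_truth_map
from renalquant.qmap import DEFAULT_B_VALUES, DEFAULT_TI_MS

from _oracles import grid_search_t1, loglinear_adc

COMPARTMENTS = (CORTEX, MEDULLA, PELVIS)


def _series_from_voxels(signals, schedule, kind="molli"):
    """Wrap per-voxel signal rows (n_vox, n_frames) as a 1-voxel-thick series."""
    arr = np.asarray(signals, float).T[:, None, None, :]  # (frames,1,1,nvox)
    if kind == "molli":
        return MOLLISeries(frames=arr, ti_ms=schedule, spacing=(1, 1, 1))
    return DWISeries(frames=arr, b_s_per_mm2=schedule, spacing=(1, 1, 1))


class TestT1Fit:
    def test_look_locker_identity_when_b_twice_a(self):
        ti = np.asarray(DEFAULT_TI_MS)
        s = 100.0 - 200.0 * np.exp(-ti / 800.0)
        pmap = fit_t1_map(_series_from_voxels([s], DEFAULT_TI_MS))
        assert pmap.values[0, 0, 0] == pytest.approx(800.0, rel=1e-6)
        assert pmap.units == "ms"

    def test_noiseless_phantom_recovery_all_compartments(self, labelmap, tissue):
        series = simulate_molli_series(labelmap, tissue, noise_sd=0)
        pmap = fit_t1_map(series)
        truth = ground_truth_map(labelmap, tissue, "t1_ms")
        for lab in COMPARTMENTS:
            sel = labelmap.labels == lab
            err = np.abs(pmap.values[sel] - truth[sel]) / truth[sel]
            assert np.nanmax(err) < 0.005

    def test_agrees_with_grid_search_oracle(self):
        rng = np.random.default_rng(11)
        ti = np.asarray(DEFAULT_TI_MS)
        rows = []
        for _ in range(10):
            a = rng.uniform(500, 1500)
            b = 2.0 * a
            t1s = rng.uniform(800, 2800)
            rows.append(a - b * np.exp(-ti / t1s))
        pmap = fit_t1_map(_series_from_voxels(rows, DEFAULT_TI_MS))
        for i, s in enumerate(rows):
            *_, t1_oracle = grid_search_t1(ti, s)
            fitted = pmap.values[0, 0, i]
            assert abs(fitted - t1_oracle) / t1_oracle < 1e-3

    def test_median_error_under_noise(self):
        rng = np.random.default_rng(7)
        ti = np.asarray(DEFAULT_TI_MS)
        a, t1 = 1000.0, 1600.0
        clean = a - 2 * a * np.exp(-ti / t1)
        noisy = clean + rng.normal(0, 0.02 * a, size=(500, len(ti)))
        pmap = fit_t1_map(_series_from_voxels(noisy, DEFAULT_TI_MS))
        errs = np.abs(pmap.values[0, 0, :] - t1) / t1
        assert np.nanmedian(errs) < 0.03

    def test_all_zero_voxel_flagged_not_raised(self):
        rows = [np.zeros(len(DEFAULT_TI_MS)),
                1000 - 2000 * np.exp(-np.asarray(DEFAULT_TI_MS) / 1500.0)]
        pmap = fit_t1_map(_series_from_voxels(rows, DEFAULT_TI_MS),
                          mask=np.ones((1, 1, 2), bool))
        assert np.isnan(pmap.values[0, 0, 0])
        assert pmap.values[0, 0, 1] == pytest.approx(1500.0, rel=1e-6)
        assert pmap.info["n_failed"] == 1


class TestADCFit:
    def test_two_point_exact_solution(self):
        s = np.array([[1000.0, 1000.0 * np.exp(-1.7)]])
        pmap = fit_adc_map(_series_from_voxels(s, (0.0, 1000.0), kind="dwi"))
        assert pmap.values[0, 0, 0] * 1e6 == pytest.approx(1700.0, rel=1e-9)
        assert pmap.units == "mm^2/s"

    def test_constant_signal_lands_on_zero_boundary(self):
        s = np.full((1, len(DEFAULT_B_VALUES)), 500.0)
        pmap = fit_adc_map(_series_from_voxels(s, DEFAULT_B_VALUES, kind="dwi"))
        assert pmap.values[0, 0, 0] == 0.0
        assert pmap.info["n_boundary"] == 1

    def test_noiseless_phantom_recovery(self, labelmap, tissue):
        series = simulate_dwi_series(labelmap, tissue, noise_sd=0)
        pmap = fit_adc_map(series)
        truth = ground_truth_map(labelmap, tissue, "adc_mm2_per_s")
        for lab in COMPARTMENTS:
            sel = labelmap.labels == lab
            err = np.abs(pmap.values[sel] - truth[sel]) / truth[sel]
            assert np.nanmax(err) < 1e-6

    def test_agrees_with_loglinear_oracle(self):
        rng = np.random.default_rng(5)
        b = np.asarray(DEFAULT_B_VALUES)
        rows = [rng.uniform(500, 1500) * np.exp(-b * rng.uniform(1e-3, 3e-3))
                for _ in range(10)]
        pmap = fit_adc_map(_series_from_voxels(rows, DEFAULT_B_VALUES, kind="dwi"))
        for i, s in enumerate(rows):
            oracle = loglinear_adc(b, s)
            assert abs(pmap.values[0, 0, i] - oracle) / oracle < 1e-3


class TestASLModel:
    def test_zero_perfusion_gives_zero_signal(self):
        assert forward_asl_signal(0.0, 1234.5) == 0.0

    def test_hand_evaluated_model_value(self):
        # independent evaluation of the displayed model:
        # (200/6e6) * (2/0.9) * 1250 * 0.98 * e^-0.6 * e^-0.6 * (1 - e^-1.2)
        expected = (200.0 / 6e6) * (2.0 / 0.9) * 1250.0 * 0.98 \
            * np.exp(-0.6) * np.exp(-0.6) * (1.0 - np.exp(-1.2))
        assert forward_asl_signal(200.0, 1.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0191, abs=5e-5)

    def test_linear_in_f_and_m0(self):
        c = ASLConstants()
        base = forward_asl_signal(120.0, 800.0, c)
        assert forward_asl_signal(240.0, 800.0, c) == pytest.approx(2 * base)
        assert forward_asl_signal(120.0, 1600.0, c) == pytest.approx(2 * base)

    def test_rejects_negative_perfusion(self):
        with pytest.raises(ValueError):
            forward_asl_signal(-1.0, 1.0)

    @pytest.mark.parametrize("bad", [
        dict(alpha=0.0), dict(alpha=1.5), dict(tau_ms=-5.0),
        dict(t_ms=1000.0),  # < tau + delta_t
    ])
    def test_invalid_constants_rejected(self, bad):
        with pytest.raises(ValueError):
            ASLConstants(**bad)

    def test_roundtrip_identity_noiseless(self, labelmap, tissue):
        asl = simulate_asl_set(labelmap, tissue, noise_sd=0)
        pmap = perfusion_map(asl)
        truth = ground_truth_map(labelmap, tissue,
                                 "perfusion_ml_per_100g_min")
        for lab in COMPARTMENTS:
            sel = labelmap.labels == lab
            err = np.abs(pmap.values[sel] - truth[sel]) / truth[sel]
            assert np.nanmax(err) < 1e-6
        assert pmap.units == "ml/100 g/min"

    def test_roundtrip_any_valid_constants(self):
        c = ASLConstants(t_ms=4000, tau_ms=1800, delta_t_ms=900, alpha=0.85,
                         lambda_ml_per_g=1.1, t1_blood_ms=1650, t1_app_ms=1400)
        m0 = np.full((1, 4, 4), 900.0)
        f_true = np.linspace(10, 400, 16).reshape(1, 4, 4)
        label = m0 - forward_asl_signal(f_true, m0, c)
        pmap = perfusion_map(ASLSet(label_img=label, control_img=m0,
                                    m0_img=m0, constants=c))
        assert np.allclose(pmap.values, f_true, rtol=1e-9)

    def test_control_equals_label_gives_zero_map(self):
        m0 = np.full((1, 3, 3), 1000.0)
        pmap = perfusion_map(ASLSet(label_img=m0, control_img=m0, m0_img=m0))
        assert np.allclose(pmap.values, 0.0)

    def test_doubling_m0_halves_f_for_fixed_dm(self):
        m0 = np.full((1, 2, 2), 1000.0)
        label = m0 - 20.0
        f1 = perfusion_map(ASLSet(label_img=label, control_img=m0, m0_img=m0))
        f2 = perfusion_map(ASLSet(label_img=label, control_img=m0,
                                  m0_img=2 * m0))
        assert np.allclose(f2.values, f1.values / 2.0)

    def test_unbiased_under_noise(self):
        rng = np.random.default_rng(31)
        n = 10_000
        m0 = np.full((1, 1, n), 1000.0)
        f_true = 220.0
        clean_label = m0 - forward_asl_signal(f_true, m0)
        noise_sd = 10.0  # 1% of the control signal
        asl = ASLSet(label_img=clean_label + rng.normal(0, noise_sd, m0.shape),
                     control_img=m0 + rng.normal(0, noise_sd, m0.shape),
                     m0_img=m0)
        pmap = perfusion_map(asl)
        assert pmap.values.mean() == pytest.approx(f_true, rel=0.02)
        # the QC counter should match the analytic Gaussian tail
        # P(f < 0) = Phi(-dM / (sqrt(2) * noise_sd))
        from scipy.stats import norm
        dm = float(forward_asl_signal(f_true, 1000.0))
        expected_neg = norm.cdf(-dm / (np.sqrt(2) * noise_sd))
        assert pmap.info["negative_fraction"] == pytest.approx(
            expected_neg, rel=0.15)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ASLSet(label_img=np.zeros((1, 4, 4)),
                   control_img=np.zeros((1, 4, 4)),
                   m0_img=np.zeros((1, 5, 5)))

    def test_frame_schedule_mismatch_rejected(self):
        with pytest.raises(ValueError):
            MOLLISeries(frames=np.zeros((10, 1, 4, 4)),
                        ti_ms=DEFAULT_TI_MS, spacing=(1, 1, 1))
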