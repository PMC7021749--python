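"""ROI taxonomy, rasterisation, per-ROI summaries and ratio arithmetic."""

import numpy as np
import pandas as pd
import pytest

from renalquant import (ROIKind, ROISummary, TissueParams,
                        cortex_medulla_ratio, define_standard_roi_masks,
                        define_standard_rois, rasterize_contour, roi_summary,
                        sd_fraction_report, simulate_asl_set,
                        simulate_molli_series, fit_t1_map, perfusion_map)
from renalquant.phantom import CORTEX, MEDULLA
from renalquant.qmap import ParameterMap
from renalquant.roistats import rasterize_roiset
from renalquant.volumetry import Contour, ROISet

from conftest import circle_vertices


def _flat_map(values2d, units="ms"):
    v = np.asarray(values2d, float)
    return ParameterMap(values=v, units=units, mask=np.isfinite(v))


class TestRasterize:
    def test_square_covering_3x3_voxel_centres(self):
        sq = np.array([[-0.4, -0.4], [2.4, -0.4], [2.4, 2.4], [-0.4, 2.4]])
        mask = rasterize_contour(Contour(0, sq), (8, 8), (1.0, 1.0, 1.0))
        assert mask.sum() == 9
        assert mask[:3, :3].all()

    def test_hole_equal_to_outer_leaves_empty_mask(self):
        sq = np.array([[-0.4, -0.4], [4.4, -0.4], [4.4, 4.4], [-0.4, 4.4]])
        rois = ROISet(
            contours=[Contour(0, sq), Contour(0, sq.copy(), hole=True)],
            spacing=(1.0, 1.0, 1.0))
        assert rasterize_roiset(rois, (8, 8), 0).sum() == 0

    def test_circle_count_matches_analytic_area(self):
        c = Contour(0, circle_vertices(10.0, n=128, center=(15.0, 15.0)))
        mask = rasterize_contour(c, (31, 31), (1.0, 1.0, 1.0))
        assert mask.sum() == pytest.approx(np.pi * 100.0, rel=0.03)

    def test_out_of_grid_contour_rejected(self):
        c = Contour(0, circle_vertices(10.0, center=(2.0, 2.0)))
        with pytest.raises(ValueError, match="outside"):
            rasterize_contour(c, (8, 8), (1.0, 1.0, 1.0))


class TestStandardROIs:
    def test_wk_is_cortex_plus_medulla(self, labelmap):
        masks = define_standard_roi_masks(labelmap, kinds={ROIKind.WK})
        s = int(np.argmax(labelmap.kidney_mask().sum(axis=(1, 2))))
        expected = (labelmap.labels[s] == CORTEX) | (labelmap.labels[s] == MEDULLA)
        assert np.array_equal(masks[ROIKind.WK], expected)

    def test_mask_algebra(self, labelmap):
        m = define_standard_roi_masks(labelmap, seed=4)
        assert np.all(m[ROIKind.WK][m[ROIKind.Cx] | m[ROIKind.Med]])
        assert np.all(m[ROIKind.Cx][m[ROIKind.repCx]])
        assert np.all(m[ROIKind.Cx][m[ROIKind.supCx]])
        assert np.all(m[ROIKind.Cx][m[ROIKind.infCx]])
        assert not (m[ROIKind.supCx] & m[ROIKind.infCx]).any()

    def test_repcx_moves_with_seed_but_stays_in_cortex(self, labelmap):
        m1 = define_standard_roi_masks(labelmap, seed=1)
        m2 = define_standard_roi_masks(labelmap, seed=2)
        assert not np.array_equal(m1[ROIKind.repCx], m2[ROIKind.repCx])
        for m in (m1, m2):
            assert np.all(m[ROIKind.Cx][m[ROIKind.repCx]])

    def test_too_large_repcx_radius_advises_smaller(self, labelmap):
        with pytest.raises(ValueError, match="smaller radius"):
            define_standard_roi_masks(labelmap, repcx_radius_mm=50.0)

    def test_contour_form_round_trips_through_rasterisation(self, labelmap):
        s = int(np.argmax(labelmap.kidney_mask().sum(axis=(1, 2))))
        masks = define_standard_roi_masks(labelmap, s, seed=3)
        rois = define_standard_rois(labelmap, s, seed=3)
        shape2d = labelmap.shape[1:]
        for kind in (ROIKind.WK, ROIKind.Cx, ROIKind.Med):
            raster = rasterize_roiset(rois, shape2d, s, kind.value)
            agree = (raster == masks[kind]).mean()
            assert agree > 0.97  # half-voxel boundary wobble only


class TestROISummary:
    def test_constant_map(self):
        pmap = _flat_map(np.full((4, 4), 1600.0))
        s = roi_summary(pmap, np.ones((4, 4), bool))
        assert (s.mean, s.sd, s.sd_fraction) == (1600.0, 0.0, 0.0)
        assert s.n_voxels == 16

    def test_closed_form_population_sd(self):
        pmap = _flat_map(np.array([[1.0, 2.0, 3.0]]))
        s = roi_summary(pmap, np.ones((1, 3), bool))
        assert s.mean == 2.0
        assert s.sd == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_sample_sd_option(self):
        pmap = _flat_map(np.array([[1.0, 2.0, 3.0]]))
        s = roi_summary(pmap, np.ones((1, 3), bool), ddof=1)
        assert s.sd == pytest.approx(1.0)

    def test_empty_mask_rejected(self):
        pmap = _flat_map(np.ones((2, 2)))
        with pytest.raises(ValueError, match="empty"):
            roi_summary(pmap, np.zeros((2, 2), bool))

    def test_merging_disjoint_masks_weights_by_count(self):
        vals = np.array([[1.0, 1.0, 4.0]])
        pmap = _flat_map(vals)
        m1 = np.array([[True, True, False]])
        m2 = np.array([[False, False, True]])
        s1 = roi_summary(pmap, m1)
        s2 = roi_summary(pmap, m2)
        s12 = roi_summary(pmap, m1 | m2)
        pooled = (s1.mean * s1.n_voxels + s2.mean * s2.n_voxels) \
            / (s1.n_voxels + s2.n_voxels)
        assert s12.mean == pytest.approx(pooled)

    def test_noiseless_phantom_cortex_mean_is_ground_truth(self, labelmap, tissue):
        series = simulate_molli_series(labelmap, tissue, noise_sd=0)
        pmap = fit_t1_map(series)
        s = int(np.argmax(labelmap.kidney_mask().sum(axis=(1, 2))))
        masks = define_standard_roi_masks(labelmap, s, kinds={ROIKind.Cx})
        m3 = np.zeros(labelmap.shape, bool)
        m3[s] = masks[ROIKind.Cx]
        summ = roi_summary(pmap, m3)
        assert summ.mean == pytest.approx(tissue.cortex.t1_ms, rel=1e-6)
        assert summ.sd == pytest.approx(0.0, abs=1e-6)

    def test_wk_sd_fraction_exceeds_cortex_on_two_compartment_phantom(
            self, labelmap, tissue):
        # the whole-kidney mean pools cortex and medulla and so is drawn
        # from a wider spread than any single-compartment ROI
        asl = simulate_asl_set(labelmap, tissue, noise_sd=5.0, seed=2)
        pmap = perfusion_map(asl)
        s = int(np.argmax(labelmap.kidney_mask().sum(axis=(1, 2))))
        masks = define_standard_roi_masks(labelmap, s, seed=1)
        sums = {}
        for kind in (ROIKind.WK, ROIKind.Cx, ROIKind.repCx):
            m3 = np.zeros(labelmap.shape, bool)
            m3[s] = masks[kind]
            sums[kind] = roi_summary(pmap, m3)
        assert sums[ROIKind.WK].sd_fraction > sums[ROIKind.Cx].sd_fraction
        assert sums[ROIKind.WK].sd_fraction > sums[ROIKind.repCx].sd_fraction

    def test_repcx_tracks_cx_better_as_radius_grows(self, labelmap, tissue):
        # placement sensitivity: the repCx-vs-Cx mean gap shrinks (in
        # expectation) as the disc grows; checked over 100 placements
        asl = simulate_asl_set(labelmap, tissue, noise_sd=5.0, seed=5)
        pmap = perfusion_map(asl)
        s = int(np.argmax(labelmap.kidney_mask().sum(axis=(1, 2))))
        cx = define_standard_roi_masks(labelmap, s, kinds={ROIKind.Cx})[ROIKind.Cx]
        m3 = np.zeros(labelmap.shape, bool)
        m3[s] = cx
        cx_mean = roi_summary(pmap, m3).mean
        gaps = {}
        for radius in (2.0, 4.0, 6.0):
            diffs = []
            for seed in range(100):
                masks = define_standard_roi_masks(
                    labelmap, s, kinds={ROIKind.repCx}, seed=seed,
                    repcx_radius_mm=radius)
                m3r = np.zeros(labelmap.shape, bool)
                m3r[s] = masks[ROIKind.repCx]
                diffs.append(abs(roi_summary(pmap, m3r).mean - cx_mean))
            gaps[radius] = np.mean(diffs)
        assert gaps[2.0] > gaps[4.0] > gaps[6.0]


class TestRatiosAndSpreadReport:
    def test_printed_t1_ratio(self):
        cx = ROISummary(1630.2, 0, 1, 0, "ms")
        med = ROISummary(1975.8, 0, 1, 0, "ms")
        assert round(cortex_medulla_ratio(cx, med), 2) == 0.83

    def test_printed_perfusion_ratio(self):
        cx = ROISummary(221.0, 0, 1, 0, "ml/100 g/min")
        med = ROISummary(95.8, 0, 1, 0, "ml/100 g/min")
        assert round(cortex_medulla_ratio(cx, med), 1) == 2.3

    def test_equal_means_give_unity(self):
        s = ROISummary(100.0, 0, 1, 0, "ms")
        assert cortex_medulla_ratio(s, s) == 1.0

    def test_zero_medullary_mean_rejected(self):
        with pytest.raises(ValueError):
            cortex_medulla_ratio(ROISummary(1, 0, 1, 0),
                                 ROISummary(0.0, 0, 1, 0))

    def test_sd_fraction_report_printed_examples(self):
        df = pd.DataFrame([
            {"sequence": "T1", "roi": "WK", "mean": 1772.8, "sd": 354.1,
             "units": "ms"},
            {"sequence": "pCASL", "roi": "WK", "mean": 181.7, "sd": 100.7,
             "units": "ml/100 g/min"},
        ])
        rep = sd_fraction_report(df).set_index(["sequence", "roi"])
        assert rep.loc[("T1", "WK"), "roi_sd_pct_of_mean"] == 20.0
        assert rep.loc[("pCASL", "WK"), "roi_sd_pct_of_mean"] == 55.4

    def test_all_constant_maps_give_zero_percent(self):
        df = pd.DataFrame([
            {"sequence": "T1", "roi": "WK", "mean": 1600.0, "sd": 0.0,
             "units": "ms"}] * 3)
        rep = sd_fraction_report(df)
        assert (rep["roi_sd_pct_of_mean"] == 0.0).all()

    def test_unit_mismatch_rejected(self):
        df = pd.DataFrame([
            {"sequence": "T1", "roi": "WK", "mean": 1.0, "sd": 0.1,
             "units": "ms"},
            {"sequence": "T1", "roi": "WK", "mean": 1.0, "sd": 0.1,
             "units": "s"}])
        with pytest.raises(ValueError, match="unit"):
            sd_fraction_report(df)
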