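"""Infarct classification, perimeter size, transmurality, mass, CNR."""

import dataclasses
import math

import numpy as np
import pytest

from t1rho_infarct import (PhantomConfig, build_chord_grid, classify_infarct,
                           cnr, compile_report, estimate_noise, fit_map,
                           generate_phantom, infarct_size_perimeter,
                           simulate_tsl_series, tissue_mass, transmurality)
from t1rho_infarct.pipeline import RunConfig, remote_region_mask


@pytest.fixture(scope="module")
def crisp_study(crisp_truth):
    """Noiseless crisp-label phantom fitted and chord-segmented."""
    series = simulate_tsl_series(crisp_truth)
    mask = crisp_truth.myocardial_mask
    t1rho_map = fit_map(series, mask)
    grid = build_chord_grid(crisp_truth.contours, mask)
    remote = remote_region_mask(crisp_truth, RunConfig())
    return crisp_truth, t1rho_map, grid, remote


class TestClassification:
    def test_noiseless_crisp_classification_matches_truth(self, crisp_study):
        truth, t1rho_map, _, remote = crisp_study
        cls = classify_infarct(t1rho_map, truth.myocardial_mask, remote)
        assert np.array_equal(cls.infarct_mask, truth.tissue_mask("infarct"))
        assert cls.method["rule"] == "mean_plus_sd"

    def test_infarct_free_noisy_false_positive_rate(self):
        # mean+5SD rule on pure remote tissue: Gaussian-tail false positives
        rng = np.random.default_rng(5)
        values = 47.2 + rng.normal(0, 2.0, size=(1, 200, 200))
        mask = np.ones(values.shape, dtype=bool)
        remote = np.zeros_like(mask)
        remote[0, :50] = True
        cls = classify_infarct(values, mask, remote, k=5.0)
        assert cls.infarct_mask.mean() < 0.001

    def test_k_zero_warns_and_splits_remote(self):
        rng = np.random.default_rng(6)
        values = 47.2 + rng.normal(0, 2.0, size=(1, 100, 100))
        mask = np.ones(values.shape, dtype=bool)
        with pytest.warns(UserWarning, match="k = 0"):
            cls = classify_infarct(values, mask, mask, k=0.0)
        assert cls.infarct_mask.mean() == pytest.approx(0.5, abs=0.05)

    def test_fwhm_and_fixed_rules(self, crisp_study):
        truth, t1rho_map, _, remote = crisp_study
        mask = truth.myocardial_mask
        fwhm = classify_infarct(t1rho_map, mask, remote, rule="fwhm")
        assert np.array_equal(fwhm.infarct_mask,
                              truth.tissue_mask("infarct"))
        fixed = classify_infarct(t1rho_map, mask, remote, rule="fixed",
                                 threshold=70.0)
        assert np.array_equal(fixed.infarct_mask,
                              truth.tissue_mask("infarct"))
        with pytest.raises(ValueError):
            classify_infarct(t1rho_map, mask, remote, rule="fixed")

    def test_empty_remote_region_raises(self, crisp_study):
        truth, t1rho_map, _, _ = crisp_study
        with pytest.raises(ValueError, match="remote"):
            classify_infarct(t1rho_map, truth.myocardial_mask,
                             np.zeros_like(truth.myocardial_mask))


class TestPerimeterSize:
    def test_quarter_sector_measures_25_percent(self, crisp_study):
        truth, t1rho_map, grid, remote = crisp_study
        cls = classify_infarct(t1rho_map, truth.myocardial_mask, remote)
        size, per_slice = infarct_size_perimeter(cls, truth.contours, grid)
        assert size == pytest.approx(25.0, abs=1.0)
        assert len(per_slice) == truth.config.n_slices

    def test_no_infarct_measures_zero(self, crisp_config):
        cfg = dataclasses.replace(crisp_config, infarct_angular_extent=0.0)
        truth = generate_phantom(cfg)
        series = simulate_tsl_series(truth)
        mask = truth.myocardial_mask
        t1rho_map = fit_map(series, mask)
        grid = build_chord_grid(truth.contours, mask)
        remote = remote_region_mask(truth, RunConfig())
        cls = classify_infarct(t1rho_map, mask, remote)
        size, _ = infarct_size_perimeter(cls, truth.contours, grid)
        assert size == 0.0

    @pytest.mark.parametrize("extent", [54.0, 90.0, 144.0])
    def test_size_tracks_angular_extent(self, crisp_config, extent):
        # perimeter-ratio consistency: noiseless transmural sector recovers
        # extent/360 within about one endocardial segment
        cfg = dataclasses.replace(crisp_config,
                                  infarct_angular_extent=extent)
        truth = generate_phantom(cfg)
        series = simulate_tsl_series(truth)
        mask = truth.myocardial_mask
        t1rho_map = fit_map(series, mask)
        grid = build_chord_grid(truth.contours, mask)
        remote = remote_region_mask(truth, RunConfig())
        cls = classify_infarct(t1rho_map, mask, remote)
        size, _ = infarct_size_perimeter(cls, truth.contours, grid)
        assert size == pytest.approx(100.0 * extent / 360.0, abs=1.0)


class TestTransmurality:
    def _aligned_config(self, crisp_config, profile=(1.0,), edges=None,
                        extent=90.0):
        return dataclasses.replace(
            crisp_config, infarct_angular_extent=extent,
            infarct_center_angle=extent / 2.0,
            infarct_transmural_profile=profile,
            infarct_profile_edges=edges)

    def _run(self, cfg):
        truth = generate_phantom(cfg)
        series = simulate_tsl_series(truth)
        mask = truth.myocardial_mask
        t1rho_map = fit_map(series, mask)
        grid = build_chord_grid(truth.contours, mask,
                                reference_angle_deg=0.0)
        remote = remote_region_mask(truth, RunConfig())
        cls = classify_infarct(t1rho_map, mask, remote)
        return cls, grid

    def test_fully_transmural_sector(self, crisp_config):
        cls, grid = self._run(self._aligned_config(crisp_config))
        result = transmurality(cls, grid)
        assert result.transmural_percent == pytest.approx(100.0)
        assert result.nontransmural_infarct_volume_fraction == 0.0
        assert result.nontransmural_lv_fraction == 0.0

    def test_partial_depth_wedges_are_nontransmural(self, crisp_config):
        # half the arc transmural, half at 40% wall depth (sections 1-2 only)
        cfg = self._aligned_config(crisp_config, profile=(1.0, 0.4),
                                   edges=(0.0, 0.5, 1.0), extent=144.0)
        cls, grid = self._run(cfg)
        result = transmurality(cls, grid)
        tbl = result.wedge_table
        border = tbl[tbl["wedge"].isin([5, 6, 7, 8])]  # 72-144 deg arc
        assert border["infarct_containing"].all()
        assert not border["transmural"].any()
        core = tbl[tbl["wedge"].isin([1, 2, 3, 4])]
        assert core["transmural"].all()
        assert 0 < result.transmural_percent < 100

    def test_empty_grid_raises(self, crisp_study):
        truth, t1rho_map, grid, remote = crisp_study
        cls = classify_infarct(t1rho_map, truth.myocardial_mask, remote)
        empty = dataclasses.replace(
            grid, wedge=np.zeros_like(grid.wedge),
            radial=np.zeros_like(grid.radial))
        with pytest.raises(ValueError, match="empty"):
            transmurality(cls, empty)


class TestMassCnrNoise:
    def test_one_ml_weighs_1_06_g(self):
        assert tissue_mass(1000.0, 1.0) == pytest.approx(1.06, rel=1e-12)

    def test_zero_voxels_zero_mass(self):
        assert tissue_mass(0, 1.0) == 0.0

    def test_reported_infarct_volume_gives_10_9_g(self):
        # 10.283 mL at 1.06 g/mL is 10.9 g to three significant figures
        assert tissue_mass(10.283e3, 1.0) == pytest.approx(10.9, abs=5e-3)

    def test_mass_additivity_in_report(self, crisp_study):
        truth, t1rho_map, grid, remote = crisp_study
        cls = classify_infarct(t1rho_map, truth.myocardial_mask, remote)
        report = compile_report(cls, grid, truth.contours,
                                truth.voxel_volume_mm3)
        n_remote = int((cls.labels == 1).sum())
        remote_mass = tissue_mass(n_remote, truth.voxel_volume_mm3)
        assert report.infarct_mass + remote_mass == pytest.approx(
            report.lv_mass, abs=1e-9)
        assert report.infarct_mass <= report.lv_mass

    def test_cnr_hand_arithmetic(self):
        img = np.array([[[3.0, 3.0, 1.0, 1.0]]])
        infarct = np.array([[[True, True, False, False]]])
        remote = ~infarct
        assert cnr(img, infarct, remote, 1.0) == pytest.approx(2.0)
        assert cnr(img, infarct, infarct[..., ::-1], 1.0) == pytest.approx(2.0)
        assert cnr(np.ones_like(img), infarct, remote, 1.0) == 0.0

    def test_cnr_scale_invariance(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(1, 5, (1, 10, 10))
        infarct = np.zeros(img.shape, dtype=bool)
        infarct[0, :5] = True
        base = cnr(img, infarct, ~infarct, 2.0)
        assert cnr(img * 3.0, infarct, ~infarct, 6.0) == pytest.approx(
            base, rel=1e-12)

    def test_cnr_input_validation(self):
        img = np.ones((1, 2, 2))
        m = np.ones((1, 2, 2), dtype=bool)
        with pytest.raises(ValueError, match="sigma"):
            cnr(img, m, ~m, 0.0)
        with pytest.raises(ValueError, match="disjoint"):
            cnr(img, m, m, 1.0)

    def test_noise_estimate_gaussian(self):
        rng = np.random.default_rng(8)
        img = rng.normal(0, 2.0, (1, 400, 400))
        assert estimate_noise(img, np.ones(img.shape, bool),
                              model="gaussian") == pytest.approx(2.0,
                                                                 rel=0.02)

    def test_noise_estimate_rician_air(self):
        rng = np.random.default_rng(9)
        img = np.hypot(rng.normal(0, 3.0, (1, 400, 400)),
                       rng.normal(0, 3.0, (1, 400, 400)))
        assert estimate_noise(img, np.ones(img.shape, bool),
                              model="rician") == pytest.approx(3.0, rel=0.02)

    def test_zero_background_warns(self):
        with pytest.warns(UserWarning, match="zero"):
            sigma = estimate_noise(np.zeros((1, 4, 4)),
                                   np.ones((1, 4, 4), bool))
        assert sigma == 0.0

    def test_empty_background_raises(self):
        with pytest.raises(ValueError, match="background"):
            estimate_noise(np.ones((1, 4, 4)), np.zeros((1, 4, 4), bool))
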