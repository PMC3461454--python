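"""Phantom geometry, signal model, noise, and ground-truth invariants."""

import dataclasses
import math

import numpy as np
import pytest

from t1rho_infarct import (ConfigurationError, PhantomConfig, TissueParams,
                           TSLSeries, add_noise, generate_phantom,
                           simulate_reference_modality, simulate_tsl_series)
from t1rho_infarct.phantom import (analytic_infarct_volume_ml,
                                   extent_for_infarct_volume,
                                   partial_depth_arc_for_fraction)


class TestGeometryTruth:
    def test_quarter_sector_perimeter_fraction(self, small_truth):
        # 90° transmural sector of a circular endocardium covers 1/4 of it
        assert small_truth.true_infarct_perimeter_fraction == pytest.approx(0.25)

    def test_no_infarct_when_extent_zero(self, small_config):
        cfg = dataclasses.replace(small_config, infarct_angular_extent=0.0)
        truth = generate_phantom(cfg)
        assert truth.true_infarct_volume == 0.0
        assert not truth.tissue_mask("infarct").any()
        assert truth.partial_volume_maps[..., truth.tissue_index("infarct")].max() == 0

    def test_annulus_volume_closed_form(self):
        # pi (30^2 - 20^2) * 10 * 2.6 mm^3 = 40.84 mL
        cfg = PhantomConfig(matrix=(96, 96), pixel_spacing=1.0, n_slices=10,
                            epi_radius=30.0, endo_radius=20.0,
                            infarct_angular_extent=0.0, supersample_factor=8)
        truth = generate_phantom(cfg)
        expected_ml = math.pi * (30**2 - 20**2) * 10 * 2.6 / 1000.0
        assert truth.true_lv_myocardial_volume == pytest.approx(expected_ml,
                                                                rel=1e-12)
        idx = truth.tissue_index("myocardium")
        voxel_ml = (truth.partial_volume_maps[..., idx].sum()
                    * truth.voxel_volume_mm3 / 1000.0)
        assert voxel_ml == pytest.approx(expected_ml, rel=0.01)

    def test_voxel_volume_converges_with_supersampling(self, small_config):
        errors = []
        for factor in (1, 4, 8):
            cfg = dataclasses.replace(small_config, supersample_factor=factor)
            truth = generate_phantom(cfg)
            idx = truth.tissue_index("infarct")
            voxel_ml = (truth.partial_volume_maps[..., idx].sum()
                        * truth.voxel_volume_mm3 / 1000.0)
            errors.append(abs(voxel_ml - truth.true_infarct_volume)
                          / truth.true_infarct_volume)
        assert errors[2] <= errors[0]
        assert errors[2] < 0.01

    def test_partial_volume_fractions_sum_to_one(self, small_truth):
        sums = small_truth.partial_volume_maps.sum(axis=-1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_identical_config_gives_identical_phantom(self, small_config):
        a = generate_phantom(small_config)
        b = generate_phantom(small_config)
        assert np.array_equal(a.label_volume, b.label_volume)
        assert np.array_equal(a.partial_volume_maps, b.partial_volume_maps)

    @pytest.mark.parametrize("field,value,match", [
        ("endo_radius", 35.0, "endo_radius"),
        ("epi_radius", 60.0, "epi_radius"),
        ("infarct_angular_extent", 400.0, "extent"),
        ("supersample_factor", 0, "supersample"),
    ])
    def test_bad_geometry_raises_naming_offender(self, small_config, field,
                                                 value, match):
        with pytest.raises(ConfigurationError, match=match):
            dataclasses.replace(small_config, **{field: value})

    def test_tissue_params_validation(self):
        with pytest.raises(ConfigurationError):
            TissueParams(t1rho=-1.0, s0=10.0)
        with pytest.raises(ConfigurationError):
            TissueParams(t1rho=50.0, s0=-1.0)


class TestSignalModel:
    def test_pure_voxel_decay_is_monoexponential(self, small_truth,
                                                 small_series):
        cfg = small_truth.config
        tsl = np.asarray(small_series.tsl_ms)
        for tissue in ("myocardium", "infarct", "blood"):
            pure = small_truth.pure_tissue_mask(tissue)
            assert pure.any()
            params = cfg.tissue_params[tissue]
            expected = params.s0 * np.exp(-tsl / params.t1rho)
            signals = small_series.data[pure]
            assert np.allclose(signals, expected, rtol=1e-12)

    def test_zero_tsl_returns_equilibrium_signal(self, small_truth):
        cfg = dataclasses.replace(small_truth.config,
                                  tsl_ms=(0.0, 47.2, 48.0))
        series = simulate_tsl_series(small_truth, cfg)
        pure = small_truth.pure_tissue_mask("myocardium")
        s = series.data[pure][0]
        assert s[0] == pytest.approx(100.0, rel=1e-12)
        # one time constant later the signal is s0/e
        assert s[1] == pytest.approx(100.0 / math.e, rel=1e-12)

    def test_half_and_half_voxel_mixes_signals(self):
        # direct scalar evaluation: 50*(e^(-48/47.2) + e^(-48/91.7)) = 47.71
        expected = 50.0 * (math.exp(-48.0 / 47.2) + math.exp(-48.0 / 91.7))
        assert expected == pytest.approx(47.709, abs=1e-3)
        cfg = PhantomConfig(matrix=(8, 8), pixel_spacing=1.0, n_slices=1,
                            epi_radius=3.0, endo_radius=2.0,
                            infarct_angular_extent=0.0, tsl_ms=(48.0,))
        truth = generate_phantom(cfg)
        pv = np.zeros((1, 1, 1, 4))
        pv[..., truth.tissue_index("myocardium")] = 0.5
        pv[..., truth.tissue_index("infarct")] = 0.5
        truth.partial_volume_maps = pv
        truth.label_volume = np.full((1, 1, 1),
                                     truth.tissue_index("myocardium"),
                                     dtype=np.int8)
        series = simulate_tsl_series(truth, cfg)
        assert series.data[0, 0, 0, 0] == pytest.approx(expected, rel=1e-12)

    def test_noiseless_signal_strictly_decreasing_in_tsl(self, small_series):
        data = small_series.data
        nonzero = data[..., 0] > 0
        diffs = np.diff(data[nonzero], axis=-1)
        assert np.all(diffs < 0)

    def test_log_ratio_identity_pure_voxel(self, small_truth, small_series):
        tsl = np.asarray(small_series.tsl_ms)
        for tissue in ("myocardium", "infarct"):
            t1rho = small_truth.config.tissue_params[tissue].t1rho
            s = small_series.data[small_truth.pure_tissue_mask(tissue)][0]
            lhs = np.log(s[0]) - np.log(s[-1])
            rhs = (tsl[-1] - tsl[0]) / t1rho
            assert lhs == pytest.approx(rhs, abs=1e-9)


class TestNoise:
    def _flat_series(self, value, shape=(1, 100, 100, 5)):
        return TSLSeries(data=np.full(shape, float(value)),
                         tsl_ms=(6.0, 18.0, 30.0, 42.0, 48.0),
                         spin_lock_amplitude_hz=500.0,
                         pixel_spacing=1.0, slice_thickness=1.0)

    def test_zero_sigma_is_identity(self, small_series):
        out = add_noise(small_series, 0.0, seed=1)
        assert np.array_equal(out.data, small_series.data)

    def test_rician_zero_signal_has_rayleigh_mean(self):
        series = self._flat_series(0.0, shape=(1, 200, 200, 5))
        out = add_noise(series, sigma=3.0, seed=42, model="rician")
        expected = 3.0 * math.sqrt(math.pi / 2.0)
        assert out.data.mean() == pytest.approx(expected, rel=0.01)

    def test_same_seed_reproduces_noise(self, small_series):
        a = add_noise(small_series, 2.0, seed=5)
        b = add_noise(small_series, 2.0, seed=5)
        c = add_noise(small_series, 2.0, seed=6)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_gaussian_noise_clips_at_zero(self):
        out = add_noise(self._flat_series(0.5), sigma=2.0, seed=0,
                        model="gaussian")
        assert out.data.min() >= 0.0

    def test_negative_sigma_rejected(self, small_series):
        with pytest.raises(ValueError):
            add_noise(small_series, -1.0, seed=0)


class TestReferenceModality:
    def test_tissue_brightness_ordering(self, small_truth):
        img = simulate_reference_modality(small_truth, sigma=0.0)
        means = {t: img[small_truth.pure_tissue_mask(t)].mean()
                 for t in ("infarct", "blood", "myocardium")}
        assert means["infarct"] > means["blood"] > means["myocardium"]

    def test_infarct_free_truth_has_no_hyperintense_myocardium(self,
                                                               small_config):
        cfg = dataclasses.replace(small_config, infarct_angular_extent=0.0)
        truth = generate_phantom(cfg)
        img = simulate_reference_modality(truth, sigma=2.0, seed=9)
        myo = img[truth.pure_tissue_mask("myocardium")]
        assert not np.any(myo > myo.mean() + 5 * myo.std())

    def test_seeded_run_reproducible(self, small_truth):
        a = simulate_reference_modality(small_truth, seed=3)
        b = simulate_reference_modality(small_truth, seed=3)
        assert np.array_equal(a, b)


class TestInverseGeometry:
    def test_extent_solver_hits_requested_volume(self, small_config):
        extent = extent_for_infarct_volume(small_config, 2.0)
        cfg = dataclasses.replace(small_config,
                                  infarct_angular_extent=extent)
        assert analytic_infarct_volume_ml(cfg) == pytest.approx(2.0,
                                                                rel=1e-12)

    def test_border_arc_solver_hits_requested_share(self, small_config):
        theta_n = partial_depth_arc_for_fraction(small_config, 90.0, 0.4,
                                                 0.06)
        extent = 90.0 + theta_n
        cfg = dataclasses.replace(
            small_config, infarct_angular_extent=extent,
            infarct_transmural_profile=(1.0, 0.4),
            infarct_profile_edges=(0.0, 90.0 / extent, 1.0))
        truth = generate_phantom(cfg)
        assert truth.true_nontransmural_infarct_fraction == pytest.approx(
            0.06, rel=1e-9)
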