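import numpy as np
import pandas as pd
import pytest

from mrirepro import synthetic
from mrirepro.core import LabelMap
from mrirepro.repro import cv
from mrirepro.synthetic import (
    AcrPhantomSpec,
    EllipsoidSpec,
    MultiSitePanelSpec,
    RaterModel,
    gen_acr_phantom,
    gen_dwi_series,
    gen_geometric_brain,
    gen_multisite_panel,
    gen_rater_labelmaps,
)

from conftest import constant_tensor_field

RAYLEIGH_SD = np.sqrt((4 - np.pi) / 2)  # SD of |N(0,s)+iN(0,s)| in units of s


class TestAcrPhantom:
    def test_noiseless_unbiased_is_exact(self, small_phantom_spec):
        img = gen_acr_phantom(small_phantom_spec)
        r = synthetic._inplane_radius_mm(img.shape, img.voxel_size_mm)
        inside = r <= small_phantom_spec.cylinder_radius_mm
        assert np.all(img.data[inside, :] == 100.0)
        assert np.all(img.data[~inside, :] == 0.0)

    def test_determinism(self):
        spec = AcrPhantomSpec(grid_shape=(32, 32, 3), cylinder_radius_mm=10.0,
                              noise_sigma=2.0, seed=7)
        a = gen_acr_phantom(spec)
        b = gen_acr_phantom(spec)
        np.testing.assert_array_equal(a.data, b.data)

    def test_background_sd_matches_rayleigh(self):
        # Monte-Carlo over >= 10 seeds against the closed-form Rayleigh SD
        sds = []
        for seed in range(12):
            spec = AcrPhantomSpec(grid_shape=(64, 64, 3), cylinder_radius_mm=15.0,
                                  signal_level=100.0, noise_sigma=2.0, seed=seed)
            img = gen_acr_phantom(spec)
            r = synthetic._inplane_radius_mm(img.shape, img.voxel_size_mm)
            bg = img.data[r > 20.0, :]
            sds.append(bg.std(ddof=1))
        assert np.mean(sds) == pytest.approx(2.0 * RAYLEIGH_SD, rel=0.10)

    def test_bias_amplitude_is_exact_over_cylinder(self):
        spec = AcrPhantomSpec(grid_shape=(64, 64, 3), cylinder_radius_mm=20.0,
                              bias_amplitude=0.2, seed=0)
        img = gen_acr_phantom(spec)
        r = synthetic._inplane_radius_mm(img.shape, img.voxel_size_mm)
        vals = img.data[r <= 20.0, 0]
        hi, lo = vals.max(), vals.min()
        assert (hi - lo) / (hi + lo) == pytest.approx(0.2, abs=1e-12)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"signal_level": 0.0},
            {"signal_level": -5.0},
            {"bias_amplitude": 1.0},
            {"bias_amplitude": -0.1},
            {"noise_sigma": -1.0},
            {"cylinder_radius_mm": 500.0},  # exceeds field of view
        ],
    )
    def test_invalid_spec_raises(self, kwargs):
        with pytest.raises(ValueError):
            AcrPhantomSpec(**kwargs)


class TestDwiSeries:
    def test_isotropic_closed_form(self, scheme_5_30):
        tf = constant_tensor_field((2, 2, 1), (0.7e-3, 0.7e-3, 0.7e-3))
        series = gen_dwi_series(tf, s0=1000.0, scheme=scheme_5_30, noise_sigma=0.0)
        dw = scheme_5_30.bvals > 0
        np.testing.assert_allclose(series.data[..., dw], 1000.0 * np.exp(-0.7), rtol=1e-12)

    def test_b0_equals_s0(self, scheme_5_30):
        tf = constant_tensor_field((2, 2, 1), (1.7e-3, 0.2e-3, 0.2e-3))
        series = gen_dwi_series(tf, s0=500.0, scheme=scheme_5_30, noise_sigma=0.0)
        b0 = scheme_5_30.bvals == 0
        np.testing.assert_array_equal(series.data[..., b0], 500.0)

    def test_axis_aligned_hand_evaluation(self):
        # g = (1,0,0), D = diag(1.7, .2, .2)e-3, b = 1000 -> S = s0 e^-1.7
        from mrirepro.dti import DiffusionScheme

        scheme = DiffusionScheme(bvals=[0.0, 1000.0],
                                 bvecs=[[0, 0, 0], [1.0, 0.0, 0.0]])
        tf = constant_tensor_field((1, 1, 1), (1.7e-3, 0.2e-3, 0.2e-3))
        series = gen_dwi_series(tf, s0=100.0, scheme=scheme, noise_sigma=0.0)
        assert series.data[0, 0, 0, 1] == pytest.approx(100.0 * np.exp(-1.7), rel=1e-12)

    def test_determinism(self, scheme_5_30):
        tf = constant_tensor_field((3, 3, 2), (1.0e-3, 0.5e-3, 0.5e-3))
        a = gen_dwi_series(tf, 1000.0, scheme_5_30, noise_sigma=20.0, seed=9)
        b = gen_dwi_series(tf, 1000.0, scheme_5_30, noise_sigma=20.0, seed=9)
        np.testing.assert_array_equal(a.data, b.data)

    @staticmethod
    def _rician_mean(s, sigma):
        # closed-form mean of |N(s, sigma) + i N(0, sigma)|
        from scipy import special

        x = -(s**2) / (2 * sigma**2)
        return sigma * np.sqrt(np.pi / 2) * np.exp(x / 2) * (
            (1 - x) * special.iv(0, -x / 2) - x * special.iv(1, -x / 2)
        )

    def test_rician_mean_matches_closed_form(self, scheme_5_30):
        tf = constant_tensor_field((40, 40, 10), (0.7e-3, 0.7e-3, 0.7e-3))
        s_dw = 1000.0 * np.exp(-0.7)
        sigma = s_dw / 5.0  # weakest signal sits at S/sigma = 5
        series = gen_dwi_series(tf, 1000.0, scheme_5_30, noise_sigma=sigma, seed=3)
        dw = scheme_5_30.bvals > 0
        observed = series.data[..., dw].mean()
        assert observed == pytest.approx(self._rician_mean(s_dw, sigma), rel=2e-3)

    def test_rician_bias_below_2pct_above_snr_5(self, scheme_5_30):
        # closed-form bias is 2.02 % at exactly S/sigma = 5 and falls as
        # 1/(2 SNR^2); the sub-2 % regime starts just above 5
        tf = constant_tensor_field((40, 40, 10), (0.7e-3, 0.7e-3, 0.7e-3))
        sigma = 1000.0 * np.exp(-0.7) / 6.0
        series = gen_dwi_series(tf, 1000.0, scheme_5_30, noise_sigma=sigma, seed=3)
        clean = gen_dwi_series(tf, 1000.0, scheme_5_30, noise_sigma=0.0)
        rel_bias = np.abs(series.data.mean(axis=(0, 1, 2)) / clean.data[0, 0, 0] - 1.0)
        assert rel_bias.max() < 0.02

    def test_mean_magnitude_approaches_clean_as_sigma_vanishes(self, scheme_5_30):
        tf = constant_tensor_field((20, 20, 5), (0.7e-3, 0.7e-3, 0.7e-3))
        clean = gen_dwi_series(tf, 1000.0, scheme_5_30, noise_sigma=0.0)
        last = np.inf
        for sigma in (50.0, 10.0, 1.0):
            noisy = gen_dwi_series(tf, 1000.0, scheme_5_30, noise_sigma=sigma, seed=2)
            bias = np.abs(noisy.data.mean() - clean.data.mean())
            assert bias < last
            last = bias
        assert last < 0.1

    def test_negative_s0_raises(self, scheme_5_30):
        tf = constant_tensor_field((1, 1, 1), (1e-3, 1e-3, 1e-3))
        with pytest.raises(ValueError, match="s0"):
            gen_dwi_series(tf, -1.0, scheme_5_30)

    def test_non_psd_tensor_raises(self, scheme_5_30):
        tf = constant_tensor_field((1, 1, 1), (1e-3, 1e-3, -1e-3))
        with pytest.raises(ValueError, match="semidefinite"):
            gen_dwi_series(tf, 100.0, scheme_5_30)

    def test_non_unit_gradient_raises(self):
        from mrirepro.dti import DiffusionScheme

        with pytest.raises(ValueError, match="unit-norm"):
            DiffusionScheme(bvals=[1000.0], bvecs=[[2.0, 0.0, 0.0]])


class TestRaterMaps:
    def test_identity_confusion_reproduces_truth(self, rng):
        truth = LabelMap(rng.integers(0, 3, (10, 10, 4)))
        model = RaterModel.symmetric(3, 3, diag=1.0, seed=0)
        for m in gen_rater_labelmaps(truth, model):
            np.testing.assert_array_equal(m.data, truth.data)

    def test_agreement_matches_confusion_diagonal(self, rng):
        truth = LabelMap(rng.integers(0, 2, (25, 25, 16)))  # 10^4 voxels
        model = RaterModel.symmetric(3, 2, diag=0.9, seed=5)
        for m in gen_rater_labelmaps(truth, model):
            agreement = (m.data == truth.data).mean()
            assert agreement == pytest.approx(0.9, abs=0.01)

    def test_zero_raters_gives_empty_list(self, rng):
        truth = LabelMap(rng.integers(0, 2, (4, 4, 1)))
        model = RaterModel(confusion=np.zeros((0, 2, 2)), seed=0)
        assert gen_rater_labelmaps(truth, model) == []

    def test_label_outside_range_raises(self):
        truth = LabelMap(np.full((2, 2, 1), 5))
        model = RaterModel.symmetric(1, 3, diag=0.9)
        with pytest.raises(ValueError, match="labels"):
            gen_rater_labelmaps(truth, model)

    def test_non_stochastic_confusion_raises(self):
        with pytest.raises(ValueError, match="sum to 1"):
            RaterModel(confusion=np.array([[[0.5, 0.4], [0.1, 0.9]]]))

    def test_determinism(self, rng):
        truth = LabelMap(rng.integers(0, 3, (8, 8, 2)))
        model = RaterModel.symmetric(2, 3, diag=0.8, seed=11)
        a = gen_rater_labelmaps(truth, model)
        b = gen_rater_labelmaps(truth, model)
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma.data, mb.data)


def _panel_spec(**overrides):
    base = dict(
        true_values={"r1": 100.0, "r2": 40.0},
        scanner_ids=["A", "B"],
        vendor_of={"A": "V1", "B": "V2"},
        sessions_per_scanner={"A": 3, "B": 3},
        inter_scanner_cv_pct=0.0,
        intra_scanner_cv_pct=0.0,
        seed=0,
    )
    base.update(overrides)
    return MultiSitePanelSpec(**base)


class TestMultiSitePanel:
    def test_zero_cv_is_exact(self):
        panel = gen_multisite_panel(_panel_spec())
        assert set(panel.columns) >= {"scanner_id", "vendor", "session_id",
                                      "is_rescan", "label", "metric", "value"}
        for label, mu in [("r1", 100.0), ("r2", 40.0)]:
            assert np.all(panel.loc[panel["label"] == label, "value"] == mu)

    def test_intra_cv_recovery_200_sessions(self):
        spec = _panel_spec(
            scanner_ids=["A"], vendor_of={"A": "V"},
            sessions_per_scanner={"A": 200},
            intra_scanner_cv_pct=1.0, inter_scanner_cv_pct=0.0, seed=42,
        )
        panel = gen_multisite_panel(spec)
        vals = panel.loc[panel["label"] == "r1", "value"]
        assert cv(vals) == pytest.approx(1.0, abs=0.15)

    def test_determinism(self):
        spec = _panel_spec(inter_scanner_cv_pct=3.0, intra_scanner_cv_pct=1.0, seed=9)
        pd.testing.assert_frame_equal(gen_multisite_panel(spec), gen_multisite_panel(spec))

    def test_moment_recovery_pooled_cv(self):
        # inter effect zero -> pooled across-scanner CV converges to intra
        spec = _panel_spec(
            scanner_ids=["A", "B"], sessions_per_scanner={"A": 250, "B": 250},
            intra_scanner_cv_pct=2.0, inter_scanner_cv_pct=0.0, seed=21,
        )
        panel = gen_multisite_panel(spec)
        vals = panel.loc[panel["label"] == "r1", "value"].to_numpy()
        n = vals.size
        se = 2.0 / np.sqrt(2 * (n - 1))  # large-sample SE of a sample CV
        assert abs(cv(vals) - 2.0) < 3 * se

    def test_rescan_fraction(self):
        spec = _panel_spec(rescan_fraction=0.5, sessions_per_scanner={"A": 4, "B": 4})
        panel = gen_multisite_panel(spec)
        per_scanner = panel.groupby("scanner_id")["is_rescan"].mean()
        assert np.all(per_scanner == 0.5)

    def test_missing_vendor_raises(self):
        with pytest.raises(ValueError, match="vendor"):
            _panel_spec(vendor_of={"A": "V1"})

    def test_negative_cv_raises(self):
        with pytest.raises(ValueError, match="nonnegative"):
            _panel_spec(intra_scanner_cv_pct=-1.0)


class TestGeometricBrain:
    def test_sphere_volume_analytic(self):
        sphere = EllipsoidSpec(center_mm=(20, 20, 20), semi_axes_mm=(10, 10, 10), label=1)
        lm = gen_geometric_brain((40, 40, 40), [sphere], (1.0, 1.0, 1.0))
        count = int((lm.data == 1).sum())
        assert count == pytest.approx(4 / 3 * np.pi * 10**3, rel=0.02)

    def test_empty_regions_all_zero(self):
        lm = gen_geometric_brain((5, 5, 5), [], (1.0, 1.0, 1.0))
        assert not lm.data.any()

    def test_disjoint_ellipsoids_additive(self):
        e1 = EllipsoidSpec((8, 8, 8), (4, 4, 4), 1)
        e2 = EllipsoidSpec((24, 24, 8), (5, 4, 4), 2)
        both = gen_geometric_brain((32, 32, 16), [e1, e2], (1.0, 1.0, 1.0))
        only1 = gen_geometric_brain((32, 32, 16), [e1], (1.0, 1.0, 1.0))
        only2 = gen_geometric_brain((32, 32, 16), [e2], (1.0, 1.0, 1.0))
        assert (both.data == 1).sum() == (only1.data == 1).sum()
        assert (both.data == 2).sum() == (only2.data == 2).sum()
        assert (both.data > 0).sum() == (only1.data > 0).sum() + (only2.data > 0).sum()

    def test_last_region_wins_on_overlap(self):
        e1 = EllipsoidSpec((8, 8, 8), (4, 4, 4), 1)
        e2 = EllipsoidSpec((8, 8, 8), (2, 2, 2), 2)
        lm = gen_geometric_brain((16, 16, 16), [e1, e2], (1.0, 1.0, 1.0))
        assert lm.data[8, 8, 8] == 2

    def test_out_of_grid_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            gen_geometric_brain((10, 10, 10), [EllipsoidSpec((5, 5, 5), (8, 2, 2), 1)])
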