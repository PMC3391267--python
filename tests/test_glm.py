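"""HRF, design matrices, GLM fitting, trial betas, smoothing, ROI definition."""
import numpy as np
import pytest

import facemvpa as fm
from facemvpa.glm import _drift_columns


class TestGammaHrf:
    def test_zero_at_and_before_onset(self):
        t = np.array([0.0, 1.0, 2.25])
        assert np.all(fm.gamma_hrf(t) == 0.0)

    def test_peak_location_matches_calculus(self):
        """Numeric argmax on a 1-ms grid agrees with delta + alpha*tau = 4.75 s."""
        t = np.arange(0.0, 20.0, 0.001)
        h = fm.gamma_hrf(t)
        assert t[np.argmax(h)] == pytest.approx(4.75, abs=0.001)
        assert h.max() == pytest.approx(1.0, abs=1e-12)

    def test_nonnegative_and_monotone_decay_after_peak(self):
        t = np.arange(0.0, 40.0, 0.01)
        h = fm.gamma_hrf(t)
        assert np.all(h >= 0)
        tail = h[t > 4.75]
        assert np.all(np.diff(tail) <= 1e-15)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            fm.HrfParams(tau_s=0.0)
        with pytest.raises(ValueError):
            fm.HrfParams(delta_s=-1.0)


class TestDesignMatrix:
    def test_empty_design_gives_drift_and_constant_only(self):
        d = fm.EventDesign(run_id=1, events=[], tr_s=2.0, n_scans=10)
        dm = fm.build_design_matrix(d, drift_order=2)
        assert dm.regressor_kinds == ["drift", "drift", "constant"]

    def test_single_event_zero_drift(self):
        d = fm.EventDesign(
            run_id=1, events=[fm.Event(2.0, 1.5, "veridical", 0)], tr_s=2.0, n_scans=20
        )
        dm = fm.build_design_matrix(d, mode="trial", drift_order=0, stim_window=None)
        assert dm.regressor_names == ["trial_0000", "constant"]

    def test_trial_mode_column_count_on_default_run(self):
        d = fm.generate_experimental_design(run_id=1, seed=0)
        dm = fm.build_design_matrix(d, mode="trial", drift_order=1)
        assert dm.matrix.shape == (164, 72 + 1 + 1)
        trial_cols = dm.columns_of_kind("trial")
        assert [dm.regressor_names[i] for i in trial_cols[:2]] == ["trial_0000", "trial_0001"]

    def test_condition_mode_on_localizer(self):
        d = fm.generate_localizer_design(seed=0)
        dm = fm.build_design_matrix(d, mode="condition", drift_order=1)
        conds = [dm.regressor_names[i] for i in dm.columns_of_kind("condition")]
        assert conds == sorted(["faces", "objects", "houses", "scrambled_objects"])

    def test_exactly_one_constant(self):
        d = fm.generate_experimental_design(run_id=1, seed=0)
        dm = fm.build_design_matrix(d, mode="condition", drift_order=3)
        assert dm.regressor_kinds.count("constant") == 1


class TestFitGlm:
    def test_noiseless_recovery_is_exact(self, rng):
        d = fm.generate_experimental_design(run_id=1, seed=1)
        dm = fm.build_design_matrix(d, mode="condition", drift_order=1)
        true = rng.standard_normal((dm.matrix.shape[1], 7))
        Y = dm.matrix @ true
        fit = fm.fit_glm(Y, dm)
        np.testing.assert_allclose(fit.betas, true, atol=1e-8)

    def test_residuals_orthogonal_to_design(self, rng):
        d = fm.generate_experimental_design(run_id=1, seed=2)
        dm = fm.build_design_matrix(d, mode="condition", drift_order=2)
        Y = rng.standard_normal((dm.matrix.shape[0], 20))
        fit = fm.fit_glm(Y, dm)
        resid = Y - dm.matrix @ fit.betas
        scale = np.abs(dm.matrix.T @ Y).max()
        assert np.abs(dm.matrix.T @ resid).max() < 1e-6 * scale

    def test_zero_contrast_gives_zero_t(self, rng):
        d = fm.generate_localizer_design(seed=1)
        dm = fm.build_design_matrix(d, mode="condition")
        Y = rng.standard_normal((dm.matrix.shape[0], 5))
        fit = fm.fit_glm(Y, dm, contrasts={"zero": {"faces": 0.0}})
        np.testing.assert_array_equal(fit.contrast_t["zero"], 0.0)

    def test_type_one_error_near_nominal_on_pure_noise(self, rng):
        """Contrast t-map on white noise rejects ~5% of voxels two-tailed."""
        from scipy import stats as sps

        d = fm.generate_localizer_design(seed=2)
        dm = fm.build_design_matrix(d, mode="condition", drift_order=1)
        Y = rng.standard_normal((dm.matrix.shape[0], 4000))
        fit = fm.fit_glm(Y, dm, contrasts={"fvo": {"faces": 1.0, "objects": -1.0}})
        crit = sps.t.isf(0.025, fit.dof)
        rate = np.mean(np.abs(fit.contrast_t["fvo"]) > crit)
        se = np.sqrt(0.05 * 0.95 / 4000)
        assert abs(rate - 0.05) < 4 * se

    def test_scan_mismatch_rejected(self, rng):
        d = fm.generate_experimental_design(run_id=1, seed=1)
        dm = fm.build_design_matrix(d, mode="condition")
        with pytest.raises(ValueError, match="scan count"):
            fm.fit_glm(rng.standard_normal((10, 3)), dm)


class TestTrialBetas:
    def test_voxel_order_equivariance(self, small_geometry, small_design_params, noiseless):
        gt = fm.make_ground_truth("holistic", small_geometry, seed=3)
        d = fm.generate_experimental_design(1, seed=3, params=small_design_params)
        b = fm.simulate_behavior(d, seed=3)
        bold = fm.simulate_bold_run(d, b, gt, noiseless, seed=3)
        idx = gt.roi_masks["ffa_like"]
        te = fm.estimate_trial_betas(bold, d, behavior=b, roi_mask=idx)
        perm = np.array([3, 1, 0, 2, 5, 4, 7, 6, 9, 8])
        te_p = fm.estimate_trial_betas(bold, d, behavior=b, roi_mask=idx[perm])
        np.testing.assert_allclose(te_p.amplitudes, te.amplitudes[perm], atol=1e-10)

    def test_all_zero_data_gives_zero_betas(self, small_design_params):
        d = fm.generate_experimental_design(1, seed=4, params=small_design_params)
        bold = fm.BoldRun(np.zeros((4, 4, 2, d.n_scans)), tr_s=2.0, run_id=1)
        te = fm.estimate_trial_betas(bold, d)
        np.testing.assert_array_equal(te.amplitudes, 0.0)

    def test_collinear_trials_rejected(self):
        d = fm.EventDesign(
            run_id=1,
            events=[fm.Event(8.0, 4.0, "veridical", 0), fm.Event(12.0, 4.0, "scrambled", 1)],
            tr_s=2.0,
            n_scans=30,
            lead_in_s=8.0,
            lead_out_s=36.0,
        )
        # overwrite with co-onsetting trials to hit the estimability guard
        d.events = [fm.Event(8.0, 4.0, "veridical", 0), fm.Event(8.0, 4.0, "scrambled", 1)]
        bold = fm.BoldRun(np.zeros((2, 2, 1, 30)), tr_s=2.0, run_id=1)
        with pytest.raises(ValueError, match="collinear"):
            fm.estimate_trial_betas(bold, d, stim_window=None)

    def test_lss_close_to_lsa_on_noiseless_data(self, small_geometry, small_design_params, noiseless):
        gt = fm.make_ground_truth("holistic", small_geometry, seed=8)
        d = fm.generate_experimental_design(1, seed=8, params=small_design_params)
        b = fm.simulate_behavior(d, seed=8)
        bold = fm.simulate_bold_run(d, b, gt, noiseless, seed=8)
        idx = gt.roi_masks["ffa_like"]
        lsa = fm.estimate_trial_betas(bold, d, behavior=b, roi_mask=idx, method="lsa")
        lss = fm.estimate_trial_betas(bold, d, behavior=b, roi_mask=idx, method="lss")
        # LSS pools other trials, so it is biased relative to LSA on
        # overlapping responses; on noiseless data they still agree coarsely
        r = np.corrcoef(lsa.amplitudes.ravel(), lss.amplitudes.ravel())[0, 1]
        assert r > 0.8


class TestSmoothing:
    def test_fwhm_zero_identity(self, rng):
        v = rng.standard_normal((6, 6, 4))
        out = fm.smooth_volume(v, 0.0, (3.0, 3.0, 4.0))
        np.testing.assert_array_equal(out, v)

    def test_constant_volume_preserved(self):
        v = np.full((8, 8, 6), 3.7)
        out = fm.smooth_volume(v, 5.0, (3.0, 3.0, 4.0))
        np.testing.assert_allclose(out, 3.7, atol=1e-9)

    def test_impulse_mass_conserved(self):
        v = np.zeros((21, 21, 11))
        v[10, 10, 5] = 1.0
        out = fm.smooth_volume(v, 5.0, (3.0, 3.0, 4.0))
        assert out.sum() == pytest.approx(1.0, abs=1e-6)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            fm.smooth_volume(np.zeros((2, 2, 2)), -1.0, (3.0, 3.0, 4.0))


class TestDefineRoi:
    def test_subthreshold_map_returns_none(self):
        t_map = np.zeros((6, 6, 4))
        assert fm.define_roi(t_map, dof=100) is None

    def test_seed_selects_its_blob(self):
        t_map = np.zeros((10, 10, 4))
        t_map[1:3, 1:3, 1] = 10.0  # blob A
        t_map[7:9, 7:9, 2] = 10.0  # blob B
        roi = fm.define_roi(t_map, dof=50, component_seed=(2, 2, 1))
        coords = np.argwhere(roi.to_flat_bool(t_map.shape).reshape(t_map.shape))
        assert coords[:, 0].max() <= 2  # only blob A voxels

    def test_nearest_blob_when_seed_subthreshold(self):
        t_map = np.zeros((10, 10, 4))
        t_map[1:3, 1:3, 1] = 10.0
        t_map[7:9, 7:9, 2] = 10.0
        roi = fm.define_roi(t_map, dof=50, component_seed=(4, 3, 1))
        coords = np.argwhere(roi.to_flat_bool(t_map.shape).reshape(t_map.shape))
        assert coords[:, 0].max() <= 2

    def test_min_size_filters_small_components(self):
        t_map = np.zeros((10, 10, 4))
        t_map[1, 1, 1] = 10.0
        assert fm.define_roi(t_map, dof=50, min_size=2) is None

    def test_monotone_in_threshold(self, rng):
        """A stricter p-threshold never grows the selected component."""
        t_map = rng.standard_normal((12, 12, 6)) + 1.0
        seed_vox = tuple(np.unravel_index(np.argmax(t_map), t_map.shape))
        sizes = []
        for p in (0.05, 0.01, 0.001):
            roi = fm.define_roi(t_map, dof=60, p_threshold=p, component_seed=seed_vox)
            sizes.append(0 if roi is None else roi.size)
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_localizer_roi_recovers_truth_at_default_snr(self):
        """Dice >= 0.8 between defined and true ROI on a simulated localizer."""
        gt = fm.make_ground_truth("null", seed=1)
        loc = fm.generate_localizer_design(seed=1)
        bold = fm.simulate_localizer_bold(loc, gt, fm.NoiseModel(), seed=1)
        dm = fm.build_design_matrix(loc, mode="condition", drift_order=1)
        fit = fm.fit_glm(bold, dm, contrasts={"fvo": {"faces": 1.0, "objects": -1.0}})
        t_map = fit.contrast_t["fvo"].reshape(gt.geometry.shape)
        for name, center in [("ffa_like", (5, 5, 4)), ("ofa_like", (14, 14, 5))]:
            roi = fm.define_roi(t_map, fit.dof, component_seed=center, min_size=4, name=name)
            true = set(gt.roi_masks[name].tolist())
            found = set(roi.voxel_indices.tolist())
            dice = 2 * len(true & found) / (len(true) + len(found))
            assert dice >= 0.8, (name, dice)


def test_drift_columns_are_legendre_orthogonal_family():
    cols = _drift_columns(100, 3)
    assert cols.shape == (100, 3)
    # odd/even symmetry of Legendre polynomials about the run midpoint
    assert cols[0, 0] == -1.0 and cols[-1, 0] == 1.0
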