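import numpy as np
import pytest
from _oracles import ols_contrast_t

from permbold import (ConfigurationError, MaskError, SubjectGLM, TaskConfig,
                      build_design_matrix, compute_brain_mask, convolve_events,
                      default_contrast, first_pc_timecourse, fit_glm_contrast,
                      gamma_hrf, generate_cohort, subject_map,
                      default_cohort_spec)
from permbold.glm import COLUMN_ROLES, _design_core
from permbold.permutation import PermutationEngine
from permbold.simulate import ActiveRegion, CohortSpec, simulate_performance, \
    generate_task_sequence


class TestHrf:
    def test_peak_lands_at_the_sample_nearest_the_gamma_mode(self):
        """The continuous gamma density with shape a = peak/b + 1 has its
        mode at (a-1)b = peak; the sampled kernel must peak there too."""
        h = gamma_hrf(peak_seconds=6.0, dispersion=0.7, tr_seconds=2.0)
        t_dense = np.linspace(1e-6, 30, 200_001)
        shape = 6.0 / 0.7 + 1.0
        dens = (shape - 1) * np.log(t_dense) - t_dense / 0.7
        mode = t_dense[np.argmax(dens)]
        assert abs(mode - 6.0) < 1e-3
        times = np.arange(len(h.samples)) * 2.0
        assert times[np.argmax(h.samples)] == pytest.approx(6.0)

    def test_single_sample_kernel_is_unit(self):
        h = gamma_hrf(kernel_length=1)
        assert h.samples.shape == (1,) and h.samples[0] == 1.0

    @pytest.mark.parametrize("peak,disp,tr", [(4, 0.5, 1), (6, 0.7, 2),
                                              (8, 1.5, 2.5)])
    def test_samples_nonnegative_unit_peak(self, peak, disp, tr):
        h = gamma_hrf(peak, disp, tr)
        assert (h.samples >= 0).all()
        assert h.samples.max() == pytest.approx(1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            gamma_hrf(peak_seconds=-1)
        with pytest.raises(ConfigurationError):
            gamma_hrf(kernel_length=0)


class TestConvolveEvents:
    def test_zero_column_gives_zero_regressor(self):
        Z = np.zeros((30, 4))
        assert not convolve_events(Z, gamma_hrf()).any()

    def test_impulse_response_is_the_kernel(self):
        h = gamma_hrf()
        Z = np.zeros((30, 4))
        Z[0, 1] = 1
        out = convolve_events(Z, h)[:, 1]
        np.testing.assert_allclose(out[:len(h.samples)], h.samples)
        assert not out[len(h.samples):].any()

    def test_two_events_superpose(self):
        h = gamma_hrf()
        Z = np.zeros((40, 4))
        Z[3, 0] = 1
        Z[17, 0] = 1
        single = np.zeros((40, 4))
        oracle = np.zeros(40)
        for onset in (3, 17):
            shifted = np.zeros(40)
            k = min(len(h.samples), 40 - onset)
            shifted[onset:onset + k] = h.samples[:k]
            oracle += shifted
        np.testing.assert_allclose(convolve_events(Z, h)[:, 0], oracle,
                                   atol=1e-12)


class TestBrainMask:
    def test_constant_volume_fully_masked(self):
        assert compute_brain_mask(np.full((4, 4, 4), 7.0), 0.5).all()

    def test_blob_recovered_exactly(self):
        vol = np.ones((8, 8, 8))
        vol[2:6, 2:6, 2:6] = 100.0
        mask = compute_brain_mask(vol, 0.4)
        assert np.array_equal(mask, vol == 100.0)

    def test_mask_contains_all_truly_active_voxels(self, tiny_cohort):
        cohort, _ = tiny_cohort
        for ds in cohort:
            mask = compute_brain_mask(ds.bold.mean(axis=-1))
            assert mask[ds.truth != 0].all()

    def test_empty_mask_raises(self):
        # every voxel sits below threshold_fraction x the robust maximum
        vol = -np.ones((4, 4, 4))
        with pytest.raises(MaskError):
            compute_brain_mask(vol, 0.5)


class TestFirstPc:
    def test_rank_one_data_recovers_shared_timecourse(self, rng):
        n = 50
        s = np.sin(np.linspace(0, 6, n))
        offsets = rng.uniform(10, 20, size=(3, 3, 3))
        bold = offsets[..., None] + s
        mask = np.ones((3, 3, 3), bool)
        pc1 = first_pc_timecourse(bold, mask)
        sc = (s - s.mean())
        sc /= np.linalg.norm(sc)
        np.testing.assert_allclose(pc1, sc, atol=1e-10)

    def test_unit_norm_and_sign_convention(self, rng):
        bold = rng.standard_normal((4, 4, 3, 60))
        mask = np.ones((4, 4, 3), bool)
        pc1 = first_pc_timecourse(bold, mask)
        assert np.linalg.norm(pc1) == pytest.approx(1.0)
        M = bold[mask].T
        Mc = M - M.mean(0)
        assert pc1 @ Mc.mean(1) >= 0

    def test_matches_covariance_eigendecomposition(self, rng):
        bold = rng.standard_normal((5, 5, 2, 40))
        mask = np.ones((5, 5, 2), bool)
        pc1 = first_pc_timecourse(bold, mask)
        M = bold[mask].T
        Mc = M - M.mean(0)
        # temporal covariance oracle
        evals, evecs = np.linalg.eigh(Mc @ Mc.T)
        top = evecs[:, -1]
        if top @ pc1 < 0:
            top = -top
        np.testing.assert_allclose(pc1, top, atol=1e-8)
        var_svd = np.linalg.svd(Mc, compute_uv=False)[0] ** 2
        assert var_svd == pytest.approx(evals[-1], rel=1e-8)

    def test_constant_data_raises(self):
        with pytest.raises(MaskError):
            first_pc_timecourse(np.ones((3, 3, 3, 20)), np.ones((3, 3, 3), bool))


class TestDesignMatrix:
    def _inputs(self, n=60):
        rng = np.random.default_rng(0)
        pc1 = rng.standard_normal(n)
        motion = rng.standard_normal((n, 6))
        seq = generate_task_sequence(TaskConfig(n_trials=n, seed=0))
        Z = simulate_performance(seq, 0.9, 0.9, 0)
        return pc1, motion, Z, gamma_hrf()

    def test_standard_inputs_give_p_11(self):
        pc1, motion, Z, h = self._inputs()
        dm = build_design_matrix(pc1, motion, Z, h)
        assert dm.p == 11
        assert dm.column_roles == COLUMN_ROLES

    def test_event_columns_match_convolution(self):
        pc1, motion, Z, h = self._inputs()
        dm = build_design_matrix(pc1, motion, Z, h)
        np.testing.assert_array_equal(dm.X[:, 7], convolve_events(Z, h)[:, 0])

    def test_missing_motion_rejected(self):
        pc1, motion, Z, h = self._inputs()
        with pytest.raises(ConfigurationError):
            build_design_matrix(pc1, motion[:, :5], Z, h)
        with pytest.raises(ConfigurationError):
            build_design_matrix(pc1[:-1], motion, Z, h)


class TestGlmContrast:
    def test_matches_normal_equations_ols_on_random_instances(self):
        """Pseudo-inverse contrast t equals a textbook OLS solve (same
        implicit-intercept df) to 1e-8 on 100 seeded 40 x 5 problems."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            X = rng.standard_normal((40, 5))
            y = rng.standard_normal(40)
            C = rng.standard_normal(5)
            t = fit_glm_contrast(y, X, C)
            assert t == pytest.approx(ols_contrast_t(y, X, C), abs=1e-8)

    def test_zero_contrast_gives_zero_t(self, rng):
        X = rng.standard_normal((30, 4))
        y = rng.standard_normal(30)
        assert fit_glm_contrast(y, X, np.zeros(4)) == 0.0

    def test_duplicated_column_keeps_unaffected_contrast(self, rng):
        X = rng.standard_normal((40, 4))
        y = rng.standard_normal(40)
        Xdup = np.column_stack([X, X[:, 0]])
        # contrast touching only non-duplicated columns
        C = np.array([0.0, 1.0, -1.0, 0.0])
        Cdup = np.array([0.0, 1.0, -1.0, 0.0, 0.0])
        t_plain = fit_glm_contrast(y, X, C)
        t_dup = fit_glm_contrast(y, Xdup, Cdup)
        # same fitted subspace, same residuals; df identical since the
        # duplicate adds no rank
        assert t_dup == pytest.approx(t_plain, abs=1e-8)

    def test_scale_equivariance(self, rng):
        X = rng.standard_normal((50, 6))
        y = rng.standard_normal(50)
        C = rng.standard_normal(6)
        t = fit_glm_contrast(y, X, C)
        assert fit_glm_contrast(3.7 * y, X, C) == pytest.approx(t, rel=1e-10)

    def test_adding_design_span_shifts_numerator_consistently(self, rng):
        X = rng.standard_normal((50, 6))
        y = rng.standard_normal(50)
        C = rng.standard_normal(6)
        b = rng.standard_normal(6)
        Xc = X - X.mean(0)
        G = np.linalg.inv(Xc.T @ Xc)

        def cbeta(yy):
            yc = yy - yy.mean()
            return float(C @ (G @ Xc.T @ yc))

        # residuals are unchanged, the contrast numerator shifts by C'b
        assert cbeta(y + X @ b) == pytest.approx(cbeta(y) + float(C @ b),
                                                 rel=1e-8)

    def test_df_of_standard_full_rank_design(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((200, 11))
        assert _design_core(X)[3] == 188


class TestSubjectMap:
    def test_active_voxel_has_largest_absolute_t(self):
        cfg = TaskConfig(n_trials=80, seed=2)
        Z = simulate_performance(generate_task_sequence(cfg), 0.9, 0.9, 2)
        region = ActiveRegion(voxels=np.array([[8, 8, 6]]),
                              amplitude={"control": 5.0}, event=1)
        spec = CohortSpec(n_per_group=1, active_regions=(region,),
                          noise_sd=0.05, motion_sd=0.05, drift_amplitude=1.0,
                          motion_coupling=0.2)
        from permbold.simulate import simulate_subject

        ds = simulate_subject(cfg, spec, Z, "control", 7)
        bm = subject_map(ds)
        assert np.unravel_index(np.argmax(np.abs(bm.tmap)), bm.tmap.shape) \
            == (8, 8, 6)

    def test_pure_noise_tmap_mean_near_zero(self, tiny_null_cohort):
        cohort, _ = tiny_null_cohort
        ds = cohort[0]
        bm = subject_map(ds)
        vals = bm.tmap[bm.mask]
        se = vals.std() / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se

    def test_results_summary_mentions_key_quantities(self, tiny_cohort):
        cohort, _ = tiny_cohort
        ds = cohort[0]
        res = SubjectGLM(ds.bold, ds.Z, ds.motion).fit()
        text = res.summary()
        assert "df:" in text and "188" in text and "11" in text

    def test_engine_fast_path_equals_direct_glm(self, tiny_cohort):
        """The Frisch-Waugh reduced solve used inside the permutation
        engine reproduces the full 11-column pseudo-inverse t-map."""
        cohort, _ = tiny_cohort
        eng = PermutationEngine(cohort[:2], smoothing_sd_mm=0.0)
        for ds, fast in zip(cohort[:2], eng.subject_maps()):
            direct = subject_map(ds).tmap
            np.testing.assert_allclose(fast, direct, atol=1e-10)

    def test_permuted_and_true_maps_exchangeable_under_null(self, tiny_null_cohort):
        """On a no-activation cohort the true-Z map has the same
        distribution as permuted-Z maps: compare spread and extremes."""
        cohort, _ = tiny_null_cohort
        eng = PermutationEngine(cohort[:1], smoothing_sd_mm=0.0)
        true_map = eng.subject_maps()[0]
        rng = np.random.default_rng(0)
        n = cohort[0].bold.shape[-1]
        perm_sds = []
        for _ in range(20):
            pm = eng.subject_maps([rng.permutation(n)])[0]
            perm_sds.append(pm[eng.group_mask].std())
        true_sd = true_map[eng.group_mask].std()
        lo, hi = np.min(perm_sds), np.max(perm_sds)
        span = hi - lo
        assert lo - span < true_sd < hi + span
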