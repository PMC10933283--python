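"""Framewise displacement, design construction, AR(1) GLM estimation."""

import numpy as np
import pytest

import threatdecode as td
from threatdecode.events import EventSchedule
from threatdecode.glm import BoldRun, ConfoundSet, double_gamma_hrf, fit_glm_ar1
from threatdecode.simulate import NoiseSpec, ar1_noise_lag1_autocorr


class TestFramewiseDisplacement:
    def test_constant_motion_is_zero(self):
        fd = td.compute_framewise_displacement(np.ones((10, 6)))
        assert np.all(fd == 0.0)

    def test_translation_step(self):
        motion = np.zeros((5, 6))
        motion[3:, 1] = 0.3
        fd = td.compute_framewise_displacement(motion)
        assert fd[3] == pytest.approx(0.3)
        assert fd[0] == 0.0 and fd[2] == 0.0 and fd[4] == 0.0

    def test_rotation_step_uses_50mm_radius(self):
        motion = np.zeros((5, 6))
        motion[2:, 4] = 0.01  # radians
        fd = td.compute_framewise_displacement(motion)
        assert fd[2] == pytest.approx(0.5)  # 50 mm x 0.01 rad

    def test_wrong_column_count_raises(self):
        with pytest.raises(ValueError, match="6 columns"):
            td.compute_framewise_displacement(np.zeros((10, 5)))


def test_hrf_matches_reference_shape():
    """Our double-gamma must match nilearn's SPM kernel up to scale."""
    from nilearn.glm.first_level import spm_hrf

    dt = 0.125
    ours = double_gamma_hrf(dt)
    ref = spm_hrf(dt, oversampling=1, time_length=32.0)
    n = min(len(ours), len(ref))
    r = np.corrcoef(ours[:n], ref[:n])[0, 1]
    assert r > 0.999


class TestDesignMatrix:
    def single_trial_schedule(self):
        sched = td.generate_event_schedule("conditioning", seed=0)
        return EventSchedule("conditioning", sched.trials[:1])

    def test_single_trial_single_task_column(self):
        sched = self.single_trial_schedule()
        tr = 1.0
        design = td.build_design_matrix(sched, None, tr=tr, n_vols=60)
        assert len(design.task_names) == 1
        col = design.column(design.task_names[0])
        onset = sched.trials[0].cs_onset_s
        lag = np.argmax(col) * tr - onset
        # 6 s boxcar + ~5 s HRF peak delay puts the maximum 5-11 s after onset
        assert 5.0 <= lag <= 11.0

    def test_empty_schedule_has_only_nuisance(self):
        design = td.build_design_matrix(EventSchedule("conditioning", []), None,
                                        tr=2.0, n_vols=50)
        assert design.task_names == []
        assert "poly0" in design.names

    def test_full_schedule_task_grid(self):
        sched = td.generate_event_schedule("conditioning", seed=1)
        design = td.build_design_matrix(sched, None, tr=2.0, n_vols=400)
        assert len(design.task_names) == 8  # 4 TB x 2 CS
        assert "shock" in design.names
        assert any(nm.startswith("cosine") for nm in design.names)

    def test_censored_volume_one_hot(self):
        sched = self.single_trial_schedule()
        motion = np.zeros((60, 6))
        motion[40:, 0] = 1.0  # 1 mm jump at volume 40
        conf = ConfoundSet.from_motion(motion)
        design = td.build_design_matrix(sched, conf, tr=1.0, n_vols=60)
        assert np.array_equal(design.censored_volumes, [40])
        col = design.column("censor0040")
        assert col[40] == 1.0 and col.sum() == 1.0

    def test_event_outside_run_raises(self):
        sched = td.generate_event_schedule("conditioning", seed=0)
        with pytest.raises(ValueError, match="run ends"):
            td.build_design_matrix(sched, None, tr=2.0, n_vols=10)

    def test_bad_tr_raises(self):
        with pytest.raises(ValueError, match="tr"):
            td.build_design_matrix(EventSchedule("conditioning", []), None,
                                   tr=0.0, n_vols=10)


class TestFitGlmAr1:
    def design_and_schedule(self, tr=2.0, n_vols=400):
        sched = td.generate_event_schedule("conditioning", seed=2)
        return sched, td.build_design_matrix(sched, None, tr=tr, n_vols=n_vols)

    def test_noiseless_exact_recovery(self):
        _, design = self.design_and_schedule()
        rng = np.random.default_rng(0)
        beta_true = rng.standard_normal((design.matrix.shape[1], 3))
        bold = BoldRun(design.matrix @ beta_true, tr=2.0)
        result = fit_glm_ar1(bold, design)
        assert np.abs(result.betas - beta_true).max() < 1e-8

    def test_white_noise_matches_plain_least_squares(self):
        _, design = self.design_and_schedule()
        rng = np.random.default_rng(1)
        beta_true = rng.standard_normal((design.matrix.shape[1], 2))
        Y = design.matrix @ beta_true + 0.5 * rng.standard_normal((design.n_vols, 2))
        gls = fit_glm_ar1(BoldRun(Y, 2.0), design)        # rho estimated (~0)
        ols = fit_glm_ar1(BoldRun(Y, 2.0), design, rho=0.0)
        assert abs(gls.rho) < 0.15
        # compare the task betas; the nearly collinear drift nuisance block
        # (cosine vs polynomial) soaks up any tiny rho-induced difference
        g = np.stack([gls.beta_map(nm) for nm in design.task_names])
        o = np.stack([ols.beta_map(nm) for nm in design.task_names])
        assert np.abs(g - o).max() < 0.02

    def test_ar1_rho_recovered(self):
        sched, design = self.design_and_schedule(tr=1.5, n_vols=520)
        rng = np.random.default_rng(2)
        V = 10
        rho = 0.5
        e = np.empty((design.n_vols, V))
        e[0] = rng.standard_normal(V)
        innov = rng.standard_normal((design.n_vols, V)) * np.sqrt(1 - rho**2)
        for t in range(1, design.n_vols):
            e[t] = rho * e[t - 1] + innov[t]
        Y = design.matrix @ rng.standard_normal((design.matrix.shape[1], V)) + e
        result = fit_glm_ar1(BoldRun(Y, 1.5), design)
        assert 0.4 <= result.rho <= 0.6

    def test_censoring_equals_row_deletion_under_ols(self):
        """A one-hot spike regressor is exactly row deletion for the OLS fit."""
        sched = td.generate_event_schedule("conditioning", seed=3)
        n_vols = 400
        rng_m = np.random.default_rng(30)
        motion = np.cumsum(rng_m.standard_normal((n_vols, 6)) * 0.001, axis=0)
        motion[123:, 0] += 1.0
        conf = ConfoundSet.from_motion(motion)
        design = td.build_design_matrix(sched, conf, tr=2.0, n_vols=n_vols)
        rng = np.random.default_rng(3)
        Y = rng.standard_normal((n_vols, 2))
        withspike = fit_glm_ar1(BoldRun(Y, 2.0), design, rho=0.0)

        keep = np.ones(n_vols, bool)
        keep[123] = False
        spike_col = design.names.index("censor0123")
        cols = [j for j in range(design.matrix.shape[1]) if j != spike_col]
        beta_del, *_ = np.linalg.lstsq(design.matrix[keep][:, cols], Y[keep], rcond=None)
        ours = withspike.betas[cols]
        assert np.abs(ours - beta_del).max() < 1e-8

    def test_rank_deficiency_raises(self):
        _, design = self.design_and_schedule()
        mat = np.column_stack([design.matrix, design.matrix[:, 0]])
        bad = td.DesignMatrix(mat, design.names + ["dup"], design.task_names)
        with pytest.raises(ValueError, match="rank"):
            fit_glm_ar1(BoldRun(np.zeros((design.n_vols, 1)), 2.0), bad)

    def test_underdetermined_raises(self):
        _, design = self.design_and_schedule()
        with pytest.raises(ValueError, match="underdetermined"):
            fit_glm_ar1(BoldRun(np.zeros((5, 1)), 2.0),
                        td.DesignMatrix(design.matrix[:5], design.names,
                                        design.task_names))


class TestGenerateBoldRun:
    def test_noiseless_equals_task_prediction(self):
        sched = td.generate_event_schedule("extinction", seed=0)
        V = 4
        rng = np.random.default_rng(0)
        design = td.build_design_matrix(sched, None, tr=2.0,
                                        n_vols=int(np.ceil((sched.duration_s + 20) / 2)))
        betas = {nm: rng.standard_normal(V) for nm in design.task_names}
        noise = NoiseSpec(sd=0.0, drift_amplitude=0.0, motion_step_sd=0.0)
        bold, conf = td.generate_bold_run(sched, betas, tr=2.0, noise=noise, seed=1)
        B = np.stack([betas[nm] for nm in design.task_names])
        expected = design.matrix[:, [design.names.index(nm) for nm in design.task_names]] @ B
        assert np.abs(bold.data - expected).max() < 1e-12

    def test_ar1_autocorrelation_near_target(self):
        sched = td.generate_event_schedule("conditioning", seed=1)
        noise = NoiseSpec(ar1_rho=0.4, sd=1.0, motion_step_sd=0.0)
        bold, _ = td.generate_bold_run(sched, {}, tr=1.5, noise=noise, seed=2,
                                       n_vols=520)
        # no task betas were supplied, so the series is pure AR(1) noise
        assert abs(ar1_noise_lag1_autocorr(bold.data) - 0.4) <= 0.1

    def test_spike_volume_exceeds_censor_threshold(self):
        sched = td.generate_event_schedule("extinction", seed=0)
        noise = NoiseSpec(spike_volumes=(40,))
        _, conf = td.generate_bold_run(sched, {}, tr=2.0, noise=noise, seed=3)
        assert conf.fd[40] > 0.9
        assert conf.censor[40]

    def test_schedule_past_run_end_raises(self):
        sched = td.generate_event_schedule("conditioning", seed=0)
        with pytest.raises(ValueError, match="run ends"):
            td.generate_bold_run(sched, {}, tr=2.0, noise=NoiseSpec(), seed=0, n_vols=20)


def test_confounds_tsv_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    motion = np.cumsum(rng.standard_normal((50, 6)) * 0.01, axis=0)
    conf = ConfoundSet.from_motion(motion)
    conf.save_tsv(tmp_path / "confounds.tsv")
    loaded = ConfoundSet.load_tsv(tmp_path / "confounds.tsv")
    assert np.allclose(loaded.motion, conf.motion)
    assert np.allclose(loaded.fd, conf.fd)
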