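"""L2-logistic training, forced choice, and cross-validation contracts."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

import threatdecode as td
from threatdecode.decoding import _cv_forced_choice, _fit_batch, _reduce_design


class TestTrainRidgeLogistic:
    def test_separable_1d_weight_sign(self):
        X = np.array([[1.0], [1.2], [-1.0], [-0.8]])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        model = td.train_ridge_logistic(X, y, c=1.0)
        assert model.w[0] > 0

    def test_penalty_dominated_limit(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 5))
        y = np.sign(rng.standard_normal(40))
        big = td.train_ridge_logistic(X, y, c=1.0)
        tiny = td.train_ridge_logistic(X, y, c=1e-8)
        assert np.linalg.norm(tiny.w) < 1e-4 < np.linalg.norm(big.w)

    @pytest.mark.parametrize("c", [0.05, 1.0, 30.0])
    def test_matches_independent_solver(self, c):
        """sklearn minimizes the same objective (C = c, unpenalized intercept)."""
        rng = np.random.default_rng(3)
        X = rng.standard_normal((10, 3))
        y = np.array([1.0] * 5 + [-1.0] * 5)
        ours = td.train_ridge_logistic(X, y, c=c)
        ref = LogisticRegression(C=c, tol=1e-10, max_iter=10000).fit(X, (y > 0).astype(int))
        assert np.abs(ours.w - ref.coef_[0]).max() < 1e-4
        assert abs(ours.b - ref.intercept_[0]) < 1e-4

    def test_reduced_path_equals_full_solution(self):
        """With more voxels than rows the SVD shortcut must be exact."""
        rng = np.random.default_rng(4)
        X = rng.standard_normal((20, 60))
        y = np.array([1.0] * 10 + [-1.0] * 10)
        ours = td.train_ridge_logistic(X, y, c=0.5)
        ref = LogisticRegression(C=0.5, tol=1e-10, max_iter=10000).fit(X, (y > 0).astype(int))
        assert np.abs(ours.w - ref.coef_[0]).max() < 1e-4

    def test_batched_fit_matches_individual(self):
        rng = np.random.default_rng(5)
        Z = rng.standard_normal((30, 8))
        Y = np.sign(rng.standard_normal((30, 6)))
        W, B = _fit_batch(Z, Y, 1.0)
        for j in range(6):
            Wj, Bj = _fit_batch(Z, Y[:, j], 1.0)
            assert np.abs(W[:, j] - Wj[:, 0]).max() < 1e-5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            td.train_ridge_logistic(np.ones((4, 2)), np.ones(4), c=1.0)

    def test_nonfinite_rejected(self):
        X = np.ones((4, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            td.train_ridge_logistic(X, np.array([1.0, 1, -1, -1]), c=1.0)


class TestForcedChoice:
    def model(self):
        return td.DecoderModel(w=np.array([1.0, 0.0]), b=0.2, c=1.0)

    def test_higher_score_wins(self):
        res = td.forced_choice_accuracy(
            self.model(), np.array([[0.7, 0.0]]), np.array([[0.3, 0.0]])
        )
        assert res.accuracy == 1.0

    def test_exact_tie_scores_half(self):
        x = np.array([[0.4, 1.0]])
        res = td.forced_choice_accuracy(self.model(), x, x.copy())
        assert res.accuracy == 0.5

    def test_common_shift_invariance(self):
        rng = np.random.default_rng(0)
        xp = rng.standard_normal((30, 2))
        xm = rng.standard_normal((30, 2))
        u = rng.standard_normal((30, 2))
        base = td.forced_choice_accuracy(self.model(), xp, xm)
        shifted = td.forced_choice_accuracy(self.model(), xp + u, xm + u)
        assert np.array_equal(base.per_participant, shifted.per_participant)

    def test_feature_mismatch_raises(self):
        with pytest.raises(ValueError, match="feature dimension"):
            self.model().decision_values(np.ones((3, 5)))


class TestCrossValidation:
    def test_identical_seed_identical_accuracy(self, signal_cohort, contrast, fast_cv):
        a = td.crossvalidate_decoding(signal_cohort, contrast, fast_cv)
        b = td.crossvalidate_decoding(signal_cohort, contrast, fast_cv)
        assert a.accuracy == b.accuracy
        assert np.array_equal(a.per_participant, b.per_participant)

    def test_strong_signal_beats_chance(self, signal_cohort, contrast, fast_cv):
        res = td.crossvalidate_decoding(signal_cohort, contrast, fast_cv)
        # Bayes ceiling is 0.92; finite-sample estimation keeps CV below it
        assert res.accuracy > 0.75

    def test_accuracy_monotone_in_effect_size(self, contrast):
        cv = td.CVConfig(repeats=2, grid=(1.0,), seed=1)
        accs = []
        for delta in (0.0, 0.7, 1.4, 2.8):
            coh = td.paired_cohort(200, 30, delta=delta, seed=17, n_signal=10)
            accs.append(td.crossvalidate_decoding(coh, contrast, cv).accuracy)
        assert all(b >= a for a, b in zip(accs, accs[1:]))

    def test_label_permutation_null_is_centered(self, contrast):
        """Mean CV accuracy over 100 within-participant label swaps ~ 0.5."""
        coh = td.paired_cohort(100, 40, delta=1.5, seed=3, n_signal=10)
        Xp, Xm = coh.values[:, 0, :], coh.values[:, 1, :]
        rng = np.random.default_rng(0)
        swaps = rng.integers(0, 2, size=(100, 100)) * 2.0 - 1.0
        cv = td.CVConfig(repeats=1, grid=(1.0,), seed=0)
        accs, _ = _cv_forced_choice(Xp, Xm, swaps, cv)
        assert 0.47 <= accs.mean() <= 0.53

    def test_inner_selection_prefers_smaller_c_on_ties(self):
        # all-zero features: every c ties at exactly 0.5; smallest c wins
        coh = td.paired_cohort(30, 5, delta=0.0, seed=2,
                               noise_sd=0.0, participant_sd=0.0)
        cv = td.CVConfig(repeats=1, grid=(0.01, 1.0, 100.0), seed=0)
        model = td.fit_decoder(coh, td.Contrast("conditioning", 1, "CSplus"), cv)
        assert model.c == 0.01

    def test_too_few_participants_raises(self, contrast):
        coh = td.paired_cohort(4, 5, delta=0.0, seed=0)
        with pytest.raises(ValueError, match="fewer participants"):
            td.crossvalidate_decoding(coh, contrast, td.CVConfig(k=5, repeats=1))


class TestApplyDecoder:
    def test_resubstitution_identity(self, signal_cohort, contrast):
        cv = td.CVConfig(repeats=1, grid=(1.0,), seed=0)
        model = td.fit_decoder(signal_cohort, contrast, cv)
        Xp, Xm = signal_cohort.values[:, 0, :], signal_cohort.values[:, 1, :]
        direct = td.forced_choice_accuracy(model, Xp, Xm)
        applied = td.apply_decoder(model, signal_cohort, contrast)
        assert applied.accuracy == direct.accuracy

    def test_participant_offsets_do_not_change_accuracy(self, signal_cohort, contrast):
        cv = td.CVConfig(repeats=1, grid=(1.0,), seed=0)
        model = td.fit_decoder(signal_cohort, contrast, cv)
        shifted = signal_cohort.subset_participants(np.arange(signal_cohort.n_participants))
        rng = np.random.default_rng(8)
        offsets = rng.standard_normal((shifted.n_participants, 1, shifted.n_voxels))
        shifted.values = shifted.values + offsets  # same shift on both maps
        a = td.apply_decoder(model, signal_cohort, contrast)
        b = td.apply_decoder(model, shifted, contrast)
        assert np.array_equal(a.per_participant, b.per_participant)

    def test_feature_space_mismatch_raises(self, community_cohort, small_atlas, contrast):
        data, _ = community_cohort
        cv = td.CVConfig(repeats=1, grid=(1.0,), seed=0)
        sel_a = (small_atlas, [1, 2])
        sel_b = (small_atlas, [3, 4])
        model = td.fit_decoder(data, contrast, cv, selector=sel_a)
        with pytest.raises(ValueError, match="voxel index record"):
            td.apply_decoder(model, data, contrast, selector=sel_b)

    def test_external_null_cohort_near_chance(self, contrast):
        train = td.paired_cohort(60, 30, delta=1.5, seed=1, n_signal=10)
        cv = td.CVConfig(repeats=1, grid=(1.0,), seed=0)
        model = td.fit_decoder(train, contrast, cv)
        null = td.paired_cohort(300, 30, delta=0.0, seed=2)
        res = td.apply_decoder(model, null, contrast)
        assert 0.44 <= res.accuracy <= 0.56  # binomial chance interval, N=300


def test_model_round_trip(tmp_path, signal_cohort, contrast):
    cv = td.CVConfig(repeats=1, grid=(1.0,), seed=0)
    model = td.fit_decoder(signal_cohort, contrast, cv)
    model.save(tmp_path / "model.json")
    loaded = td.DecoderModel.load(tmp_path / "model.json")
    assert np.allclose(loaded.w, model.w)
    assert loaded.feature_space_id == model.feature_space_id
    assert loaded.trained_on == contrast.label


def test_reduce_design_shortcut_only_when_wide():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((10, 4))
    Z, Vt = _reduce_design(X)
    assert Vt is None and Z is X
    Xw = rng.standard_normal((4, 10))
    Z, Vt = _reduce_design(Xw)
    assert Z.shape == (4, 4) and np.allclose(Z @ Vt, Xw)
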