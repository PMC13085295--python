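"""MCR-ALS: initialization, constraints, figures of merit and one-by-one
quantification against generator ground truth."""

import itertools

import numpy as np
import pytest

from mixcal.mcr import (MCRALS, McrConstraints, apply_correlation_constraint,
                        apply_unimodality, initialize_profiles, lack_of_fit,
                        quantify_test_samples, run_mcr_als)


class TestInitialization:
    def test_pure_standards_returns_windowed_profiles(self, clean_xy, pure, pure_window):
        S0 = initialize_profiles(clean_xy["windowed"], 4, method="pure_standards", pure=pure)
        assert np.array_equal(S0, pure_window.absorptivity)

    def test_pure_standards_without_pure_rejected(self, clean_xy):
        with pytest.raises(ValueError, match="requires"):
            initialize_profiles(clean_xy["windowed"], 4, method="pure_standards")

    def test_purest_rows_finds_orthogonal_rows(self):
        # 4 orthogonal spectra + mixtures; brute-force subset oracle
        rng = np.random.default_rng(0)
        basis = np.linalg.qr(rng.normal(size=(20, 4)))[0].T  # 4 x 20 orthonormal
        basis = np.abs(basis) + 0.1
        basis = basis / np.linalg.norm(basis, axis=1, keepdims=True)
        mixes = np.array([[0.5, 0.5, 0, 0], [0.25, 0.25, 0.25, 0.25],
                          [0, 0.3, 0.7, 0], [0.1, 0.2, 0.3, 0.4]]) @ basis
        D = np.vstack([basis * 2.0, mixes])
        S0 = initialize_profiles(D, 4, method="purest_rows")
        # oracle: exhaustive search of the 4-subset maximizing the Gram det
        N = D / np.linalg.norm(D, axis=1, keepdims=True)
        best = max(itertools.combinations(range(8), 4),
                   key=lambda idx: np.linalg.det(N[list(idx)] @ N[list(idx)].T))
        assert sorted(best) == [0, 1, 2, 3]
        got = {tuple(np.round(S0[:, j], 12)) for j in range(4)}
        want = {tuple(np.round(D[i], 12)) for i in range(4)}
        assert got == want

    def test_k_one_selects_largest_norm_row(self):
        D = np.array([[1.0, 0, 0], [0, 3.0, 0], [0, 0, 2.0]])
        S0 = initialize_profiles(D, 1)
        assert np.array_equal(S0.ravel(), D[1])

    def test_k_above_rank_warns(self):
        D = np.outer([1.0, 2.0, 3.0], [1.0, 1.0, 1.0, 1.0])
        with pytest.warns(RuntimeWarning, match="rank"):
            initialize_profiles(D, 3)


class TestUnimodality:
    def test_already_unimodal_unchanged(self):
        v = [0.0, 1.0, 3.0, 2.0, 0.5]
        assert apply_unimodality(v).tolist() == v

    def test_secondary_peak_flattened_by_horizontal_rule(self):
        assert apply_unimodality([0, 2, 1, 3, 0]).tolist() == [0, 2, 2, 3, 0]

    def test_constant_profile_is_single_plateau(self):
        v = [0.4] * 6
        assert apply_unimodality(v).tolist() == v

    def test_idempotent(self):
        v = np.array([0.0, 2, 1, 3, 1, 2, 0.5, 0])
        once = apply_unimodality(v)
        assert np.array_equal(apply_unimodality(once), once)

    def test_exactly_one_strict_local_maximum(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            v = apply_unimodality(rng.normal(size=30), tol=1.0)
            m = np.argmax(v)
            assert np.all(np.diff(v[: m + 1]) >= 0)
            assert np.all(np.diff(v[m:]) <= 0)

    def test_global_maximum_position_preserved(self):
        v = np.array([0.0, 5, 1, 2, 9, 3, 4, 0])
        assert np.argmax(apply_unimodality(v)) == np.argmax(v)


class TestCorrelationConstraint:
    def test_identity_when_already_calibrated(self):
        c = np.array([1.0, 2.0, 3.0, 4.0])
        mask = np.array([True, True, True, False])
        out, slope, intercept = apply_correlation_constraint(c, mask, c[:3])
        assert (slope, intercept) == pytest.approx((1.0, 0.0))
        assert np.allclose(out, c)

    def test_affine_distortion_inverted(self):
        ref = np.array([2.0, 5.0, 8.0])
        c = np.r_[2 * ref + 3, [2 * 4.0 + 3]]  # test entry encodes t = 4
        mask = np.array([True, True, True, False])
        out, slope, intercept = apply_correlation_constraint(c, mask, ref)
        assert np.allclose(out[:3], ref)
        assert out[3] == pytest.approx(4.0)
        assert (slope, intercept) == pytest.approx((0.5, -1.5))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            apply_correlation_constraint([1.0, 1.0, 2.0], [True, True, False], [3.0, 4.0])

    def test_too_few_calibration_rows_rejected(self):
        with pytest.raises(ValueError, match="calibration rows"):
            apply_correlation_constraint([1.0, 2.0], [True, False], [1.0])


class TestLackOfFit:
    def test_zero_residual(self):
        D = np.array([[1.0, 2], [3, 4]])
        C = D.copy()
        S = np.eye(2)
        lof, r2 = lack_of_fit(D, C, S)
        assert (lof, r2) == (0.0, 100.0)

    def test_hand_arithmetic(self):
        D = np.ones((2, 2))
        C = np.array([[1.0, 0], [1, 1]])
        S = np.array([[1.0, 0], [1, -1]])  # C S^T = [[1,1],[1,0]]
        lof, r2 = lack_of_fit(D, C, S)
        assert lof == pytest.approx(50.0)
        assert r2 == pytest.approx(75.0)

    def test_halving_residual_halves_lof(self):
        rng = np.random.default_rng(2)
        D0 = rng.normal(size=(5, 7))
        C = rng.normal(size=(5, 2))
        S = rng.normal(size=(7, 2))
        E = D0 - C @ S.T
        lof1, _ = lack_of_fit(D0, C, S)
        lof2, _ = lack_of_fit(C @ S.T + E / 2, C, S)
        # same data denominator only when D is the same; compare pure ratio instead
        num1 = np.sqrt(np.sum(E**2))
        num2 = np.sqrt(np.sum((E / 2) ** 2))
        assert num2 == pytest.approx(num1 / 2)
        assert lof1 > lof2

    def test_all_zero_data_rejected(self):
        with pytest.raises(ValueError):
            lack_of_fit(np.zeros((2, 2)), np.zeros((2, 1)), np.zeros((2, 1)))


class TestAlsRun:
    def test_noiseless_resolution_recovers_truth(self, clean_xy, pure_window):
        X, Y = clean_xy["X_cal"], clean_xy["Y_cal"]
        cons = McrConstraints(correlation=Y, calibration_mask=np.ones(17, dtype=bool))
        res = run_mcr_als(X, pure_window.absorptivity, cons)
        assert res.lof_percent < 0.1
        for j in range(4):
            s, t = res.S[:, j], pure_window.absorptivity[:, j]
            cos = s @ t / (np.linalg.norm(s) * np.linalg.norm(t))
            assert cos >= 0.999

    def test_rank_one_system_recovered_up_to_scale(self, pure_window):
        s_true = pure_window.absorptivity[:, 0]
        conc = np.array([2.0, 5.0, 8.0, 11.0])
        D = np.outer(conc, s_true)
        cons = McrConstraints(correlation=conc[:, None],
                              calibration_mask=np.ones(4, dtype=bool))
        res = run_mcr_als(D, (s_true * 3.0)[:, None], cons)
        assert np.allclose(res.C.ravel(), conc, atol=1e-8)
        cos = res.S[:, 0] @ s_true / np.linalg.norm(res.S) / np.linalg.norm(s_true)
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_zero_residual_converges_at_iteration_two(self):
        C = np.array([[1.0, 2], [2, 1], [3, 1]])
        S = np.array([[0.5, 0.1], [0.2, 0.4], [0.3, 0.2], [0.1, 0.1]])
        D = C @ S.T
        cons = McrConstraints()
        res = run_mcr_als(D, S, cons)
        assert res.lof_percent == pytest.approx(0.0, abs=1e-10)
        assert res.r2_percent == pytest.approx(100.0, abs=1e-10)
        assert res.converged and res.n_iterations == 2

    def test_reconstruction_identity_bitwise(self, noisy_xy, pure_window):
        X, Y = noisy_xy["X_cal"], noisy_xy["Y_cal"]
        cons = McrConstraints(correlation=Y, calibration_mask=np.ones(17, dtype=bool))
        res = run_mcr_als(X, pure_window.absorptivity, cons)
        assert np.array_equal(X, res.C @ res.S.T + res.E)

    def test_nonnegativity_enforced(self, noisy_xy, pure_window):
        cons = McrConstraints(nonneg_C=True, nonneg_S=True)
        res = run_mcr_als(noisy_xy["X_cal"], pure_window.absorptivity, cons)
        assert res.C.min() >= -1e-12
        assert res.S.min() >= -1e-12

    def test_accepted_lof_sequence_nonincreasing(self, noisy_xy, pure_window):
        X, Y = noisy_xy["X_cal"], noisy_xy["Y_cal"]
        cons = McrConstraints(correlation=Y, calibration_mask=np.ones(17, dtype=bool))
        res = run_mcr_als(X, pure_window.absorptivity, cons)
        accepted = np.minimum.accumulate(res.lof_history)
        assert np.all(np.diff(accepted) <= 1e-9)
        # the retained solution is the best accepted iterate
        assert res.lof_percent <= min(res.lof_history) + 1e-9

    def test_nan_rejected(self, pure_window):
        D = np.full((3, 107), np.nan)
        with pytest.raises(ValueError, match="NaN"):
            run_mcr_als(D, pure_window.absorptivity, McrConstraints())


class TestQuantification:
    def test_noiseless_validation_within_1e5(self, clean_xy, pure_window):
        cons = McrConstraints(correlation=clean_xy["Y_cal"],
                              calibration_mask=np.ones(17, dtype=bool))
        pred = quantify_test_samples(clean_xy["X_cal"], clean_xy["X_val"], cons, pure=pure_window)
        assert pred.shape == (8, 4)
        assert np.max(np.abs(pred - clean_xy["Y_val"])) < 1e-5

    def test_duplicated_calibration_row_predicts_its_reference(self, noisy_xy, pure_window):
        cons = McrConstraints(correlation=noisy_xy["Y_cal"],
                              calibration_mask=np.ones(17, dtype=bool))
        pred = quantify_test_samples(noisy_xy["X_cal"], noisy_xy["X_cal"][:1], cons, pure=pure_window)
        assert np.max(np.abs(pred[0] - noisy_xy["Y_cal"][0])) < 0.2

    def test_order_permutation_invariant(self, noisy_xy, pure_window):
        cons = McrConstraints(correlation=noisy_xy["Y_cal"],
                              calibration_mask=np.ones(17, dtype=bool))
        perm = np.array([5, 2, 7, 0, 1, 3, 6, 4])
        a = quantify_test_samples(noisy_xy["X_cal"], noisy_xy["X_val"], cons, pure=pure_window)
        b = quantify_test_samples(noisy_xy["X_cal"], noisy_xy["X_val"][perm], cons, pure=pure_window)
        assert np.array_equal(a[perm], b)


class TestEstimatorSurface:
    def test_fit_predict_roundtrip(self, noisy_xy, pure):
        est = MCRALS(n_components=4, init="pure_standards")
        est.fit(noisy_xy["X_cal"], C_ref=noisy_xy["Y_cal"], pure=pure.restrict(224, 330))
        assert est.C_.shape == (17, 4)
        assert est.S_.shape == (107, 4)
        assert est.converged_
        rec = 100 * est.predict(noisy_xy["X_val"]) / noisy_xy["Y_val"]
        assert np.all(np.abs(rec.mean(axis=0) - 100) < 2)

    def test_get_params_roundtrip(self):
        est = MCRALS(n_components=3, unimodal_C=True)
        params = est.get_params()
        assert params["n_components"] == 3 and params["unimodal_C"]
        est2 = MCRALS(**params)
        assert est2.get_params() == params

    def test_at_least_one_constraint_required(self):
        with pytest.raises(ValueError, match="constraint"):
            McrConstraints(nonneg_C=False, nonneg_S=False)
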