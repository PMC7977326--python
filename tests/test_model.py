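"""Tests for the full two-block model layer: orthogonal estimation and
filtering, fitting, prediction, reduction identities and serialization."""

import numpy as np
import pytest

from go2pls import (
    GroupStructure,
    PenaltySpec,
    estimate_orthogonal,
    filter_orthogonal,
    fit,
    load_fit,
    metrics,
    predict,
    save_fit,
    simulate_exact,
    transform,
)


@pytest.fixture(scope="module")
def exact_data():
    return simulate_exact(seed=5, N=60, p=80, q=50, K=2, Kx=1, Ky=1)


@pytest.fixture(scope="module")
def exact_fit(exact_data):
    X, Y, _ = exact_data
    return fit(X, Y, K=2, Kx=1, Ky=1)


class TestEstimateOrthogonal:
    def test_kx0_empty(self, rng):
        X = rng.standard_normal((10, 6))
        T = rng.standard_normal((10, 2))
        Worth, Torth, Porth = estimate_orthogonal(X, T, 0)
        assert Worth.shape == (6, 0) and Torth.shape == (10, 0)

    def test_recovers_planted_orthogonal_direction(self, exact_data, exact_fit):
        X, Y, truth = exact_data
        cos = abs(exact_fit.Porth[:, 0] @ truth["Porth"][:, 0]) / (
            np.linalg.norm(exact_fit.Porth[:, 0])
            * np.linalg.norm(truth["Porth"][:, 0])
        )
        assert cos >= 0.99

    def test_rank_deficient_rejected(self, rng):
        T = rng.standard_normal((10, 1))
        X = T @ rng.standard_normal((1, 6))  # residual E = 0 => rank 0
        with pytest.raises(ValueError, match="rank"):
            estimate_orthogonal(X, T, 1)


class TestFilterOrthogonal:
    def test_empty_scores_identity(self, rng):
        X = rng.standard_normal((8, 5))
        assert np.array_equal(filter_orthogonal(X, np.zeros((8, 0))), X)

    def test_full_removal(self, rng):
        Torth = rng.standard_normal((12, 2))
        X = Torth @ rng.standard_normal((2, 7))
        assert np.allclose(filter_orthogonal(X, Torth), 0.0)

    def test_filtered_orthogonal_to_scores(self, rng):
        X = rng.standard_normal((15, 9))
        Torth = rng.standard_normal((15, 2))
        assert np.max(np.abs(Torth.T @ filter_orthogonal(X, Torth))) < 1e-10

    def test_collinear_scores_rejected(self, rng):
        t = rng.standard_normal(10)
        with pytest.raises(ValueError, match="collinear"):
            filter_orthogonal(rng.standard_normal((10, 4)),
                              np.column_stack([t, t]))


class TestFitInvariants:
    def test_unit_norm_loadings(self, exact_fit):
        assert np.allclose(np.linalg.norm(exact_fit.W, axis=0), 1.0, atol=1e-8)
        assert np.allclose(np.linalg.norm(exact_fit.C, axis=0), 1.0, atol=1e-8)

    def test_joint_scores_orthogonal(self, exact_fit):
        G = exact_fit.T.T @ exact_fit.T
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-6 * np.max(np.diag(G))

    def test_orthogonal_scores_orthogonal_to_joint(self, exact_fit):
        assert np.max(np.abs(exact_fit.Torth.T @ exact_fit.T)) < 1e-6
        assert np.max(np.abs(exact_fit.Uorth.T @ exact_fit.U)) < 1e-6

    def test_variance_fractions_sum_to_one(self, small_xy):
        X, Y = small_xy
        f = fit(X, Y, K=2, Kx=1, Ky=1)
        for side in ("x", "y"):
            assert sum(f.variance_summary[side].values()) == pytest.approx(
                1.0, abs=1e-8
            )

    def test_k_zero_rejected(self, small_xy):
        X, Y = small_xy
        with pytest.raises(ValueError):
            fit(X, Y, K=0)

    def test_too_many_components_rejected(self, small_xy):
        X, Y = small_xy
        with pytest.raises(ValueError):
            fit(X, Y, K=10, Kx=15, Ky=0)


class TestReductionIdentities:
    """GO2PLS with degenerate settings must coincide with the simpler methods."""

    def test_singleton_groups_equal_sparse(self, small_xy):
        X, Y = small_xy
        f_sparse = fit(X, Y, K=2, Kx=1, Ky=1, pen_x=PenaltySpec.sparse(keep=10))
        f_group = fit(X, Y, K=2, Kx=1, Ky=1,
                      pen_x=PenaltySpec.group(GroupStructure.singletons(40), keep=10))
        assert np.array_equal(f_sparse.W, f_group.W)
        assert np.array_equal(f_sparse.C, f_group.C)

    def test_lam_zero_equals_unpenalized(self, small_xy):
        X, Y = small_xy
        f0 = fit(X, Y, K=2, Kx=1, Ky=1)
        fz = fit(X, Y, K=2, Kx=1, Ky=1,
                 pen_x=PenaltySpec.sparse(lam=0.0), pen_y=PenaltySpec.sparse(lam=0.0))
        assert np.max(np.abs(f0.W - fz.W)) < 1e-10
        assert np.max(np.abs(f0.C - fz.C)) < 1e-10

    def test_plain_pls_matches_sequential_svd_oracle(self, rng):
        """Kx=Ky=0, no penalty: loadings match a dense-SVD-with-deflation oracle."""
        X = rng.standard_normal((25, 15))
        Y = rng.standard_normal((25, 12))
        f = fit(X, Y, K=2, Kx=0, Ky=0)
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        for k in range(2):
            U, _, Vt = np.linalg.svd(Yc.T @ Xc)
            assert abs(f.W[:, k] @ Vt[0]) >= 1 - 1e-8
            assert abs(f.C[:, k] @ U[:, 0]) >= 1 - 1e-8
            t = Xc @ Vt[0]
            u = Yc @ U[:, 0]
            Xc = Xc - np.outer(t, t @ Xc) / (t @ t)
            Yc = Yc - np.outer(u, u @ Yc) / (u @ u)

    def test_exact_low_rank_top_k_svd(self, rng):
        """On data with sample-orthogonal scores the top-K singular pairs of
        YᵀX are recovered exactly."""
        X, Y, truth = simulate_exact(seed=9, N=40, p=30, q=25, K=2, Kx=0, Ky=0)
        f = fit(X, Y, K=2, Kx=0, Ky=0)
        _, _, Vt = np.linalg.svd(
            (Y - Y.mean(0)).T @ (X - X.mean(0))
        )
        for k in range(2):
            assert abs(f.W[:, k] @ Vt[k]) >= 1 - 1e-8


class TestParameterRecovery:
    def test_noiseless_recovery(self):
        X, Y, truth = simulate_exact(seed=3, N=100, p=500, q=200, K=2, Kx=1, Ky=1)
        f = fit(X, Y, K=2, Kx=1, Ky=1)
        rep = metrics(truth, f)
        assert np.all(rep.loading_cosine >= 0.999)
        assert rep.r2_that_t >= 0.999

    def test_support_sizes_match_keep(self, rng):
        """Asked to keep h groups / m features per component, the fit does."""
        n, p, q = 40, 120, 60
        X = rng.standard_normal((n, p))
        Y = rng.standard_normal((n, q))
        gx = GroupStructure.from_labels([f"g{j // 6}" for j in range(p)])
        f = fit(X, Y, K=1, Kx=0, Ky=2,
                pen_x=PenaltySpec.group(gx, keep=5))
        alive = [j for j, ix in enumerate(gx.indices) if np.any(f.W[ix, 0] != 0)]
        assert len(alive) == 5
        assert np.all(f.C != 0)  # Y unpenalized: dense
        f2 = fit(X, Y, K=2, Kx=1, Ky=1,
                 pen_x=PenaltySpec.sparse(keep=30),
                 pen_y=PenaltySpec.sparse(keep=15))
        for k in range(2):
            assert np.count_nonzero(f2.W[:, k]) == 30
            assert np.count_nonzero(f2.C[:, k]) == 15

    def test_one_joint_many_y_orthogonal(self, rng):
        """Methylation-vs-glycomics shape: a single joint component with
        several Y-orthogonal components, group selection on X only, small
        dense Y.  More orthogonal than joint components must be feasible."""
        n, p, q = 40, 300, 22
        gx = GroupStructure.from_labels([f"g{j // 5}" for j in range(p)])
        X = rng.standard_normal((n, p))
        Y = rng.standard_normal((n, q))
        f = fit(X, Y, K=1, Kx=0, Ky=3, pen_x=PenaltySpec.group(gx, keep=20))
        alive = [j for j, ix in enumerate(gx.indices) if np.any(f.W[ix, 0] != 0)]
        assert len(alive) == 20
        assert np.all(f.C != 0)
        assert f.Uorth.shape == (n, 3) and f.Qorth.shape == (q, 3)


class TestTransformPredict:
    def test_training_scores_reproduced(self, exact_data, exact_fit):
        X, Y, _ = exact_data
        assert np.max(np.abs(transform(exact_fit, X, "x") - exact_fit.T)) < 1e-8
        assert np.max(np.abs(transform(exact_fit, Y, "y") - exact_fit.U)) < 1e-8

    def test_mean_row_maps_to_zero_scores(self, exact_data, exact_fit):
        X, _, _ = exact_data
        assert np.allclose(transform(exact_fit, X.mean(axis=0), "x"), 0.0)

    def test_heldout_scores_track_truth(self):
        X, Y, truth = simulate_exact(seed=21, N=120, p=100, q=60, K=2, Kx=1, Ky=1)
        f = fit(X[:80], Y[:80], K=2, Kx=1, Ky=1)
        T_new = transform(f, X[80:], "x")
        for k in range(2):
            rho = np.corrcoef(T_new[:, k], truth["T"][80:, k])[0, 1]
            assert abs(rho) > 0.9

    def test_feature_mismatch_rejected(self, exact_fit):
        with pytest.raises(ValueError, match="features"):
            transform(exact_fit, np.zeros((2, 7)), "x")

    def test_noiseless_rank1_prediction_exact(self, rng):
        w = rng.standard_normal(20)
        c = rng.standard_normal(10)
        t = rng.standard_normal(50)
        X = np.outer(t, w)
        Y = np.outer(t, c)  # B_T = 1 in the generating model
        f = fit(X, Y, K=1)
        assert np.max(np.abs(predict(f, X, "x_to_y") - Y)) < 1e-8

    def test_row_permutation_equivariance(self, exact_data, exact_fit):
        X, _, _ = exact_data
        perm = np.random.default_rng(0).permutation(X.shape[0])
        Yhat = predict(exact_fit, X, "x_to_y")
        assert np.allclose(predict(exact_fit, X[perm], "x_to_y"), Yhat[perm])

    def test_orthogonal_filtering_improves_prediction(self):
        """Under strong specific variation, modelling it (correct Kx, Ky)
        beats ignoring it (Kx=Ky=0) on held-out prediction."""
        from go2pls.simulation import scenario2_design, simulate_scenario2

        d = scenario2_design(p=400, q=200, n_groups=40, n_relevant=8,
                             N=120, alpha=0.2, orth_ratio=3.0)
        X, Y, truth = simulate_scenario2(d, seed=4)
        Xa, Ya = X.data[:80], Y.data[:80]
        Xte, Yte = X.data[80:], Y.data[80:]
        f_o2 = fit(Xa, Ya, K=2, Kx=1, Ky=1)
        f_pls = fit(Xa, Ya, K=2, Kx=0, Ky=0)
        mse_o2 = np.mean((predict(f_o2, Xte, "x_to_y") - Yte) ** 2)
        mse_pls = np.mean((predict(f_pls, Xte, "x_to_y") - Yte) ** 2)
        assert mse_o2 < mse_pls


class TestSerialization:
    def test_round_trip_bit_exact(self, exact_fit, tmp_path):
        path = tmp_path / "model.json"
        save_fit(exact_fit, path)
        back = load_fit(path)
        for name in ("W", "C", "T", "U", "Worth", "Torth", "Porth",
                     "Corth", "Uorth", "Qorth", "B_T", "B_U",
                     "x_rotation", "y_rotation", "x_means", "y_means"):
            assert np.array_equal(getattr(back, name), getattr(exact_fit, name)), name
        assert back.K == exact_fit.K
        assert back.x_feature_ids == exact_fit.x_feature_ids
        assert back.variance_summary == exact_fit.variance_summary
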