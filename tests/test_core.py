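"""Unit and property tests for the penalized NIPALS engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from go2pls import (
    DegenerateComponentError,
    GroupStructure,
    OmicsBlock,
    OverPenalizedError,
    PenaltySpec,
    center_scale,
    deflate,
    group_threshold,
    lambda_for_top_h,
    nipals_pair,
    orthogonalize_loading,
    soft_threshold,
)


class TestCenterScale:
    def test_mean_removal(self):
        b = center_scale(OmicsBlock(np.array([[1.0], [2.0], [3.0]])))
        assert np.allclose(b.data.ravel(), [-1, 0, 1])
        assert np.allclose(b.means, [2.0])

    def test_idempotent_on_centered(self, rng):
        X = rng.standard_normal((10, 4))
        X -= X.mean(axis=0)
        b = center_scale(OmicsBlock(X))
        assert np.allclose(b.data, X)

    def test_constant_column_scale_error(self):
        X = np.column_stack([np.arange(3.0), np.full(3, 2.0)])
        block = OmicsBlock(X, feature_ids=["a", "const"])
        with pytest.raises(ValueError, match="const"):
            center_scale(block, scale=True)

    def test_missing_values_named(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="f1"):
            center_scale(OmicsBlock(X))


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "a, lam, expected",
        [
            ([3.0, -3.0, 0.5], 1.0, [2.0, -2.0, 0.0]),
            ([1.5, -0.2, 0.0], 0.0, [1.5, -0.2, 0.0]),
            ([3.0, -3.0, 0.5], 3.0, [0.0, 0.0, 0.0]),
        ],
    )
    def test_definition(self, a, lam, expected):
        assert np.allclose(soft_threshold(np.array(a), lam), expected)

    def test_negative_lam_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.ones(3), -0.1)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a=arrays(np.float64, 8, elements=st.floats(-10, 10)),
        lam=st.floats(0, 5),
    )
    def test_shrinkage_properties(self, a, lam):
        out = soft_threshold(a, lam)
        assert np.all(np.abs(out) <= np.abs(a) + 1e-12)
        assert np.all((out == 0) | (np.sign(out) == np.sign(a)))
        assert np.all((np.abs(a) > lam) == (out != 0))


class TestGroupThreshold:
    def test_boundary_zeroes_group(self):
        # group of size 4 with sub-vector (3,4,0,0): ‖a‖=5 equals √4·2.5
        a = np.array([3.0, 4.0, 0.0, 0.0, 10.0])
        groups = GroupStructure(names=["g", "h"],
                                indices=[np.arange(4), np.array([4])])
        out = group_threshold(a, groups, 2.5)
        assert np.all(out[:4] == 0)
        assert out[4] > 0

    def test_hand_computed_scaling(self):
        # ‖a^(1)‖=5, √4·1.25=2.5 → scale (5-2.5)/5 = 0.5 → (1.5, 2) pre-renorm
        a = np.array([3.0, 4.0, 0.0, 0.0, 10.0])
        groups = GroupStructure(names=["g", "h"],
                                indices=[np.arange(4), np.array([4])])
        out = group_threshold(a, groups, 1.25)
        pre = np.array([1.5, 2.0, 0.0, 0.0, 10.0 - 1.25])
        assert np.allclose(out, pre / np.linalg.norm(pre))

    def test_singletons_match_soft_threshold(self, rng):
        a = rng.standard_normal(12)
        lam = 0.4
        out = group_threshold(a, GroupStructure.singletons(12), lam)
        ref = soft_threshold(a, lam)
        assert np.allclose(out, ref / np.linalg.norm(ref))

    def test_all_zero_raises_with_feasible_lam(self):
        a = np.array([1.0, 1.0])
        groups = GroupStructure.singletons(2)
        with pytest.raises(OverPenalizedError) as ei:
            group_threshold(a, groups, 5.0)
        assert ei.value.max_feasible_lam == pytest.approx(1.0)

    def test_group_allin_allout(self, rng, mixed_groups):
        out = group_threshold(rng.standard_normal(40), mixed_groups, 0.2)
        for ix in mixed_groups.indices:
            sub = out[ix]
            assert np.all(sub == 0) or np.all(sub != 0)


class TestLambdaForTopH:
    @pytest.mark.parametrize(
        "norms, h, expected", [([5, 3, 1], 2, 2.0), ([5, 3, 1], 3, 0.0)]
    )
    def test_order_statistics(self, norms, h, expected):
        assert lambda_for_top_h(np.array(norms, float), h) == expected

    def test_tie_keeps_all(self):
        lam = lambda_for_top_h(np.array([4.0, 4.0, 1.0]), 1)
        assert 1.0 < lam < 4.0  # both tied groups survive a strict > test

    def test_invalid_h(self):
        with pytest.raises(ValueError):
            lambda_for_top_h(np.array([1.0]), 0)


class TestNipalsPair:
    def test_rank1_exact_recovery(self, rng):
        w0 = rng.standard_normal(15)
        w0 /= np.linalg.norm(w0)
        c0 = rng.standard_normal(10)
        c0 /= np.linalg.norm(c0)
        t0 = rng.standard_normal(20)
        pair = nipals_pair(np.outer(t0, w0), np.outer(t0, c0))
        assert abs(pair.w @ w0) > 1 - 1e-8
        assert abs(pair.c @ c0) > 1 - 1e-8

    def test_matches_dense_svd(self, rng):
        """Unpenalized fixed point is the dominant singular pair of YᵀX."""
        for _ in range(5):
            X = rng.standard_normal((20, 15))
            Y = rng.standard_normal((20, 10))
            X -= X.mean(axis=0)
            Y -= Y.mean(axis=0)
            pair = nipals_pair(X, Y)
            U, _, Vt = np.linalg.svd(Y.T @ X)
            assert abs(pair.w @ Vt[0]) >= 1 - 1e-8
            assert abs(pair.c @ U[:, 0]) >= 1 - 1e-8

    def test_objective_monotone_without_penalty(self, rng):
        """|cᵀYᵀXw| is non-decreasing across iterations (deterministic init).

        The magnitude is the approximated dominant singular value; the sign of
        the reported pair is fixed by the largest-entry convention afterwards,
        so only the magnitude is meaningful here.
        """
        X = rng.standard_normal((25, 30))
        Y = rng.standard_normal((25, 12))
        X -= X.mean(axis=0)
        Y -= Y.mean(axis=0)
        objs = []
        for iters in range(1, 12):
            pair = nipals_pair(X, Y, max_iter=iters)
            objs.append(abs(float(pair.c @ Y.T @ X @ pair.w)))
        assert all(b >= a - 1e-9 for a, b in zip(objs, objs[1:]))

    def test_group_keep_count_exact(self, rng, mixed_groups):
        X = rng.standard_normal((30, 40))
        Y = rng.standard_normal((30, 20))
        X -= X.mean(axis=0)
        Y -= Y.mean(axis=0)
        for h in (2, 4, 7):
            pair = nipals_pair(X, Y, pen_x=PenaltySpec.group(mixed_groups, keep=h))
            alive = sum(
                1 for ix in mixed_groups.indices if np.any(pair.w[ix] != 0)
            )
            assert alive == h

    def test_support_scale_equivariant(self, rng, mixed_groups):
        X = rng.standard_normal((30, 40))
        Y = rng.standard_normal((30, 20))
        X -= X.mean(axis=0)
        Y -= Y.mean(axis=0)
        pen = PenaltySpec.group(mixed_groups, keep=3)
        s1 = np.flatnonzero(nipals_pair(X, Y, pen_x=pen).w)
        s2 = np.flatnonzero(nipals_pair(7.3 * X, Y, pen_x=pen).w)
        assert np.array_equal(s1, s2)

    def test_keep_larger_than_units_rejected(self, rng, mixed_groups):
        X = rng.standard_normal((30, 40))
        Y = rng.standard_normal((30, 20))
        with pytest.raises(ValueError, match="keep"):
            nipals_pair(X, Y, pen_x=PenaltySpec.group(mixed_groups, keep=11))

    def test_overpenalized_raises(self, rng):
        X = rng.standard_normal((30, 40))
        Y = rng.standard_normal((30, 20))
        X -= X.mean(axis=0)
        Y -= Y.mean(axis=0)
        with pytest.raises(OverPenalizedError):
            nipals_pair(X, Y, pen_x=PenaltySpec.sparse(lam=1e6))

    def test_sign_convention(self, rng):
        X = rng.standard_normal((20, 15))
        Y = rng.standard_normal((20, 10))
        pair = nipals_pair(X - X.mean(0), Y - Y.mean(0))
        assert pair.w[np.argmax(np.abs(pair.w))] > 0
        assert pair.c[np.argmax(np.abs(pair.c))] > 0


class TestOrthogonalizeLoading:
    def test_disjoint_support_unchanged(self):
        wk = np.array([0.0, 0.0, 3.0, 4.0]) / 5.0
        prev = [np.array([1.0, 0.0, 0.0, 0.0])]
        out = orthogonalize_loading(wk, prev)
        assert np.allclose(out, wk)

    def test_fully_spanned_raises(self):
        w = np.array([0.6, 0.8, 0.0])
        with pytest.raises(DegenerateComponentError):
            orthogonalize_loading(w, [w.copy()])

    def test_matches_gram_schmidt(self, rng):
        """Third loading orthogonal to the first two on the shared support."""
        support = np.arange(6)
        w1 = np.zeros(10)
        w2 = np.zeros(10)
        w1[:6] = rng.standard_normal(6)
        w2[:6] = rng.standard_normal(6)
        wk = np.zeros(10)
        wk[:8] = rng.standard_normal(8)
        out = orthogonalize_loading(wk, [w1, w2], support=support)
        # independent Gram-Schmidt oracle on the restricted vectors
        M = np.column_stack([w1[support], w2[support]])
        Qb, _ = np.linalg.qr(M)
        oracle = wk[support] - Qb @ (Qb.T @ wk[support])
        assert abs(out[support] @ w1[support]) < 1e-10
        assert abs(out[support] @ w2[support]) < 1e-10
        assert np.allclose(
            out[support] / np.linalg.norm(out[support]) * np.linalg.norm(oracle),
            np.sign(out[support] @ oracle) * oracle,
        )
        assert np.isclose(np.linalg.norm(out), 1.0)


class TestDeflate:
    def test_rank1_becomes_zero(self, rng):
        t = rng.standard_normal(12)
        a = rng.standard_normal(7)
        assert np.allclose(deflate(np.outer(t, a), t), 0.0)

    def test_orthogonal_unchanged(self, rng):
        t = np.zeros(10)
        t[0] = 1.0
        X = np.zeros((10, 3))
        X[1:, :] = rng.standard_normal((9, 3))
        assert np.allclose(deflate(X, t), X)

    def test_result_orthogonal_to_score(self, rng):
        X = rng.standard_normal((15, 8))
        t = rng.standard_normal(15)
        assert np.max(np.abs(t @ deflate(X, t))) < 1e-10 * np.linalg.norm(X)

    def test_zero_score_rejected(self):
        with pytest.raises(ValueError):
            deflate(np.ones((3, 2)), np.zeros(3))
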