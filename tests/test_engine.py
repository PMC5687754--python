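"""Unit and property tests for the core fitting engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omicspls import (DesignMatrix, OmicsBlock, center_and_scale, encode_dummy,
                      fit_mint_standardise, fit_model, nipals_pca,
                      sparsify_loading)
from omicspls.engine import deflate, fit_component

from conftest import align_sign


class TestCenterAndScale:
    def test_two_point_column(self):
        b = center_and_scale(OmicsBlock(np.array([[1.0, 5.0], [3.0, 5.0]])))
        assert np.allclose(b.values[:, 0], [-1 / np.sqrt(2), 1 / np.sqrt(2)])
        assert np.isclose(b.col_sds[0], np.sqrt(2))  # N-1 denominator

    def test_constant_column_protected(self):
        b = center_and_scale(OmicsBlock(np.array([[5.0, 1], [5.0, 2], [5.0, 3]])))
        assert np.allclose(b.values[:, 0], 0)
        assert b.col_sds[0] == 1.0

    def test_columns_centered(self, rng):
        b = center_and_scale(OmicsBlock(rng.normal(3, 2, (10, 4))))
        assert np.abs(b.values.mean(axis=0)).max() < 1e-12
        assert np.allclose(b.values.std(axis=0, ddof=1), 1)

    def test_double_standardisation_rejected(self, rng):
        b = center_and_scale(OmicsBlock(rng.normal(size=(5, 3))))
        with pytest.raises(ValueError, match="already standardized"):
            center_and_scale(b)

    def test_all_missing_column_named(self):
        x = np.array([[1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(ValueError, match="f2"):
            center_and_scale(OmicsBlock(x))


class TestEncodeDummy:
    def test_basic_indicator(self):
        d = encode_dummy(["A", "B", "A"])
        assert d.class_labels == ["A", "B"]
        assert np.array_equal(d.indicator, [[1, 0], [0, 1], [1, 0]])

    def test_column_sums_are_class_counts(self):
        # the four-tumour design: 8 BL, 23 EWS, 12 NB, 20 RMS
        y = ["EWS"] * 23 + ["BL"] * 8 + ["NB"] * 12 + ["RMS"] * 20
        d = encode_dummy(y)
        assert d.class_labels == ["BL", "EWS", "NB", "RMS"]
        assert d.class_counts.tolist() == [8, 23, 12, 20]
        assert np.allclose(d.indicator.sum(axis=1), 1)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 distinct"):
            encode_dummy(["A", "A", "A"])


class TestSparsifyLoading:
    @pytest.mark.parametrize("keepx,expected", [
        (3, np.array([3, -2, 1]) / np.linalg.norm([3, -2, 1])),
        (1, np.array([1.0, 0, 0])),
        (2, np.array([2, -1, 0]) / np.sqrt(5)),
    ])
    def test_hand_soft_threshold(self, keepx, expected):
        out = sparsify_loading(np.array([3.0, -2.0, 1.0]), keepx)
        assert np.allclose(out, expected)

    def test_keepx_out_of_range(self):
        with pytest.raises(ValueError):
            sparsify_loading(np.ones(3), 0)
        with pytest.raises(ValueError):
            sparsify_loading(np.ones(3), 4)

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning, match="all-zero"):
            out = sparsify_loading(np.zeros(4), 2)
        assert np.array_equal(out, np.zeros(4))

    def test_boundary_tie_exact_count(self):
        # |w| = [2, 2, 1]: the tie at the keepX=1 boundary must still
        # leave exactly one survivor (lowest index wins)
        out = sparsify_loading(np.array([2.0, -2.0, 1.0]), 1)
        assert np.count_nonzero(out) == 1
        assert out[0] != 0

    @given(st.integers(1, 12), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_exact_sparsity_and_unit_norm(self, keepx, seed):
        w = np.random.default_rng(seed).normal(size=12)
        out = sparsify_loading(w, keepx)
        assert np.count_nonzero(out) == keepx
        assert np.isclose(np.linalg.norm(out), 1.0)


class TestFitComponent:
    def test_single_block_svd_oracle(self, rng):
        X = rng.standard_normal((20, 10))
        Xs = center_and_scale(OmicsBlock(X)).values
        Y = encode_dummy(rng.permutation(["A"] * 10 + ["B"] * 10)).indicator
        Yc = Y - Y.mean(axis=0)
        a, t, c, u, info = fit_component([Xs], Yc, np.zeros((1, 1)), [10])
        u_, _, _ = np.linalg.svd(Xs.T @ Yc, full_matrices=False)
        ref = u_[:, 0] * np.sign(u_[np.argmax(np.abs(u_[:, 0])), 0])
        assert info["converged"]
        assert np.abs(a[0] - ref).max() < 1e-6

    def test_identical_blocks_symmetric(self, rng):
        X = rng.standard_normal((15, 8))
        Xs = center_and_scale(OmicsBlock(X)).values
        Y = encode_dummy(["A"] * 8 + ["B"] * 7).indicator
        Yc = Y - Y.mean(axis=0)
        design = DesignMatrix.default(2).weights
        a, t, *_ = fit_component([Xs, Xs.copy()], Yc, design, [8, 8])
        assert np.allclose(a[0], a[1], atol=1e-8)

    def test_unit_norm_and_score_consistency(self, rng):
        X = rng.standard_normal((12, 6))
        Xs = center_and_scale(OmicsBlock(X)).values
        Yc = encode_dummy(["A"] * 6 + ["B"] * 6).indicator - 0.5
        a, t, *_ = fit_component([Xs], Yc, np.zeros((1, 1)), [3])
        assert np.isclose(np.linalg.norm(a[0]), 1)
        assert np.allclose(t[0], Xs @ a[0])


class TestDeflate:
    def test_orthogonal_after_deflation(self, rng):
        X = rng.standard_normal((10, 5))
        t = rng.standard_normal(10)
        Xd, p = deflate(X, t)
        assert np.abs(t @ Xd).max() < 1e-10

    def test_rank_one_annihilated(self, rng):
        t = rng.standard_normal(8)
        v = rng.standard_normal(4)
        Xd, _ = deflate(np.outer(t, v), t)
        assert np.abs(Xd).max() < 1e-12

    def test_zero_score_rejected(self, rng):
        with pytest.raises(ValueError, match="zero-norm"):
            deflate(rng.standard_normal((5, 3)), np.zeros(5))


class TestFitModel:
    def test_successive_scores_orthogonal(self, small_single):
        block, y, _ = small_single
        m = fit_model([block], Y=encode_dummy(y), ncomp=2,
                      design=DesignMatrix(np.zeros((1, 1))))
        T = m.scores[0]
        assert abs(T[:, 0] @ T[:, 1]) < 1e-8

    def test_deterministic(self, small_single):
        block, y, _ = small_single
        kw = dict(Y=encode_dummy(y), ncomp=2, keepX=[[5, 5]],
                  design=DesignMatrix(np.zeros((1, 1))))
        m1 = fit_model([block.copy()], **kw)
        m2 = fit_model([block.copy()], **kw)
        assert np.array_equal(m1.loadings[0], m2.loadings[0])
        assert np.array_equal(m1.scores[0], m2.scores[0])

    def test_dense_matches_independent_nipals_pls(self, rng):
        """keepX=P fit must agree with a directly-coded NIPALS PLS2."""
        X = rng.standard_normal((25, 12))
        y = rng.permutation(["A"] * 9 + ["B"] * 8 + ["C"] * 8)
        dummy = encode_dummy(y)
        m = fit_model([OmicsBlock(X)], Y=dummy, ncomp=3,
                      design=DesignMatrix(np.zeros((1, 1))))

        # independent oracle: textbook NIPALS PLS2 with unit-norm weights
        Xs = center_and_scale(OmicsBlock(X)).values
        Yw = dummy.indicator - dummy.indicator.mean(axis=0)
        W = np.zeros((12, 3))
        T = np.zeros((25, 3))
        for h in range(3):
            u = Yw[:, 0]
            for _ in range(500):
                w = Xs.T @ u
                w = w / np.linalg.norm(w)
                t = Xs @ w
                c = Yw.T @ t
                c = c / np.linalg.norm(c)
                u_new = Yw @ c
                if np.abs(u_new - u).max() < 1e-12:
                    u = u_new
                    break
                u = u_new
            W[:, h], T[:, h] = w, t
            p = Xs.T @ t / (t @ t)
            Xs = Xs - np.outer(t, p)
            Yw = Yw - np.outer(t, t @ Yw / (t @ t))
        assert np.abs(align_sign(W, m.loadings[0]) - m.loadings[0]).max() < 1e-6
        assert np.abs(align_sign(T, m.scores[0]) - m.scores[0]).max() < 1e-6

    def test_ncomp_too_large_rejected(self, rng):
        block = OmicsBlock(rng.standard_normal((6, 4)))
        with pytest.raises(ValueError, match="ncomp"):
            fit_model([block], Y=encode_dummy(["A", "A", "A", "B", "B", "B"]),
                      ncomp=4, design=DesignMatrix(np.zeros((1, 1))))


class TestMintStandardise:
    def test_single_study_equals_global(self, rng):
        x = rng.normal(2, 3, (10, 4))
        a = fit_mint_standardise(OmicsBlock(x), ["s1"] * 10)
        b = center_and_scale(OmicsBlock(x))
        assert np.allclose(a.values, b.values)

    def test_offsets_removed(self, rng):
        x = rng.standard_normal((12, 5))
        x[:6] += 10
        x[6:] -= 10
        study = ["a"] * 6 + ["b"] * 6
        out = fit_mint_standardise(OmicsBlock(x), study)
        assert np.abs(out.values[:6].mean(axis=0)).max() < 1e-12
        assert np.abs(out.values[6:].mean(axis=0)).max() < 1e-12

    def test_between_study_variance_vanishes(self, small_multistudy):
        block, y, study, _ = small_multistudy
        out = fit_mint_standardise(block, study)
        means = np.array([out.values[study == s].mean(axis=0)
                          for s in sorted(set(study))])
        assert means.var(axis=0).max() < 1e-10

    def test_singleton_study_rejected(self, rng):
        x = rng.standard_normal((5, 3))
        with pytest.raises(ValueError, match="centering-only"):
            fit_mint_standardise(OmicsBlock(x), ["a", "a", "a", "a", "b"])


class TestNipalsPCA:
    def test_matches_svd_on_complete_data(self, rng):
        X = rng.standard_normal((50, 20))
        m = nipals_pca(OmicsBlock(X), ncomp=3)
        Xc = X - X.mean(axis=0)
        U, S, _ = np.linalg.svd(Xc, full_matrices=False)
        ref = U[:, :3] * S[:3]
        assert np.abs(align_sign(m.scores[0], ref) - ref).max() < 1e-6
        assert np.allclose(m.explained_variance[0],
                           (S[:3] ** 2) / np.sum(S ** 2), atol=1e-9)

    def test_explained_variance_shape(self, rng):
        m = nipals_pca(OmicsBlock(rng.standard_normal((30, 10))), ncomp=4)
        ev = m.explained_variance[0]
        assert ev.sum() <= 1 + 1e-9
        assert np.all(np.diff(ev) <= 1e-9)

    def test_masked_cell_recovery(self, rng):
        from omicspls import inject_missing, nipals_impute
        W = rng.standard_normal((60, 3)) @ rng.standard_normal((3, 30))
        block = inject_missing(OmicsBlock(W), 0.05, seed=3)
        imputed = nipals_impute(block, ncomp=3)
        mask = np.isnan(block.values)
        rmse = np.sqrt(np.mean((imputed[mask] - W[mask]) ** 2))
        assert rmse < 0.1 * W.std()
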