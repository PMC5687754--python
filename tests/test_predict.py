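"""Tests for projection, prediction distances, votes and regions."""

import numpy as np
import pytest

from omicspls import (OmicsBlock, SimConfig, block_splsda, combine_votes,
                      encode_dummy, gen_single, plsda, prediction_region,
                      splsda, weighted_vote)
from omicspls.predict import (assign_class, block_weights, predict,
                              predict_dummy, project_new)


class TestProjectNew:
    def test_self_projection_reproduces_training_scores(self, small_single):
        block, y, _ = small_single
        m = splsda(block.values, y, ncomp=2, keepX=[6, 6])
        s = project_new(m, block.values)
        assert np.abs(s - m.scores[0]).max() < 1e-10

    def test_feature_reconciliation_by_id(self, small_single):
        block, y, _ = small_single
        m = splsda(block, y, ncomp=2, keepX=[6, 6])
        perm = np.random.default_rng(0).permutation(block.n_features)
        s = project_new(m, block.values[:, perm],
                        feature_ids=[block.feature_ids[j] for j in perm])
        assert np.abs(s - m.scores[0]).max() < 1e-10

    def test_missing_features_listed(self, small_single):
        block, y, _ = small_single
        m = splsda(block, y, ncomp=2)
        with pytest.raises(ValueError, match="lacks"):
            project_new(m, block.values[:, :10],
                        feature_ids=block.feature_ids[:10])

    def test_heldout_scores_finite_and_shaped(self, small_single):
        block, y, truth = small_single
        m = splsda(block.values, y, ncomp=2, keepX=[6, 6])
        new, _, _ = gen_single(SimConfig(n_per_class=4, p=40, k=3,
                                         n_informative=12, effect=3.0,
                                         seed=99))
        s = project_new(m, new.values)
        assert s.shape == (12, 2)
        assert np.isfinite(s).all()


class TestPredictDummy:
    def test_closed_form_regression_oracle(self):
        # hand-checkable 1-component toy: N=4, P=2, K=2
        X = np.array([[1.0, 0.0], [2.0, 0.5], [-1.0, 0.2], [-2.0, -0.1]])
        y = ["A", "A", "B", "B"]
        m = plsda(X, y, ncomp=1)
        s = project_new(m, X)
        d = predict_dummy(m, s)
        Y = encode_dummy(y).indicator
        A = np.column_stack([np.ones(4), m.scores[0][:, :1]])
        coef, *_ = np.linalg.lstsq(A, Y, rcond=None)
        expect = A @ coef
        assert np.abs(d[0] - expect).max() < 1e-10

    def test_separated_classes_predict_near_indicator(self, small_single):
        block, y, _ = small_single
        m = plsda(block.values, y, ncomp=2)
        pr = predict(m, block.values)
        d = pr.predicted_dummy[0][-1]  # depth H uses all components
        truth = encode_dummy(y).indicator
        assert np.abs(d - truth).max() < 0.45
        assert (np.argmax(d, axis=1) == np.argmax(truth, axis=1)).all()


class TestAssignClass:
    def test_max_is_argmax(self, small_single):
        block, y, _ = small_single
        m = plsda(block.values, y, ncomp=2)
        pr = predict(m, block.values)
        lab = pr.class_by_distance["max"][0][1]
        expect = np.asarray(m.class_labels)[
            np.argmax(pr.predicted_dummy[0][1], axis=1)]
        assert (lab == expect).all()

    def test_brute_force_distance_oracle(self, rng):
        X = rng.standard_normal((30, 8))
        y = rng.permutation(["A"] * 10 + ["B"] * 10 + ["C"] * 10)
        m = plsda(X, y, ncomp=2)
        Xnew = rng.standard_normal((15, 8))
        s = project_new(m, Xnew)
        T, ind = m.scores[0], m.y_indicator
        for dist in ("centroid", "mahalanobis"):
            got = assign_class(m, s, distance=dist)
            for h in (1, 2):
                cents = {k: T[ind[:, ki] == 1, :h].mean(axis=0)
                         for ki, k in enumerate(m.class_labels)}
                if dist == "mahalanobis":
                    S = sum((np.atleast_2d(np.cov(T[ind[:, ki] == 1, :h],
                                                  rowvar=False))
                             * (ind[:, ki].sum() - 1))
                            for ki in range(3)) / (30 - 3)
                    Si = np.linalg.inv(S)
                else:
                    Si = np.eye(h)
                for i in range(15):
                    d = {k: (s[i, :h] - c) @ Si @ (s[i, :h] - c)
                         for k, c in cents.items()}
                    assert got[h - 1][i] == min(d, key=d.get)

    def test_identity_covariance_equates_distances(self, rng):
        # construct a model whose training-score covariance is identity
        X = rng.standard_normal((40, 6))
        y = rng.permutation(["A"] * 20 + ["B"] * 20)
        m = plsda(X, y, ncomp=2)
        from omicspls.predict import _pooled_within_cov
        S = _pooled_within_cov(m.scores[0], m.y_indicator)
        W = np.linalg.cholesky(np.linalg.inv(S)).T
        m.scores[0] = m.scores[0] @ W.T  # whitened scores: pooled cov = I
        s = rng.standard_normal((25, 2))
        a = assign_class(m, s, distance="centroid")
        b = assign_class(m, s, distance="mahalanobis")
        assert np.array_equal(a, b)

    def test_label_permutation_equivariance(self, small_single):
        block, y, _ = small_single
        ren = {"C1": "Z", "C2": "Q", "C3": "M"}
        y2 = np.array([ren[v] for v in y])
        m1 = splsda(block.values, y, ncomp=2, keepX=[6, 6])
        m2 = splsda(block.values, y2, ncomp=2, keepX=[6, 6])
        p1 = predict(m1, block.values)
        p2 = predict(m2, block.values)
        lab1 = np.array([ren[v] for v in p1.class_by_distance["centroid"][0][1]])
        assert np.array_equal(lab1, p2.class_by_distance["centroid"][0][1])


class TestVotes:
    def test_majority(self):
        assert combine_votes([["A"], ["A"], ["B"]])[0] == "A"

    def test_even_tie_is_na(self):
        assert combine_votes([["A"], ["B"]])[0] is None

    def test_unanimous_any_size(self):
        for b in (2, 3, 5):
            assert combine_votes([["C"]] * b)[0] == "C"

    def test_order_invariant(self, rng):
        labs = [rng.choice(["A", "B", "C"], size=20) for _ in range(3)]
        a = combine_votes(labs)
        b = combine_votes(labs[::-1])
        assert np.array_equal(a, b)

    def test_weighted_dominant_block_decides(self):
        labels = [["A", "A"], ["B", "B"], ["B", "B"]]
        out = weighted_vote(labels, [0.99, 0.01, 0.01])
        assert list(out) == ["A", "A"]

    def test_equal_weights_reduce_to_majority(self):
        labels = [["A"], ["A"], ["B"]]
        assert weighted_vote(labels, [1, 1, 1])[0] == "A"

    def test_weighted_breaks_even_discordance(self, small_multiblock):
        """With an even number of disagreeing blocks the weighted vote
        resolves ties the majority vote cannot."""
        blocks, y, _ = small_multiblock
        m = block_splsda([b.values for b in blocks], y, ncomp=2,
                         keepX=[[8, 8], [8, 8]])
        rng = np.random.default_rng(5)
        noise = [rng.standard_normal((30, b.n_features)) for b in blocks]
        pr = predict(m, noise)
        maj = pr.majority_vote["centroid"][1]
        wv = pr.weighted_vote["centroid"][1]
        n_na_maj = sum(1 for v in maj if v is None)
        n_na_wv = sum(1 for v in wv if v is None)
        assert n_na_wv <= n_na_maj
        assert pr.block_weights is not None and (pr.block_weights > 0).all()


class TestPredictionRegion:
    def test_training_samples_inside_extent(self, small_single):
        block, y, _ = small_single
        m = splsda(block.values, y, ncomp=2, keepX=[6, 6])
        xs, ys, lab = prediction_region(m, "centroid", grid_n=25)
        T = m.scores[0]
        assert xs[0] <= T[:, 0].min() and xs[-1] >= T[:, 0].max()
        assert ys[0] <= T[:, 1].min() and ys[-1] >= T[:, 1].max()
        assert lab.shape == (25, 25)

    def test_distances_draw_different_boundaries(self, small_single):
        block, y, _ = small_single
        m = splsda(block.values, y, ncomp=2, keepX=[6, 6])
        regions = {d: prediction_region(m, d, grid_n=40)[2]
                   for d in ("max", "centroid", "mahalanobis")}
        assert (regions["max"] != regions["centroid"]).any()
        assert (regions["centroid"] != regions["mahalanobis"]).any()

    def test_max_boundary_at_dummy_half(self, rng):
        # 2 classes, 1 component: the max-distance frontier sits where the
        # two predicted dummy columns cross, i.e. at dummy value 0.5
        X = np.vstack([rng.normal(-2, 0.3, (20, 3)), rng.normal(2, 0.3, (20, 3))])
        y = ["A"] * 20 + ["B"] * 20
        m = plsda(X, y, ncomp=1)
        xs, lab = prediction_region(m, "max", grid_n=400, comps=(1,))
        intercept, beta = m.y_coefs[0][0]
        flip = np.where(lab[:-1] != lab[1:])[0]
        assert len(flip) == 1
        t_bound = (xs[flip[0]] + xs[flip[0] + 1]) / 2
        dummy = intercept + np.array([[t_bound]]) @ beta
        assert np.abs(dummy - 0.5).max() < 0.01


def test_self_prediction_zero_error_all_distances(small_single):
    block, y, _ = small_single
    m = splsda(block.values, y, ncomp=2, keepX=[12, 12])
    pr = predict(m, block.values)
    for d in ("max", "centroid", "mahalanobis"):
        assert (pr.class_by_distance[d][0][1] == y).all()
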