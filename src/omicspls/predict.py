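"""Class prediction for fitted projection models.

New samples are standardised with the training parameters, pushed through
the training deflation sequence to obtain predicted scores, mapped to
predicted dummy values by the score-to-outcome regression learnt at
training time, and finally assigned a class by one of three prediction
distances:

``max``
    argmax over the K predicted dummy values.
``centroid``
    nearest class centroid of the training scores (Euclidean).
``mahalanobis``
    nearest centroid under the pooled within-class covariance of the
    training scores.

For multi-block models each block yields its own prediction; block
predictions are combined by majority vote (ties reported as ``None``) or
by a weighted vote where each block's weight is how strongly its training
components correlate with the outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import FittedModel

__all__ = [
    "Prediction", "project_new", "predict_dummy", "assign_class",
    "combine_votes", "block_weights", "weighted_vote", "predict",
    "prediction_region", "DISTANCES",
]

DISTANCES = ("max", "centroid", "mahalanobis")


@dataclass
class Prediction:
    """Bundle of everything computed for a set of new samples.

    ``class_by_distance[dist]`` is a per-block list of (H, N_new) label
    arrays (object dtype; ``None`` marks a vote tie). ``majority_vote``
    and ``weighted_vote`` are only set for multi-block models.
    """

    predicted_scores: list[np.ndarray]
    predicted_dummy: list[np.ndarray]      # per block: (H, N_new, K)
    combined_dummy: np.ndarray             # (H, N_new, K), mean over blocks
    class_by_distance: dict[str, list[np.ndarray]]
    majority_vote: dict[str, np.ndarray] = field(default_factory=dict)
    weighted_vote: dict[str, np.ndarray] = field(default_factory=dict)
    block_weights: np.ndarray | None = None

    def labels(self, distance: str = "mahalanobis", depth: int | None = None,
               block: int = 0, vote: str | None = None) -> np.ndarray:
        """Headline labels at ``depth`` (default: all components)."""
        h = (depth or self.predicted_dummy[0].shape[0]) - 1
        if vote == "majority":
            return self.majority_vote[distance][h]
        if vote == "weighted":
            return self.weighted_vote[distance][h]
        return self.class_by_distance[distance][block][h]


def _reconcile(x: np.ndarray, feat_in, feat_train) -> np.ndarray:
    if list(feat_in) == list(feat_train):
        return x
    pos = {f: j for j, f in enumerate(feat_in)}
    missing = [f for f in feat_train if f not in pos]
    if missing:
        raise ValueError(
            f"new data lacks {len(missing)} training features, e.g. {missing[:5]}")
    return x[:, [pos[f] for f in feat_train]]


def project_new(model: FittedModel, Xnew, block: int = 0,
                feature_ids=None, study=None) -> np.ndarray:
    """Predicted scores (N_new x H) of new samples on one block.

    Standardisation replays the training parameters; for multi-study
    models, samples from a training study reuse that study's parameters,
    samples from a new study are standardised by their own means/sds when
    the study has at least 3 samples, otherwise by the global training
    parameters.
    """
    x = np.asarray(Xnew, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if feature_ids is not None:
        x = _reconcile(x, feature_ids, model.feature_ids[block])
    elif x.shape[1] != len(model.feature_ids[block]):
        raise ValueError(
            f"new data has {x.shape[1]} features; model block "
            f"{model.block_names[block]!r} expects {len(model.feature_ids[block])}")
    if np.isnan(x).any():
        raise ValueError("missing values are not supported in prediction")

    if model.study_params is not None and study is not None:
        study = np.asarray([str(s) for s in study])
        xs = np.empty_like(x)
        for s in np.unique(study):
            idx = np.where(study == s)[0]
            if s in model.study_params:
                mu, sd = model.study_params[s]
            elif len(idx) >= 3:
                mu = x[idx].mean(axis=0)
                sd = x[idx].std(axis=0, ddof=1)
                sd = np.where(sd == 0, 1.0, sd)
                if not model.scaled:
                    sd = np.ones_like(sd)
            else:
                mu, sd = model.col_means[block], model.col_sds[block]
            xs[idx] = (x[idx] - mu) / sd
        xd = xs
    else:
        xd = (x - model.col_means[block]) / model.col_sds[block]

    H = model.ncomp
    scores = np.zeros((x.shape[0], H))
    a = model.loadings[block]
    p = model.projection[block]
    for h in range(H):
        t = xd @ a[:, h]
        scores[:, h] = t
        xd = xd - np.outer(t, p[:, h])
    return scores


def predict_dummy(model: FittedModel, predicted_scores: np.ndarray,
                  block: int = 0) -> np.ndarray:
    """Predicted dummy values at every depth: array (H, N_new, K).

    Depth h uses the least-squares regression of the training outcome on
    the first h training components of the block, so depth H uses all
    components.
    """
    H = model.ncomp
    n_new = predicted_scores.shape[0]
    K = model.y_indicator.shape[1]
    out = np.zeros((H, n_new, K))
    for h in range(1, H + 1):
        intercept, beta = model.y_coefs[block][h - 1]
        out[h - 1] = intercept + predicted_scores[:, :h] @ beta
    return out


def _centroids(T: np.ndarray, indicator: np.ndarray) -> np.ndarray:
    return np.stack([T[indicator[:, k] == 1].mean(axis=0)
                     for k in range(indicator.shape[1])])


def _pooled_within_cov(T: np.ndarray, indicator: np.ndarray) -> np.ndarray:
    n, h = T.shape
    K = indicator.shape[1]
    S = np.zeros((h, h))
    for k in range(K):
        tk = T[indicator[:, k] == 1]
        if len(tk) > 1:
            S += (len(tk) - 1) * np.cov(tk, rowvar=False).reshape(h, h)
    dof = max(n - K, 1)
    return S / dof


def assign_class(model: FittedModel, predicted_scores: np.ndarray,
                 predicted_dummy: np.ndarray | None = None,
                 distance: str = "max", block: int = 0) -> np.ndarray:
    """Class labels at every depth h=1..H: object array (H, N_new)."""
    if distance not in DISTANCES:
        raise ValueError(f"distance must be one of {DISTANCES}, got {distance!r}")
    labels = np.asarray(model.class_labels, dtype=object)
    H = model.ncomp
    n_new = predicted_scores.shape[0]
    out = np.empty((H, n_new), dtype=object)
    if distance == "max":
        if predicted_dummy is None:
            predicted_dummy = predict_dummy(model, predicted_scores, block)
        for h in range(H):
            out[h] = labels[np.argmax(predicted_dummy[h], axis=1)]
        return out
    T = model.scores[block]
    ind = model.y_indicator
    for h in range(1, H + 1):
        cents = _centroids(T[:, :h], ind)
        diff = predicted_scores[:, None, :h] - cents[None, :, :]
        if distance == "centroid":
            d2 = np.einsum("nkh,nkh->nk", diff, diff)
        else:
            S = _pooled_within_cov(T[:, :h], ind)
            try:
                Sinv = np.linalg.inv(S)
            except np.linalg.LinAlgError:
                warnings.warn("singular within-class covariance; "
                              "falling back to centroid distance")
                Sinv = None
            if Sinv is None:
                d2 = np.einsum("nkh,nkh->nk", diff, diff)
            else:
                d2 = np.einsum("nkh,hj,nkj->nk", diff, Sinv, diff)
        out[h - 1] = labels[np.argmin(d2, axis=1)]
    return out


def combine_votes(per_block_labels) -> np.ndarray:
    """Majority vote across blocks; ties are reported as ``None``."""
    per_block_labels = [np.asarray(l, dtype=object) for l in per_block_labels]
    n = per_block_labels[0].shape[-1]
    out = np.empty(n, dtype=object)
    for i in range(n):
        votes = [l[i] for l in per_block_labels]
        counts: dict = {}
        for v in votes:
            counts[v] = counts.get(v, 0) + 1
        best = max(counts.values())
        winners = [c for c, k in counts.items() if k == best]
        out[i] = winners[0] if len(winners) == 1 else None
    return out


def block_weights(model: FittedModel) -> np.ndarray:
    """Per-block outcome weight for the weighted vote.

    For each component of a block the correlation with the outcome is the
    multiple correlation of the component on the dummy indicator (the
    plain |correlation| for two classes); the block weight is the mean
    over components.
    """
    Y = model.y_indicator
    Yc = Y - Y.mean(axis=0)
    w = np.zeros(model.n_blocks)
    for b in range(model.n_blocks):
        rs = []
        for h in range(model.ncomp):
            t = model.scores[b][:, h]
            tc = t - t.mean()
            tt = float(tc @ tc)
            if tt == 0:
                rs.append(0.0)
                continue
            beta, *_ = np.linalg.lstsq(Yc, tc, rcond=None)
            fitted = Yc @ beta
            r2 = float(fitted @ fitted) / tt
            rs.append(np.sqrt(max(min(r2, 1.0), 0.0)))
        w[b] = float(np.mean(rs))
    return w


def weighted_vote(per_block_labels, weights) -> np.ndarray:
    """Weighted vote: the class with the highest total block weight wins;
    residual ties (equal total weight) are ``None``."""
    per_block_labels = [np.asarray(l, dtype=object) for l in per_block_labels]
    weights = np.asarray(weights, dtype=float)
    n = per_block_labels[0].shape[-1]
    out = np.empty(n, dtype=object)
    for i in range(n):
        tally: dict = {}
        for b, l in enumerate(per_block_labels):
            tally[l[i]] = tally.get(l[i], 0.0) + weights[b]
        best = max(tally.values())
        winners = [c for c, v in tally.items() if abs(v - best) < 1e-12]
        out[i] = winners[0] if len(winners) == 1 else None
    return out


def predict(model: FittedModel, Xnew, feature_ids=None, study=None) -> Prediction:
    """Full prediction for new samples on every block of the model.

    ``Xnew`` is one matrix for single-block models or a list of matrices
    (one per block, same sample order) for multi-block models.
    """
    if model.class_labels is None and model.mode == "pca":
        raise ValueError("PCA models do not predict classes; use project_new")
    if model.n_blocks == 1 and not isinstance(Xnew, (list, tuple)):
        Xnew = [Xnew]
    if len(Xnew) != model.n_blocks:
        raise ValueError(f"expected {model.n_blocks} new-data blocks, got {len(Xnew)}")
    if feature_ids is not None and not isinstance(feature_ids[0], (list, tuple)):
        feature_ids = [feature_ids]

    scores, dummies = [], []
    for b in range(model.n_blocks):
        fid = feature_ids[b] if feature_ids is not None else None
        s = project_new(model, Xnew[b], block=b, feature_ids=fid, study=study)
        scores.append(s)
        dummies.append(predict_dummy(model, s, block=b))
    combined = np.mean(dummies, axis=0)

    class_by_distance = {}
    for dist in DISTANCES:
        class_by_distance[dist] = [
            assign_class(model, scores[b], dummies[b], distance=dist, block=b)
            for b in range(model.n_blocks)
        ]

    pred = Prediction(scores, dummies, combined, class_by_distance)
    if model.n_blocks > 1:
        w = block_weights(model)
        pred.block_weights = w
        H = model.ncomp
        n_new = scores[0].shape[0]
        for dist in DISTANCES:
            maj = np.empty((H, n_new), dtype=object)
            wv = np.empty((H, n_new), dtype=object)
            for h in range(H):
                per_block = [class_by_distance[dist][b][h]
                             for b in range(model.n_blocks)]
                maj[h] = combine_votes(per_block)
                wv[h] = weighted_vote(per_block, w)
            pred.majority_vote[dist] = maj
            pred.weighted_vote[dist] = wv
    return pred


def prediction_region(model: FittedModel, distance: str = "max",
                      grid_n: int = 100, comps=(1, 2), block: int = 0):
    """Classify a rectangular grid of the component-score plane.

    The grid spans the training score range on the chosen components with
    a 10% margin; each grid point is treated as a predicted score at depth
    ``len(comps)`` and classified by the chosen distance. Returns
    ``(xs, ys, labels)`` with ``labels`` a (grid_n, grid_n) object array
    (for one-component models: ``(xs, labels)`` with a 1-D grid).
    """
    comps = tuple(c for c in comps if c <= model.ncomp)
    if not comps:
        raise ValueError("no valid components for the prediction region")
    depth = max(comps)
    T = model.scores[block][:, :depth]
    labels_arr = np.asarray(model.class_labels, dtype=object)

    def classify(points):
        if distance == "max":
            intercept, beta = model.y_coefs[block][depth - 1]
            dummy = intercept + points @ beta
            return labels_arr[np.argmax(dummy, axis=1)]
        ind = model.y_indicator
        cents = _centroids(T, ind)
        diff = points[:, None, :] - cents[None, :, :]
        if distance == "centroid":
            d2 = np.einsum("nkh,nkh->nk", diff, diff)
        else:
            S = _pooled_within_cov(T, ind)
            Sinv = np.linalg.inv(S)
            d2 = np.einsum("nkh,hj,nkj->nk", diff, Sinv, diff)
        return labels_arr[np.argmin(d2, axis=1)]

    def axis(c):
        v = model.scores[block][:, c - 1]
        lo, hi = v.min(), v.max()
        m = 0.1 * (hi - lo)
        return np.linspace(lo - m, hi + m, grid_n)

    if len(comps) == 1:
        xs = axis(comps[0])
        pts = np.zeros((grid_n, depth))
        pts[:, comps[0] - 1] = xs
        return xs, classify(pts)
    xs, ys = axis(comps[0]), axis(comps[1])
    gx, gy = np.meshgrid(xs, ys)
    pts = np.zeros((grid_n * grid_n, depth))
    pts[:, comps[0] - 1] = gx.ravel()
    pts[:, comps[1] - 1] = gy.ravel()
    lab = classify(pts).reshape(grid_n, grid_n)
    return xs, ys, lab
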