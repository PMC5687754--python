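"""Numeric backends for the standard multivariate plots.

These functions compute the coordinates, orderings and edge lists behind
sample plots, correlation circles, clustered image maps (CIM), relevance
networks / circos-style similarity links, loading barplots and arrow
plots. Rendering is left to the caller (any plotting library will do);
every backend returns plain arrays / dataclasses that are easy to dump to
TSV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.stats import chi2

from .containers import FittedModel

__all__ = [
    "SimilarityEdge", "correlation_circle", "feature_similarity",
    "cim_data", "loading_display", "arrow_data", "sample_plot_data",
]


@dataclass(frozen=True)
class SimilarityEdge:
    """Undirected component-based similarity between two selected features."""

    feature_i: str
    feature_j: str
    block_i: str
    block_j: str
    similarity: float

    @property
    def positive(self) -> bool:
        return self.similarity > 0


def _require_xstd(model: FittedModel):
    if model.X_std is None:
        raise ValueError("model does not carry its training data; "
                         "refit with the standard constructors")


def _feature_component_cor(model: FittedModel, block: int, comps) -> np.ndarray:
    """Correlation of every block feature with the block's components."""
    _require_xstd(model)
    X = model.X_std[block]
    T = model.scores[block]
    out = np.zeros((X.shape[1], len(comps)))
    Xc = X - X.mean(axis=0)
    sx = np.sqrt(np.sum(Xc * Xc, axis=0))
    for ci, h in enumerate(comps):
        t = T[:, h - 1]
        tc = t - t.mean()
        st = np.sqrt(float(tc @ tc))
        denom = sx * st
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, Xc.T @ tc / denom, 0.0)
        out[:, ci] = r
    return out


def correlation_circle(model: FittedModel, block: int = 0, comps=(1, 2)):
    """Feature coordinates on the correlation circle.

    Coordinate h is the correlation between the (standardised) feature and
    the block's component t_h; only features selected on at least one of
    the requested components are emitted. Returns (feature_ids, coords).
    """
    comps = tuple(c for c in comps if c <= model.ncomp)
    cors = _feature_component_cor(model, block, comps)
    a = model.loadings[block]
    mask = np.zeros(a.shape[0], dtype=bool)
    for c in comps:
        mask |= a[:, c - 1] != 0
    feats = [f for f, m in zip(model.feature_ids[block], mask) if m]
    return feats, cors[mask]


def feature_similarity(model: FittedModel, threshold: float = 0.7,
                       comps=None) -> list[SimilarityEdge]:
    """Component-proxy similarity edges between selected features.

    similarity(i, j) = sum_h cor(x_i, t_h) cor(x_j, t_h), each feature
    correlated with its own block's components; edges are kept when
    |similarity| exceeds ``threshold`` (default 0.7, the conventional
    relevance-network cut-off). Cross-block and within-block pairs are
    both reported; self-pairs never are.
    """
    comps = tuple(range(1, model.ncomp + 1)) if comps is None else tuple(comps)
    feats_all, cors_all, blocks_all = [], [], []
    for b in range(model.n_blocks):
        a = model.loadings[b]
        mask = np.zeros(a.shape[0], dtype=bool)
        for c in comps:
            mask |= a[:, c - 1] != 0
        cors = _feature_component_cor(model, b, comps)[mask]
        ids = [f for f, m in zip(model.feature_ids[b], mask) if m]
        feats_all.extend(ids)
        blocks_all.extend([model.block_names[b]] * len(ids))
        cors_all.append(cors)
    M = np.vstack(cors_all) if cors_all else np.zeros((0, len(comps)))
    sim = M @ M.T
    edges = []
    for i in range(len(feats_all)):
        for j in range(i + 1, len(feats_all)):
            s = float(sim[i, j])
            if abs(s) > threshold:
                edges.append(SimilarityEdge(feats_all[i], feats_all[j],
                                            blocks_all[i], blocks_all[j], s))
    return edges


def cim_data(model: FittedModel, comp_depth: int | None = None):
    """Matrix and leaf orders for a clustered image map.

    Rows are samples, columns the features selected on components
    1..comp_depth (all blocks concatenated), values standardised as used
    in the fit. Both dendrograms use Euclidean distance with complete
    linkage. Returns a dict with the matrix, ids and leaf orders.
    """
    _require_xstd(model)
    depth = comp_depth or model.ncomp
    cols, col_ids, col_blocks = [], [], []
    for b in range(model.n_blocks):
        a = model.loadings[b]
        mask = (a[:, :depth] != 0).any(axis=1)
        cols.append(model.X_std[b][:, mask])
        col_ids.extend(f for f, m in zip(model.feature_ids[b], mask) if m)
        col_blocks.extend([model.block_names[b]] * int(mask.sum()))
    mat = np.hstack(cols)
    if mat.shape[1] < 2 or mat.shape[0] < 2:
        row_order = np.arange(mat.shape[0])
        col_order = np.arange(mat.shape[1])
    else:
        row_order = leaves_list(linkage(pdist(mat), method="complete"))
        col_order = leaves_list(linkage(pdist(mat.T), method="complete"))
    return {
        "matrix": mat,
        "sample_ids": list(model.sample_ids),
        "feature_ids": col_ids,
        "feature_blocks": col_blocks,
        "row_order": row_order,
        "col_order": col_order,
    }


def loading_display(model: FittedModel, comp: int = 1, block: int = 0,
                    study: str | None = None, maximum: bool = True):
    """Ordered loading-barplot data for one component.

    Returns (feature, weight, class_label) triples sorted by increasing
    |weight| (bottom-to-top of the pyramid barplot). The class label is
    the outcome class with the maximal (or minimal) mean standardised
    value of that feature; with ``study`` given, means are computed within
    that study only.
    """
    if model.class_labels is None:
        raise ValueError("loading_display requires a discriminant model")
    _require_xstd(model)
    a = model.loadings[block][:, comp - 1]
    mask = a != 0
    X = model.X_std[block]
    rows = np.arange(X.shape[0])
    if study is not None:
        if model.study_labels is None:
            raise ValueError("model was not fitted with study information")
        rows = rows[model.study_labels == str(study)]
    ind = model.y_indicator[rows]
    triples = []
    for j in np.where(mask)[0]:
        means = [X[rows, j][ind[:, k] == 1].mean()
                 if (ind[:, k] == 1).any() else np.nan
                 for k in range(ind.shape[1])]
        pick = np.nanargmax(means) if maximum else np.nanargmin(means)
        triples.append((model.feature_ids[block][j], float(a[j]),
                        model.class_labels[int(pick)]))
    triples.sort(key=lambda t: abs(t[1]))
    return triples


def arrow_data(model: FittedModel, comps=(1, 2)):
    """Per-sample arrow start/end coordinates.

    The start is the sample's predictor-space variate (averaged over
    blocks for multi-block fits), the end its outcome-space variate; short
    arrows mean the model's two views of the sample agree.
    """
    if model.y_scores is None:
        raise ValueError("arrow_data requires a supervised fit")
    comps = tuple(c for c in comps if c <= model.ncomp)
    idx = [c - 1 for c in comps]
    start = np.mean([model.scores[b][:, idx] for b in range(model.n_blocks)],
                    axis=0)
    end = model.y_scores[:, idx]
    return start, end


def _ellipse_params(points: np.ndarray, level: float = 0.95):
    mean = points.mean(axis=0)
    cov = np.cov(points, rowvar=False)
    r2 = chi2.ppf(level, df=points.shape[1])
    vals, vecs = np.linalg.eigh(cov)
    return {"mean": mean, "cov": cov, "radii": np.sqrt(np.maximum(vals, 0) * r2),
            "axes": vecs, "level": level}


def sample_plot_data(model: FittedModel, block: int = 0, comps=(1, 2),
                     by_study: bool = False, ellipse_level: float = 0.95):
    """Score coordinates with class labels and 95% confidence ellipses.

    Returns a dict (or study-name -> dict when ``by_study``) with
    ``coords`` (N x len(comps)), ``labels`` and per-class bivariate-normal
    ellipse parameters.
    """
    comps = tuple(c for c in comps if c <= model.ncomp)
    idx = [c - 1 for c in comps]
    coords = model.scores[block][:, idx]
    labels = (np.asarray([str(v) for v in model.y])
              if model.y is not None else np.array(["-"] * coords.shape[0]))

    def pack(rows):
        sub, lab = coords[rows], labels[rows]
        ellipses = {}
        if model.class_labels and len(comps) == 2:
            for c in model.class_labels:
                pts = sub[lab == c]
                if len(pts) > 2:
                    ellipses[c] = _ellipse_params(pts, ellipse_level)
        return {"coords": sub, "labels": lab,
                "sample_ids": [model.sample_ids[i] for i in rows],
                "ellipses": ellipses}

    if by_study:
        if model.study_labels is None:
            raise ValueError("model was not fitted with study information")
        return {s: pack(np.where(model.study_labels == s)[0])
                for s in sorted(set(model.study_labels))}
    return pack(np.arange(coords.shape[0]))
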