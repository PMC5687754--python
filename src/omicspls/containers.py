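"""Core data containers for supervised multivariate omics analysis.

Samples are rows everywhere; features are columns; matrices are dense
:class:`numpy.ndarray`. Containers are plain dataclasses: they validate on
construction and carry the bookkeeping (identifiers, standardisation
parameters, sparsity record) that model fitting and prediction need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OmicsBlock",
    "OutcomeDummy",
    "DesignMatrix",
    "FittedModel",
]


def _as_labels(labels, n: int, prefix: str) -> list[str]:
    if labels is None:
        return [f"{prefix}{i + 1}" for i in range(n)]
    labels = [str(x) for x in labels]
    if len(labels) != n:
        raise ValueError(f"expected {n} {prefix} labels, got {len(labels)}")
    if len(set(labels)) != n:
        dup = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate {prefix} identifiers: {dup[:5]}")
    return labels


@dataclass
class OmicsBlock:
    """One samples x features continuous matrix with identifiers.

    Missing values (NaN) are tolerated by the container; individual
    operations declare whether they accept them (only NIPALS PCA does).

    Parameters
    ----------
    values
        N x P float matrix, samples in rows.
    sample_ids, feature_ids
        Unique labels; generated (``s1..``, ``f1..``) when omitted.
    standardized
        Whether columns have been centred (and possibly scaled); set by
        :func:`omicspls.engine.center_and_scale`.
    col_means, col_sds
        Standardisation parameters recorded for projecting new samples.
    """

    values: np.ndarray
    sample_ids: list[str] = None
    feature_ids: list[str] = None
    standardized: bool = False
    col_means: np.ndarray | None = None
    col_sds: np.ndarray | None = None
    name: str = "X"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x features matrix")
        n, p = self.values.shape
        if n < 2:
            raise ValueError("need at least 2 samples")
        if p < 1:
            raise ValueError("need at least 1 feature")
        if np.isinf(self.values).any():
            raise ValueError("infinite entries are not allowed")
        self.sample_ids = _as_labels(self.sample_ids, n, "s")
        self.feature_ids = _as_labels(self.feature_ids, p, "f")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def copy(self) -> "OmicsBlock":
        return OmicsBlock(
            self.values.copy(),
            list(self.sample_ids),
            list(self.feature_ids),
            self.standardized,
            None if self.col_means is None else self.col_means.copy(),
            None if self.col_sds is None else self.col_sds.copy(),
            self.name,
        )


@dataclass
class OutcomeDummy:
    """N x K dummy indicator matrix derived from a categorical outcome.

    ``indicator[i, k] == 1`` iff sample ``i`` belongs to class ``k``;
    classes are ordered by sorted label.
    """

    indicator: np.ndarray
    class_labels: list[str]
    y: np.ndarray

    def __post_init__(self):
        self.indicator = np.asarray(self.indicator, dtype=float)
        self.y = np.asarray(self.y)
        if self.indicator.ndim != 2 or self.indicator.shape[1] < 2:
            raise ValueError("indicator must be N x K with K >= 2")
        if not np.allclose(self.indicator.sum(axis=1), 1.0):
            raise ValueError("each indicator row must sum to exactly 1")
        counts = self.indicator.sum(axis=0)
        if (counts < 1).any():
            empty = [l for l, c in zip(self.class_labels, counts) if c < 1]
            raise ValueError(f"classes with no samples: {empty}")

    @property
    def n_classes(self) -> int:
        return self.indicator.shape[1]

    @property
    def class_counts(self) -> np.ndarray:
        return self.indicator.sum(axis=0).astype(int)


@dataclass
class DesignMatrix:
    """Symmetric block-connection weights for multi-block models.

    ``weights[i, j]`` in [0, 1] sets how strongly the covariance between
    the scores of blocks *i* and *j* enters the objective; the diagonal is
    zero (a block is never connected to itself). The outcome block is
    handled separately and always connected with weight 1.
    """

    weights: np.ndarray
    block_names: list[str] = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        b = self.weights.shape[0]
        if self.weights.shape != (b, b) or b < 1:
            raise ValueError("design must be a square B x B matrix, B >= 1")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("design matrix must be symmetric")
        if np.diag(self.weights).any():
            raise ValueError("design diagonal must be zero")
        if ((self.weights < 0) | (self.weights > 1)).any():
            raise ValueError("design weights must lie in [0, 1]")
        self.block_names = _as_labels(self.block_names, b, "block")

    @classmethod
    def default(cls, n_blocks: int, off_diagonal: float = 0.1,
                block_names=None) -> "DesignMatrix":
        """Weakly-connected default: all block-block weights ``off_diagonal``."""
        w = np.full((n_blocks, n_blocks), float(off_diagonal))
        np.fill_diagonal(w, 0.0)
        return cls(w, block_names)


@dataclass
class FittedModel:
    """Everything a fitted projection model knows.

    Attributes
    ----------
    loadings
        Per block: P_b x H matrix of loading vectors ``a_h`` (unit norm,
        exactly ``keepX[b][h]`` nonzeros for sparse fits).
    scores
        Per block: N x H latent component matrix ``t_h``.
    y_loadings
        K x H outcome-side weights (unit norm per component); ``None`` for PCA.
    y_coefs
        Per block, per depth h: regression coefficients (h x K) plus
        intercept used to predict the dummy outcome from the first h
        scores of that block.
    projection
        Per block: P_b x H matrix of regression vectors ``p_h`` used to
        replay the deflation sequence on new samples.
    explained_variance
        Per block: fraction of (standardised) block variance captured by
        each component.
    """

    method: str
    loadings: list[np.ndarray]
    scores: list[np.ndarray]
    y_loadings: np.ndarray | None
    projection: list[np.ndarray]
    keepX: list[list[int]]
    ncomp: int
    mode: str
    block_names: list[str]
    feature_ids: list[list[str]]
    sample_ids: list[str]
    col_means: list[np.ndarray]
    col_sds: list[np.ndarray]
    scaled: bool
    class_labels: list[str] | None = None
    y: np.ndarray | None = None
    y_indicator: np.ndarray | None = None
    y_coefs: list[list[tuple[np.ndarray, np.ndarray]]] | None = None
    study_labels: np.ndarray | None = None
    study_params: dict | None = None
    design: np.ndarray | None = None
    convergence: list[dict] = field(default_factory=list)
    explained_variance: list[np.ndarray] = field(default_factory=list)
    X_std: list[np.ndarray] | None = None
    y_scores: np.ndarray | None = None

    @property
    def n_blocks(self) -> int:
        return len(self.loadings)

    @property
    def is_discriminant(self) -> bool:
        return self.class_labels is not None

    def block_index(self, name: str) -> int:
        try:
            return self.block_names.index(name)
        except ValueError:
            raise KeyError(f"unknown block {name!r}; have {self.block_names}")

    def selected_features(self, block: int = 0, comp: int | None = None):
        """Feature ids with nonzero loading on ``comp`` (1-based), or on
        any component when ``comp`` is None."""
        a = self.loadings[block]
        if comp is not None:
            mask = a[:, comp - 1] != 0
        else:
            mask = (a != 0).any(axis=1)
        return [f for f, m in zip(self.feature_ids[block], mask) if m]
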