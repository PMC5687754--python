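"""User-facing model constructors.

Ten supervised/unsupervised entry points over the one generic engine:

============  ====================================================
``pca``       principal components (NIPALS, missing-value tolerant)
``spca``      sparse PCA (keepX features per component)
``pls``       two-block PLS regression, continuous response
``spls``      sparse PLS regression
``plsda``     PLS discriminant analysis (dummy-coded outcome)
``splsda``    sparse PLS-DA with keepX feature selection
``block_plsda``   multi-block (N-integration) PLS-DA
``block_splsda``  sparse multi-block PLS-DA (DIABLO-style)
``mint_plsda``    multi-study (P-integration) PLS-DA
``mint_splsda``   sparse multi-study PLS-DA (MINT-style)
============  ====================================================

Each constructor validates its argument combination and delegates to
:func:`omicspls.engine.fit_model` / :func:`omicspls.engine.nipals_pca`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import DesignMatrix, FittedModel, OmicsBlock
from .engine import encode_dummy, fit_model, nipals_pca

__all__ = [
    "pca", "spca", "pls", "spls", "plsda", "splsda",
    "block_plsda", "block_splsda", "mint_plsda", "mint_splsda",
    "METHODS", "MethodSpec",
]


def _as_block(X, name="X") -> OmicsBlock:
    if isinstance(X, OmicsBlock):
        return X
    return OmicsBlock(np.asarray(X, dtype=float), name=name)


def _as_blocks(X_list, names=None) -> list[OmicsBlock]:
    if isinstance(X_list, (OmicsBlock, np.ndarray)):
        raise ValueError("block methods expect a list (or dict) of blocks; "
                         "use plsda/splsda for a single data set")
    if isinstance(X_list, dict):
        return [_as_block(v, name=str(k)) for k, v in X_list.items()]
    return [_as_block(x, name=f"block{i + 1}") for i, x in enumerate(X_list)]


def _default_ncomp_da(y) -> int:
    k = len({str(v) for v in np.asarray(y)})
    return max(1, k - 1)


# -- single omics -----------------------------------------------------------

def pca(X, ncomp: int = 2, scale: bool = False) -> FittedModel:
    """Principal component analysis; accepts missing values (NIPALS)."""
    return nipals_pca(_as_block(X), ncomp=ncomp, scale=scale)


def spca(X, ncomp: int = 2, keepX=None, scale: bool = False) -> FittedModel:
    """Sparse PCA selecting ``keepX`` features per component."""
    return nipals_pca(_as_block(X), ncomp=ncomp, keepX=keepX, scale=scale)


def pls(X, Y, ncomp: int = 2, scale: bool = True) -> FittedModel:
    """Two-block PLS regression with a continuous response."""
    return spls(X, Y, ncomp=ncomp, keepX=None, scale=scale)


def spls(X, Y, ncomp: int = 2, keepX=None, scale: bool = True) -> FittedModel:
    """Sparse PLS regression: keepX X-features per component."""
    block = _as_block(X)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    Yc = Y - Y.mean(axis=0)
    sds = Y.std(axis=0, ddof=1)
    sds = np.where(sds == 0, 1.0, sds)
    if scale:
        Yc = Yc / sds
    m = fit_model([block], Y=Yc, design=DesignMatrix(np.zeros((1, 1))),
                  ncomp=ncomp, keepX=keepX, scale=scale,
                  method="spls" if keepX is not None else "pls")
    return m


def plsda(X, y, ncomp: int | None = None, scale: bool = True) -> FittedModel:
    """PLS discriminant analysis on a single block.

    The categorical outcome is dummy-coded internally; ``ncomp`` defaults
    to K-1 for K classes.
    """
    return splsda(X, y, ncomp=ncomp, keepX=None, scale=scale)


def splsda(X, y, ncomp: int | None = None, keepX=None,
           scale: bool = True) -> FittedModel:
    """Sparse PLS-DA: selects ``keepX`` features per component.

    ``keepX`` may be a single integer (same on every component) or a
    per-component list; omitted means all features (dense PLS-DA).
    """
    block = _as_block(X)
    dummy = encode_dummy(y)
    if ncomp is None:
        ncomp = _default_ncomp_da(y)
    m = fit_model([block], Y=dummy, design=DesignMatrix(np.zeros((1, 1))),
                  ncomp=ncomp, keepX=keepX, scale=scale,
                  method="splsda" if keepX is not None else "plsda")
    return m


# -- N-integration ----------------------------------------------------------

def block_plsda(X_list, y, design=None, ncomp: int | None = None,
                scale: bool = True) -> FittedModel:
    """Multi-block PLS-DA: several omics blocks on the same samples."""
    return block_splsda(X_list, y, design=design, ncomp=ncomp,
                        keepX=None, scale=scale)


def block_splsda(X_list, y, design=None, ncomp: int | None = None,
                 keepX=None, scale: bool = True) -> FittedModel:
    """Sparse multi-block PLS-DA (DIABLO-style N-integration).

    ``design`` sets the block-connection weights (default: 0.1 between
    every pair of blocks, 1 to the outcome); ``keepX`` is a per-block list
    of per-component selection sizes.
    """
    blocks = _as_blocks(X_list)
    dummy = encode_dummy(y)
    if ncomp is None:
        ncomp = _default_ncomp_da(y)
    if design is None:
        design = DesignMatrix.default(len(blocks),
                                      block_names=[b.name for b in blocks])
    m = fit_model(blocks, Y=dummy, design=design, ncomp=ncomp, keepX=keepX,
                  scale=scale,
                  method="block_splsda" if keepX is not None else "block_plsda")
    return m


# -- P-integration ----------------------------------------------------------

def mint_plsda(X, y, study, ncomp: int | None = None,
               scale: bool = True) -> FittedModel:
    """Multi-study PLS-DA: one block measured across independent studies."""
    return mint_splsda(X, y, study, ncomp=ncomp, keepX=None, scale=scale)


def mint_splsda(X, y, study, ncomp: int | None = None, keepX=None,
                scale: bool = True) -> FittedModel:
    """Sparse multi-study PLS-DA (MINT-style P-integration).

    Each feature is centred and scaled within each study before the global
    fit, which removes additive and multiplicative batch effects; loadings
    are global, scores are available globally and per study.
    """
    block = _as_block(X)
    study = np.asarray(study)
    if len(study) != block.n_samples:
        raise ValueError("study vector length must match sample count")
    dummy = encode_dummy(y)
    if ncomp is None:
        ncomp = _default_ncomp_da(y)
    m = fit_model([block], Y=dummy, design=DesignMatrix(np.zeros((1, 1))),
                  ncomp=ncomp, keepX=keepX, study=study, scale=scale,
                  method="mint_splsda" if keepX is not None else "mint_plsda")
    return m


METHODS = {
    "pca": pca, "spca": spca, "pls": pls, "spls": spls,
    "plsda": plsda, "splsda": splsda,
    "block_plsda": block_plsda, "block_splsda": block_splsda,
    "mint_plsda": mint_plsda, "mint_splsda": mint_splsda,
}


@dataclass
class MethodSpec:
    """A fully specified model: method name plus every argument.

    Validates argument compatibility on construction (study only for
    mint_*, multiple blocks only for block_*, no outcome for pca/spca)
    and fits on demand — convenient for passing one object through
    tuning and performance-evaluation pipelines.
    """

    method: str
    X: object
    y: object = None
    design: object = None
    ncomp: int | None = None
    keepX: object = None
    study: object = None
    scale: bool = True

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.study is not None and not self.method.startswith("mint_"):
            raise ValueError("'study' is only valid for mint_* methods")
        multi = isinstance(self.X, (list, dict)) \
            and not isinstance(self.X, np.ndarray)
        if multi and not self.method.startswith("block_"):
            raise ValueError("multiple blocks require a block_* method")
        if self.method in ("pca", "spca") and self.y is not None:
            raise ValueError(f"{self.method} is unsupervised")
        if self.method not in ("pca", "spca") and self.y is None:
            raise ValueError(f"{self.method} requires an outcome")

    def fit(self) -> FittedModel:
        kwargs = {k: getattr(self, k)
                  for k in ("design", "ncomp", "keepX", "study", "scale")
                  if getattr(self, k) is not None}
        return fit_by_name(self.method, self.X, self.y, **kwargs)


def fit_by_name(method: str, X, y=None, **kwargs) -> FittedModel:
    """Dispatch by method name with argument-compatibility validation."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from "
                         f"{sorted(METHODS)}")
    if "study" in kwargs and kwargs["study"] is not None \
            and not method.startswith("mint_"):
        raise ValueError(f"'study' is only valid for mint_* methods, not {method!r}")
    multi = isinstance(X, (list, dict)) and not isinstance(X, np.ndarray)
    if multi and not method.startswith("block_"):
        raise ValueError(f"multiple blocks require a block_* method, not {method!r}")
    if not multi and method.startswith("block_"):
        X = [X]
    if method in ("pca", "spca"):
        if y is not None:
            raise ValueError(f"{method} is unsupervised; no outcome allowed")
        return METHODS[method](X, **kwargs)
    if y is None:
        raise ValueError(f"{method} requires an outcome")
    if method.startswith("mint_"):
        study = kwargs.pop("study", None)
        if study is None:
            raise ValueError(f"{method} requires a 'study' vector")
        return METHODS[method](X, y, study, **kwargs)
    kwargs.pop("study", None)
    return METHODS[method](X, y, **kwargs)
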