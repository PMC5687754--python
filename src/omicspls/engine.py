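"""Generic iterative fitting engine for PLS-family projection models.

Every supervised method in this package — PLS-DA, sparse PLS-DA, the
multi-block and multi-study variants — is an instantiation of one
alternating algorithm: each block's loading vector is recomputed from the
design-weighted sum of the scores of the blocks it is connected to (the
outcome, coded as a dummy matrix, counts as a connected block), sparsified
by soft-thresholding to exactly ``keepX`` nonzero weights, and
unit-normalised, until the loadings stop moving. Components beyond the
first are obtained by regression deflation.

The solver is deterministic: initialisation is the first singular vector of
:math:`X_b^T Y` and a fixed sign rule (largest-magnitude loading entry
positive) is applied to every converged component.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.linalg import svd

from .containers import DesignMatrix, FittedModel, OmicsBlock, OutcomeDummy

__all__ = [
    "center_and_scale",
    "encode_dummy",
    "sparsify_loading",
    "fit_component",
    "deflate",
    "fit_model",
    "fit_mint_standardise",
    "nipals_pca",
]

TOL = 1e-6
MAX_ITER = 100


# ---------------------------------------------------------------------------
# standardisation and encoding
# ---------------------------------------------------------------------------

def center_and_scale(block: OmicsBlock, scale: bool = True) -> OmicsBlock:
    """Centre every column to mean 0 and, optionally, scale to unit sd.

    The sd uses the N-1 denominator. Constant columns are left at zero
    after centering and their sd is recorded as 1 so that projection of
    new samples never divides by zero. Missing cells are ignored when
    computing the parameters and stay missing afterwards.
    """
    if block.standardized:
        raise ValueError(f"block {block.name!r} is already standardized")
    x = block.values
    n_obs = np.sum(~np.isnan(x), axis=0)
    if (n_obs == 0).any():
        bad = [block.feature_ids[j] for j in np.where(n_obs == 0)[0]]
        raise ValueError(f"all-missing columns: {bad[:5]}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(x, axis=0)
        sds = np.nanstd(x, axis=0, ddof=1)
    sds = np.where(np.isnan(sds) | (sds == 0), 1.0, sds)
    out = (x - means) / (sds if scale else 1.0)
    return OmicsBlock(
        out, list(block.sample_ids), list(block.feature_ids),
        standardized=True, col_means=means,
        col_sds=sds if scale else np.ones_like(sds), name=block.name,
    )


def encode_dummy(y) -> OutcomeDummy:
    """Encode a categorical outcome as an N x K dummy indicator matrix.

    Classes are ordered by sorted label; column k is 1 for samples of
    class k and 0 elsewhere.
    """
    y = np.asarray(y)
    labels = sorted({str(v) for v in y})
    if len(labels) < 2:
        raise ValueError("outcome must have at least 2 distinct classes")
    ys = np.array([str(v) for v in y])
    indicator = np.column_stack([(ys == lab).astype(float) for lab in labels])
    return OutcomeDummy(indicator, labels, y)


def fit_mint_standardise(block: OmicsBlock, study, scale: bool = True) -> OmicsBlock:
    """Centre (and scale) each feature within each study separately.

    This is the batch-robust standardisation used for multi-study
    (P-integration) fits: per-study additive offsets vanish exactly, and
    with scaling so do per-study multiplicative factors. Per-study
    parameters are attached for projecting samples from known studies.
    """
    if block.standardized:
        raise ValueError(f"block {block.name!r} is already standardized")
    study = np.asarray([str(s) for s in study])
    if len(study) != block.n_samples:
        raise ValueError("study vector length must match sample count")
    out = np.empty_like(block.values)
    params: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for s in sorted(set(study)):
        idx = np.where(study == s)[0]
        if len(idx) < 2:
            hint = "; use scale=False (centering-only) or merge studies" if scale else ""
            raise ValueError(
                f"study {s!r} has {len(idx)} sample(s); at least 2 required{hint}")
        sub = OmicsBlock(block.values[idx],
                         [block.sample_ids[i] for i in idx],
                         block.feature_ids, name=block.name)
        std = center_and_scale(sub, scale=scale)
        out[idx] = std.values
        params[s] = (std.col_means, std.col_sds)
    gmeans = np.nanmean(block.values, axis=0)
    gsds = np.nanstd(block.values, axis=0, ddof=1)
    gsds = np.where(np.isnan(gsds) | (gsds == 0), 1.0, gsds)
    res = OmicsBlock(out, list(block.sample_ids), list(block.feature_ids),
                     standardized=True, col_means=gmeans,
                     col_sds=gsds if scale else np.ones_like(gsds),
                     name=block.name)
    res.study_params = params  # type: ignore[attr-defined]
    return res


# ---------------------------------------------------------------------------
# sparsity
# ---------------------------------------------------------------------------

def sparsify_loading(w: np.ndarray, keepX: int) -> np.ndarray:
    """Soft-threshold ``w`` so that exactly ``keepX`` entries survive.

    The keepX largest entries in absolute value are kept, each shrunk
    toward zero by the (keepX+1)-th largest magnitude (no shrinkage when
    keepX equals the length of ``w``); the result is renormalised to unit
    Euclidean norm. Ties at the selection boundary are broken by feature
    index, and the threshold is nudged below the smallest kept magnitude
    so the nonzero count is exact even under ties.
    """
    w = np.asarray(w, dtype=float)
    p = w.size
    if not 1 <= keepX <= p:
        raise ValueError(f"keepX must be in [1, {p}], got {keepX}")
    if not w.any():
        warnings.warn("all-zero loading passed to sparsify_loading; returned unchanged")
        return w.copy()
    aw = np.abs(w)
    # stable order: by decreasing magnitude, ties by increasing index
    order = np.lexsort((np.arange(p), -aw))
    kept = order[:keepX]
    if keepX == p:
        lam = 0.0
    else:
        lam = aw[order[keepX]]
        min_kept = aw[kept].min()
        if lam >= min_kept:  # tie at the boundary
            lam = np.nextafter(min_kept, 0.0)
    out = np.zeros(p)
    out[kept] = np.sign(w[kept]) * (aw[kept] - lam)
    nrm = np.linalg.norm(out)
    if nrm > 0:
        out /= nrm
    return out


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _apply_sign_rule(a: np.ndarray):
    """Return +1/-1 so that the largest-|.| entry of ``a`` is positive
    (ties broken by lowest index, which argmax already guarantees)."""
    j = int(np.argmax(np.abs(a)))
    return -1.0 if a[j] < 0 else 1.0


# ---------------------------------------------------------------------------
# one component of the alternating solver
# ---------------------------------------------------------------------------

def fit_component(Xs: list[np.ndarray], Yc: np.ndarray,
                  design: np.ndarray, keepX: list[int],
                  tol: float = TOL, max_iter: int = MAX_ITER):
    """Extract one component from (deflated) blocks by alternating updates.

    Parameters
    ----------
    Xs
        Current (standardised, possibly deflated) block matrices.
    Yc
        Current (centred, possibly deflated) outcome-side matrix — the
        dummy indicator for discriminant fits or a continuous response.
    design
        B x B block-connection weights; the outcome is connected to every
        block with weight 1.
    keepX
        Number of features to keep per block for this component.

    Returns
    -------
    loadings, scores, y_loading, y_score, info
        Per-block unit-norm loadings ``a_b`` and scores ``t_b = X_b a_b``,
        the outcome loading ``c`` and score ``u = Yc c``, and a dict with
        iteration count / final change / convergence flag.
    """
    B = len(Xs)
    # deterministic init: first left singular vector of X_b' Y
    loadings = []
    for b in range(B):
        m = Xs[b].T @ Yc
        if not m.any():
            a0 = np.zeros(Xs[b].shape[1])
            a0[0] = 1.0
        else:
            u_, _, _ = svd(m, full_matrices=False)
            a0 = u_[:, 0]
        loadings.append(a0)
    scores = [Xs[b] @ loadings[b] for b in range(B)]
    c = _unit(Yc.T @ np.sum(scores, axis=0))
    u = Yc @ c

    info = {"iterations": 0, "final_change": np.inf, "converged": False}
    for it in range(1, max_iter + 1):
        change = 0.0
        for b in range(B):
            z = u.copy()  # outcome always connected, weight 1
            for j in range(B):
                if j != b and design[b, j] > 0:
                    z += design[b, j] * scores[j]
            w = Xs[b].T @ z
            a_new = sparsify_loading(w, keepX[b]) if w.any() else loadings[b]
            change = max(change, float(np.max(np.abs(a_new - loadings[b]))))
            loadings[b] = a_new
            scores[b] = Xs[b] @ a_new
        c = _unit(Yc.T @ np.sum(scores, axis=0))
        u = Yc @ c
        info["iterations"] = it
        info["final_change"] = change
        if change < tol:
            info["converged"] = True
            break
    if not info["converged"]:
        warnings.warn(
            f"component did not converge in {max_iter} iterations "
            f"(last change {info['final_change']:.2e})")
    # fixed sign rule for determinism; the outcome side follows the scores
    # so that t and u stay positively associated
    for b in range(B):
        s = _apply_sign_rule(loadings[b])
        loadings[b] = s * loadings[b]
        scores[b] = s * scores[b]
    align = float(u @ np.sum(scores, axis=0))
    s = -1.0 if align < 0 else (1.0 if align > 0 else _apply_sign_rule(c))
    c, u = s * c, s * u
    return loadings, scores, c, u, info


def deflate(X: np.ndarray, t: np.ndarray):
    """Regression deflation: remove the rank-1 contribution of score ``t``.

    Returns the deflated matrix and the regression vector
    ``p = X't / t't`` needed to replay the step on new samples.
    """
    tt = float(t @ t)
    if tt == 0:
        raise ValueError("zero-norm score cannot deflate")
    p = X.T @ t / tt
    return X - np.outer(t, p), p


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

def _resolve_keepx(keepX, B, ncomp, Ps):
    """Normalise user keepX (None / int / per-comp list / per-block lists)
    into a per-block list of per-component integers."""
    if keepX is None:
        return [[Ps[b]] * ncomp for b in range(B)]
    if isinstance(keepX, (int, np.integer)):
        return [[int(keepX)] * ncomp for _ in range(B)]
    keepX = list(keepX)
    if B == 1 and keepX and isinstance(keepX[0], (int, np.integer)):
        keepX = [keepX]
    out = []
    for b in range(B):
        kb = [int(k) for k in keepX[b]]
        if len(kb) < ncomp:
            kb = kb + [Ps[b]] * (ncomp - len(kb))
        if len(kb) != ncomp:
            raise ValueError(
                f"block {b}: keepX has {len(kb)} entries for ncomp={ncomp}")
        for k in kb:
            if not 1 <= k <= Ps[b]:
                raise ValueError(f"block {b}: keepX value {k} outside [1, {Ps[b]}]")
        out.append(kb)
    return out


def fit_model(blocks, Y=None, design: DesignMatrix | None = None,
              ncomp: int = 2, keepX=None, study=None, scale: bool = True,
              tol: float = TOL, max_iter: int = MAX_ITER,
              method: str = "pls") -> FittedModel:
    """Fit an H-component projection model on one or more blocks.

    ``Y`` is an :class:`OutcomeDummy` for discriminant fits, a continuous
    response matrix for regression fits. ``study`` switches the
    standardisation to study-wise (multi-study / batch-robust mode).
    Blocks not yet standardised are centred and scaled here; the
    parameters are stored so new samples can be projected identically.
    """
    if isinstance(blocks, OmicsBlock):
        blocks = [blocks]
    blocks = list(blocks)
    B = len(blocks)
    n = blocks[0].n_samples
    for blk in blocks[1:]:
        if blk.n_samples != n:
            raise ValueError("all blocks must share the same samples")
        if blk.sample_ids != blocks[0].sample_ids:
            raise ValueError("sample ids differ between blocks")

    study_labels = None
    study_params = None
    std_blocks = []
    for blk in blocks:
        if blk.standardized:
            std_blocks.append(blk)
        elif study is not None:
            sb = fit_mint_standardise(blk, study, scale=scale)
            study_params = getattr(sb, "study_params")
            std_blocks.append(sb)
        else:
            std_blocks.append(center_and_scale(blk, scale=scale))
    if study is not None:
        study_labels = np.asarray([str(s) for s in study])

    for sb in std_blocks:
        if np.isnan(sb.values).any():
            raise ValueError(
                f"block {sb.name!r} contains missing values; only NIPALS PCA "
                "accepts missing data")

    Ps = [sb.n_features for sb in std_blocks]
    if ncomp < 1:
        raise ValueError("ncomp must be >= 1")
    if ncomp >= n or ncomp >= min(Ps):
        raise ValueError(
            f"ncomp={ncomp} must be smaller than N={n} and every block's P "
            f"(min {min(Ps)})")

    if isinstance(Y, OutcomeDummy):
        dummy = Y
        y_raw = dummy.indicator
        class_labels = dummy.class_labels
    else:
        dummy = None
        y_raw = np.asarray(Y, dtype=float)
        if y_raw.ndim == 1:
            y_raw = y_raw[:, None]
        class_labels = None
    if y_raw.shape[0] != n:
        raise ValueError("response rows must match sample count")
    # outcome side: centred, never scaled (keeps X'Y identical to the raw
    # dummy cross-product and the dummy interpretable as class membership)
    Yc = y_raw - y_raw.mean(axis=0)

    if design is None:
        design_w = DesignMatrix.default(B).weights
    elif isinstance(design, DesignMatrix):
        design_w = design.weights
    else:
        design_w = DesignMatrix(np.asarray(design, dtype=float)).weights
    if design_w.shape[0] != B:
        raise ValueError(f"design is {design_w.shape[0]}x{design_w.shape[0]} "
                         f"but there are {B} blocks")

    keepX_r = _resolve_keepx(keepX, B, ncomp, Ps)

    Xw = [sb.values.copy() for sb in std_blocks]
    Yw = Yc.copy()
    X0_ss = [float(np.sum(x * x)) for x in Xw]

    loadings = [np.zeros((Ps[b], ncomp)) for b in range(B)]
    scores = [np.zeros((n, ncomp)) for b in range(B)]
    projection = [np.zeros((Ps[b], ncomp)) for b in range(B)]
    y_loadings = np.zeros((Yc.shape[1], ncomp))
    y_scores = np.zeros((n, ncomp))
    convergence = []
    expl = [np.zeros(ncomp) for _ in range(B)]

    for h in range(ncomp):
        kx = [keepX_r[b][h] for b in range(B)]
        a_h, t_h, c, u, info = fit_component(Xw, Yw, design_w, kx,
                                             tol=tol, max_iter=max_iter)
        for b in range(B):
            loadings[b][:, h] = a_h[b]
            scores[b][:, h] = t_h[b]
            Xw[b], p = deflate(Xw[b], t_h[b])
            projection[b][:, h] = p
            if X0_ss[b] > 0:
                expl[b][h] = float(t_h[b] @ t_h[b]) * float(p @ p) / X0_ss[b]
        y_loadings[:, h] = c
        y_scores[:, h] = u
        # regression deflation of the outcome on the (mean) X score
        t_bar = np.mean(t_h, axis=0)
        tt = float(t_bar @ t_bar)
        if tt > 0:
            Yw = Yw - np.outer(t_bar, t_bar @ Yw / tt)
        convergence.append(info)

    # per-block, per-depth least-squares map from scores to the raw outcome
    y_coefs = []
    for b in range(B):
        per_depth = []
        for h in range(1, ncomp + 1):
            T = scores[b][:, :h]
            A = np.column_stack([np.ones(n), T])
            coef, *_ = np.linalg.lstsq(A, y_raw, rcond=None)
            per_depth.append((coef[0], coef[1:]))
        y_coefs.append(per_depth)

    return FittedModel(
        method=method,
        loadings=loadings,
        scores=scores,
        y_loadings=y_loadings,
        projection=projection,
        keepX=keepX_r,
        ncomp=ncomp,
        mode="regression",
        block_names=[sb.name for sb in std_blocks],
        feature_ids=[list(sb.feature_ids) for sb in std_blocks],
        sample_ids=list(std_blocks[0].sample_ids),
        col_means=[sb.col_means for sb in std_blocks],
        col_sds=[sb.col_sds for sb in std_blocks],
        scaled=scale,
        class_labels=class_labels,
        y=None if dummy is None else dummy.y,
        y_indicator=y_raw if dummy is not None else y_raw,
        y_coefs=y_coefs,
        study_labels=study_labels,
        study_params=study_params,
        design=design_w,
        convergence=convergence,
        explained_variance=expl,
        X_std=[sb.values for sb in std_blocks],
        y_scores=y_scores,
    )


# ---------------------------------------------------------------------------
# NIPALS PCA (missing-value tolerant)
# ---------------------------------------------------------------------------

def nipals_pca(block: OmicsBlock, ncomp: int = 2, keepX=None,
               scale: bool = False, tol: float = 1e-12,
               max_iter: int = 20000) -> FittedModel:
    """PCA by the NIPALS power loop, skipping missing cells.

    On complete data this reproduces the truncated SVD (up to sign). With
    missing cells, inner products are restricted to observed entries and
    deflation subtracts the rank-1 reconstruction on observed cells only,
    which makes the fit usable as a simple low-rank imputation.

    ``keepX`` (per component) gives sparse PCA: the feature-side vector is
    soft-thresholded inside the loop.
    """
    sb = block if block.standardized else center_and_scale(block, scale=scale)
    X = sb.values.copy()
    n, p = X.shape
    if ncomp >= min(n, p) + 1:
        raise ValueError(f"ncomp={ncomp} too large for a {n}x{p} matrix")
    mask = ~np.isnan(X)
    if (~mask).all(axis=0).any() or (~mask).all(axis=1).any():
        raise ValueError("all-missing rows or columns are not allowed")
    Xf = np.where(mask, X, 0.0)
    total_var = float(np.sum(Xf * Xf))
    keepX_r = _resolve_keepx(keepX, 1, ncomp, [p])[0]

    T = np.zeros((n, ncomp))
    P = np.zeros((p, ncomp))
    expl = np.zeros(ncomp)
    convergence = []
    complete = mask.all()
    for h in range(ncomp):
        # start from the column with the largest observed variance
        j0 = int(np.argmax(np.sum(Xf * Xf, axis=0)))
        t = Xf[:, j0].copy()
        if not t.any():
            t = np.ones(n)
        info = {"iterations": 0, "final_change": np.inf, "converged": False}
        for it in range(1, max_iter + 1):
            if complete:
                v = X.T @ t / float(t @ t)
            else:
                num = Xf.T @ t
                den = mask.T @ (t * t)
                v = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
            if keepX_r[h] < p:
                v = sparsify_loading(v, keepX_r[h])
            else:
                v = _unit(v)
            if complete:
                t_new = X @ v
            else:
                num = Xf @ v
                den = mask @ (v * v)
                t_new = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
            change = float(np.max(np.abs(t_new - t)))
            t = t_new
            info["iterations"] = it
            info["final_change"] = change
            if change < tol * max(1.0, float(np.abs(t).max())):
                info["converged"] = True
                break
        if not info["converged"]:
            warnings.warn(f"NIPALS component {h + 1} did not converge "
                          f"in {max_iter} iterations")
        s = _apply_sign_rule(v)
        v, t = s * v, s * t
        T[:, h] = t
        P[:, h] = v
        recon = np.outer(t, v)
        Xf = Xf - np.where(mask, recon, 0.0)
        if complete:
            X = X - recon
        expl[h] = float(t @ t) / total_var if total_var > 0 else 0.0
        convergence.append(info)

    return FittedModel(
        method="spca" if any(k < p for k in keepX_r) else "pca",
        loadings=[P],
        scores=[T],
        y_loadings=None,
        projection=[P.copy()],
        keepX=[keepX_r],
        ncomp=ncomp,
        mode="pca",
        block_names=[sb.name],
        feature_ids=[list(sb.feature_ids)],
        sample_ids=list(sb.sample_ids),
        col_means=[sb.col_means],
        col_sds=[sb.col_sds],
        scaled=scale,
        convergence=convergence,
        explained_variance=[expl],
    )


def nipals_impute(block: OmicsBlock, ncomp: int = 2, scale: bool = False,
                  refine_iter: int = 100, refine_tol: float = 1e-8) -> np.ndarray:
    """Fill missing cells with a low-rank NIPALS reconstruction.

    The initial estimate comes from the missing-value NIPALS fit; it is
    then refined EM-style — fill the gaps, refit the PCA on the completed
    matrix, update the filled cells with the new rank-``ncomp``
    reconstruction — until the imputed values stop moving. Values are
    returned on the original (unstandardised) data scale.
    """
    model = nipals_pca(block, ncomp=ncomp, scale=scale)
    means, sds = model.col_means[0], model.col_sds[0]
    recon = model.scores[0] @ model.loadings[0].T * sds + means
    out = block.values.copy()
    miss = np.isnan(out)
    if not miss.any():
        return out
    out[miss] = recon[miss]
    scale_ref = np.nanstd(block.values)
    for _ in range(refine_iter):
        filled = OmicsBlock(out, list(block.sample_ids),
                            list(block.feature_ids), name=block.name)
        m = nipals_pca(filled, ncomp=ncomp, scale=scale)
        recon = (m.scores[0] @ m.loadings[0].T) * m.col_sds[0] + m.col_means[0]
        change = np.abs(recon[miss] - out[miss]).max()
        out[miss] = recon[miss]
        if change < refine_tol * max(scale_ref, 1e-12):
            break
    return out
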