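"""Cross-validation machinery: folds, error measures, keepX and ncomp tuning.

Tuning follows the one-component-at-a-time protocol: the selection size of
component 1 is fixed at its CV-optimal value before component 2 is tuned,
and so on. Ties on the error curve resolve to the smallest selection size
(for multi-block factorial grids: smallest total, then lexicographic), so
the returned signature is minimal. The number of components is chosen by
one-sided paired t-tests across CV repeats: stop adding components as soon
as the gain is no longer significant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import FittedModel
from .methods import fit_by_name
from .predict import predict as predict_model

__all__ = [
    "FoldPlan", "TuneResult", "error_rate", "ber", "make_folds",
    "cv_predict", "tune_keepx", "choose_ncomp",
]


# ---------------------------------------------------------------------------
# error measures
# ---------------------------------------------------------------------------

def error_rate(truth, predicted) -> float:
    """Overall misclassification rate; tie predictions (None) count as errors."""
    truth = np.asarray(truth, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    if truth.shape != predicted.shape:
        raise ValueError("truth and prediction lengths differ")
    wrong = sum(1 for t, p in zip(truth, predicted)
                if p is None or str(p) != str(t))
    return wrong / len(truth)


def ber(truth, predicted) -> float:
    """Balanced error rate: unweighted mean of per-class error proportions.

    Appropriate for unbalanced classes — each class contributes equally
    regardless of its size. Tie predictions (None) count as errors.
    """
    truth = np.asarray([str(t) for t in truth], dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    rates = []
    for cls in sorted(set(truth)):
        idx = truth == cls
        rates.append(error_rate(truth[idx], predicted[idx]))
    return float(np.mean(rates))


MEASURES = {"overall": error_rate, "ber": ber}


# ---------------------------------------------------------------------------
# fold construction
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """CV fold assignments.

    ``assignments`` holds one length-N integer fold-id vector per repeat.
    Stratified M-fold keeps per-fold class counts within one sample of
    proportional; leave-one-group-out uses the study labels as folds and
    has a single repeat.
    """

    assignments: list[np.ndarray]
    scheme: str
    nfolds: int
    nrepeats: int
    seed: int | None = None
    fold_names: list[str] | None = None

    def test_indices(self, repeat: int):
        a = self.assignments[repeat]
        for f in range(self.nfolds):
            yield f, np.where(a == f)[0]


def make_folds(y, scheme: str = "stratified", nfolds: int = 5,
               nrepeats: int = 1, seed: int = 0, study=None) -> FoldPlan:
    """Build a stratified M-fold (x repeats) or leave-one-group-out plan."""
    y = np.asarray([str(v) for v in np.asarray(y)])
    n = len(y)
    if scheme == "logocv":
        if study is None:
            raise ValueError("logocv requires a study vector")
        study = np.asarray([str(s) for s in study])
        groups = sorted(set(study))
        a = np.zeros(n, dtype=int)
        for f, g in enumerate(groups):
            a[study == g] = f
        return FoldPlan([a], "logocv", len(groups), 1, seed, fold_names=groups)
    if scheme != "stratified":
        raise ValueError(f"unknown scheme {scheme!r}")
    classes = sorted(set(y))
    min_count = min(int((y == c).sum()) for c in classes)
    if nfolds > n:
        raise ValueError(f"nfolds={nfolds} exceeds N={n}")
    if min_count < 1:
        raise ValueError("every class needs at least one sample")
    rng = np.random.default_rng(seed)
    assignments = []
    for _ in range(nrepeats):
        a = np.empty(n, dtype=int)
        for c in classes:
            idx = np.where(y == c)[0]
            rng.shuffle(idx)
            start = rng.integers(nfolds)  # rotate which folds get extras
            for i, s in enumerate(idx):
                a[s] = (start + i) % nfolds
        assignments.append(a)
    return FoldPlan(assignments, "stratified", nfolds, nrepeats, seed)


# ---------------------------------------------------------------------------
# generic CV refit/predict
# ---------------------------------------------------------------------------

def _subset_X(X, idx):
    if isinstance(X, dict):
        return {k: np.asarray(v)[idx] for k, v in X.items()}
    if isinstance(X, (list, tuple)):
        return [np.asarray(v)[idx] for v in X]
    return np.asarray(X)[idx]


def _fit_predict_fold(method, X, y, test_idx, ncomp, keepX, design, study,
                      scale, distance, vote):
    n = len(y)
    train_idx = np.setdiff1d(np.arange(n), test_idx)
    kwargs = dict(ncomp=ncomp, keepX=keepX, scale=scale)
    if method.startswith("block_"):
        kwargs["design"] = design
    if method.startswith("mint_"):
        kwargs["study"] = study[train_idx]
    if keepX is None or method in ("plsda", "pls", "mint_plsda",
                                   "block_plsda"):
        kwargs.pop("keepX")
    model = fit_by_name(method, _subset_X(X, train_idx),
                        y[train_idx], **kwargs)
    pr = predict_model(model, _subset_X(X, test_idx),
                       study=None if study is None else study[test_idx])
    labs = []
    for h in range(ncomp):
        if model.n_blocks > 1:
            labs.append(pr.labels(distance, depth=h + 1, vote=vote))
        else:
            labs.append(pr.class_by_distance[distance][0][h])
    return test_idx, labs


def cv_predict(method: str, X, y, folds: FoldPlan, ncomp: int,
               keepX=None, design=None, study=None, scale: bool = True,
               distance: str = "centroid", vote: str = "weighted",
               n_jobs: int = 1):
    """Refit the model in each training fold and predict the test fold.

    Returns, per repeat, an (ncomp, N) object array of predicted labels -
    depth h predictions in row h-1 - aligned with the sample order of
    ``y``. Multi-block models are reduced to one label per sample by the
    requested vote. ``n_jobs`` parallelises over folds without changing
    any result (every fold fit is deterministic and nothing inside a fold
    draws random numbers).
    """
    y = np.asarray(y)
    study = None if study is None else np.asarray(study)
    tasks = [(rep, test_idx)
             for rep in range(folds.nrepeats)
             for _, test_idx in folds.test_indices(rep)
             if len(test_idx) > 0]
    kw = dict(ncomp=ncomp, keepX=keepX, design=design, study=study,
              scale=scale, distance=distance, vote=vote)
    if n_jobs != 1:
        from joblib import Parallel, delayed
        results = Parallel(n_jobs=n_jobs)(
            delayed(_fit_predict_fold)(method, X, y, test_idx, **kw)
            for _, test_idx in tasks)
    else:
        results = [_fit_predict_fold(method, X, y, test_idx, **kw)
                   for _, test_idx in tasks]
    out = [np.empty((ncomp, len(y)), dtype=object)
           for _ in range(folds.nrepeats)]
    for (rep, _), (test_idx, labs) in zip(tasks, results):
        for h in range(ncomp):
            out[rep][h, test_idx] = labs[h]
    return out


# ---------------------------------------------------------------------------
# keepX tuning
# ---------------------------------------------------------------------------

@dataclass
class TuneResult:
    """Outcome of the sequential keepX grid search."""

    grid: list[list[int]]                  # per block
    error_surface: dict = field(default_factory=dict)
    # comp (1-based) -> {"candidates": [...], "mean": (n_cand,),
    #                    "sd": (n_cand,), "per_repeat": (n_cand, nrepeats)}
    chosen_keepX: list[list[int]] = field(default_factory=list)  # per block
    chosen_ncomp: int = 0
    measure: str = "ber"
    distance: str = "centroid"
    final_errors: np.ndarray | None = None  # (ncomp, nrepeats)


def _candidate_list(grid, n_blocks):
    """Factorial candidate tuples over per-block grids, ordered so that
    ties resolve to the smallest total then lexicographic."""
    if n_blocks == 1:
        cands = [(int(g),) for g in grid[0]]
    else:
        cands = [tuple(int(v) for v in c) for c in itertools.product(*grid)]
    return sorted(cands, key=lambda c: (sum(c), c))


def tune_keepx(method: str, X, y, grid, folds: FoldPlan, ncomp: int,
               design=None, study=None, scale: bool = True,
               distance: str = "centroid", measure: str = "ber",
               alpha: float = 0.05, n_jobs: int = 1) -> TuneResult:
    """Sequential per-component grid search for the selection sizes.

    ``grid`` is a flat list for single-block methods or a per-block list
    of lists (evaluated factorially) for multi-block methods. Component h
    is tuned with components 1..h-1 fixed at their chosen values; the
    model is refitted inside every training fold for every candidate.
    """
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {sorted(MEASURES)}")
    y = np.asarray(y)
    if isinstance(X, dict):
        n_blocks = len(X)
        Ps = [np.asarray(v).shape[1] for v in X.values()]
    elif isinstance(X, (list, tuple)):
        n_blocks = len(X)
        Ps = [np.asarray(v).shape[1] for v in X]
    else:
        n_blocks = 1
        Ps = [np.asarray(X).shape[1]]
    if grid and not isinstance(grid[0], (list, tuple, np.ndarray)):
        grid = [list(grid)] * n_blocks
    grid = [[int(v) for v in g] for g in grid]
    for g, p in zip(grid, Ps):
        bad = [v for v in g if not 1 <= v <= p]
        if bad:
            raise ValueError(f"grid values {bad} outside [1, {p}]")

    measure_fn = MEASURES[measure]
    cands = _candidate_list(grid, n_blocks)
    chosen: list[tuple[int, ...]] = []
    result = TuneResult(grid=grid, measure=measure, distance=distance)

    for h in range(1, ncomp + 1):
        per_repeat = np.zeros((len(cands), folds.nrepeats))
        for ci, cand in enumerate(cands):
            keepX = [[chosen[j][b] for j in range(h - 1)] + [cand[b]]
                     for b in range(n_blocks)]
            if n_blocks == 1:
                keepX = keepX[0]
            preds = cv_predict(method, X, y, folds, ncomp=h, keepX=keepX,
                               design=design, study=study, scale=scale,
                               distance=distance, n_jobs=n_jobs)
            for rep in range(folds.nrepeats):
                per_repeat[ci, rep] = measure_fn(y, preds[rep][h - 1])
        means = per_repeat.mean(axis=1)
        best = int(np.argmin(means))  # candidates pre-sorted for the tie rule
        chosen.append(cands[best])
        result.error_surface[h] = {
            "candidates": list(cands),
            "mean": means,
            "sd": per_repeat.std(axis=1, ddof=1) if folds.nrepeats > 1
            else np.zeros(len(cands)),
            "per_repeat": per_repeat,
        }

    result.chosen_keepX = [[chosen[h][b] for h in range(ncomp)]
                           for b in range(n_blocks)]
    final = np.array([
        result.error_surface[h]["per_repeat"][
            result.error_surface[h]["candidates"].index(chosen[h - 1])]
        for h in range(1, ncomp + 1)
    ])
    result.final_errors = final
    result.chosen_ncomp = choose_ncomp(final, alpha=alpha)
    return result


def choose_ncomp(cv_errors: np.ndarray, alpha: float = 0.05) -> int:
    """Smallest H whose successor adds no significant performance gain.

    ``cv_errors`` is (ncomp, nrepeats): per-repeat mean CV error at each
    component depth. A one-sided paired t-test asks whether depth H+1
    improves on depth H across repeats; the first non-significant step
    stops the search. A flat (or single-repeat) curve yields H=1 unless a
    strict mean improvement is observed with repeats to support it.
    """
    cv_errors = np.atleast_2d(np.asarray(cv_errors, dtype=float))
    ncomp = cv_errors.shape[0]
    for h in range(ncomp - 1):
        a, b = cv_errors[h], cv_errors[h + 1]
        if len(a) < 2:
            if b.mean() < a.mean():  # no repeats: fall back to strict gain
                continue
            return h + 1
        diff = a - b
        if np.allclose(diff, 0):
            return h + 1
        t = stats.ttest_rel(a, b, alternative="greater")
        if not np.isfinite(t.pvalue) or t.pvalue >= alpha:
            return h + 1
    return ncomp
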