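"""Final-model performance assessment, selection stability, and ROC/AUC.

``perf`` refits the model inside every CV training fold (so feature
selection is repeated per fold), evaluates the held-out samples at every
component depth under all three prediction distances, and records which
features each fold selected. Stability is the per-feature selection
frequency across those refits. ROC/AUC uses one-vs-all comparisons on the
predicted dummy values, averaged over the CV process; note that for
distance-based classifiers the AUC is a complementary measure only — the
classifier itself never thresholds the dummy values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import FittedModel
from .methods import fit_by_name
from .predict import DISTANCES, predict as predict_model
from .tuning import FoldPlan, ber, error_rate

__all__ = ["PerfReport", "perf", "stability", "roc_auc", "roc_points"]


@dataclass
class PerfReport:
    """Cross-validated performance of a fixed model specification.

    ``error_rates[distance][measure]`` is a dict with "mean" and "sd"
    arrays of length ncomp (depth h at index h-1), aggregated over CV
    repeats. ``stability[block]`` maps component (1-based) to a
    feature-id -> frequency dict. ``auc[h]`` maps class label to the
    one-vs-all AUC at depth h, averaged over folds and repeats.
    """

    method: str
    ncomp: int
    measures: tuple = ("overall", "ber")
    error_rates: dict = field(default_factory=dict)
    stability: list = field(default_factory=list)
    auc: dict = field(default_factory=dict)
    note: str = ("AUC complements but may not reflect the performance of a "
                 "prediction-distance classifier")

    def error(self, distance: str = "centroid", measure: str = "ber",
              depth: int | None = None) -> float:
        arr = self.error_rates[distance][measure]["mean"]
        return float(arr[(depth or self.ncomp) - 1])


def _perf_fold(method, X, y, test_idx, ncomp, keepX, design, study_arr,
               scale, distances, vote, multi, n_blocks, classes):
    n = len(y)
    train_idx = np.setdiff1d(np.arange(n), test_idx)
    kwargs = dict(ncomp=ncomp, scale=scale)
    if keepX is not None:
        kwargs["keepX"] = keepX
    if method.startswith("block_"):
        kwargs["design"] = design
    if method.startswith("mint_"):
        kwargs["study"] = study_arr[train_idx]
    Xtr = [np.asarray(x)[train_idx] for x in X] if multi \
        else np.asarray(X)[train_idx]
    Xte = [np.asarray(x)[test_idx] for x in X] if multi \
        else np.asarray(X)[test_idx]
    model = fit_by_name(method, Xtr, y[train_idx], **kwargs)
    selections = [
        {h: model.selected_features(b, comp=h) for h in range(1, ncomp + 1)}
        for b in range(n_blocks)
    ]
    pr = predict_model(
        model, Xte,
        study=None if study_arr is None else study_arr[test_idx])
    labels = {}
    for dist in distances:
        labels[dist] = [
            pr.labels(dist, depth=h + 1, vote=vote) if n_blocks > 1
            else pr.class_by_distance[dist][0][h]
            for h in range(ncomp)
        ]
    # fold-level one-vs-all AUC on the (combined) dummy predictions
    truth_te = np.asarray([str(v) for v in y[test_idx]])
    aucs = []
    for h in range(1, ncomp + 1):
        dummy = pr.combined_dummy[h - 1]
        for ki, c in enumerate(model.class_labels):
            bin_truth = (truth_te == c).astype(int)
            if 0 < bin_truth.sum() < len(bin_truth):
                aucs.append((h, c, _auc(bin_truth, dummy[:, ki])))
    return test_idx, selections, labels, aucs


def perf(method: str, X, y, folds: FoldPlan, ncomp: int, keepX=None,
         design=None, study=None, scale: bool = True,
         distances=DISTANCES, vote: str = "weighted",
         n_jobs: int = 1) -> PerfReport:
    """Estimate generalisation error of a model spec by repeated CV."""
    y = np.asarray(y)
    n = len(y)
    study_arr = None if study is None else np.asarray(study)
    if isinstance(X, dict):
        X = list(X.values())
    multi = isinstance(X, (list, tuple))
    n_blocks = len(X) if multi else 1

    err = {d: {m: np.zeros((ncomp, folds.nrepeats)) for m in ("overall", "ber")}
           for d in distances}
    sel_counts = [dict() for _ in range(n_blocks)]  # comp -> feature -> count
    classes = sorted({str(v) for v in y})
    auc_acc = {h: {c: [] for c in classes} for h in range(1, ncomp + 1)}

    tasks = [(rep, test_idx)
             for rep in range(folds.nrepeats)
             for _, test_idx in folds.test_indices(rep)
             if len(test_idx) > 0]
    kw = dict(ncomp=ncomp, keepX=keepX, design=design, study_arr=study_arr,
              scale=scale, distances=distances, vote=vote, multi=multi,
              n_blocks=n_blocks, classes=classes)
    if n_jobs != 1:
        from joblib import Parallel, delayed
        results = Parallel(n_jobs=n_jobs)(
            delayed(_perf_fold)(method, X, y, test_idx, **kw)
            for _, test_idx in tasks)
    else:
        results = [_perf_fold(method, X, y, test_idx, **kw)
                   for _, test_idx in tasks]
    n_fits = len(results)

    preds = {rep: {d: np.empty((ncomp, n), dtype=object) for d in distances}
             for rep in range(folds.nrepeats)}
    for (rep, _), (test_idx, selections, labels, aucs) in zip(tasks, results):
        for b in range(n_blocks):
            for h, feats in selections[b].items():
                d = sel_counts[b].setdefault(h, {})
                for f in feats:
                    d[f] = d.get(f, 0) + 1
        for dist in distances:
            for h in range(ncomp):
                preds[rep][dist][h, test_idx] = labels[dist][h]
        for h, c, a in aucs:
            auc_acc[h][c].append(a)
    for rep in range(folds.nrepeats):
        for dist in distances:
            for h in range(ncomp):
                err[dist]["overall"][h, rep] = error_rate(y, preds[rep][dist][h])
                err[dist]["ber"][h, rep] = ber(y, preds[rep][dist][h])

    report = PerfReport(method=method, ncomp=ncomp)
    for dist in distances:
        report.error_rates[dist] = {
            m: {"mean": err[dist][m].mean(axis=1),
                "sd": err[dist][m].std(axis=1, ddof=1) if folds.nrepeats > 1
                else np.zeros(ncomp)}
            for m in ("overall", "ber")
        }
    report.stability = [
        {h: {f: cnt / n_fits for f, cnt in comp_counts.items()}
         for h, comp_counts in sel_counts[b].items()}
        for b in range(n_blocks)
    ]
    report.auc = {
        h: {c: float(np.mean(v)) if v else np.nan
            for c, v in auc_acc[h].items()}
        for h in auc_acc
    }
    return report


def stability(fold_selections, feature_ids=None) -> dict:
    """Selection frequencies from a list of per-fold selected-feature lists.

    ``fold_selections`` is an iterable over folds, each fold a list of
    selected feature ids (one component) or a dict comp -> list. Returns
    feature -> frequency in [0, 1] (or comp -> that dict).
    """
    fold_selections = list(fold_selections)
    n = len(fold_selections)
    if n == 0:
        raise ValueError("no fold selections given")
    if isinstance(fold_selections[0], dict):
        comps = sorted({h for fs in fold_selections for h in fs})
        return {h: stability([fs.get(h, []) for fs in fold_selections],
                             feature_ids) for h in comps}
    counts: dict = {}
    for feats in fold_selections:
        for f in feats:
            counts[f] = counts.get(f, 0) + 1
    freqs = {f: c / n for f, c in counts.items()}
    if feature_ids is not None:
        freqs = {f: freqs.get(f, 0.0) for f in feature_ids}
    return freqs


# ---------------------------------------------------------------------------
# ROC / AUC (one-vs-all, trapezoid)
# ---------------------------------------------------------------------------

def roc_points(bin_truth, score):
    """ROC curve points (FPR, TPR) from a threshold sweep.

    Tied scores are grouped (stable sort) so each unique score contributes
    one step; the curve starts at (0,0) and ends at (1,1).
    """
    bin_truth = np.asarray(bin_truth, dtype=int)
    score = np.asarray(score, dtype=float)
    n_pos = int(bin_truth.sum())
    n_neg = len(bin_truth) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both positive and negative samples")
    order = np.argsort(-score, kind="stable")
    s, t = score[order], bin_truth[order]
    tp = np.cumsum(t)
    fp = np.cumsum(1 - t)
    distinct = np.r_[np.diff(s) != 0, True]
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    return fpr, tpr


def _auc(bin_truth, score) -> float:
    fpr, tpr = roc_points(bin_truth, score)
    return float(np.trapezoid(tpr, fpr))


def roc_auc(predicted_dummy, truth, class_labels=None):
    """One-vs-all ROC and AUC per class from predicted dummy values.

    ``predicted_dummy`` is (N, K); returns ``(curves, aucs)`` where
    ``curves[label] = (fpr, tpr)`` and ``aucs[label]`` is the trapezoid
    area.
    """
    predicted_dummy = np.asarray(predicted_dummy, dtype=float)
    truth = np.asarray([str(v) for v in truth])
    if class_labels is None:
        class_labels = sorted(set(truth))
    curves, aucs = {}, {}
    for k, c in enumerate(class_labels):
        bin_truth = (truth == c).astype(int)
        fpr, tpr = roc_points(bin_truth, predicted_dummy[:, k])
        curves[c] = (fpr, tpr)
        aucs[c] = float(np.trapezoid(tpr, fpr))
    return curves, aucs
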