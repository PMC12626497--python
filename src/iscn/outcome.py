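"""Surgical-outcome prediction: F-score selection + linear SVM with CV10.

Features are per-region abnormality strengths at one laterality level.
Within every training fold the features are standardized, ranked by the
Fisher criterion (F-score)

    F(i) = [(m_i+ - m_i)^2 + (m_i- - m_i)^2] / [s2_i+ + s2_i-]

(class means vs overall mean over summed unbiased within-class variances),
the top-k are kept, and a linear-kernel SVM is fit.  Held-out predictions
are pooled over the 10 stratified folds into accuracy, sensitivity and
specificity (positive class = NSF, not seizure-free) and an AUC from the
pooled decision values.  k runs over a grid (top 20, step 5 by default) and
the grid value with the best pooled accuracy is retained.  Classifier
significance uses a label-permutation test; model interpretation averages
the absolute SVM weights per region and per Yeo-7 functional network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .data_model import Atlas, ValidationError


@dataclass
class ModelConfig:
    """Settings for the outcome classifier."""

    level: str = "contralateral"
    k_grid: tuple[int, ...] | None = None  # default: 20..min(100, p) step 5
    svm_cost: float = 1.0
    n_folds: int = 10
    n_permutations: int = 5000
    seed: int = 0
    positive_class: str = "NSF"
    whole_cohort_selection: bool = False  # leakage mode, sensitivity analysis only

    def resolve_k_grid(self, n_features: int) -> list[int]:
        if self.k_grid is not None:
            grid = [int(k) for k in self.k_grid]
            if grid != sorted(grid):
                raise ValidationError("k_grid must be ascending")
        else:
            grid = list(range(20, min(100, n_features) + 1, 5))
        grid = [min(k, n_features) for k in grid]
        grid = sorted(set(grid))
        return grid or [n_features]


@dataclass
class CVReport:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    k_chosen: int
    per_fold: list[dict] = field(default_factory=list)
    selected_features: list[list[int]] = field(default_factory=list)
    mean_weights: dict[int, float] = field(default_factory=dict)
    accuracy_by_k: dict[int, float] = field(default_factory=dict)
    fold_assignment: list[int] = field(default_factory=list)


@dataclass
class FrozenModel:
    selected_regions: list[int]
    center: np.ndarray
    scale: np.ndarray
    weights: np.ndarray
    intercept: float
    level: str
    positive_class: str


def f_score(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Fisher criterion per feature for a binary labelling.

    Features constant everywhere score 0; features with zero within-class
    variance but separated class means get +inf (ranked first).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(bool)
    if not y.any() or y.all():
        raise ValidationError("both classes must be present")
    pos, neg = X[y], X[~y]
    if len(pos) < 2 or len(neg) < 2:
        raise ValidationError("each class needs at least 2 samples")
    m = X.mean(axis=0)
    mp, mn = pos.mean(axis=0), neg.mean(axis=0)
    num = (mp - m) ** 2 + (mn - m) ** 2
    den = pos.var(axis=0, ddof=1) + neg.var(axis=0, ddof=1)
    out = np.empty(X.shape[1])
    zero_den = den == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(zero_den, np.where(num == 0, 0.0, np.inf), num / np.where(zero_den, 1.0, den))
    return out


def select_top_k(scores: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k highest scores; ties broken by ascending index."""
    scores = np.asarray(scores, dtype=float)
    k = min(int(k), len(scores))
    order = np.lexsort((np.arange(len(scores)), -scores))
    return order[:k]


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) from confusion counts."""
    total = tp + fp + tn + fn
    if total == 0:
        raise ValidationError("empty confusion matrix")
    if tp + fn == 0 or tn + fp == 0:
        raise ValidationError("a class is absent; sensitivity/specificity undefined")
    return tp / (tp + fn), tn / (tn + fp), (tp + tn) / total


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)
    return center, scale


def cross_validate(
    X: np.ndarray,
    labels: Sequence[str],
    config: ModelConfig,
    feature_ids: Sequence[int] | None = None,
) -> CVReport:
    """Stratified 10-fold CV of the select-then-classify pipeline.

    Standardization and F-score selection are refit inside every training
    fold (no information leaks from held-out patients unless the explicit
    ``whole_cohort_selection`` sensitivity flag is set).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    y = (labels == config.positive_class).astype(int)
    n, p = X.shape
    if n < config.n_folds:
        raise ValidationError(f"cohort of {n} smaller than {config.n_folds} folds")
    if feature_ids is None:
        feature_ids = np.arange(p)
    feature_ids = np.asarray(feature_ids)
    grid = config.resolve_k_grid(p)

    skf = StratifiedKFold(
        n_splits=config.n_folds, shuffle=True, random_state=config.seed
    )
    folds = list(skf.split(X, y))
    for tr, _ in folds:
        if len(np.unique(y[tr])) < 2:
            raise ValidationError("a training fold lacks one of the classes")

    global_rank = None
    if config.whole_cohort_selection:
        c, s = _standardize_fit(X)
        global_rank = select_top_k(f_score((X - c) / s, y), p)

    # per k: pooled predictions / decision values in original subject order
    preds = {k: np.empty(n, dtype=int) for k in grid}
    decs = {k: np.empty(n, dtype=float) for k in grid}
    weights_by_fold: dict[int, list[tuple[np.ndarray, np.ndarray]]] = {
        k: [] for k in grid
    }
    fold_assignment = np.empty(n, dtype=int)
    for f, (tr, te) in enumerate(folds):
        fold_assignment[te] = f
        center, scale = _standardize_fit(X[tr])
        Xtr = (X[tr] - center) / scale
        Xte = (X[te] - center) / scale
        rank = (
            global_rank
            if global_rank is not None
            else select_top_k(f_score(Xtr, y[tr]), p)
        )
        for k in grid:
            sel = rank[:k]
            clf = SVC(kernel="linear", C=config.svm_cost)
            clf.fit(Xtr[:, sel], y[tr])
            preds[k][te] = clf.predict(Xte[:, sel])
            decs[k][te] = clf.decision_function(Xte[:, sel])
            weights_by_fold[k].append((sel, np.abs(clf.coef_.ravel())))

    accuracy_by_k = {k: float((preds[k] == y).mean()) for k in grid}
    k_chosen = min(
        grid, key=lambda k: (-accuracy_by_k[k], k)
    )  # best pooled accuracy, ties to smallest k

    yp = preds[k_chosen]
    tp = int(((yp == 1) & (y == 1)).sum())
    fp = int(((yp == 1) & (y == 0)).sum())
    tn = int(((yp == 0) & (y == 0)).sum())
    fn = int(((yp == 0) & (y == 1)).sum())
    sens, spec, acc = confusion_metrics(tp, fp, tn, fn)
    auc = float(roc_auc_score(y, decs[k_chosen]))

    per_fold = []
    selected = []
    for f, (tr, te) in enumerate(folds):
        yf, pf = y[te], yp[te]
        per_fold.append(
            {
                "fold": f,
                "tp": int(((pf == 1) & (yf == 1)).sum()),
                "fp": int(((pf == 1) & (yf == 0)).sum()),
                "tn": int(((pf == 0) & (yf == 0)).sum()),
                "fn": int(((pf == 0) & (yf == 1)).sum()),
            }
        )
        sel, _ = weights_by_fold[k_chosen][f]
        selected.append([int(feature_ids[i]) for i in sel])

    weight_sum: dict[int, float] = {}
    weight_n: dict[int, int] = {}
    for sel, w in weights_by_fold[k_chosen]:
        for i, wi in zip(sel, w):
            fid = int(feature_ids[i])
            weight_sum[fid] = weight_sum.get(fid, 0.0) + float(wi)
            weight_n[fid] = weight_n.get(fid, 0) + 1
    mean_weights = {fid: weight_sum[fid] / weight_n[fid] for fid in weight_sum}

    return CVReport(
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        k_chosen=int(k_chosen),
        per_fold=per_fold,
        selected_features=selected,
        mean_weights=mean_weights,
        accuracy_by_k=accuracy_by_k,
        fold_assignment=fold_assignment.tolist(),
    )


def permutation_test(
    X: np.ndarray,
    labels: Sequence[str],
    config: ModelConfig,
    observed_accuracy: float | None = None,
) -> tuple[float, np.ndarray]:
    """Label-permutation significance of the CV accuracy.

    Re-runs the full cross-validation on uniformly permuted labels and
    returns p = (1 + #{perm >= observed}) / (B + 1) plus the permuted
    accuracies.
    """
    labels = np.asarray(labels)
    if observed_accuracy is None:
        observed_accuracy = cross_validate(X, labels, config).accuracy
    rng = np.random.default_rng(config.seed)
    B = int(config.n_permutations)
    perm_acc = np.empty(B)
    for b in range(B):
        y_perm = rng.permutation(labels)
        sub = ModelConfig(
            **{
                **config.__dict__,
                "seed": int(rng.integers(2**31 - 1)),
                "n_permutations": 0,
            }
        )
        perm_acc[b] = cross_validate(X, y_perm, sub).accuracy
    p = (1 + int((perm_acc >= observed_accuracy).sum())) / (B + 1)
    return float(p), perm_acc


def aggregate_weights_yeo(
    mean_weights: Mapping[int, float], atlas: Atlas
) -> tuple[pd.Series, list[int]]:
    """Average absolute SVM weight per Yeo-7 functional network.

    Regions mapped to ``none`` (e.g. subcortex, which the cortical Yeo
    parcellation does not cover) are excluded and returned separately.
    """
    yeo_of = dict(zip((int(i) for i in atlas.region_ids), atlas.yeo))
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    excluded = []
    for rid, w in mean_weights.items():
        net = yeo_of.get(int(rid))
        if net is None:
            raise ValidationError(f"region {rid} not in atlas")
        if net == "none":
            excluded.append(int(rid))
            continue
        sums[net] = sums.get(net, 0.0) + abs(float(w))
        counts[net] = counts.get(net, 0) + 1
    means = pd.Series(
        {net: sums[net] / counts[net] for net in sums}, dtype=float
    ).sort_values(ascending=False)
    return means, sorted(excluded)


def freeze(
    X: np.ndarray,
    labels: Sequence[str],
    config: ModelConfig,
    feature_ids: Sequence[int] | None = None,
    k: int | None = None,
) -> FrozenModel:
    """Fit the final model on the full internal cohort.

    Standardization, F-score selection (at ``k``, defaulting to the CV-chosen
    grid value) and the SVM are all fit once on the whole training cohort;
    the frozen parameters are what external cohorts are pushed through.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    y = (labels == config.positive_class).astype(int)
    p = X.shape[1]
    if feature_ids is None:
        feature_ids = np.arange(p)
    feature_ids = np.asarray(feature_ids)
    if k is None:
        k = cross_validate(X, labels, config, feature_ids).k_chosen
    center, scale = _standardize_fit(X)
    Xs = (X - center) / scale
    sel = select_top_k(f_score(Xs, y), k)
    clf = SVC(kernel="linear", C=config.svm_cost)
    clf.fit(Xs[:, sel], y)
    return FrozenModel(
        selected_regions=[int(feature_ids[i]) for i in sel],
        center=center[sel],
        scale=scale[sel],
        weights=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        level=config.level,
        positive_class=config.positive_class,
    )


def apply_frozen(
    frozen: FrozenModel,
    X: np.ndarray,
    labels: Sequence[str],
    feature_ids: Sequence[int],
) -> dict:
    """Score an external cohort with a frozen model; confusion-based metrics."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    feature_ids = [int(i) for i in feature_ids]
    missing = [r for r in frozen.selected_regions if r not in feature_ids]
    if missing:
        raise ValidationError(f"external cohort missing selected regions: {missing}")
    cols = [feature_ids.index(r) for r in frozen.selected_regions]
    Xs = (X[:, cols] - frozen.center) / frozen.scale
    dec = Xs @ frozen.weights + frozen.intercept
    pred = (dec > 0).astype(int)
    y = (labels == frozen.positive_class).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    sens, spec, acc = confusion_metrics(tp, fp, tn, fn)
    auc = float(roc_auc_score(y, dec)) if len(np.unique(y)) == 2 else float("nan")
    return {
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
        "auc": auc,
    }
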