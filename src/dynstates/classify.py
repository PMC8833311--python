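"""State-wise supervised classification with embedded feature selection.

For the static design and for each brain state, an L1-regularized logistic
regression predicts group status from the subject-level connectivity
features in a leave-one-out cross-validation (LOOCV) scheme.  Within each
outer fold the regularization strength lambda is chosen on the training
rows by inner stratified 5-fold cross-validation over a linearly spaced
grid, feature z-scoring uses training statistics only, and the held-out
subject never influences scaling, lambda choice or fit.  The L1 penalty
zeroes uninformative weights; a feature's *selection frequency* is the rate
of non-zero weights across the outer folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "FeatureMatrix",
    "ClassifierResult",
    "build_features",
    "lambda_grid_for",
    "loocv_l1_logreg",
    "confusion_measures",
    "selection_frequency_matrix",
]


@dataclass
class FeatureMatrix:
    """Subjects x FC-feature matrix for one classification target."""

    values: np.ndarray  # n x P_filtered, raw (z-scoring happens inside CV)
    labels: np.ndarray  # n, 0 = group A (control-like), 1 = group B
    subject_ids: list[str]
    feature_pairs: list[tuple[int, int]]  # component index pairs (i < j)

    def __post_init__(self) -> None:
        if self.values.shape[0] != len(self.labels):
            raise ValueError("one label per row required")
        if np.isnan(self.values).any():
            raise ValueError("missing entries in feature matrix")


@dataclass
class ClassifierResult:
    subject_ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    selection_frequency: np.ndarray  # per feature, in [0, 1]
    lambda_grid: np.ndarray
    lambda_per_fold: np.ndarray
    fold_nonzero: np.ndarray  # n_folds x P boolean log of non-zero weights

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.y_true == self.y_pred))


DEFAULT_NETWORK_FILTER = frozenset({"VIS", "FPN", "DMN"})


def build_features(
    fc_by_subject: dict[str, np.ndarray],
    groups: dict[str, str],
    network_map: pd.DataFrame,
    network_filter: frozenset[str] | set[str] = DEFAULT_NETWORK_FILTER,
    group_b: str = "B",
) -> FeatureMatrix:
    """Restrict subject FC vectors to pairs within the target networks.

    ``fc_by_subject`` maps subject id -> full length-P pair vector (state
    mean or static, residualized upstream).  Only pairs whose *both*
    endpoints belong to a network in ``network_filter`` survive; the
    default keeps visual, fronto-parietal and default-mode pairs, the
    networks with known discriminative value in this disorder.
    """
    nets = np.asarray(network_map["network"])
    C = len(nets)
    iu, ju = np.triu_indices(C, k=1)
    keep = np.array([
        nets[i] in network_filter and nets[j] in network_filter
        for i, j in zip(iu, ju)
    ])
    if not keep.any():
        raise ValueError("network filter leaves no feature pairs")
    sids = list(fc_by_subject)
    X = np.vstack([np.asarray(fc_by_subject[s], dtype=float) for s in sids])
    if X.shape[1] != keep.size:
        raise ValueError(
            f"expected {keep.size} pairs from the network map, got {X.shape[1]}")
    y = np.array([1 if groups[s] == group_b else 0 for s in sids])
    pairs = [(int(i), int(j)) for i, j, k in zip(iu, ju, keep) if k]
    return FeatureMatrix(values=X[:, keep], labels=y, subject_ids=sids,
                         feature_pairs=pairs)


def lambda_grid_for(X: np.ndarray, y: np.ndarray, n_points: int = 25) -> np.ndarray:
    """Linearly spaced lambda grid from near-dense to fully sparse.

    The largest useful penalty is the smallest lambda at which the L1
    logistic solution is entirely zero, ``max |X^T (y - mean(y))|`` on
    column-standardized X; the grid spans (0, lambda_max] linearly.
    """
    if n_points < 3:
        raise ValueError("grid needs at least 3 points")
    Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
    lam_max = float(np.max(np.abs(Xs.T @ (y - y.mean()))))
    if lam_max <= 0:
        lam_max = 1.0
    return np.linspace(lam_max / n_points, lam_max, n_points)


def _fit_l1(X: np.ndarray, y: np.ndarray, lam: float, seed: int) -> LogisticRegression:
    # liblinear objective: C * sum(logloss) + ||w||_1  =>  C = 1 / lambda
    clf = LogisticRegression(
        C=1.0 / lam, l1_ratio=1.0, solver="liblinear", max_iter=2000,
        random_state=seed,
    )
    clf.fit(X, y)
    return clf


def _zscore_train_apply(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def loocv_l1_logreg(
    features: FeatureMatrix,
    lambda_grid: np.ndarray | None = None,
    n_grid: int = 25,
    inner_folds: int = 5,
    seed: int = 0,
) -> ClassifierResult:
    """Leave-one-out CV with per-fold inner lambda selection.

    For each held-out subject: z-score on the training rows, pick lambda by
    inner stratified ``inner_folds``-fold accuracy over the grid (ties go
    to the sparser model), refit on all training rows, predict the held-out
    subject, and log which weights were non-zero.
    """
    X, y = features.values, features.labels
    n, P = X.shape
    if n < 10:
        raise ValueError("need at least 10 subjects for LOOCV")
    if lambda_grid is None:
        lambda_grid = lambda_grid_for(X, y, n_grid)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size < 3:
        raise ValueError("lambda grid needs at least 3 values")

    y_pred = np.empty(n, dtype=int)
    lam_per_fold = np.empty(n)
    fold_nonzero = np.zeros((n, P), dtype=bool)
    for hold in range(n):
        train_idx = np.delete(np.arange(n), hold)
        X_tr_raw, y_tr = X[train_idx], y[train_idx]
        if len(np.unique(y_tr)) < 2:
            # degenerate training labels: predict the only class seen
            y_pred[hold] = int(y_tr[0])
            lam_per_fold[hold] = np.nan
            continue
        # inner CV over the grid, on training rows only
        n_splits = min(inner_folds, np.bincount(y_tr).min())
        inner_scores = np.zeros(lambda_grid.size)
        if n_splits >= 2:
            skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                                  random_state=seed + hold)
            for in_tr, in_te in skf.split(X_tr_raw, y_tr):
                Xi_tr, Xi_te = _zscore_train_apply(X_tr_raw[in_tr], X_tr_raw[in_te])
                for g, lam in enumerate(lambda_grid):
                    clf = _fit_l1(Xi_tr, y_tr[in_tr], lam, seed)
                    inner_scores[g] += np.mean(clf.predict(Xi_te) == y_tr[in_te])
        # ties resolved toward the larger penalty (sparser model)
        best = np.flatnonzero(inner_scores == inner_scores.max())[-1]
        lam = float(lambda_grid[best])
        lam_per_fold[hold] = lam
        X_tr, X_te = _zscore_train_apply(X_tr_raw, X[hold:hold + 1])
        clf = _fit_l1(X_tr, y_tr, lam, seed)
        y_pred[hold] = int(clf.predict(X_te)[0])
        fold_nonzero[hold] = np.abs(clf.coef_[0]) > 0
    selection = fold_nonzero.mean(axis=0)
    return ClassifierResult(
        subject_ids=features.subject_ids, y_true=y.copy(), y_pred=y_pred,
        selection_frequency=selection, lambda_grid=lambda_grid,
        lambda_per_fold=lam_per_fold, fold_nonzero=fold_nonzero,
    )


def confusion_measures(result: ClassifierResult) -> dict[str, float]:
    """TPR/FPR/TNR/FNR and accuracy; class 1 (patient-like) is positive."""
    y, yhat = result.y_true, result.y_pred
    tp = int(np.sum((y == 1) & (yhat == 1)))
    fn = int(np.sum((y == 1) & (yhat == 0)))
    tn = int(np.sum((y == 0) & (yhat == 0)))
    fp = int(np.sum((y == 0) & (yhat == 1)))
    n_pos, n_neg = tp + fn, tn + fp
    out = {
        "TP": tp, "FP": fp, "TN": tn, "FN": fn,
        "accuracy": (tp + tn) / max(len(y), 1),
        "TPR": tp / n_pos if n_pos else float("nan"),
        "FNR": fn / n_pos if n_pos else float("nan"),
        "TNR": tn / n_neg if n_neg else float("nan"),
        "FPR": fp / n_neg if n_neg else float("nan"),
    }
    return out


def selection_frequency_matrix(
    result: ClassifierResult,
    feature_pairs: list[tuple[int, int]],
    C: int,
    threshold: float = 0.10,
) -> np.ndarray:
    """Pair-space selection-rate map; rates below ``threshold`` masked (NaN)."""
    mat = np.full((C, C), np.nan)
    for (i, j), rate in zip(feature_pairs, result.selection_frequency):
        val = rate if rate >= threshold else np.nan
        mat[i, j] = val
        mat[j, i] = val
    return mat
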