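"""K-means brain states from pooled windowed connectivity.

Windowed Fisher-z connectivity vectors from all subjects are concatenated
and clustered with k-means (squared Euclidean distance, many replicates,
best inertia kept).  Each window is thereby assigned to one of k recurrent
connectivity states.  The number of states is chosen with an elbow
criterion on the within/between dispersion ratio.

State ids are reported in descending total-occupancy order, so State 1 is
always the dominant (most visited) state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

__all__ = [
    "StateModel",
    "ElbowCurve",
    "concat_windows",
    "kmeans_states",
    "elbow_select",
    "match_states",
    "state_similarity_to_static",
]


@dataclass
class StateModel:
    """Fitted k-means state solution over pair-space."""

    k: int
    centroids: np.ndarray  # k x P, fisher-z scale
    labels: pd.DataFrame  # columns: subject_id, window, state (1..k)
    inertia: float
    seed: int

    def labels_for(self, subject_id: str) -> np.ndarray:
        sub = self.labels[self.labels["subject_id"] == subject_id]
        return sub.sort_values("window")["state"].to_numpy()

    @property
    def subject_ids(self) -> list[str]:
        return list(dict.fromkeys(self.labels["subject_id"]))


@dataclass
class ElbowCurve:
    k_values: list[int]
    validity: list[float]  # within/between dispersion ratio per k
    chosen_k: int
    flat: bool = False


def concat_windows(
    window_fc: dict[str, np.ndarray],
) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack per-subject window-vector arrays into one observations x P matrix.

    ``window_fc`` maps subject id -> (n_windows x P) array.  Subjects keep
    their input order and windows their temporal order; the returned index
    table (subject_id, window) maps every row back.
    """
    if not window_fc:
        raise ValueError("no subjects provided")
    P = None
    blocks, idx_sub, idx_win = [], [], []
    for sid, arr in window_fc.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"subject {sid}: window array must be 2-D")
        if P is None:
            P = arr.shape[1]
        elif arr.shape[1] != P:
            raise ValueError(
                f"subject {sid}: {arr.shape[1]} pairs, expected {P}")
        blocks.append(arr)
        idx_sub.extend([sid] * arr.shape[0])
        idx_win.extend(range(arr.shape[0]))
    data = np.vstack(blocks)
    index = pd.DataFrame({"subject_id": idx_sub, "window": idx_win})
    return data, index


def kmeans_states(
    data: np.ndarray,
    k: int,
    index: pd.DataFrame | None = None,
    n_replicates: int = 100,
    seed: int = 0,
) -> StateModel:
    """Best-of-``n_replicates`` k-means solution, states ordered by occupancy.

    k-means++ initialization per replicate; the replicate with the lowest
    within-cluster sum of squares wins.  Empty clusters are re-seeded
    internally by scikit-learn.  Output state ids 1..k are sorted by
    descending total occupancy (ties by centroid norm for determinism).
    """
    data = np.asarray(data, dtype=float)
    if data.shape[0] < k:
        raise ValueError("fewer observations than clusters")
    km = KMeans(n_clusters=k, n_init=n_replicates, init="k-means++",
                random_state=seed)
    raw = km.fit_predict(data)
    counts = np.bincount(raw, minlength=k)
    order = np.lexsort((-np.linalg.norm(km.cluster_centers_, axis=1), -counts))
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    states = relabel[raw] + 1
    centroids = km.cluster_centers_[order]
    if index is None:
        index = pd.DataFrame({"subject_id": ["all"] * len(states),
                              "window": np.arange(len(states))})
    labels = index.copy()
    labels["state"] = states
    return StateModel(k=k, centroids=centroids, labels=labels,
                      inertia=float(km.inertia_), seed=seed)


def _dispersion_ratio(data: np.ndarray, km: KMeans) -> float:
    """Within-cluster SS divided by between-cluster SS."""
    labels = km.labels_
    grand = data.mean(axis=0)
    counts = np.bincount(labels, minlength=km.n_clusters)
    between = float(np.sum(counts * np.sum((km.cluster_centers_ - grand) ** 2, axis=1)))
    if between <= 0:
        return np.inf
    return float(km.inertia_) / between


def elbow_select(
    data: np.ndarray,
    k_range: range | list[int] = range(2, 9),
    n_replicates: int = 10,
    seed: int = 0,
    flat_tol: float = 0.05,
) -> ElbowCurve:
    """Choose k at the elbow of the dispersion-ratio curve.

    validity(k) = within-cluster dispersion / between-cluster dispersion,
    which decreases with k.  The elbow is where the curve turns from steep
    to flat: the k maximizing the ratio of the drop into k to the drop out
    of k, ``(v(k-1) - v(k)) / (v(k) - v(k+1))``.  This relative-curvature
    reading is scale-invariant; the raw second difference of a convex
    decreasing curve would always favour the smallest k.  A flat curve
    (relative drop below ``flat_tol`` everywhere) falls back to the
    smallest k with a warning.
    """
    data = np.asarray(data, dtype=float)
    ks = sorted(k_range)
    if len(ks) < 3:
        raise ValueError("k_range must contain at least 3 values for curvature")
    if max(ks) > data.shape[0]:
        raise ValueError("k_range exceeds number of observations")
    validity = []
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_replicates, init="k-means++",
                    random_state=seed).fit(data)
        validity.append(_dispersion_ratio(data, km))
    v = np.asarray(validity)
    drops = np.diff(v)  # negative on a decreasing curve
    rel_drops = np.abs(drops) / np.maximum(v[:-1], 1e-12)
    if np.all(rel_drops < flat_tol):
        warnings.warn("validity curve is flat; defaulting to smallest k",
                      stacklevel=2)
        return ElbowCurve(ks, validity, chosen_k=ks[0], flat=True)
    drop_in = np.maximum(-drops[:-1], 1e-12)  # into each interior k
    drop_out = np.maximum(-drops[1:], 1e-12)  # out of each interior k
    chosen = ks[1 + int(np.argmax(drop_in / drop_out))]
    return ElbowCurve(ks, validity, chosen_k=chosen)


def match_states(centroids_a: np.ndarray, centroids_b: np.ndarray) -> np.ndarray:
    """Permutation p with p[i] = index in B best matching A's state i.

    Hungarian assignment maximizing the summed Pearson correlation between
    matched centroid pair-vectors.
    """
    A = np.asarray(centroids_a, dtype=float)
    B = np.asarray(centroids_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError("centroid sets must share k and P")
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    denom = np.outer(np.linalg.norm(Ac, axis=1), np.linalg.norm(Bc, axis=1))
    denom[denom == 0] = 1.0
    corr = (Ac @ Bc.T) / denom
    rows, cols = linear_sum_assignment(-corr)
    perm = np.empty(A.shape[0], dtype=int)
    perm[rows] = cols
    return perm


def state_similarity_to_static(centroid: np.ndarray, static_vec: np.ndarray) -> float:
    """Pearson r between a state centroid and the cohort-mean static FC vector."""
    x = np.asarray(centroid, dtype=float).ravel()
    y = np.asarray(static_vec, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("vectors must share length")
    if np.std(x) < 1e-15 or np.std(y) < 1e-15:
        raise ValueError("zero-variance input; similarity undefined")
    return float(np.corrcoef(x, y)[0, 1])
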