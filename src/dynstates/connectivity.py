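"""Static and sliding-window functional connectivity.

Connectivity is Pearson correlation between component time courses,
optionally Fisher z-transformed, computed either once over the whole scan
(static FC) or over short sliding windows (dynamic FC).  Two global graph
summaries characterize a connectivity matrix: *overall connectivity* (mean
absolute off-diagonal entry) and *modularity* (Newman Q of the best
partition found by seeded Louvain on the positive-weight graph).

Pair-space vectorization uses the strict upper triangle in row-major order
(i < j), the convention shared by all downstream modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import networkx as nx
from networkx.algorithms import community as nx_community

__all__ = [
    "WindowSpec",
    "static_fc",
    "fisher_z",
    "sliding_windows",
    "windowed_fc",
    "residualize_fc",
    "overall_connectivity",
    "modularity",
    "vectorize_upper",
    "unvectorize_upper",
    "pair_index",
]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry.

    ``count_convention`` controls the number of windows for step 1:
    ``n_minus_w`` (default) yields T - W windows, matching the worked
    window count of 225 for T = 255, W = 30; ``n_minus_w_plus_1`` yields
    the exhaustive T - W + 1.
    """

    width_tr: int = 30
    step_tr: int = 1
    count_convention: str = "n_minus_w"

    def __post_init__(self) -> None:
        if self.width_tr < 2:
            raise ValueError("window width must be >= 2")
        if self.step_tr < 1:
            raise ValueError("window step must be >= 1")
        if self.count_convention not in ("n_minus_w", "n_minus_w_plus_1"):
            raise ValueError(f"unknown count convention {self.count_convention!r}")


def pair_index(C: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the strict upper triangle (i < j, row-major)."""
    return np.triu_indices(C, k=1)


def vectorize_upper(mat: np.ndarray) -> np.ndarray:
    """C x C symmetric matrix -> length C(C-1)/2 pair vector."""
    i, j = pair_index(mat.shape[-1])
    return np.asarray(mat)[..., i, j]


def unvectorize_upper(vec: np.ndarray, C: int, diag: float = 0.0) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`; the diagonal is filled with ``diag``."""
    i, j = pair_index(C)
    mat = np.full((C, C), diag, dtype=float)
    mat[i, j] = vec
    mat[j, i] = vec
    return mat


def _corr(data: np.ndarray) -> np.ndarray:
    """Pearson correlation of columns; constant columns give r = 0 (warned)."""
    X = data - data.mean(axis=0)
    sd = X.std(axis=0)
    const = sd < 1e-12
    if const.any():
        warnings.warn(f"{const.sum()} constant column(s); their r set to 0",
                      stacklevel=3)
        sd = np.where(const, 1.0, sd)
    Xn = X / sd
    r = (Xn.T @ Xn) / data.shape[0]
    r[const, :] = 0.0
    r[:, const] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip((r + r.T) / 2.0, -1.0, 1.0)


def static_fc(data: np.ndarray) -> np.ndarray:
    """Whole-scan Pearson correlation matrix (C x C) of a T x C series."""
    data = np.asarray(data, dtype=float)
    if data.shape[0] < 3:
        raise ValueError("need at least 3 time points")
    return _corr(data)


def fisher_z(r: np.ndarray, clamp: float = 1.0 - 1e-7) -> np.ndarray:
    """Elementwise atanh with |r| clamped below 1; diagonal of matrices kept 0."""
    r = np.asarray(r, dtype=float)
    square = r.ndim == 2 and r.shape[0] == r.shape[1]
    if square:  # the diagonal is not a correlation between distinct components
        r = r.copy()
        np.fill_diagonal(r, 0.0)
    clipped = np.clip(r, -clamp, clamp)
    if np.any(np.abs(r) > clamp):
        warnings.warn("correlations at |r| ~ 1 clamped before atanh", stacklevel=2)
    z = np.arctanh(clipped)
    if square:
        np.fill_diagonal(z, 0.0)
    return z


def sliding_windows(T: int, spec: WindowSpec = WindowSpec()) -> list[range]:
    """Half-open window index ranges [start, start + width) under the spec."""
    if T <= spec.width_tr:
        raise ValueError(f"T={T} must exceed window width {spec.width_tr}")
    n_starts = T - spec.width_tr
    if spec.count_convention == "n_minus_w_plus_1":
        n_starts += 1
    starts = np.arange(0, n_starts, spec.step_tr)
    return [range(int(s), int(s) + spec.width_tr) for s in starts]


def windowed_fc(data: np.ndarray, spec: WindowSpec = WindowSpec(),
                taper_sd_tr: float | None = None) -> np.ndarray:
    """Per-window Pearson matrices, stacked as (n_windows, C, C).

    With ``taper_sd_tr`` set, samples in each window are weighted by a
    Gaussian taper of that standard deviation (in TR) centred on the window
    before correlating.
    """
    data = np.asarray(data, dtype=float)
    T, C = data.shape
    windows = sliding_windows(T, spec)
    W = spec.width_tr
    if taper_sd_tr is not None:
        x = np.arange(W) - (W - 1) / 2.0
        wts = np.exp(-0.5 * (x / taper_sd_tr) ** 2)
        wts /= wts.sum()
    starts = np.array([w.start for w in windows])
    # batched windows: (n_windows, W, C)
    idx = starts[:, None] + np.arange(W)[None, :]
    seg = data[idx]
    if taper_sd_tr is None:
        mean = seg.mean(axis=1, keepdims=True)
        Xc = seg - mean
        cov = np.einsum("nwi,nwj->nij", Xc, Xc) / W
    else:
        mean = np.einsum("w,nwi->ni", wts, seg)[:, None, :]
        Xc = seg - mean
        cov = np.einsum("w,nwi,nwj->nij", wts, Xc, Xc)
    sd = np.sqrt(np.diagonal(cov, axis1=1, axis2=2))
    const = sd < 1e-12
    if const.any():
        warnings.warn("constant column inside a window; pair r set to 0",
                      stacklevel=2)
    sd = np.where(const, 1.0, sd)
    r = cov / (sd[:, :, None] * sd[:, None, :])
    r[np.broadcast_to(const[:, :, None], r.shape)] = 0.0
    r[np.broadcast_to(const[:, None, :], r.shape)] = 0.0
    eye = np.eye(C, dtype=bool)
    r[:, eye] = 1.0
    return np.clip(r, -1.0, 1.0)


def residualize_fc(fc_vectors: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Per-pair least-squares residuals against [1, covariates].

    With no covariates (``None`` or zero columns) this demeans each pair.
    Residualizing twice equals residualizing once (projection).
    """
    Y = np.asarray(fc_vectors, dtype=float)
    n = Y.shape[0]
    if covariates is None or (hasattr(covariates, "shape") and np.size(covariates) == 0):
        design = np.ones((n, 1))
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != n:
            raise ValueError("covariates must have one row per observation")
        if n <= X.shape[1] + 1:
            raise ValueError("need more observations than covariates + 1")
        design = np.column_stack([np.ones(n), X])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            warnings.warn("collinear covariates; using pseudoinverse", stacklevel=2)
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    return Y - design @ beta


def overall_connectivity(mat: np.ndarray) -> float:
    """Mean absolute off-diagonal (upper-triangle) connectivity."""
    mat = np.asarray(mat, dtype=float)
    return float(np.mean(np.abs(vectorize_upper(mat))))


def modularity(mat: np.ndarray, n_runs: int = 20, seed: int = 0,
               resolution: float = 1.0) -> tuple[float, np.ndarray]:
    """Newman modularity Q of the positive-weight graph, best of Louvain runs.

    Negative entries are dropped (correlation graphs are signed; the
    community structure is defined on the positive part).  Returns Q and the
    community label per node.  An all-nonpositive matrix yields Q = 0 and a
    single community with a warning.
    """
    mat = np.asarray(mat, dtype=float)
    C = mat.shape[0]
    i, j = pair_index(C)
    w = mat[i, j]
    pos = w > 0
    if not pos.any():
        warnings.warn("no positive weights; modularity undefined, returning 0",
                      stacklevel=2)
        return 0.0, np.zeros(C, dtype=int)
    G = nx.Graph()
    G.add_nodes_from(range(C))
    G.add_weighted_edges_from(zip(i[pos].tolist(), j[pos].tolist(), w[pos].tolist()))
    best_q, best_part = -np.inf, None
    for run in range(n_runs):
        part = nx_community.louvain_communities(
            G, weight="weight", resolution=resolution, seed=seed + run)
        q = nx_community.modularity(G, part, weight="weight", resolution=resolution)
        if q > best_q:
            best_q, best_part = q, part
    labels = np.empty(C, dtype=int)
    for lab, nodes in enumerate(best_part):
        labels[list(nodes)] = lab
    return float(best_q), labels
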