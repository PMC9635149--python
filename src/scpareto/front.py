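"""Pareto-front quality metrics and surrogate biological/batch metrics.

Front metrics (all on 2-D objective pairs, minimization convention):
culling to the non-dominated subset, percentage of non-dominated points,
hypervolume against a shared reference point, and the number of distinct
choices (NDC) on a shared μ-grid.

Surrogate metrics on the latent space: batch entropy (BE; mean entropy of
batch labels among latent nearest neighbors — higher means better mixing)
and cell-type clustering agreement (ASW on annotated types; ARI/NMI/UCA of
seeded k-means against the annotation).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import (
    adjusted_rand_score,
    normalized_mutual_info_score,
    silhouette_samples,
    silhouette_score,
)
from sklearn.neighbors import NearestNeighbors

from .measures import nn_mutual_information

logger = logging.getLogger(__name__)

__all__ = [
    "cull_nondominated",
    "percentage_nondominated",
    "hypervolume2d",
    "ndc",
    "batch_entropy",
    "clustering_metrics",
    "unsupervised_clustering_accuracy",
    "surrogate_trade_off_table",
]


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=np.float64)
    if pts.size == 0:
        raise ValueError("empty point set")
    pts = np.atleast_2d(pts)
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    return pts


def nondominated_mask(points) -> np.ndarray:
    """Boolean mask of non-dominated points (minimization, ties retained).

    Sorted-sweep over the first coordinate; duplicates of a non-dominated
    coordinate pair are all retained (neither dominates the other without a
    strict inequality).
    """
    pts = _as_points(points)
    if pts.shape[1] != 2:
        raise ValueError("front metrics are 2-D only")
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    mask = np.zeros(pts.shape[0], dtype=bool)
    best_y = np.inf          # min y among points with strictly smaller x
    i = 0
    while i < order.size:
        j = i
        x = pts[order[i], 0]
        while j < order.size and pts[order[j], 0] == x:
            j += 1
        group = order[i:j]
        gy = pts[group, 1]
        gmin = gy.min()
        if gmin < best_y:
            mask[group[gy == gmin]] = True
        best_y = min(best_y, gmin)
        i = j
    return mask


def cull_nondominated(points) -> np.ndarray:
    """The non-dominated subset of a 2-D point set."""
    pts = _as_points(points)
    return pts[nondominated_mask(pts)]


def percentage_nondominated(points) -> float:
    """|non-dominated| / |points|."""
    pts = _as_points(points)
    return float(nondominated_mask(pts).sum() / pts.shape[0])


def hypervolume2d(points, reference) -> float:
    """Area dominated by the front relative to a shared reference point.

    Every point must be component-wise ≤ the reference with at least one
    strict inequality; the area of the union of point-to-reference
    rectangles is accumulated by a sorted sweep over the non-dominated set.
    """
    pts = _as_points(points)
    ref = np.asarray(reference, dtype=np.float64)
    if pts.shape[1] != 2 or ref.shape != (2,):
        raise ValueError("hypervolume2d handles 2-D points only")
    for p in pts:
        if not (np.all(p <= ref) and np.any(p < ref)):
            raise ValueError(
                f"reference {ref.tolist()} does not strictly cover point "
                f"{p.tolist()}"
            )
    front = cull_nondominated(pts)
    # unique coordinates, x ascending => y strictly descending
    front = np.unique(front, axis=0)
    area = 0.0
    prev_y = ref[1]
    for x, y in front:
        area += (ref[0] - x) * (prev_y - y)
        prev_y = y
    return float(area)


def ndc(points, mu: float, grid_origin) -> int:
    """Number of distinct μ×μ grid cells occupied by non-dominated points.

    Cells are half-open ``[lo, lo+μ)`` anchored at ``grid_origin``; the grid
    (μ and origin) must be shared across compared methods.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    origin = np.asarray(grid_origin, dtype=np.float64)
    front = cull_nondominated(points)
    cells = np.floor((front - origin) / mu).astype(np.int64)
    return int(np.unique(cells, axis=0).shape[0])


def shared_reference_point(*point_sets, pad: float = 0.01) -> np.ndarray:
    """Component-wise max over all compared sets plus ``pad`` of each range."""
    allpts = np.vstack([_as_points(p) for p in point_sets])
    hi = allpts.max(axis=0)
    span = np.maximum(allpts.max(axis=0) - allpts.min(axis=0), 1e-12)
    return hi + pad * span


def shared_grid(*point_sets, divisions: int = 10):
    """Shared NDC grid: origin at the component-wise min, μ = range/divisions."""
    allpts = np.vstack([_as_points(p) for p in point_sets])
    lo = allpts.min(axis=0)
    span = float(np.max(allpts.max(axis=0) - lo))
    mu = max(span / divisions, 1e-12)
    return mu, lo


# ---------------------------------------------------------------------------
# surrogate metrics


def batch_entropy(z: np.ndarray, s: np.ndarray, *, n_neighbors: int = 50,
                  n_pools: int = 50, pool_size: int = 100,
                  seed: int = 0) -> float:
    """Mean natural-log entropy of batch frequencies among latent neighbors.

    ``n_pools`` pools of ``pool_size`` anchor cells are sampled with
    replacement; each anchor contributes the entropy of the batch composition
    of its ``n_neighbors`` Euclidean nearest neighbors.  Higher = better
    mixing; a single batch returns 0 with a warning.
    """
    z = np.asarray(z, dtype=np.float64)
    s = np.asarray(s)
    n = z.shape[0]
    if np.unique(s).size < 2:
        logger.warning("batch entropy of a single batch is 0 by convention")
        return 0.0
    if n < n_neighbors + 1:
        raise ValueError("need at least n_neighbors+1 cells")
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(z)
    rng = np.random.default_rng(seed)
    levels = np.unique(s)
    entropies = []
    for _ in range(n_pools):
        anchors = rng.choice(n, size=min(pool_size, n), replace=False)
        _, nbr = nn.kneighbors(z[anchors])
        nbr = nbr[:, 1:]  # drop self
        for row in nbr:
            freqs = np.array([(s[row] == b).mean() for b in levels])
            nzfreqs = freqs[freqs > 0]
            entropies.append(float(-(nzfreqs * np.log(nzfreqs)).sum()))
    return float(np.mean(entropies))


def unsupervised_clustering_accuracy(labels_true: np.ndarray,
                                     labels_pred: np.ndarray) -> float:
    """Best accuracy over one-to-one cluster/label matchings (Hungarian)."""
    true = pd.Categorical(np.asarray(labels_true)).codes
    pred = pd.Categorical(np.asarray(labels_pred)).codes
    n_true, n_pred = true.max() + 1, pred.max() + 1
    dim = max(n_true, n_pred)
    cost = np.zeros((dim, dim))
    for t, p in zip(true, pred):
        cost[p, t] += 1
    rows, cols = linear_sum_assignment(-cost)
    return float(cost[rows, cols].sum() / true.size)


def clustering_metrics(z: np.ndarray, cell_type: np.ndarray,
                       seed: int = 0) -> dict[str, float]:
    """ASW of annotated types plus ARI/NMI/UCA of seeded k-means vs types.

    k-means uses k = number of annotated types.  A type with a single member
    contributes silhouette 0 for that cell (logged).
    """
    z = np.asarray(z, dtype=np.float64)
    ct = pd.Categorical(np.asarray(cell_type)).codes
    levels, counts = np.unique(ct, return_counts=True)
    if levels.size < 2:
        raise ValueError("need at least 2 annotated cell types")
    if np.any(counts == 1):
        logger.warning("cell types %s have a single member; silhouette 0 used",
                       levels[counts == 1].tolist())
        sil = silhouette_samples(z, ct)
        sil[np.isin(ct, levels[counts == 1])] = 0.0
        asw = float(sil.mean())
    else:
        asw = float(silhouette_score(z, ct))
    km = KMeans(n_clusters=levels.size, random_state=seed, n_init=10).fit(z)
    pred = km.labels_
    return {
        "ASW": asw,
        "ARI": float(adjusted_rand_score(ct, pred)),
        "NMI": float(normalized_mutual_info_score(ct, pred)),
        "UCA": unsupervised_clustering_accuracy(ct, pred),
    }


def surrogate_trade_off_table(candidates, z_by_candidate, s: np.ndarray,
                              cell_type: np.ndarray | None,
                              u_bar_by_candidate, *, seed: int = 0,
                              be_kwargs: dict | None = None) -> pd.DataFrame:
    """Per-candidate surrogate objectives, sign-flipped so lower is better.

    Columns: U̅_n, NN (kNN MI of latent vs batch), −ASW, −NMI, −ARI, −UCA,
    −BE.  Clustering columns are omitted (with a log message) when no
    cell-type annotation is available.
    """
    be_kwargs = be_kwargs or {}
    rows = []
    for tag, z, u_bar in zip(candidates, z_by_candidate, u_bar_by_candidate):
        row = {
            "candidate": tag,
            "U_bar": float(u_bar),
            "NN": nn_mutual_information(z, s),
            "neg_BE": -batch_entropy(z, s, seed=seed, **be_kwargs),
        }
        if cell_type is not None:
            cm = clustering_metrics(z, cell_type, seed=seed)
            row.update({f"neg_{k}": -v for k, v in cm.items()})
        rows.append(row)
    if cell_type is None:
        logger.warning("no cell-type annotation; clustering columns omitted")
    return pd.DataFrame(rows).set_index("candidate")
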