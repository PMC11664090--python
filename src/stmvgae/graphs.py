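"""Construction of the spot-adjacency views.

Spatial views use exact radius / k-nearest-neighbor searches (BallTree or
KDTree backends — exact structures, identical results); expression views use
Spearman rank correlation or cosine similarity. All builders return binary,
symmetric, zero-diagonal adjacency matrices, with ties broken by the smaller
spot index so outputs are deterministic across backends and platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.neighbors import BallTree, KDTree

from .data import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["ViewGraph", "NormalizedGraph", "build_radius_graph",
           "build_knn_graph", "build_spearman_graph", "build_cosine_graph",
           "normalize_adjacency", "build_views", "default_view_specs",
           "write_edge_list"]

_TREES = {"balltree": BallTree, "kdtree": KDTree}


@dataclass
class ViewGraph:
    adjacency: np.ndarray      # binary symmetric, zero diagonal
    method: str                # radius | knn | spearman | cosine
    backend: str               # balltree | kdtree | none
    param: float               # r or k
    view_id: str

    def __post_init__(self):
        a = np.asarray(self.adjacency, dtype=np.float64)
        if a.shape[0] != a.shape[1]:
            raise ValidationError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValidationError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValidationError("adjacency diagonal must be zero")
        if not np.isin(a, (0.0, 1.0)).all():
            raise ValidationError("adjacency must be binary")
        self.adjacency = a


@dataclass
class NormalizedGraph:
    a_hat: np.ndarray     # A + I
    norm: np.ndarray      # D^{-1/2} (A+I) D^{-1/2}
    degree: np.ndarray
    view_id: str = ""


def _sym(a: np.ndarray) -> np.ndarray:
    return np.maximum(a, a.T)


def build_radius_graph(coords: np.ndarray, r: float,
                       backend: str = "balltree") -> ViewGraph:
    """Edge iff 0 < Euclidean distance < r (strict)."""
    if r <= 0:
        raise ValidationError("radius must be positive")
    if backend not in _TREES:
        raise ValidationError(f"unknown backend {backend!r}")
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    tree = _TREES[backend](coords)
    ind, dist = tree.query_radius(coords, r=r, return_distance=True)
    a = np.zeros((n, n))
    for i in range(n):
        # strict inequality and no self edge
        nb = ind[i][(dist[i] < r) & (ind[i] != i)]
        a[i, nb] = 1.0
    a = _sym(a)
    if a.sum() == 0:
        logger.warning("radius graph at r=%.4g has no edges", r)
    return ViewGraph(a, "radius", backend, float(r),
                     f"radius_{'ball' if backend == 'balltree' else 'kd'}")


def build_knn_graph(coords: np.ndarray, k: int,
                    backend: str = "balltree") -> ViewGraph:
    """Directed kNN (self excluded) symmetrized by OR.

    Distance ties at the k-boundary are resolved toward the smaller spot
    index, so both tree backends produce identical graphs.
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    if not 1 <= k < n:
        raise ValidationError(f"k={k} must satisfy 1 <= k < n_spots={n}")
    if backend not in _TREES:
        raise ValidationError(f"unknown backend {backend!r}")
    tree = _TREES[backend](coords)
    # distance of the k-th neighbor (excluding self), then take everything
    # within that shell and keep the first k by (distance, index)
    dist_k, _ = tree.query(coords, k=k + 1)
    a = np.zeros((n, n))
    for i in range(n):
        dk = dist_k[i, -1]
        cand, cdist = tree.query_radius(coords[i:i + 1], r=dk * (1 + 1e-12),
                                        return_distance=True)
        cand, cdist = cand[0], cdist[0]
        mask = cand != i
        cand, cdist = cand[mask], cdist[mask]
        order = np.lexsort((cand, cdist))
        a[i, cand[order[:k]]] = 1.0
    return ViewGraph(_sym(a), "knn", backend, float(k),
                     f"knn_{'ball' if backend == 'balltree' else 'kd'}")


def _topk_similarity_graph(sim: np.ndarray, k: int, method: str) -> ViewGraph:
    n = sim.shape[0]
    if not 1 <= k < n:
        raise ValidationError(f"k={k} must satisfy 1 <= k < n_spots={n}")
    np.fill_diagonal(sim, -np.inf)
    # quantize so mathematically tied similarities (common for rank
    # correlations over few features) compare equal and the index
    # tie-break actually applies, independent of float evaluation order
    sim = np.round(sim, 10)
    a = np.zeros((n, n))
    idx = np.arange(n)
    for i in range(n):
        valid = np.flatnonzero(np.isfinite(sim[i]))
        order = valid[np.lexsort((idx[valid], -sim[i][valid]))]
        a[i, order[:k]] = 1.0  # fewer than k if row has < k valid partners
    return ViewGraph(_sym(a), method, "none", float(k), method)


def spearman_similarity(x: np.ndarray) -> np.ndarray:
    """Pairwise Spearman rank correlation between spot feature vectors.

    Tied values receive average ranks; a constant spot vector gets -inf
    similarity to everything (it carries no ranking information).
    """
    x = np.asarray(x, dtype=np.float64)
    ranks = np.apply_along_axis(rankdata, 1, x)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    constant = norms == 0
    if constant.any():
        logger.warning("%d constant spot vectors excluded from Spearman "
                       "neighbor selection", int(constant.sum()))
    safe = np.where(constant, 1.0, norms)
    c = centered / safe[:, None]
    sim = c @ c.T
    sim[constant, :] = -np.inf
    sim[:, constant] = -np.inf
    return sim


def cosine_similarity_matrix(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    norms = np.linalg.norm(x, axis=1)
    zero = norms == 0
    if zero.any():
        logger.warning("%d zero-norm spot vectors get cosine similarity 0",
                       int(zero.sum()))
    safe = np.where(zero, 1.0, norms)
    xn = x / safe[:, None]
    sim = xn @ xn.T
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    return sim


def build_spearman_graph(x: np.ndarray, k: int) -> ViewGraph:
    """Top-k Spearman-correlation neighbors per spot, OR-symmetrized."""
    if x.shape[1] < 2:
        raise ValidationError("need >= 2 feature columns for Spearman")
    return _topk_similarity_graph(spearman_similarity(x), k, "spearman")


def build_cosine_graph(x: np.ndarray, k: int) -> ViewGraph:
    """Top-k cosine-similarity neighbors per spot, OR-symmetrized."""
    if x.shape[1] < 2:
        raise ValidationError("need >= 2 feature columns for cosine")
    return _topk_similarity_graph(cosine_similarity_matrix(x), k, "cosine")


def normalize_adjacency(g: ViewGraph) -> NormalizedGraph:
    """Symmetric normalization D^{-1/2} (A+I) D^{-1/2} with self-loops."""
    a_hat = g.adjacency + np.eye(g.adjacency.shape[0])
    degree = a_hat.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(degree)
    norm = a_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    return NormalizedGraph(a_hat=a_hat, norm=norm, degree=degree,
                           view_id=g.view_id)


def write_edge_list(g: ViewGraph, path, spot_ids: list[str] | None = None
                    ) -> None:
    """Export the upper-triangle edges as a TSV for inspection."""
    ii, jj = np.nonzero(np.triu(g.adjacency))
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for i, j in zip(ii, jj):
            a = spot_ids[i] if spot_ids else str(i)
            b = spot_ids[j] if spot_ids else str(j)
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# view-spec driven construction
# ---------------------------------------------------------------------------

_SPATIAL_IDS = {
    "radius_ball": ("radius", "balltree"),
    "radius_kd": ("radius", "kdtree"),
    "knn_ball": ("knn", "balltree"),
    "knn_kd": ("knn", "kdtree"),
}


def default_view_specs() -> list[dict]:
    """The default 3-view combination: radius-balltree, knn-balltree,
    knn-kdtree (the best-performing spatial trio)."""
    return [{"view_id": "radius_ball"},
            {"view_id": "knn_ball"},
            {"view_id": "knn_kd"}]


def _default_radius(coords: np.ndarray) -> float:
    tree = KDTree(coords)
    d, _ = tree.query(coords, k=min(2, len(coords)))
    nn = d[:, -1]
    return 1.5 * float(np.median(nn))


def build_views(coords: np.ndarray, x: np.ndarray,
                specs: list[dict]) -> list[ViewGraph]:
    """Build a list of views from spec dicts {view_id, param?}.

    Known ids: radius_ball, radius_kd, knn_ball, knn_kd, spearman, cosine.
    Default params: r = 1.5x median nearest-neighbor distance, k = 6.
    """
    graphs = []
    for spec in specs:
        vid = spec["view_id"]
        param = spec.get("param")
        if vid in _SPATIAL_IDS:
            method, backend = _SPATIAL_IDS[vid]
            if method == "radius":
                r = float(param) if param is not None else _default_radius(coords)
                graphs.append(build_radius_graph(coords, r, backend))
            else:
                k = int(param) if param is not None else 6
                graphs.append(build_knn_graph(coords, k, backend))
        elif vid == "spearman":
            graphs.append(build_spearman_graph(x, int(param or 6)))
        elif vid == "cosine":
            graphs.append(build_cosine_graph(x, int(param or 6)))
        else:
            raise ValidationError(f"unknown view id {vid!r}")
    return graphs
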