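"""Per-view clustering of embeddings, consensus matrix construction, and
extraction of the final labels by hierarchical clustering.

Each view's latent embedding is clustered with a full-covariance Gaussian
mixture (EM, multiple restarts, best likelihood). The consensus matrix
entry C_ij is the fraction of views in which spots i and j share a label;
final labels come from average-linkage agglomerative clustering of 1 - C.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.mixture import GaussianMixture

from .data import ValidationError, canonicalize_labels

logger = logging.getLogger(__name__)

__all__ = ["ConsensusResult", "cluster_embedding", "consensus_matrix",
           "consensus_cluster", "run_consensus"]


@dataclass
class ConsensusResult:
    view_labels: list[np.ndarray]
    consensus_matrix: np.ndarray
    final_labels: np.ndarray
    n_views: int
    n_clusters: int
    embeddings: list = field(default_factory=list, repr=False)


def _fit_gmm(z: np.ndarray, n_clusters: int, seed: int,
             restarts: int) -> tuple[GaussianMixture, np.ndarray]:
    z = np.asarray(z, dtype=np.float64)
    if n_clusters < 2:
        raise ValidationError("n_clusters must be >= 2")
    if z.shape[0] <= n_clusters:
        raise ValidationError("need more spots than clusters")
    last_err: Exception | None = None
    for reg in (1e-6, 1e-3, 1e-1):
        try:
            gmm = GaussianMixture(n_components=n_clusters,
                                  covariance_type="full",
                                  n_init=restarts, reg_covar=reg,
                                  random_state=seed, max_iter=200)
            labels = gmm.fit_predict(z)
            if not np.all(np.isfinite(gmm.means_)):
                raise ValueError("non-finite mixture means")
            return gmm, labels.astype(np.int64)
        except Exception as exc:  # degenerate EM; retry with more ridge
            last_err = exc
            logger.warning("GMM failed at reg_covar=%g: %s", reg, exc)
    raise RuntimeError(f"Gaussian mixture clustering failed: {last_err}")


def cluster_embedding(z: np.ndarray, n_clusters: int, seed: int = 0,
                      restarts: int = 10) -> np.ndarray:
    """Hard assignments from an EM-fitted full-covariance Gaussian mixture.

    Degenerate covariances are handled by increasing ridge regularization
    and retrying; seed-deterministic.
    """
    _, labels = _fit_gmm(z, n_clusters, seed, restarts)
    return labels


def consensus_matrix(view_labels: list[np.ndarray]) -> np.ndarray:
    """C_ij = fraction of label vectors in which i and j share a label."""
    if not view_labels:
        raise ValidationError("need at least one label vector")
    n = len(view_labels[0])
    for i, y in enumerate(view_labels):
        if len(y) != n:
            raise ValidationError(
                f"label vector {i} has length {len(y)}, expected {n}")
    c = np.zeros((n, n))
    for y in view_labels:
        y = np.asarray(y)
        c += (y[:, None] == y[None, :])
    return c / len(view_labels)


def consensus_cluster(c: np.ndarray, n_clusters: int) -> np.ndarray:
    """Average-linkage agglomerative clustering of 1 - C cut at n_clusters."""
    c = np.asarray(c, dtype=np.float64)
    d = 1.0 - c
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)  # guard tiny asymmetries
    z = linkage(squareform(d, checks=False), method="average")
    labels = fcluster(z, t=n_clusters, criterion="maxclust") - 1
    found = len(np.unique(labels))
    if found < n_clusters:
        logger.warning("consensus produced %d < %d clusters (degenerate C)",
                       found, n_clusters)
    return canonicalize_labels(labels)


def run_consensus(embeddings: list, n_clusters: int, seed: int = 0,
                  restarts: int = 10,
                  no_consensus: bool = False) -> ConsensusResult:
    """Cluster each view's embedding, then integrate.

    With ``no_consensus`` the single view with the best mixture likelihood
    supplies the final labels directly (the without-consensus ablation);
    the consensus matrix is still reported.
    """
    if not embeddings:
        raise ValidationError("need at least one embedding")
    view_labels = []
    likelihoods = []
    for i, emb in enumerate(embeddings):
        z = emb.z if hasattr(emb, "z") else np.asarray(emb)
        gmm, labels = _fit_gmm(z, n_clusters, seed, restarts)
        view_labels.append(labels)
        likelihoods.append(gmm.score(z))
    c = consensus_matrix(view_labels)
    if no_consensus:
        best = int(np.argmax(likelihoods))
        logger.info("no_consensus: using view %d (best likelihood)", best)
        final = canonicalize_labels(view_labels[best])
    else:
        final = consensus_cluster(c, n_clusters)
    return ConsensusResult(view_labels=view_labels, consensus_matrix=c,
                           final_labels=final, n_views=len(view_labels),
                           n_clusters=n_clusters,
                           embeddings=list(embeddings))
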