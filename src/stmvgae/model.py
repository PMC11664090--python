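"""Per-view variational graph auto-encoder with a self-supervised
clustering head.

Encoder: a fully-connected stack compresses the (augmented) expression to
Zf, a graph-convolution layer (symmetric-normalized propagation) produces
Zg, and two heads sharing that first layer emit the posterior mean and
log-variance. Decoding reconstructs both the adjacency (inner product +
sigmoid) and the feature matrix (mirror linear stack).

Training runs two phases: reconstruction-only pretraining, then joint
training with a Student-t soft-assignment head whose target distribution is
refreshed periodically. The total objective is the weighted sum
lambda1*L_A + lambda2*L_X + lambda3*L_KL + lambda4*L_DEC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, Linear, Parameter, Tensor
from .data import ValidationError
from .graphs import NormalizedGraph

logger = logging.getLogger(__name__)

__all__ = ["ModelConfig", "ViewEmbedding", "DECState", "MVGAE",
           "reparameterize", "decode_adjacency", "dec_soft_assign",
           "dec_target_distribution", "dec_loss", "init_centers",
           "train_view", "TrainingError"]


class TrainingError(RuntimeError):
    def __init__(self, msg: str, history: list | None = None):
        super().__init__(msg)
        self.history = history or []


@dataclass
class ModelConfig:
    fc_dims: tuple[int, ...] = (1000, 500, 30)
    gcn_hidden: int = 64
    latent_dim: int = 8
    conv_type: str = "gcn"
    activation: str = "relu"
    dropout: float = 0.0
    lr: float = 1e-3
    weight_decay: float = 1e-4
    pretrain_epochs: int = 200
    train_epochs: int = 200
    dec_interval: int = 20
    lambda1: float = 1.0    # adjacency reconstruction
    lambda2: float = 1.0    # feature reconstruction
    lambda3: float = 1.0    # variational (BCE + KL) term
    lambda4: float = 0.001  # self-supervised clustering term (L_DEC is a
                            # sum over spots, so its scale grows with n)
    seed: int = 0
    gmm_restarts: int = 10  # restarts for center initialization

    def __post_init__(self):
        if self.latent_dim < 2:
            raise ValidationError("latent_dim must be >= 2")
        lams = (self.lambda1, self.lambda2, self.lambda3, self.lambda4)
        if any(l < 0 for l in lams):
            raise ValidationError("loss weights must be >= 0")
        if not any(l > 0 for l in lams):
            raise ValidationError("at least one loss weight must be > 0")
        if self.conv_type != "gcn":
            raise NotImplementedError(
                f"conv_type {self.conv_type!r} is an extension point; "
                "only 'gcn' is implemented")


@dataclass
class ViewEmbedding:
    z: np.ndarray                 # spots x latent_dim (noise-free)
    mu: np.ndarray
    logvar: np.ndarray
    x_recon: np.ndarray           # spots x features
    history: list[dict] = field(default_factory=list)
    view_id: str = ""
    dec_refreshes: list[dict] = field(default_factory=list)

    def a_recon(self) -> np.ndarray:
        """Edge probabilities sigmoid(Z Z^T), materialized lazily."""
        return decode_adjacency(self.z)


@dataclass
class DECState:
    centers: np.ndarray   # J x latent_dim
    q: np.ndarray         # spots x J
    p: np.ndarray         # spots x J
    n_clusters: int


# ---------------------------------------------------------------------------
# numpy-facing primitives (the testable contracts)
# ---------------------------------------------------------------------------

def reparameterize(mu: np.ndarray, logvar: np.ndarray,
                   noise: np.ndarray) -> np.ndarray:
    """z = mu + exp(logvar/2) * noise (standard Gaussian reparameterization)."""
    mu, logvar, noise = (np.asarray(a, dtype=np.float64)
                         for a in (mu, logvar, noise))
    if not (mu.shape == logvar.shape == noise.shape):
        raise ValidationError("mu/logvar/noise shapes must match")
    return mu + np.exp(0.5 * logvar) * noise


def decode_adjacency(z: np.ndarray) -> np.ndarray:
    """Edge probabilities sigmoid(Z Z^T)."""
    logits = np.asarray(z) @ np.asarray(z).T
    return 1.0 / (1.0 + np.exp(-logits))


def dec_soft_assign(z: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Student-t (df=1) soft assignment of each row of z to each center."""
    z = np.asarray(z, dtype=np.float64)
    centers = np.asarray(centers, dtype=np.float64)
    d2 = ((z[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    kernel = 1.0 / (1.0 + d2)
    return kernel / kernel.sum(axis=1, keepdims=True)


def dec_target_distribution(q: np.ndarray) -> np.ndarray:
    """Sharpened target p_ij = (q_ij^2 / f_j) / sum_j'(q_ij'^2 / f_j')."""
    q = np.asarray(q, dtype=np.float64)
    f = q.sum(axis=0)
    empty = f == 0
    if empty.any():
        logger.warning("%d empty clusters in target distribution",
                       int(empty.sum()))
    weight = np.where(empty, 0.0, q ** 2 / np.where(empty, 1.0, f))
    return weight / weight.sum(axis=1, keepdims=True)


def dec_loss(p: np.ndarray, q: np.ndarray, eps: float = 1e-12) -> float:
    """KL(P || Q) summed over spots, with 0*log 0 = 0."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValidationError("p and q shapes must match")
    if np.any((q <= 0) & (p > 0)):
        logger.warning("q has zeros where p > 0; clamping by %.0e", eps)
    mask = p > 0
    return float(np.sum(p[mask] * (np.log(p[mask])
                                   - np.log(np.maximum(q[mask], eps)))))


def init_centers(z: np.ndarray, n_clusters: int, clusterer=None,
                 seed: int = 0) -> DECState:
    """Cluster z and take per-cluster means as initial centers."""
    if clusterer is None:
        from .consensus import cluster_embedding
        clusterer = cluster_embedding
    for attempt_seed in (seed, seed + 1):
        labels = clusterer(z, n_clusters, seed=attempt_seed)
        counts = np.bincount(labels, minlength=n_clusters)
        if np.all(counts > 0):
            break
    else:
        raise TrainingError(
            f"clusterer produced empty clusters for J={n_clusters} "
            "after re-seeding")
    centers = np.vstack([z[labels == j].mean(axis=0)
                         for j in range(n_clusters)])
    q = dec_soft_assign(z, centers)
    return DECState(centers=centers, q=q,
                    p=dec_target_distribution(q), n_clusters=n_clusters)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class MVGAE:
    """One view's variational graph auto-encoder (full-batch, CPU)."""

    def __init__(self, n_features: int, cfg: ModelConfig,
                 rng: np.random.Generator | None = None):
        self.cfg = cfg
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        dims = [n_features, *cfg.fc_dims]
        self.fc = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        zf_dim = dims[-1]
        # graph conv weights: shared first layer, separate mu/sigma heads
        self.w1 = Linear(zf_dim, cfg.gcn_hidden, rng)
        self.w2_mu = Linear(cfg.gcn_hidden, cfg.latent_dim, rng)
        self.w2_sig = Linear(cfg.gcn_hidden, cfg.latent_dim, rng)
        rev = [cfg.latent_dim, *reversed(cfg.fc_dims), n_features]
        self.dec = [Linear(a, b, rng) for a, b in zip(rev[:-1], rev[1:])]

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for layer in (*self.fc, self.w1, self.w2_mu, self.w2_sig, *self.dec):
            params += layer.parameters()
        return params

    def encode(self, x: Tensor, g: NormalizedGraph) -> tuple[Tensor, Tensor]:
        if x.shape[0] != g.norm.shape[0]:
            raise ValidationError(
                f"x has {x.shape[0]} rows but graph has {g.norm.shape[0]}")
        norm = Tensor(g.norm)
        h = x
        for lin in self.fc:
            h = lin(h).relu()
        zg = (norm @ self.w1(h)).relu()
        mu = norm @ self.w2_mu(zg)
        logvar = norm @ self.w2_sig(zg)
        return mu, logvar

    def decode_features(self, z: Tensor) -> Tensor:
        h = z
        for li, lin in enumerate(self.dec):
            h = lin(h)
            if li < len(self.dec) - 1:
                h = h.relu()
        return h

    # -- losses ------------------------------------------------------------
    def loss_terms(self, x: Tensor, g: NormalizedGraph, mu: Tensor,
                   logvar: Tensor, z: Tensor, x_recon: Tensor
                   ) -> tuple[Tensor, Tensor, Tensor]:
        """(L_A, L_X, L_KL) with off-diagonal targets and edge reweighting.

        L_A: squared error between the binary adjacency and sigmoid(ZZ^T),
        edges upweighted by the non-edge/edge ratio. L_X: mean squared
        feature reconstruction error. L_KL: balanced binary cross-entropy
        of the adjacency logits (the negated expected log-likelihood) plus
        the closed-form Gaussian KL to the standard-normal prior.
        """
        key = id(g)
        if getattr(self, "_loss_cache_key", None) != key:
            n = g.norm.shape[0]
            a = g.a_hat - np.eye(n)        # binary adjacency, no self-loops
            offdiag = 1.0 - np.eye(n)
            n_edges = a.sum()
            n_non = offdiag.sum() - n_edges
            pos_w = (n_non / n_edges) if n_edges > 0 else 1.0
            w = offdiag * (1.0 + (pos_w - 1.0) * a)
            self._loss_cache_key = key
            self._loss_cache = (Tensor(a * pos_w), Tensor(a), Tensor(w),
                                float(w.sum()))
        a_pw, a_t, w, w_sum = self._loss_cache

        logits = z @ z.T
        a_tilde = logits.sigmoid()
        l_a = (w * (a_t - a_tilde) ** 2.0).sum() * (1.0 / w_sum)

        l_x = ((x - x_recon) ** 2.0).mean()

        # weighted BCE from logits; with per-entry weight w and edge
        # upweight pos_w this collapses to
        #   sum(w * softplus(l)) - pos_w * sum(a * l), all over w_sum
        bce = ((w * logits.softplus()).sum()
               - (a_pw * logits).sum()) * (1.0 / w_sum)
        kl = ((logvar.exp() + mu ** 2.0 - logvar - 1.0) * 0.5).mean()
        l_kl = bce + kl
        return l_a, l_x, l_kl


def _dec_loss_tensor(p: np.ndarray, z: Tensor, centers: Tensor) -> Tensor:
    """Differentiable KL(P || Q(z, centers)), P held fixed."""
    z2 = (z ** 2.0).sum(axis=1, keepdims=True)
    c2 = (centers ** 2.0).sum(axis=1, keepdims=True).T
    d2 = z2 + c2 - 2.0 * (z @ centers.T)
    kernel = (d2 + 1.0) ** -1.0
    q = kernel * kernel.sum(axis=1, keepdims=True) ** -1.0
    logq = (q + 1e-12).log()
    p_safe = np.maximum(p, 0.0)
    plogp = float(np.sum(p_safe[p_safe > 0] * np.log(p_safe[p_safe > 0])))
    return plogp - (Tensor(p) * logq).sum()


def train_view(x: np.ndarray, g: NormalizedGraph, n_clusters: int,
               cfg: ModelConfig) -> ViewEmbedding:
    """Two-phase training of one view's auto-encoder.

    Phase 1 (``pretrain_epochs``): minimize the reconstruction/variational
    terms only. Phase 2 (``train_epochs``): initialize cluster centers from
    the current noise-free embedding, then minimize the full weighted loss,
    refreshing the sharpened target every ``dec_interval`` epochs. The
    self-supervised head is skipped entirely when lambda4 == 0.
    Deterministic given ``cfg.seed``.
    """
    x = np.asarray(x, dtype=np.float64)
    rng = np.random.default_rng(cfg.seed)
    model = MVGAE(x.shape[1], cfg, rng)
    opt = Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    x_t = Tensor(x)
    history: list[dict] = []

    def epoch_step(epoch: int, phase: int, dec_state: DECState | None,
                   centers_t: Tensor | None) -> None:
        mu, logvar = model.encode(x_t, g)
        noise = rng.standard_normal(mu.shape)
        z = mu + (logvar * 0.5).exp() * Tensor(noise)
        x_recon = model.decode_features(z)
        l_a, l_x, l_kl = model.loss_terms(x_t, g, mu, logvar, z, x_recon)
        total = cfg.lambda1 * l_a + cfg.lambda2 * l_x + cfg.lambda3 * l_kl
        l_dec_val = 0.0
        if dec_state is not None:
            # soft assignment from the noise-free mean, matching evaluation
            l_dec = _dec_loss_tensor(dec_state.p, mu, centers_t)
            total = total + cfg.lambda4 * l_dec
            l_dec_val = float(l_dec.data)
        rec = {"epoch": epoch, "phase": phase,
               "L_A": float(l_a.data), "L_X": float(l_x.data),
               "L_KL": float(l_kl.data), "L_DEC": l_dec_val,
               "total": float(total.data)}
        history.append(rec)
        if not np.isfinite(rec["total"]) or rec["total"] > 1e6:
            raise TrainingError(
                f"training diverged at epoch {epoch}: {rec}", history)
        opt.zero_grad()
        total.backward()
        opt.step()

    # phase 1: pretraining without the self-supervised head
    for epoch in range(cfg.pretrain_epochs):
        epoch_step(epoch, 1, None, None)

    # phase 2
    dec_state = None
    centers_t = None
    if cfg.lambda4 > 0 and cfg.train_epochs > 0:
        mu, _ = model.encode(x_t, g)
        dec_state = init_centers(mu.data, n_clusters, seed=cfg.seed)
        centers_t = Parameter(dec_state.centers.copy())
        opt = Adam(model.parameters() + [centers_t], lr=cfg.lr,
                   weight_decay=cfg.weight_decay)
    def _mean_row_entropy(dist: np.ndarray) -> float:
        d = np.maximum(dist, 1e-300)
        return float(-(dist * np.log(d)).sum(axis=1).mean())

    refreshes: list[dict] = []
    for epoch in range(cfg.train_epochs):
        if dec_state is not None and epoch % cfg.dec_interval == 0:
            mu, _ = model.encode(x_t, g)
            dec_state.q = dec_soft_assign(mu.data, centers_t.data)
            dec_state.p = dec_target_distribution(dec_state.q)
            refreshes.append({"epoch": cfg.pretrain_epochs + epoch,
                              "H_q": _mean_row_entropy(dec_state.q),
                              "H_p": _mean_row_entropy(dec_state.p)})
        epoch_step(cfg.pretrain_epochs + epoch, 2, dec_state, centers_t)

    # evaluation: noise-free embedding and reconstructions
    mu, logvar = model.encode(x_t, g)
    x_recon = model.decode_features(mu)
    return ViewEmbedding(z=mu.data.copy(), mu=mu.data.copy(),
                         logvar=logvar.data.copy(),
                         x_recon=x_recon.data.copy(), history=history,
                         view_id=g.view_id, dec_refreshes=refreshes)
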