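"""Per-spot image features and expression augmentation.

A pluggable extractor maps each spot tile to a fixed-length vector; a small
fully-connected autoencoder then expands those features to the expression
dimension (the aligned matrix MS), and the model input is the weighted sum
alpha1*MS + alpha2*GE.

The extractor is an injected dependency. The built-in extractor (channel
statistics + a coarse 2-D color histogram) needs no downloads and is
deterministic, which is what the tests use; a torchvision ResNet50 can be
plugged in where available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, BatchNorm1d, Linear, Tensor
from .data import STDataset, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["AugmentConfig", "ImageFeatureSet", "BuiltinExtractor",
           "cut_tiles", "extract_cnn_features", "align_features",
           "augment_expression", "augment_dataset"]


class ConfigurationError(ValueError):
    pass


@dataclass
class AugmentConfig:
    alpha1: float = 0.3      # weight of aligned image features MS
    alpha2: float = 1.0      # weight of expression GE
    tile_size: int = 16
    ae_hidden: tuple[int, ...] = (512,)
    ae_epochs: int = 100
    ae_lr: float = 1e-3
    seed: int = 0
    extractor: str = "builtin"

    def __post_init__(self):
        if self.alpha1 < 0 or self.alpha2 < 0:
            raise ValidationError("alpha weights must be >= 0")
        if self.alpha1 + self.alpha2 <= 0:
            raise ValidationError("alpha1 + alpha2 must be > 0")


@dataclass
class ImageFeatureSet:
    raw_features: np.ndarray       # spots x d0
    aligned_features: np.ndarray   # spots x n_hvg (MS)
    extractor_name: str


def cut_tiles(ds: STDataset, tile_size: int) -> np.ndarray:
    """Crop one tile_size x tile_size patch centered at each spot's pixel
    position; edge crops are zero-padded. Order follows spot order."""
    if ds.image is None or ds.pixel_coords is None:
        raise ConfigurationError(
            "dataset has no image/pixel_coords; disable augmentation")
    img = np.asarray(ds.image)
    h, w = img.shape[:2]
    half = tile_size // 2
    tiles = np.zeros((ds.n_spots, tile_size, tile_size, 3), dtype=img.dtype)
    for i, (px, py) in enumerate(ds.pixel_coords):
        x0, y0 = int(round(px)) - half, int(round(py)) - half
        xs0, ys0 = max(x0, 0), max(y0, 0)
        xs1, ys1 = min(x0 + tile_size, w), min(y0 + tile_size, h)
        if xs1 > xs0 and ys1 > ys0:
            tiles[i, ys0 - y0:ys1 - y0, xs0 - x0:xs1 - x0] = \
                img[ys0:ys1, xs0:xs1, :3]
    return tiles


def _auto_contrast(tile: np.ndarray) -> np.ndarray:
    """Normalize + stretch a tile to [0, 1] per channel."""
    t = tile.astype(np.float64) / 255.0
    lo = t.min(axis=(0, 1), keepdims=True)
    hi = t.max(axis=(0, 1), keepdims=True)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    return (t - lo) / span


class BuiltinExtractor:
    """Deterministic no-download tile featurizer.

    Concatenates per-channel mean/std with a coarse 2-D hue/intensity
    histogram. Purely a stand-in for a pre-trained CNN in offline tests.
    """

    def __init__(self, n_bins: int = 8):
        self.n_bins = n_bins
        self.dim = 6 + n_bins * n_bins

    def __call__(self, tile: np.ndarray) -> np.ndarray:
        t = _auto_contrast(tile)
        mean = t.mean(axis=(0, 1))
        std = t.std(axis=(0, 1))
        intensity = t.mean(axis=2).ravel()
        # crude hue proxy: R-channel share of total
        total = t.sum(axis=2).ravel()
        hue = np.divide(t[:, :, 0].ravel(), total,
                        out=np.full_like(total, 1 / 3.0), where=total > 0)
        hist, _, _ = np.histogram2d(hue, intensity, bins=self.n_bins,
                                    range=[[0, 1], [0, 1]])
        hist = hist.ravel() / max(hist.sum(), 1.0)
        return np.concatenate([mean, std, hist])


def extract_cnn_features(tiles: np.ndarray, extractor=None) -> np.ndarray:
    """Apply the extractor tile-by-tile -> spots x d0 feature matrix."""
    if extractor is None:
        extractor = BuiltinExtractor()
    rows = [np.asarray(extractor(t), dtype=np.float64) for t in tiles]
    dims = {r.shape for r in rows}
    if len(dims) > 1:
        raise ValidationError(
            f"extractor returned varying feature lengths: {sorted(dims)}")
    return np.vstack(rows)


def align_features(raw_features: np.ndarray, target_dim: int,
                   cfg: AugmentConfig,
                   return_history: bool = False):
    """Expand raw image features to the expression dimension with a small
    fully-connected autoencoder and return the target-dimension layer MS.

    Architecture: d0 -> hidden -> target_dim -> hidden -> d0, hidden layers
    ReLU(BN(affine)), trained to reconstruct the (standardized) raw
    features by squared error. MS is the affine output of the width-
    ``target_dim`` layer, z-scored per feature so its scale is commensurate
    with log-expression before weighting.
    """
    if target_dim < 1:
        raise ValidationError("target_dim must be >= 1")
    raw = np.asarray(raw_features, dtype=np.float64)
    n, d0 = raw.shape
    # standardize inputs; constant features stay zero
    mu, sd = raw.mean(axis=0), raw.std(axis=0)
    raw_std = (raw - mu) / np.where(sd > 0, sd, 1.0)

    rng = np.random.default_rng(cfg.seed)
    widths = [d0, *cfg.ae_hidden, target_dim, *reversed(cfg.ae_hidden), d0]
    layers, bns = [], []
    for a, b in zip(widths[:-1], widths[1:]):
        layers.append(Linear(a, b, rng))
        bns.append(BatchNorm1d(b))
    ms_layer = len(cfg.ae_hidden)  # index of the target_dim layer

    params = []
    for lin, bn in zip(layers, bns):
        params += lin.parameters() + bn.parameters()
    opt = Adam(params, lr=cfg.ae_lr)

    x_in = Tensor(raw_std)

    def forward() -> tuple[Tensor, Tensor]:
        h = x_in
        ms = None
        for li, (lin, bn) in enumerate(zip(layers, bns)):
            pre = lin(h)
            if li == ms_layer:
                ms = pre
            if li < len(layers) - 1:
                h = bn(pre).relu()
            else:
                h = pre  # linear output layer
        return h, ms

    losses: list[float] = []
    for epoch in range(cfg.ae_epochs):
        recon, _ = forward()
        loss = ((recon - x_in) ** 2.0).mean()
        if not np.isfinite(loss.data):
            raise RuntimeError(
                f"aligner loss became non-finite at epoch {epoch}")
        losses.append(float(loss.data))
        opt.zero_grad()
        loss.backward()
        opt.step()

    _, ms = forward()
    ms = ms.data
    m, s = ms.mean(axis=0), ms.std(axis=0)
    ms = (ms - m) / np.where(s > 0, s, 1.0)
    return (ms, losses) if return_history else ms


def augment_expression(ms: np.ndarray, ge: np.ndarray,
                       alpha1: float, alpha2: float) -> np.ndarray:
    """Weighted elementwise sum alpha1*MS + alpha2*GE."""
    ms = np.asarray(ms, dtype=np.float64)
    ge = np.asarray(ge, dtype=np.float64)
    if ms.shape != ge.shape:
        raise ValidationError(
            f"MS shape {ms.shape} != GE shape {ge.shape}")
    return alpha1 * ms + alpha2 * ge


def augment_dataset(ds: STDataset, cfg: AugmentConfig,
                    extractor=None) -> tuple[np.ndarray, ImageFeatureSet]:
    """Full augmentation path: tiles -> raw features -> aligned MS ->
    augmented input. Uses precomputed ``ds.tiles`` when present, otherwise
    cuts tiles from the full image."""
    if ds.tiles is not None:
        tiles = ds.tiles
    else:
        tiles = cut_tiles(ds, cfg.tile_size)
    raw = extract_cnn_features(tiles, extractor)
    ms = align_features(raw, ds.n_genes, cfg)
    fs = ImageFeatureSet(raw_features=raw, aligned_features=ms,
                         extractor_name=type(extractor).__name__
                         if extractor else "builtin")
    return augment_expression(ms, ds.expression, cfg.alpha1, cfg.alpha2), fs
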