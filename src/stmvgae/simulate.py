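"""Synthetic Visium-like tissues: hexagonal lattice, contiguous layered
domains, negative-binomial expression with dropout, optional pseudo-histology
tiles. All stages of the pipeline are testable on these without downloads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmwrite

from .data import STDataset, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "generate_hex_lattice", "assign_layered_domains",
           "simulate_expression", "render_pseudo_tiles", "simulate_dataset",
           "write_fixture"]

# base colors for pseudo-histology, one per domain (cycled if K > 8)
_DOMAIN_COLORS = np.array([
    [200, 80, 80], [80, 160, 80], [90, 90, 200], [200, 180, 70],
    [170, 90, 180], [80, 180, 190], [220, 130, 60], [120, 120, 120],
], dtype=np.float64)


@dataclass
class SimConfig:
    n_rows: int = 20
    n_cols: int = 30
    n_genes: int = 150
    k_domains: int = 4
    markers_per_domain: int = 10
    log_fold_change: float = 2.5
    baseline_mean: float = 2.0
    dropout_rate: float = 0.3
    noise_dispersion: float = 2.0
    seed: int = 0
    make_tiles: bool = False
    tile_size: int = 16

    def __post_init__(self):
        if self.k_domains < 2:
            raise ValidationError("k_domains must be >= 2")
        if self.n_rows * self.n_cols < 10 * self.k_domains:
            raise ValidationError(
                "lattice too small: need n_rows*n_cols >= 10*k_domains")
        if self.markers_per_domain * self.k_domains > self.n_genes:
            raise ValidationError(
                "markers_per_domain*k_domains exceeds n_genes")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValidationError("dropout_rate must be in [0, 1)")


def generate_hex_lattice(n_rows: int, n_cols: int) -> np.ndarray:
    """Offset-row hexagonal packing with unit nearest-neighbor distance.

    Odd rows are shifted by half a spacing; row pitch is sqrt(3)/2, so each
    interior spot has exactly six neighbors at distance 1.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValidationError("lattice dims must be >= 1")
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols),
                             indexing="ij")
    x = cols + 0.5 * (rows % 2)
    y = rows * (np.sqrt(3.0) / 2.0)
    return np.column_stack([x.ravel(), y.ravel()]).astype(np.float64)


def assign_layered_domains(coords: np.ndarray, k_domains: int) -> np.ndarray:
    """Slice the y-range into k contiguous horizontal bands.

    Bands are equal-width in y; every band must catch at least one spot.
    """
    if k_domains < 2:
        raise ValidationError("k_domains must be >= 2")
    y = coords[:, 1]
    lo, hi = y.min(), y.max()
    span = hi - lo
    if span <= 0:
        raise ValidationError("degenerate y-range; lattice has a single row")
    labels = np.minimum((k_domains * (y - lo) / span).astype(np.int64),
                        k_domains - 1)
    counts = np.bincount(labels, minlength=k_domains)
    if np.any(counts == 0):
        empty = np.flatnonzero(counts == 0).tolist()
        raise ValidationError(
            f"domain bands {empty} are empty; use a larger lattice")
    return labels


def simulate_expression(labels: np.ndarray, cfg: SimConfig
                        ) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Negative-binomial counts with domain marker programs and dropout.

    Each domain gets ``markers_per_domain`` disjoint marker genes whose mean
    is ``baseline_mean * 2**log_fold_change`` inside the domain and
    ``baseline_mean`` outside; non-markers sit at baseline everywhere.
    Bernoulli(dropout_rate) zero-masking is applied independently.
    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = len(labels)
    means = np.full((n, cfg.n_genes), cfg.baseline_mean)
    marker_map: dict[int, np.ndarray] = {}
    for d in range(cfg.k_domains):
        g0 = d * cfg.markers_per_domain
        gsl = np.arange(g0, g0 + cfg.markers_per_domain)
        marker_map[d] = gsl
        inside = labels == d
        means[np.ix_(inside, gsl)] = (
            cfg.baseline_mean * 2.0 ** cfg.log_fold_change)

    # NB via gamma-Poisson; dispersion r = noise_dispersion
    r = cfg.noise_dispersion
    lam = rng.gamma(shape=r, scale=means / r)
    counts = rng.poisson(lam).astype(np.float64)
    if cfg.dropout_rate > 0:
        keep = rng.random(counts.shape) >= cfg.dropout_rate
        counts *= keep
    return counts, marker_map


def render_pseudo_tiles(labels: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Per-spot RGB tiles: a domain base color plus Gaussian pixel noise."""
    rng = np.random.default_rng(cfg.seed + 1)
    t = cfg.tile_size
    colors = _DOMAIN_COLORS[np.asarray(labels) % len(_DOMAIN_COLORS)]
    tiles = colors[:, None, None, :] + rng.normal(
        0.0, 10.0, size=(len(labels), t, t, 3))
    return np.clip(tiles, 0, 255).astype(np.uint8)


def simulate_dataset(cfg: SimConfig) -> tuple[STDataset, dict[int, np.ndarray]]:
    """Compose lattice, domains, expression and optional tiles into an
    :class:`STDataset` whose ``truth_labels`` are the generator domains."""
    coords = generate_hex_lattice(cfg.n_rows, cfg.n_cols)
    labels = assign_layered_domains(coords, cfg.k_domains)
    counts, marker_map = simulate_expression(labels, cfg)
    tiles = render_pseudo_tiles(labels, cfg) if cfg.make_tiles else None
    n = coords.shape[0]
    ds = STDataset(
        expression=counts,
        gene_ids=[f"gene_{j}" for j in range(cfg.n_genes)],
        spot_ids=[f"spot_{i}" for i in range(n)],
        coords=coords,
        truth_labels=labels,
        tiles=tiles,
    )
    return ds, marker_map


def write_fixture(cfg: SimConfig, out_dir) -> Path:
    """Emit a 10x-style matrix directory (+ coords, labels, optional tiles)
    readable by :func:`stmvgae.data.read_tenx_matrix_dir`."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ds, _ = simulate_dataset(cfg)

    # genes x spots, the 10x on-disk orientation
    mmwrite(str(out_dir / "matrix.mtx"),
            sparse.csr_matrix(ds.expression.T.astype(np.int64)))
    (out_dir / "barcodes.tsv").write_text(
        "\n".join(ds.spot_ids) + "\n")
    (out_dir / "features.tsv").write_text(
        "\n".join(f"{g}\t{g}\tGene Expression" for g in ds.gene_ids) + "\n")
    pd.DataFrame({
        "spot_id": ds.spot_ids,
        "x": ds.coords[:, 0],
        "y": ds.coords[:, 1],
    }).to_csv(out_dir / "coords.csv", index=False)
    pd.DataFrame({"spot_id": ds.spot_ids,
                  "label": ds.truth_labels}).to_csv(
        out_dir / "labels.csv", index=False)
    if ds.tiles is not None:
        tdir = out_dir / "tiles"
        tdir.mkdir(exist_ok=True)
        for sid, tile in zip(ds.spot_ids, ds.tiles):
            Image.fromarray(tile).save(tdir / f"{sid}.png")
    return out_dir
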