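"""Fixed preprocessing recipe: gene filter -> library-size normalization ->
log1p -> dispersion-ranked highly-variable-gene selection.

Spot order is never changed by any step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import STDataset, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["PreprocessConfig", "filter_genes", "normalize_log", "select_hvg",
           "preprocess"]


@dataclass
class PreprocessConfig:
    min_cells: int = 50
    n_hvg: int = 3000
    target_sum: float | str = "median"   # scale each spot to this total
    hvg_method: str = "dispersion"
    n_bins: int = 20

    def __post_init__(self):
        if self.min_cells < 0:
            raise ValidationError("min_cells must be >= 0")
        if self.n_hvg < 1:
            raise ValidationError("n_hvg must be >= 1")


def filter_genes(ds: STDataset, min_cells: int) -> STDataset:
    """Keep genes detected (count > 0) in at least ``min_cells`` spots."""
    if min_cells <= 0:
        return ds
    n_pos = (ds.expression > 0).sum(axis=0)
    keep = n_pos >= min_cells
    if not keep.any():
        raise ValidationError(
            f"all {ds.n_genes} genes removed at min_cells={min_cells}")
    kept_ids = [g for g, k in zip(ds.gene_ids, keep) if k]
    return ds.replace_expression(ds.expression[:, keep], kept_ids)


def normalize_log(ds: STDataset, target_sum: float | str = "median"
                  ) -> STDataset:
    """Scale each spot's total to ``target_sum`` (or the median library
    size), then apply log(1+x). All-zero spots are left as zeros."""
    x = ds.expression
    if np.any(x < 0):
        raise ValidationError("normalize_log requires non-negative input")
    totals = x.sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.warning("%d all-zero spots left unnormalized", int(zero.sum()))
    if target_sum == "median":
        nz = totals[~zero]
        target = float(np.median(nz)) if nz.size else 1.0
    else:
        target = float(target_sum)
    scale = np.where(zero, 1.0, target / np.where(zero, 1.0, totals))
    return ds.replace_expression(np.log1p(x * scale[:, None]))


def _normalized_dispersion(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Seurat-style dispersion: var/mean per gene, z-scored within bins of
    genes grouped by mean expression."""
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    # bin genes by mean; z-score dispersion inside each bin
    edges = np.quantile(mean, np.linspace(0, 1, n_bins + 1)[1:-1])
    bins = np.searchsorted(edges, mean, side="right")
    out = np.zeros_like(disp)
    for b in np.unique(bins):
        sel = bins == b
        d = disp[sel]
        mu = d.mean()
        sd = d.std(ddof=1) if sel.sum() > 1 else 0.0
        out[sel] = (d - mu) / sd if sd > 0 else 0.0
    return out


def select_hvg(ds: STDataset, n_hvg: int, n_bins: int = 20) -> STDataset:
    """Return the ``n_hvg`` genes with highest normalized dispersion.

    If the dataset has fewer genes than requested, all genes are returned
    with a warning. Kept genes preserve their original order.
    """
    if n_hvg >= ds.n_genes:
        if n_hvg > ds.n_genes:
            logger.warning("n_hvg=%d > %d genes; keeping all",
                           n_hvg, ds.n_genes)
        return ds
    score = _normalized_dispersion(ds.expression, n_bins)
    var = ds.expression.var(axis=0)
    raw = np.where(ds.expression.mean(axis=0) > 0,
                   var / np.maximum(ds.expression.mean(axis=0), 1e-300), 0.0)
    score[var == 0] = -np.inf  # constant genes are never variable
    # rank: binned z-score desc, then raw dispersion desc, then index asc
    top = np.sort(np.lexsort((np.arange(len(score)), -raw, -score))[:n_hvg])
    return ds.replace_expression(ds.expression[:, top],
                                 [ds.gene_ids[j] for j in top])


def preprocess(ds: STDataset, cfg: PreprocessConfig) -> STDataset:
    ds = filter_genes(ds, cfg.min_cells)
    ds = normalize_log(ds, cfg.target_sum)
    return select_hvg(ds, cfg.n_hvg, cfg.n_bins)
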