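"""Dataset container and readers/writers for the standard spot-level formats.

The :class:`STDataset` is the universal container passed between stages:
expression (spots x genes), 2-D coordinates, optional image + pixel
positions, optional ground-truth domain labels. Spot order is canonical and
never re-sorted downstream.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = ["STDataset", "ValidationError", "read_tenx_matrix_dir",
           "read_table_dataset", "write_results", "canonicalize_labels"]


class ValidationError(ValueError):
    """Raised when inputs violate a dataset contract."""


def canonicalize_labels(labels) -> np.ndarray:
    """Map arbitrary label values to contiguous 0-based integers.

    Ordering of the canonical ids follows sorted order of the original
    values, so the mapping is deterministic.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    lut = {v: i for i, v in enumerate(uniq.tolist())}
    return np.array([lut[v] for v in labels.tolist()], dtype=np.int64)


@dataclass
class STDataset:
    expression: np.ndarray              # spots x genes, non-negative
    gene_ids: list[str]
    spot_ids: list[str]
    coords: np.ndarray                  # spots x 2
    pixel_coords: np.ndarray | None = None
    image: np.ndarray | None = None     # H x W x 3 uint8
    truth_labels: np.ndarray | None = None
    layer_names: dict[int, str] | None = None
    tiles: np.ndarray | None = field(default=None, repr=False)  # spots x t x t x 3

    def __post_init__(self):
        self.expression = np.asarray(self.expression, dtype=np.float64)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        n = self.expression.shape[0]
        if self.coords.shape != (n, 2):
            raise ValidationError(
                f"coords shape {self.coords.shape} != ({n}, 2)")
        if len(self.spot_ids) != n:
            raise ValidationError(
                f"{len(self.spot_ids)} spot_ids for {n} expression rows")
        if len(self.gene_ids) != self.expression.shape[1]:
            raise ValidationError(
                f"{len(self.gene_ids)} gene_ids for "
                f"{self.expression.shape[1]} expression columns")
        if len(set(self.spot_ids)) != n:
            raise ValidationError("spot_ids are not unique")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("gene_ids are not unique")
        if not np.all(np.isfinite(self.expression)):
            raise ValidationError("expression contains non-finite values")
        if np.any(self.expression < 0):
            raise ValidationError("expression contains negative values")
        if self.truth_labels is not None:
            self.truth_labels = canonicalize_labels(self.truth_labels)
            if len(self.truth_labels) != n:
                raise ValidationError("truth_labels length != number of spots")

    @property
    def n_spots(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    def replace_expression(self, expr: np.ndarray,
                           gene_ids: list[str] | None = None) -> "STDataset":
        """Return a copy with a new expression matrix (same spots)."""
        return STDataset(
            expression=expr,
            gene_ids=list(gene_ids) if gene_ids is not None else list(self.gene_ids),
            spot_ids=list(self.spot_ids),
            coords=self.coords.copy(),
            pixel_coords=None if self.pixel_coords is None else self.pixel_coords.copy(),
            image=self.image,
            truth_labels=None if self.truth_labels is None else self.truth_labels.copy(),
            layer_names=self.layer_names,
            tiles=self.tiles,
        )


# ---------------------------------------------------------------------------
# 10x-style matrix directory
# ---------------------------------------------------------------------------

def _find_file(path: Path, stems: list[str]) -> Path:
    for stem in stems:
        for cand in (path / stem, path / (stem + ".gz")):
            if cand.exists():
                return cand
    raise FileNotFoundError(
        f"none of {stems} (or .gz) found in {path}")


def _read_lines(p: Path) -> list[str]:
    opener = gzip.open if p.suffix == ".gz" else open
    with opener(p, "rt") as fh:
        return [ln.rstrip("\n") for ln in fh if ln.strip()]


def _read_positions(p: Path) -> pd.DataFrame:
    """Parse a tissue_positions table, headered or headerless 6-column."""
    first = pd.read_csv(p, header=None, nrows=1)
    headered = any(isinstance(v, str) and "barcode" in v.lower()
                   for v in first.iloc[0].tolist())
    if headered:
        df = pd.read_csv(p)
        df = df.rename(columns={df.columns[0]: "barcode"})
        cols = {c.lower(): c for c in df.columns}
        row_c = cols.get("pxl_row_in_fullres", df.columns[-2])
        col_c = cols.get("pxl_col_in_fullres", df.columns[-1])
        arow = cols.get("array_row", df.columns[2])
        acol = cols.get("array_col", df.columns[3])
        out = df[["barcode", arow, acol, row_c, col_c]].copy()
    else:
        df = pd.read_csv(p, header=None)
        if df.shape[1] < 6:
            raise ValidationError(
                f"positions file {p} has {df.shape[1]} columns, expected >= 6")
        out = df[[0, 2, 3, 4, 5]].copy()
    out.columns = ["barcode", "array_row", "array_col", "pxl_row", "pxl_col"]
    return out


def read_tenx_matrix_dir(path) -> STDataset:
    """Read an MTX + barcodes + features directory (optionally gzipped).

    The on-disk matrix may be genes x spots (the 10x convention) or
    spots x genes; orientation is detected from the barcode/feature counts
    and the result is always spots x genes in barcode order. A
    tissue_positions CSV, labels CSV, and tile PNGs are picked up when
    present.
    """
    path = Path(path)
    mtx_p = _find_file(path, ["matrix.mtx"])
    bc_p = _find_file(path, ["barcodes.tsv"])
    ft_p = _find_file(path, ["features.tsv", "genes.tsv"])

    barcodes = [ln.split("\t")[0] for ln in _read_lines(bc_p)]
    features = [ln.split("\t")[0] for ln in _read_lines(ft_p)]

    mat = spio.mmread(str(mtx_p))
    if sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=np.float64)

    n_bc, n_ft = len(barcodes), len(features)
    if mat.shape == (n_ft, n_bc) and n_ft != n_bc:
        mat = mat.T
    elif mat.shape == (n_bc, n_ft):
        pass
    elif mat.shape == (n_ft, n_bc):  # square case: assume 10x orientation
        mat = mat.T
    else:
        raise ValidationError(
            f"matrix shape {mat.shape} matches neither ({n_bc},{n_ft}) "
            f"nor ({n_ft},{n_bc})")

    coords = None
    pixel_coords = None
    for stem in ["tissue_positions.csv", "tissue_positions_list.csv"]:
        p = path / stem
        if p.exists():
            pos = _read_positions(p)
            pos = pos.set_index("barcode")
            missing = [b for b in barcodes if b not in pos.index]
            if missing:
                raise ValidationError(
                    f"{len(missing)} barcodes missing from positions file, "
                    f"e.g. {missing[:5]}")
            pos = pos.loc[barcodes]
            coords = pos[["array_col", "array_row"]].to_numpy(dtype=np.float64)
            pixel_coords = pos[["pxl_col", "pxl_row"]].to_numpy(dtype=np.float64)
            break
    if coords is None and (path / "coords.csv").exists():
        pos = pd.read_csv(path / "coords.csv")
        pos = pos.set_index(pos.columns[0])
        missing = [b for b in barcodes if b not in pos.index]
        if missing:
            raise ValidationError(
                f"{len(missing)} barcodes missing from coords.csv, "
                f"e.g. {missing[:5]}")
        coords = pos.loc[barcodes].iloc[:, :2].to_numpy(dtype=np.float64)
    if coords is None:
        # caller must attach coordinates separately
        coords = np.zeros((n_bc, 2))
        logger.warning("no positions file in %s; coords set to zeros", path)

    truth = None
    lab_p = path / "labels.csv"
    if lab_p.exists():
        lab = pd.read_csv(lab_p).set_index("spot_id")
        truth = lab.loc[barcodes, "label"].to_numpy()

    return STDataset(expression=mat, gene_ids=features, spot_ids=barcodes,
                     coords=coords, pixel_coords=pixel_coords,
                     truth_labels=truth)


def read_anndata(path, labels_key: str | None = None) -> STDataset:
    """Optional path: load an h5ad container via :mod:`anndata` if the
    ecosystem provides it. Spatial coordinates are taken from
    ``obsm['spatial']`` (or obs columns x/y)."""
    try:
        import anndata
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading h5ad requires the anndata package") from exc
    ad = anndata.read_h5ad(path)
    x = ad.X.toarray() if sparse.issparse(ad.X) else np.asarray(ad.X)
    if "spatial" in ad.obsm:
        coords = np.asarray(ad.obsm["spatial"], dtype=np.float64)[:, :2]
    elif {"x", "y"} <= set(ad.obs.columns):
        coords = ad.obs[["x", "y"]].to_numpy(dtype=np.float64)
    else:
        raise ValidationError("h5ad has neither obsm['spatial'] nor "
                              "obs columns x/y")
    truth = None
    if labels_key is not None:
        truth = ad.obs[labels_key].to_numpy()
    return STDataset(expression=x, gene_ids=list(map(str, ad.var_names)),
                     spot_ids=list(map(str, ad.obs_names)), coords=coords,
                     truth_labels=truth)


# ---------------------------------------------------------------------------
# Plain tables
# ---------------------------------------------------------------------------

def _read_table(p) -> pd.DataFrame:
    p = Path(p)
    sep = "\t" if p.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(p, sep=sep)


def read_table_dataset(expr_path, coords_path, labels_path=None) -> STDataset:
    """Read expression/coords (and optional labels) CSV or TSV tables.

    Expression: first column spot id, remaining columns genes. Coordinate
    table: spot id, x, y. Spots are aligned on the id intersection in
    expression-file order; unmatched spots are dropped with a logged count.
    """
    expr = _read_table(expr_path)
    expr = expr.set_index(expr.columns[0])
    try:
        expr = expr.astype(np.float64)
    except (TypeError, ValueError) as exc:
        # locate the first offending cell for the error message
        for col in expr.columns:
            coerced = pd.to_numeric(expr[col], errors="coerce")
            bad = coerced.isna() & expr[col].notna()
            if bad.any():
                row = expr.index[bad.to_numpy().argmax()]
                raise ValidationError(
                    f"non-numeric expression value at row {row!r}, "
                    f"column {col!r}") from exc
        raise

    coords = _read_table(coords_path)
    coords = coords.set_index(coords.columns[0])

    keep = [sid for sid in expr.index if sid in coords.index]
    if not keep:
        raise ValidationError("no overlapping spot ids between expression "
                              "and coordinates tables")
    dropped = expr.shape[0] - len(keep)
    if dropped:
        logger.warning("dropped %d spots absent from coordinates table", dropped)

    expr = expr.loc[keep]
    cxy = coords.loc[keep].iloc[:, :2].to_numpy(dtype=np.float64)

    truth = None
    if labels_path is not None:
        lab = _read_table(labels_path)
        lab = lab.set_index(lab.columns[0])
        truth = lab.loc[keep].iloc[:, 0].to_numpy()

    return STDataset(expression=expr.to_numpy(), gene_ids=list(expr.columns),
                     spot_ids=[str(s) for s in keep], coords=cxy,
                     truth_labels=truth)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

def write_results(dataset: STDataset, result, out_dir) -> None:
    """Write per-view labels, consensus labels/matrix, embeddings and the
    denoised expression to ``out_dir``. Overwrites are idempotent."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = dataset.n_spots
    if len(result.final_labels) != n:
        raise ValidationError(
            f"result has {len(result.final_labels)} labels for {n} spots")

    lab = pd.DataFrame({"spot_id": dataset.spot_ids,
                        "consensus": result.final_labels})
    for i, y in enumerate(result.view_labels):
        if len(y) != n:
            raise ValidationError(f"view {i} labels length {len(y)} != {n}")
        lab[f"view_{i}"] = y
    lab.to_csv(out_dir / "labels.csv", index=False)

    np.savez_compressed(out_dir / "consensus_matrix.npz",
                        C=result.consensus_matrix)
    if getattr(result, "embeddings", None):
        np.savez_compressed(
            out_dir / "embeddings.npz",
            **{f"view_{i}": emb.z for i, emb in enumerate(result.embeddings)})
        np.savez_compressed(
            out_dir / "denoised.npz",
            **{f"view_{i}": emb.x_recon
               for i, emb in enumerate(result.embeddings)})
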