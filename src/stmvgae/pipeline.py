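"""End-to-end orchestration: preprocess -> (optional) augment -> build views
-> train one auto-encoder per view -> cluster per view -> consensus ->
metrics, with every ablation axis exposed as a config flag.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .consensus import ConsensusResult, run_consensus
from .data import STDataset, ValidationError, write_results
from .graphs import build_views, default_view_specs, normalize_adjacency
from .histology import AugmentConfig, ConfigurationError, augment_dataset
from .metrics import MetricReport, evaluate
from .model import ModelConfig, train_view
from .preprocess import PreprocessConfig, preprocess

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "run_view_sweep"]


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    augment_enabled: bool = False
    views: list[dict] = field(default_factory=default_view_specs)
    model: ModelConfig = field(default_factory=ModelConfig)
    n_clusters: int = 4
    seed: int = 0
    output_dir: str | None = None
    consensus_restarts: int = 10
    no_dec: bool = False          # drop the self-supervised term (lambda4=0)
    no_image: bool = False        # drop histology augmentation
    no_consensus: bool = False    # use best single view's labels

    def __post_init__(self):
        if not self.views:
            raise ValidationError("need at least one view")
        if self.n_clusters < 2:
            raise ValidationError("n_clusters must be >= 2")


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-12s done in %.2fs", name, t1 - t0)
    return t1


def run_pipeline(ds: STDataset, cfg: PipelineConfig
                 ) -> tuple[ConsensusResult, MetricReport | None]:
    """Run the full pipeline on a dataset. Deterministic given cfg.seed."""
    t0 = time.perf_counter()
    logger.info("pipeline start: %d spots, %d genes, seed=%d",
                ds.n_spots, ds.n_genes, cfg.seed)

    pp = preprocess(ds, cfg.preprocess)
    t0 = _stage("preprocess", t0)

    if cfg.augment_enabled and not cfg.no_image:
        if ds.tiles is None and (ds.image is None or ds.pixel_coords is None):
            raise ConfigurationError(
                "stage 'augment': augmentation enabled but the dataset has "
                "no image tiles; pass no_image=True or provide an image")
        aug = replace(cfg.augment, seed=cfg.seed)
        x, _ = augment_dataset(pp, aug)
        t0 = _stage("augment", t0)
    else:
        x = pp.expression

    graphs = build_views(pp.coords, x, cfg.views)
    t0 = _stage("views", t0)

    mcfg = replace(cfg.model, seed=cfg.seed,
                   lambda4=0.0 if cfg.no_dec else cfg.model.lambda4)
    embeddings = []
    for g in graphs:
        ng = normalize_adjacency(g)
        emb = train_view(x, ng, cfg.n_clusters, mcfg)
        logger.info("view %-12s final loss %.4f", g.view_id,
                    emb.history[-1]["total"] if emb.history else float("nan"))
        embeddings.append(emb)
    t0 = _stage("train", t0)

    result = run_consensus(embeddings, cfg.n_clusters, seed=cfg.seed,
                           restarts=cfg.consensus_restarts,
                           no_consensus=cfg.no_consensus)
    t0 = _stage("consensus", t0)

    report = None
    if ds.truth_labels is not None:
        report = evaluate(ds.truth_labels, result.final_labels)
        logger.info("metrics: ARI=%.3f NMI=%.3f HS=%.3f Purity=%.3f",
                    report.ari, report.nmi, report.hs, report.purity)

    if cfg.output_dir is not None:
        write_results(ds, result, cfg.output_dir)
        _stage("write", t0)
    return result, report


def _preprocess_cached(ds: STDataset, cfg: PipelineConfig,
                       cache: dict) -> STDataset:
    key = hashlib.sha256(
        repr((cfg.preprocess, ds.n_spots, ds.n_genes)).encode()).hexdigest()
    if key not in cache:
        cache[key] = preprocess(ds, cfg.preprocess)
    return cache[key]


def run_view_sweep(ds: STDataset, cfg: PipelineConfig,
                   view_subsets: list[list[str]]) -> pd.DataFrame:
    """One pipeline run per view subset, sharing the preprocessing cache.

    Requires ground-truth labels; returns one metric row per subset. Each
    row's seed is offset deterministically by its position.
    """
    if ds.truth_labels is None:
        raise ValidationError("view sweep requires truth labels")
    cache: dict = {}
    rows = []
    for i, subset in enumerate(view_subsets):
        sub_cfg = replace(cfg,
                          views=[{"view_id": v} for v in subset],
                          seed=cfg.seed + i,
                          output_dir=None)
        pp = _preprocess_cached(ds, sub_cfg, cache)
        # run stages on the cached preprocessing result
        x = pp.expression
        graphs = build_views(pp.coords, x, sub_cfg.views)
        mcfg = replace(sub_cfg.model, seed=sub_cfg.seed,
                       lambda4=0.0 if sub_cfg.no_dec
                       else sub_cfg.model.lambda4)
        embeddings = [train_view(x, normalize_adjacency(g),
                                 sub_cfg.n_clusters, mcfg) for g in graphs]
        result = run_consensus(embeddings, sub_cfg.n_clusters,
                               seed=sub_cfg.seed,
                               restarts=sub_cfg.consensus_restarts,
                               no_consensus=sub_cfg.no_consensus)
        rep = evaluate(ds.truth_labels, result.final_labels)
        rows.append({"subset": "+".join(subset), "seed": sub_cfg.seed,
                     **rep.as_dict()})
    return pd.DataFrame(rows)
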