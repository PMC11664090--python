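# stmvgae

Spatial-domain identification for spot-level spatial transcriptomics by
multi-view variational graph auto-encoders with consensus clustering.

The pipeline:

1. **Preprocess** — gene filtering, library-size normalization, log1p,
   dispersion-ranked highly-variable-gene selection.
2. **Augment (optional)** — per-spot histology tile features (pluggable
   extractor; a deterministic built-in needs no downloads) are expanded to
   the expression dimension by a small autoencoder and mixed into the
   expression matrix as `alpha1*MS + alpha2*GE`.
3. **Views** — several binary spot-adjacency graphs: radius and k-nearest
   neighbor searches over spatial coordinates (BallTree/KDTree backends),
   plus Spearman- and cosine-similarity graphs over expression.
4. **Model** — one variational graph auto-encoder per view (linear stack →
   shared graph-conv layer → mean/log-variance heads; inner-product
   adjacency decoder and mirror feature decoder), trained in two phases
   with an optional Student-t self-supervised clustering head. The neural
   network runs on a small built-in numpy autodiff engine — no GPU or deep
   learning framework required; training is bit-deterministic per seed.
5. **Consensus** — each view's embedding is clustered by a full-covariance
   Gaussian mixture; the consensus matrix (fraction of views co-clustering
   each spot pair) is cut by average-linkage hierarchical clustering.
6. **Evaluation** — ARI, NMI, homogeneity and purity against ground truth.

A synthetic-data module generates Visium-like hexagonal lattices with
contiguous layered domains, negative-binomial expression with dropout, and
pseudo-histology tiles, so the entire pipeline is testable offline.

## CLI

```bash
# write a synthetic 600-spot, 4-domain fixture (10x-style matrix dir)
stmvgae simulate --out data/sim --k 4 --spots 600 --seed 0

# run the pipeline (config optional; flags mirror the ablation axes)
stmvgae run --config cfg.toml --data data/sim --out results/run \
    --views radius_ball,knn_ball,cosine --k-clusters 4 --seed 0
stmvgae run --data data/sim --no-dec --no-consensus   # ablation modes

# metric table over view subsets
stmvgae sweep --config cfg.toml --subsets subsets.json --out sweep.csv
```

Known view ids: `radius_ball`, `radius_kd`, `knn_ball`, `knn_kd`,
`spearman`, `cosine`. Config is TOML (see `tests/test_pipeline_cli.py` for
a complete example); sections `[preprocess]`, `[augment]`, `[views]`,
`[model]`, `[consensus]`, plus top-level `n_clusters`, `seed`,
`output_dir`.

## Layout

- `src/stmvgae/data.py` — dataset container, MTX/table readers, writers
- `src/stmvgae/simulate.py` — synthetic layered tissues
- `src/stmvgae/preprocess.py` — filtering/normalization/HVG
- `src/stmvgae/histology.py` — tile features and expression augmentation
- `src/stmvgae/graphs.py` — adjacency views and normalization
- `src/stmvgae/model.py` — the per-view auto-encoder and trainer
- `src/stmvgae/_nn.py` — minimal autodiff engine backing the models
- `src/stmvgae/consensus.py` — mixture clustering + consensus integration
- `src/stmvgae/metrics.py` — clustering agreement metrics
- `src/stmvgae/pipeline.py`, `cli.py` — orchestration and CLI
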