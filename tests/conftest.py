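import numpy as np
import pytest

from stmvgae.graphs import build_views, default_view_specs, normalize_adjacency
from stmvgae.preprocess import PreprocessConfig, preprocess
from stmvgae.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """A tiny 10x12 lattice dataset for cheap unit tests."""
    cfg = SimConfig(n_rows=10, n_cols=12, n_genes=60, k_domains=3,
                    markers_per_domain=8, seed=7)
    ds, markers = simulate_dataset(cfg)
    return ds, markers, cfg


@pytest.fixture(scope="session")
def benchmark_sim():
    """The 600-spot / 150-gene / K=4 benchmark the acceptance criteria use."""
    cfg = SimConfig(n_rows=20, n_cols=30, n_genes=150, k_domains=4,
                    markers_per_domain=10, log_fold_change=2.5,
                    dropout_rate=0.3, seed=0)
    ds, markers = simulate_dataset(cfg)
    return ds, markers, cfg


@pytest.fixture(scope="session")
def benchmark_prep(benchmark_sim):
    ds, _, _ = benchmark_sim
    pp = preprocess(ds, PreprocessConfig(min_cells=10, n_hvg=100))
    return ds, pp


@pytest.fixture(scope="session")
def benchmark_graphs(benchmark_prep):
    _, pp = benchmark_prep
    return [normalize_adjacency(g)
            for g in build_views(pp.coords, pp.expression,
                                 default_view_specs())]


def fast_model_config(**overrides):
    """Model hyperparameters scaled to the synthetic benchmark."""
    from stmvgae.model import ModelConfig
    defaults = dict(fc_dims=(64, 32), gcn_hidden=32, latent_dim=8,
                    pretrain_epochs=150, train_epochs=150, dec_interval=20,
                    seed=0)
    defaults.update(overrides)
    return ModelConfig(**defaults)


@pytest.fixture(scope="session")
def trained_benchmark(benchmark_prep, benchmark_graphs):
    """One full multi-view training at seed 0, shared across tests."""
    from stmvgae.consensus import run_consensus
    from stmvgae.model import train_view

    ds, pp = benchmark_prep
    cfg = fast_model_config()
    embeddings = [train_view(pp.expression, g, 4, cfg)
                  for g in benchmark_graphs]
    result = run_consensus(embeddings, 4, seed=0)
    return ds, embeddings, result
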