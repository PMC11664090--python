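import numpy as np
import pytest

from stmvgae._nn import Tensor
from stmvgae.data import ValidationError
from stmvgae.graphs import ViewGraph, build_knn_graph, normalize_adjacency
from stmvgae.model import (DECState, ModelConfig, MVGAE, dec_loss,
                           dec_soft_assign, dec_target_distribution,
                           decode_adjacency, init_centers, reparameterize,
                           train_view)

from .conftest import fast_model_config


def _tiny_graph(n=12, seed=0):
    coords = np.random.default_rng(seed).random((n, 2))
    return normalize_adjacency(build_knn_graph(coords, 3))


def _tiny_model(n_features=10, seed=0, **kw):
    cfg = fast_model_config(fc_dims=(8, 6), gcn_hidden=5, latent_dim=3, **kw)
    return MVGAE(n_features, cfg, np.random.default_rng(seed)), cfg


class TestEncode:
    def test_zero_input_zero_weights(self):
        model, _ = _tiny_model()
        for p in model.parameters():
            p.data[...] = 0.0
        g = _tiny_graph()
        mu, logvar = model.encode(Tensor(np.zeros((12, 10))), g)
        np.testing.assert_array_equal(mu.data, 0.0)
        np.testing.assert_array_equal(logvar.data, 0.0)

    def test_output_shapes(self):
        model, cfg = _tiny_model()
        mu, logvar = model.encode(Tensor(np.random.default_rng(1)
                                         .random((12, 10))), _tiny_graph())
        assert mu.shape == (12, cfg.latent_dim)
        assert logvar.shape == (12, cfg.latent_dim)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        n = 15
        x = rng.random((n, 10))
        coords = rng.random((n, 2))
        g = normalize_adjacency(build_knn_graph(coords, 3))
        model, _ = _tiny_model()
        mu, _ = model.encode(Tensor(x), g)

        perm = rng.permutation(n)
        gp = normalize_adjacency(ViewGraph(
            g.a_hat[np.ix_(perm, perm)] - np.eye(n), "knn", "none", 3, "p"))
        mu_p, _ = model.encode(Tensor(x[perm]), gp)
        np.testing.assert_allclose(mu_p.data, mu.data[perm], atol=1e-10)

    def test_dimension_mismatch(self):
        model, _ = _tiny_model()
        with pytest.raises(ValidationError):
            model.encode(Tensor(np.zeros((5, 10))), _tiny_graph(12))


class TestReparameterize:
    def test_zero_noise_returns_mu(self):
        mu = np.random.default_rng(0).random((4, 3))
        z = reparameterize(mu, np.zeros_like(mu), np.zeros_like(mu))
        np.testing.assert_array_equal(z, mu)

    def test_unit_variance(self):
        mu = np.zeros((4, 3))
        eps = np.random.default_rng(1).standard_normal((4, 3))
        z = reparameterize(mu, np.zeros_like(mu), eps)
        np.testing.assert_allclose(z, eps)

    def test_monte_carlo_std(self):
        # logvar = ln 4 -> std of z - mu is 2
        rng = np.random.default_rng(2)
        n = 100_000
        noise = rng.standard_normal((n, 1))
        z = reparameterize(np.zeros((n, 1)), np.full((n, 1), np.log(4.0)),
                           noise)
        assert z.std() == pytest.approx(2.0, abs=0.02)


class TestDecodeAdjacency:
    def test_zero_latent_gives_half(self):
        np.testing.assert_allclose(decode_adjacency(np.zeros((3, 2))), 0.5)

    def test_symmetric(self):
        z = np.random.default_rng(3).random((6, 4))
        a = decode_adjacency(z)
        np.testing.assert_allclose(a, a.T, atol=1e-12)

    def test_scalar_closed_form(self):
        a = decode_adjacency(np.array([[2.0], [-2.0]]))
        assert a[0, 1] == pytest.approx(1 / (1 + np.exp(4.0)), abs=1e-10)
        assert a[0, 1] == pytest.approx(0.01799, abs=1e-5)


class TestDecodeFeatures:
    def test_shape_contract(self):
        model, cfg = _tiny_model()
        out = model.decode_features(Tensor(np.zeros((12, cfg.latent_dim))))
        assert out.shape == (12, 10)

    def test_zero_weights_zero_output(self):
        model, cfg = _tiny_model()
        for p in model.parameters():
            p.data[...] = 0.0
        out = model.decode_features(
            Tensor(np.random.default_rng(4).random((12, cfg.latent_dim))))
        np.testing.assert_array_equal(out.data, 0.0)


class TestLossTerms:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        model, cfg = _tiny_model()
        g = _tiny_graph()
        x = Tensor(rng.random((12, 10)))
        mu, logvar = model.encode(x, g)
        z = mu
        x_recon = model.decode_features(z)
        return model, g, x, mu, logvar, z, x_recon

    def test_prior_match_kl_zero(self):
        model, g, x, mu, logvar, z, x_recon = self._setup()
        zero = Tensor(np.zeros(mu.shape))
        _, _, l_kl = model.loss_terms(x, g, zero, zero, z, x_recon)
        # subtract BCE part: recompute with mu=logvar=0 on 0 edges
        kl_only = ((zero.exp() + zero ** 2.0 - zero - 1.0) * 0.5).mean()
        assert float(kl_only.data) == 0.0

    def test_perfect_reconstruction(self):
        model, g, x, mu, logvar, z, _ = self._setup()
        _, l_x, _ = model.loss_terms(x, g, mu, logvar, z, x)
        assert float(l_x.data) == 0.0

    def test_three_node_hand_case(self):
        # A = single edge 0-1; fixed 1-D z; recompute L_A and BCE by hand
        a = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]], dtype=float)
        g = normalize_adjacency(ViewGraph(a, "knn", "none", 1, "toy"))
        model, cfg = _tiny_model(n_features=2)
        zv = np.array([[1.0, 0.0], [0.5, 0.0], [-1.0, 0.0]])
        z = Tensor(zv)
        x = Tensor(np.zeros((3, 2)))
        mu = Tensor(np.zeros((3, 2)))
        logvar = Tensor(np.zeros((3, 2)))
        l_a, _, l_kl = model.loss_terms(x, g, mu, logvar, z, x)

        logits = zv @ zv.T
        sig = 1 / (1 + np.exp(-logits))
        pos_w = 4.0 / 2.0  # 4 non-edges, 2 edge entries (symmetric count)
        w = (1 - np.eye(3)) * (1 + (pos_w - 1) * a)
        l_a_hand = (w * (a - sig) ** 2).sum() / w.sum()
        assert float(l_a.data) == pytest.approx(l_a_hand, abs=1e-12)

        sp = np.log1p(np.exp(logits))
        bce_hand = ((w * sp).sum() - pos_w * (a * logits).sum()) / w.sum()
        # mu = logvar = 0 -> KL part 0, so L_KL == BCE
        assert float(l_kl.data) == pytest.approx(bce_hand, abs=1e-10)

    def test_kl_component_closed_form(self):
        rng = np.random.default_rng(7)
        mu = Tensor(rng.normal(0, 1, (5, 3)))
        logvar = Tensor(rng.normal(0, 0.5, (5, 3)))
        kl = ((logvar.exp() + mu ** 2.0 - logvar - 1.0) * 0.5).mean()
        hand = np.mean(-0.5 * (1 + logvar.data - mu.data ** 2
                               - np.exp(logvar.data)))
        assert float(kl.data) == pytest.approx(hand, abs=1e-12)
        assert float(kl.data) >= 0.0


class TestDECOps:
    def test_point_at_center_is_row_max(self):
        centers = np.array([[0.0, 0.0], [5.0, 5.0]])
        q = dec_soft_assign(np.array([[0.0, 0.0]]), centers)
        assert q[0, 0] == q[0].max()

    def test_equidistant_uniform(self):
        centers = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0],
                            [0.0, -1.0]])
        q = dec_soft_assign(np.array([[0.0, 0.0]]), centers)
        np.testing.assert_allclose(q[0], 0.25)

    def test_one_dim_hand_case(self):
        # z=0, centers {-1, 1, 3}: kernels (0.5, 0.5, 0.1)
        q = dec_soft_assign(np.array([[0.0]]),
                            np.array([[-1.0], [1.0], [3.0]]))
        np.testing.assert_allclose(q[0], [5 / 11, 5 / 11, 1 / 11],
                                   atol=1e-12)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(8)
        q = dec_soft_assign(rng.normal(0, 1, (20, 4)),
                            rng.normal(0, 1, (5, 4)))
        np.testing.assert_allclose(q.sum(axis=1), 1.0, atol=1e-9)

    def test_target_idempotent_on_onehot(self):
        q = np.eye(3)[[0, 1, 2, 0]]
        np.testing.assert_allclose(dec_target_distribution(q.astype(float)),
                                   q, atol=1e-12)

    def test_target_uniform_stays_uniform(self):
        q = np.full((6, 3), 1 / 3.0)
        np.testing.assert_allclose(dec_target_distribution(q), 1 / 3.0,
                                   atol=1e-12)

    def test_target_hand_case(self):
        q = np.array([[0.8, 0.2], [0.4, 0.6]])
        p = dec_target_distribution(q)
        f = np.array([1.2, 0.8])
        un = q ** 2 / f
        expected = un / un.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(p, expected, atol=1e-12)
        np.testing.assert_allclose(p[0], [0.9143, 0.0857], atol=1e-4)

    def test_dec_loss_zero_when_equal(self):
        q = np.array([[0.3, 0.7], [0.5, 0.5]])
        assert dec_loss(q, q) == pytest.approx(0.0, abs=1e-12)

    def test_dec_loss_onehot_vs_uniform(self):
        n, j = 5, 4
        p = np.eye(j)[np.zeros(n, dtype=int)].astype(float)
        q = np.full((n, j), 1 / j)
        assert dec_loss(p, q) == pytest.approx(n * np.log(j), abs=1e-9)

    def test_dec_loss_nonnegative_random(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            p = rng.dirichlet(np.ones(4), size=10)
            q = rng.dirichlet(np.ones(4), size=10)
            assert dec_loss(p, q) >= 0.0

    def test_sharpening_reduces_mean_entropy(self):
        # mean row entropy of p <= that of q for soft assignments that
        # came from a Student-t kernel (the regime DEC runs in)
        rng = np.random.default_rng(10)
        z = rng.normal(0, 2, (50, 3))
        centers = rng.normal(0, 2, (4, 3))
        q = dec_soft_assign(z, centers)
        p = dec_target_distribution(q)

        def mean_entropy(d):
            return float(-(d * np.log(np.maximum(d, 1e-300))).sum(1).mean())

        assert mean_entropy(p) <= mean_entropy(q) + 1e-12


class TestInitCenters:
    def test_separated_blobs(self):
        rng = np.random.default_rng(11)
        z = np.vstack([rng.normal(0, 0.1, (30, 2)),
                       rng.normal(5, 0.1, (30, 2))])
        state = init_centers(z, 2, seed=0)
        got = sorted(state.centers[:, 0].tolist())
        assert got[0] == pytest.approx(0.0, abs=0.1)
        assert got[1] == pytest.approx(5.0, abs=0.1)
        assert state.n_clusters == 2

    def test_duplicated_points_exact(self):
        z = np.repeat(np.array([[0.0, 0.0], [4.0, 4.0]]), 10, axis=0)
        z += np.random.default_rng(12).normal(0, 1e-6, z.shape)
        state = init_centers(z, 2, seed=0)
        got = sorted(state.centers[:, 0].tolist())
        np.testing.assert_allclose(got, [0.0, 4.0], atol=1e-3)


class TestTrainView:
    @pytest.fixture(scope="class")
    def tiny_training(self):
        rng = np.random.default_rng(13)
        n = 40
        coords = rng.random((n, 2)) * 4
        x = rng.random((n, 12))
        g = normalize_adjacency(build_knn_graph(coords, 4))
        cfg = fast_model_config(fc_dims=(8, 6), gcn_hidden=6, latent_dim=3,
                                pretrain_epochs=30, train_epochs=30,
                                dec_interval=10, gmm_restarts=2)
        emb = train_view(x, g, 3, cfg)
        return x, g, cfg, emb

    def test_determinism(self, tiny_training):
        x, g, cfg, emb = tiny_training
        emb2 = train_view(x, g, 3, cfg)
        np.testing.assert_allclose(emb2.z, emb.z, atol=1e-6)

    def test_history_additivity(self, tiny_training):
        # total equals the lambda-weighted sum of the logged terms
        x, g, cfg, emb = tiny_training
        for rec in emb.history:
            expected = (cfg.lambda1 * rec["L_A"] + cfg.lambda2 * rec["L_X"]
                        + cfg.lambda3 * rec["L_KL"]
                        + cfg.lambda4 * rec["L_DEC"])
            assert rec["total"] == pytest.approx(expected, abs=1e-6)

    def test_dec_terms_nonnegative(self, tiny_training):
        _, _, _, emb = tiny_training
        assert all(rec["L_DEC"] >= 0.0 for rec in emb.history)

    def test_no_dec_mode_skips_phase2_head(self):
        rng = np.random.default_rng(14)
        n = 30
        x = rng.random((n, 10))
        g = normalize_adjacency(build_knn_graph(rng.random((n, 2)), 3))
        cfg = fast_model_config(fc_dims=(8,), gcn_hidden=6, latent_dim=3,
                                pretrain_epochs=10, train_epochs=10,
                                lambda4=0.0)
        emb = train_view(x, g, 3, cfg)
        assert all(rec["L_DEC"] == 0.0 for rec in emb.history)
        assert emb.dec_refreshes == []

    def test_better_than_null_reconstruction(self, benchmark_prep,
                                             benchmark_graphs):
        _, pp = benchmark_prep
        x = pp.expression
        cfg = fast_model_config(pretrain_epochs=60, train_epochs=0,
                                lambda4=0.0)
        emb = train_view(x, benchmark_graphs[0], 4, cfg)
        assert np.sum((x - emb.x_recon) ** 2) < np.sum(x ** 2)

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            ModelConfig(latent_dim=1)
        with pytest.raises(ValidationError):
            ModelConfig(lambda1=0, lambda2=0, lambda3=0, lambda4=0)
        with pytest.raises(NotImplementedError):
            ModelConfig(conv_type="gat")
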