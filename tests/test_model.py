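"""The fusion network: channels, delivery, attention, decoder, forward pass."""

import numpy as np
import pytest

from ddifuse import (
    DDIEventTable,
    ModelConfig,
    attention_fuse,
    build_adjacency,
    delivery,
    forward,
    init_params,
    load_checkpoint,
    reconstruction_loss,
    save_checkpoint,
)
from ddifuse.model import FusionParams, ae_layer, gcn_layer


def identity_params(d, layers=1):
    return FusionParams(
        ae_W=[np.eye(d) for _ in range(layers)],
        ae_b=[np.zeros(d) for _ in range(layers)],
        gcn_W=[np.eye(d) for _ in range(layers)],
        att_w=np.eye(d),
        att_b=np.zeros(d),
        att_q=np.ones(d),
    )


def adjacency_from_edges(edges, n):
    table = DDIEventTable(
        pairs=np.array([[i, j, 1] for i, j in edges]).reshape(-1, 3), n_classes=1
    ) if edges else DDIEventTable(pairs=np.empty((0, 3), dtype=int), n_classes=1)
    return build_adjacency(table, n)


class TestAeLayer:
    def test_identity_weights_pass_nonnegative_input(self):
        p = identity_params(3)
        X = np.array([[1.0, 0.5, 0.0], [2.0, 0.0, 3.0]])
        assert np.array_equal(ae_layer(X, 0, p), X)

    def test_relu_clamps_negatives(self):
        p = identity_params(2)
        assert np.array_equal(ae_layer(-np.ones((4, 2)), 0, p), np.zeros((4, 2)))

    def test_matches_dense_oracle(self, rng):
        W = rng.normal(size=(4, 3))
        b = rng.normal(size=3)
        p = FusionParams(ae_W=[W], ae_b=[b], gcn_W=[np.eye(4)],
                         att_w=np.eye(3), att_b=np.zeros(3), att_q=np.ones(3))
        X = rng.normal(size=(3, 4))
        expected = np.array([[max(0.0, x_row @ W[:, k] + b[k]) for k in range(3)]
                             for x_row in X])
        assert np.allclose(ae_layer(X, 0, p), expected, atol=1e-12)

    def test_width_mismatch_names_layer(self):
        with pytest.raises(ValueError, match="layer 0"):
            ae_layer(np.ones((2, 5)), 0, identity_params(3))


class TestDelivery:
    def test_endpoints_exact(self, rng):
        Z, H = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        assert np.array_equal(delivery(Z, H, 0.0), Z)
        assert np.array_equal(delivery(Z, H, 1.0), H)

    def test_midpoint(self):
        assert np.array_equal(
            delivery(2 * np.ones((2, 2)), np.zeros((2, 2)), 0.5), np.ones((2, 2))
        )

    def test_linearity(self, rng):
        Z, H = rng.normal(size=(5, 4)), rng.normal(size=(5, 4))
        # exact for binary-fraction coefficients, where scaling commutes with
        # rounding; to float precision otherwise
        for a in (0.0, 0.5, 1.0):
            assert np.array_equal(delivery(Z, H, a) + delivery(H, Z, a), Z + H)
        for a in (0.25, 0.3, 0.9):
            assert np.allclose(
                delivery(Z, H, a) + delivery(H, Z, a), Z + H, atol=1e-12
            )

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shapes"):
            delivery(np.ones((2, 2)), np.ones((3, 2)), 0.5)


class TestGcnLayer:
    def test_isolated_node_self_loop_identity(self):
        A = adjacency_from_edges([], 1)
        p = identity_params(2)
        X = np.array([[3.0, 1.0]])
        assert np.allclose(gcn_layer(X, A, 0, p), X)

    def test_two_node_single_edge(self):
        A = adjacency_from_edges([(0, 1)], 2)
        p = identity_params(2)
        out = gcn_layer(np.array([[2.0, 0.0], [0.0, 2.0]]), A, 0, p)
        assert np.allclose(out, np.ones((2, 2)))

    def test_zero_weights_zero_output(self, rng):
        A = adjacency_from_edges([(0, 1)], 2)
        p = identity_params(2)
        p.gcn_W[0] = np.zeros((2, 2))
        assert np.array_equal(
            gcn_layer(rng.random((2, 2)), A, 0, p), np.zeros((2, 2))
        )


class TestAttention:
    def test_equal_channels_force_half(self, rng):
        config = ModelConfig(layer_dims=(4,), seed=0)
        p = init_params(4, config)
        Z = rng.normal(size=(6, 4))
        emb = attention_fuse(Z, Z.copy(), p)
        assert np.allclose(emb.att_z, 0.5)
        assert np.allclose(emb.att_h, 0.5)
        assert np.allclose(emb.E, Z)

    def test_zero_query_gives_half(self, rng):
        p = identity_params(3)
        p.att_q = np.zeros(3)
        emb = attention_fuse(rng.normal(size=(4, 3)), rng.normal(size=(4, 3)), p)
        assert np.allclose(emb.att_z, 0.5)

    def test_scalar_oracle_five_drugs(self, rng):
        d, a, n = 4, 3, 5
        p = FusionParams(
            ae_W=[np.eye(d)], ae_b=[np.zeros(d)], gcn_W=[np.eye(d)],
            att_w=rng.normal(size=(a, d)), att_b=rng.normal(size=a),
            att_q=rng.normal(size=a),
        )
        Z, H = rng.normal(size=(n, d)), rng.normal(size=(n, d))
        emb = attention_fuse(Z, H, p)
        for i in range(n):
            # score per channel: q^T tanh(w x_i + b), scalar arithmetic
            sz = sum(
                p.att_q[k] * np.tanh(sum(p.att_w[k, m] * Z[i, m] for m in range(d))
                                     + p.att_b[k])
                for k in range(a)
            )
            sh = sum(
                p.att_q[k] * np.tanh(sum(p.att_w[k, m] * H[i, m] for m in range(d))
                                     + p.att_b[k])
                for k in range(a)
            )
            az = np.exp(sz) / (np.exp(sz) + np.exp(sh))
            assert emb.att_z[i] == pytest.approx(az, abs=1e-10)
            for m in range(d):
                assert emb.E[i, m] == pytest.approx(
                    az * Z[i, m] + (1 - az) * H[i, m], abs=1e-10
                )

    def test_normalization_contract(self, rng):
        for seed in range(3):
            config = ModelConfig(layer_dims=(6,), seed=seed)
            p = init_params(6, config)
            emb = attention_fuse(rng.normal(size=(10, 6)) * 10,
                                 rng.normal(size=(10, 6)), p)
            assert np.allclose(emb.att_z + emb.att_h, 1.0, atol=1e-6)
            assert ((emb.att_z > 0) & (emb.att_z < 1)).all()

    def test_non_finite_scores_rejected(self):
        p = identity_params(2)
        with pytest.raises(FloatingPointError):
            attention_fuse(np.array([[np.inf, 0.0]]), np.zeros((1, 2)), p)


class TestReconstructionLoss:
    def test_exact_target_zero_loss(self, rng):
        H = rng.normal(size=(4, 3))
        S = 1 / (1 + np.exp(-(H @ H.T)))
        assert reconstruction_loss(H, S) == pytest.approx(0.0, abs=1e-12)

    def test_zero_embedding_against_half(self):
        H = np.zeros((3, 2))
        assert reconstruction_loss(H, np.full((3, 3), 0.5)) == pytest.approx(0.0)

    def test_scalar_oracle(self, rng):
        H = rng.normal(size=(4, 2))
        T = rng.random((4, 4))
        got = reconstruction_loss(H, T)
        acc = 0.0
        for i in range(4):
            for j in range(4):
                s = 1 / (1 + np.exp(-sum(H[i, k] * H[j, k] for k in range(2))))
                acc += (s - T[i, j]) ** 2
        assert got == pytest.approx(acc / 16, abs=1e-12)

    def test_identity_link(self, rng):
        H = rng.normal(size=(3, 2))
        T = rng.random((3, 3))
        assert reconstruction_loss(H, T, link="identity") == pytest.approx(
            np.mean((H @ H.T - T) ** 2)
        )


def reference_gcn(X, A_dense_csr, weights):
    """Independent plain multilayer GCN: ReLU(Â · Z · W) stacked."""
    Z = X
    for W in weights:
        Z = np.maximum((A_dense_csr @ Z) @ W, 0.0)
    return Z


class TestForward:
    def test_attention_sums_to_one(self, rng):
        n, C = 8, 3
        config = ModelConfig(layer_dims=(5, C), seed=0)
        p = init_params(2 * n, config)
        A = adjacency_from_edges([(0, 1), (2, 3), (4, 5)], n)
        emb = forward(rng.random((n, 2 * n)), A, config, p)
        assert np.allclose(emb.att_z + emb.att_h, 1.0, atol=1e-6)

    def test_no_ae_variant_is_plain_gcn(self, rng):
        """α=0 with attention bypassed to Z must equal an independent GCN bit-for-bit."""
        n, C = 10, 4
        config = ModelConfig(layer_dims=(6, C), alpha=0.0, seed=3)
        p = init_params(n, config)
        A = adjacency_from_edges([(0, 1), (1, 2), (3, 4), (5, 9)], n)
        X = rng.random((n, n))
        emb = forward(X, A, config, p, variant="no_ae")
        ref = reference_gcn(X, A.A_hat, p.gcn_W)
        assert np.array_equal(emb.E, ref)

    def test_no_gcn_variant_is_plain_encoder(self, rng):
        n, C = 6, 2
        config = ModelConfig(layer_dims=(4, C), seed=0)
        p = init_params(n, config)
        X = rng.random((n, n))
        emb = forward(X, None, config, p, variant="no_gcn")
        H = X
        for W, b in zip(p.ae_W, p.ae_b):
            H = np.maximum(H @ W + b, 0.0)
        assert np.array_equal(emb.E, H)

    def test_no_att_is_channel_sum(self, rng):
        n, C = 6, 2
        config = ModelConfig(layer_dims=(4, C), seed=1)
        p = init_params(n, config)
        A = adjacency_from_edges([(0, 1), (2, 3)], n)
        X = rng.random((n, n))
        emb = forward(X, A, config, p, variant="no_att")
        assert np.array_equal(emb.E, emb.Z_final + emb.H_final)
        assert emb.att_z is None

    def test_single_drug_single_layer(self):
        """1×d case: one GCN step and one AE step on a [[1]] adjacency."""
        config = ModelConfig(layer_dims=(2,), seed=0)
        A = adjacency_from_edges([], 1)
        X = np.array([[0.5, 0.25]])
        p = identity_params(2)
        emb = forward(X, A, config, p)
        assert np.allclose(emb.H_final, X)
        assert np.allclose(emb.Z_final, X)
        # equal channels: attention is 0.5/0.5 and E equals the channels
        assert np.allclose(emb.att_z, 0.5)
        assert np.allclose(emb.E, X)

    def test_permutation_equivariance(self, rng):
        n, v, C = 9, 2, 3
        config = ModelConfig(layer_dims=(5, C), seed=2)
        X = rng.random((n, v * n))
        A = adjacency_from_edges([(0, 1), (1, 2), (4, 7), (5, 8)], n)
        p = init_params(v * n, config)
        emb = forward(X, A, config, p)

        perm = rng.permutation(n)
        # permute drugs: rows of X and both axes of A; the per-view column
        # blocks of X and the first-layer input weights follow the same map
        col_perm = np.concatenate([perm + k * n for k in range(v)])
        Xp = X[perm][:, col_perm]
        from ddifuse.features import NormalizedAdjacency
        Ap = NormalizedAdjacency(
            A_hat=A.A_hat[perm][:, perm].tocsr()
        )
        import copy
        pp = p.copy()
        pp.ae_W[0] = p.ae_W[0][col_perm]
        pp.gcn_W[0] = p.gcn_W[0][col_perm]
        emb_p = forward(Xp, Ap, config, pp)
        assert np.allclose(emb_p.E, emb.E[perm], atol=1e-8)
        assert np.allclose(emb_p.att_z, emb.att_z[perm], atol=1e-8)

    def test_delivery_counteracts_oversmoothing(self, rng):
        """On a deep stack over a 2-block graph, the delivery mix keeps node
        embeddings more spread out than pure propagation (α = 0)."""
        n = 20
        edges = [(i, j) for i in range(10) for j in range(i + 1, 10)]
        edges += [(i, j) for i in range(10, 20) for j in range(i + 1, 20)]
        edges += [(0, 10), (1, 11)]
        A = adjacency_from_edges(edges, n)
        X = rng.random((n, 12))
        L = 8
        dims = (12,) * L

        spreads = {}
        for alpha in (0.0, 0.5):
            config = ModelConfig(layer_dims=dims, alpha=alpha, seed=0)
            p = init_params(12, config)
            emb = forward(X, A, config, p)
            Z = emb.Z_final
            diff = Z[:, None, :] - Z[None, :, :]
            spreads[alpha] = np.sqrt((diff**2).sum(-1)).mean()
        assert spreads[0.5] > spreads[0.0]


class TestCheckpoint:
    def test_roundtrip_bit_exact(self, tmp_path):
        config = ModelConfig(layer_dims=(7, 3), seed=9, alpha=0.25)
        p = init_params(12, config)
        path = tmp_path / "model.npz"
        save_checkpoint(path, p, config, extra={"note": "test"})
        p2, config2, extra = load_checkpoint(path)
        assert config2 == config
        assert extra == {"note": "test"}
        for a, b in zip(p.arrays(), p2.arrays()):
            assert np.array_equal(a, b)


class TestModelConfig:
    def test_validation(self):
        with pytest.raises(ValueError, match="alpha"):
            ModelConfig(layer_dims=(4,), alpha=1.5)
        with pytest.raises(ValueError, match="nonempty"):
            ModelConfig(layer_dims=())
        with pytest.raises(ValueError, match="recon_link"):
            ModelConfig(layer_dims=(4,), recon_link="probit")

    def test_five_layer_stack_supported(self):
        config = ModelConfig(layer_dims=(512, 1024, 2000, 256, 65))
        assert config.n_classes == 65
        p = init_params(1716, config)
        assert [w.shape for w in p.ae_W] == [
            (1716, 512), (512, 1024), (1024, 2000), (2000, 256), (256, 65)
        ]
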