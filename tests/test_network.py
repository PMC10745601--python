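"""Architecture contracts: shapes, determinism, invariances, attention."""

import dataclasses

import numpy as np
import pytest

from heterodta.autodiff import Tensor
from heterodta.featurize import ComplexSample
from heterodta.graphs import Graph
from heterodta.network import (
    AffinityModel,
    ModelConfig,
    bidirectional_attention,
    load_checkpoint,
    save_checkpoint,
)


def permute_graph(graph: Graph, perm: np.ndarray) -> Graph:
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    return Graph(
        n_vertices=graph.n_vertices,
        edges={(int(inv[i]), int(inv[j])) for i, j in graph.edges},
        vertex_features=graph.vertex_features[perm],
        vertex_labels=(
            [graph.vertex_labels[i] for i in perm] if graph.vertex_labels else None
        ),
    )


def permute_drug(sample: ComplexSample, perm: np.ndarray) -> ComplexSample:
    return dataclasses.replace(sample, drug_graph=permute_graph(sample.drug_graph, perm))


class TestSequenceEncoders:
    @pytest.mark.parametrize("kind", ["cnn", "lstm", "bilstm", "cnn_lstm"])
    def test_output_shape(self, kind, rng):
        model = AffinityModel(ModelConfig(seq_encoder=kind), seed=0)
        out = model.encode_sequence(rng.random((10, 20)), "target")
        assert out.shape == (10, 128)

    def test_cnn_zero_input_zero_bias_is_zero(self):
        model = AffinityModel(ModelConfig(), seed=0)
        out = model.target_encoder.conv([np.zeros((6, 20))])
        assert np.allclose(out.data, 0.0)

    def test_cnn_padding_equivalence(self, rng):
        # positions away from the tail are identical whether the sequence is
        # zero-padded to a long fixed length or only to length + kernel
        model = AffinityModel(ModelConfig(), seed=1)
        x = rng.random((12, 20))
        long_pad = np.zeros((60, 20)); long_pad[:12] = x
        short_pad = np.zeros((12 + 5, 20)); short_pad[:12] = x
        out_long = model.encode_sequence(long_pad, "target").data
        out_short = model.encode_sequence(short_pad, "target").data
        np.testing.assert_allclose(out_long[:10], out_short[:10], atol=1e-12)

    def test_lstm_prefix_independent_of_padding(self, rng):
        model = AffinityModel(ModelConfig(seq_encoder="lstm"), seed=1)
        x = rng.random((8, 20))
        padded = np.zeros((15, 20)); padded[:8] = x
        a = model.encode_sequence(x, "target").data
        b = model.encode_sequence(padded, "target").data
        np.testing.assert_allclose(a, b[:8], atol=1e-12)

    def test_wrong_channel_count_raises(self):
        model = AffinityModel(ModelConfig(), seed=0)
        with pytest.raises(ValueError):
            model.encode_sequence(np.zeros((5, 7)), "target")


class TestGraphEncoder:
    def _graph(self, rng, n=6, d=20):
        edges = {(i, i + 1) for i in range(n - 1)} | {(0, n - 1)}
        return Graph(n, edges, rng.random((n, d)))

    @pytest.mark.parametrize("layer", ["graphsage", "gcn", "gat", "gin"])
    def test_single_vertex_readout_identity(self, layer, rng):
        cfg = ModelConfig(gnn_layer=layer, seq_encoder="none")
        model = AffinityModel(cfg, seed=0)
        g = Graph(1, set(), rng.random((1, 20)))
        emb, pooled = model.encode_graph(g, "target")
        assert emb.shape == (1, 128)
        np.testing.assert_allclose(pooled.data[0], emb.data[0])

    @pytest.mark.parametrize("layer", ["graphsage", "gcn", "gat", "gin"])
    def test_permutation_invariant_readout(self, layer, rng):
        cfg = ModelConfig(gnn_layer=layer, seq_encoder="none")
        model = AffinityModel(cfg, seed=0)
        g = self._graph(rng)
        _, pooled = model.encode_graph(g, "target")
        perm = rng.permutation(g.n_vertices)
        _, pooled_p = model.encode_graph(permute_graph(g, perm), "target")
        np.testing.assert_allclose(pooled.data, pooled_p.data, atol=1e-5)

    def test_disconnected_duplicate_components(self, rng):
        cfg = ModelConfig(seq_encoder="none")
        model = AffinityModel(cfg, seed=0)
        feats = rng.random((3, 20))
        single = Graph(3, {(0, 1), (1, 2)}, feats)
        double = Graph(
            6, {(0, 1), (1, 2), (3, 4), (4, 5)}, np.vstack([feats, feats])
        )
        _, p1 = model.encode_graph(single, "target")
        _, p2 = model.encode_graph(double, "target")
        np.testing.assert_allclose(p1.data, p2.data, atol=1e-8)

    def test_empty_graph_rejected(self):
        model = AffinityModel(ModelConfig(seq_encoder="none"), seed=0)
        with pytest.raises((ValueError, Exception)):
            model.encode_graph(Graph(0, set(), np.zeros((0, 20))), "target")


class TestProjectionAndFusion:
    def test_projection_affine(self, rng):
        model = AffinityModel(ModelConfig(), seed=0)
        a = Tensor(rng.random((1, 128)))
        b = Tensor(rng.random((1, 128)))
        zero = Tensor(np.zeros((1, 128)))
        fa = model.project(a, "drug").data
        fb = model.project(b, "drug").data
        f0 = model.project(zero, "drug").data
        fab = model.project(a + b, "drug").data
        np.testing.assert_allclose(fab, fa + fb - f0, atol=1e-10)
        assert fa.shape == (1, 256)

    def test_streams_have_independent_weights(self):
        model = AffinityModel(ModelConfig(), seed=0)
        assert not np.allclose(model.proj_drug.W.data, model.proj_target.W.data)

    def test_fusion_eval_deterministic(self, rng):
        model = AffinityModel(ModelConfig(), seed=0)
        vecs = [Tensor(rng.random((2, 256))) for _ in range(3)]
        out1 = model.fuse_and_predict(*vecs).data
        out2 = model.fuse_and_predict(*vecs).data
        np.testing.assert_array_equal(out1, out2)
        assert np.all(np.isfinite(out1))


class TestForward:
    def test_finite_prediction(self, tiny_samples):
        model = AffinityModel(ModelConfig(), seed=0)
        pred, _ = model.forward(tiny_samples[0])
        assert np.isfinite(pred)

    def test_batch_composition_invariance(self, tiny_samples):
        model = AffinityModel(ModelConfig(), seed=0)
        alone, _ = model.forward_batch(tiny_samples[:1])
        batched, _ = model.forward_batch(tiny_samples[:4])
        assert alone.data[0, 0] == pytest.approx(batched.data[0, 0], abs=1e-5)

    def test_drug_permutation_invariance(self, tiny_samples, rng):
        model = AffinityModel(ModelConfig(), seed=0)
        s = tiny_samples[0]
        base, _ = model.forward(s)
        perm = rng.permutation(s.drug_graph.n_vertices)
        permuted, _ = model.forward(permute_drug(s, perm))
        assert permuted == pytest.approx(base, abs=1e-5)

    def test_seq_encoder_none_ablation(self, tiny_samples):
        model = AffinityModel(ModelConfig(seq_encoder="none"), seed=0)
        pred, _ = model.forward(tiny_samples[0])
        assert np.isfinite(pred)

    def test_parameter_count_independent_of_input_size(self, tiny_samples):
        model = AffinityModel(ModelConfig(), seed=0)
        n_before = sum(p.data.size for p in model.parameters())
        model.forward(tiny_samples[0])
        model.forward(tiny_samples[1])
        assert sum(p.data.size for p in model.parameters()) == n_before


class TestAttention:
    def test_rows_sum_to_one(self, rng):
        res = bidirectional_attention(rng.normal(size=(5, 128)), rng.normal(size=(9, 128)))
        np.testing.assert_allclose(res.atoms_to_residues.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(res.residues_to_atoms.sum(axis=1), 1.0, atol=1e-6)
        assert res.atoms_to_residues.shape == (5, 9)
        assert res.residues_to_atoms.shape == (9, 5)

    def test_identical_embeddings_give_uniform_rows(self, rng):
        row = rng.normal(size=128)
        target = np.tile(row, (7, 1))
        res = bidirectional_attention(rng.normal(size=(3, 128)), target)
        np.testing.assert_allclose(res.atoms_to_residues, 1.0 / 7, atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        drug, target = rng.normal(size=(2, 128)), rng.normal(size=(3, 128))
        res = bidirectional_attention(drug, target)
        scores = np.array(
            [[np.dot(drug[i], target[j]) / np.sqrt(128) for j in range(3)] for i in range(2)]
        )
        expected = np.exp(scores) / np.exp(scores).sum(axis=1, keepdims=True)
        np.testing.assert_allclose(res.atoms_to_residues, expected, atol=1e-10)

    def test_row_shift_invariance_of_ranking(self, rng):
        # adding a constant to a row of the raw scores leaves each row's
        # softmax ranking unchanged
        scores = rng.normal(size=(4, 6))
        shifts = rng.normal(size=(4, 1)) * 10

        def softmax_rows(m):
            e = np.exp(m - m.max(axis=1, keepdims=True))
            return e / e.sum(axis=1, keepdims=True)

        base = softmax_rows(scores)
        shifted = softmax_rows(scores + shifts)
        np.testing.assert_array_equal(
            np.argsort(-base, axis=1), np.argsort(-shifted, axis=1)
        )

    def test_dim_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            bidirectional_attention(rng.normal(size=(2, 8)), rng.normal(size=(2, 9)))


class TestCheckpointing:
    def test_round_trip(self, tiny_samples, tmp_path):
        model = AffinityModel(ModelConfig(), seed=42)
        pred_before, _ = model.forward(tiny_samples[0])
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model)
        restored = load_checkpoint(path)
        pred_after, _ = restored.forward(tiny_samples[0])
        assert pred_after == pytest.approx(pred_before, abs=1e-12)
        assert restored.config == model.config


class TestFullModelGradients:
    def test_loss_gradient_matches_finite_differences(self, tiny_samples):
        from conftest import numeric_grad

        cfg = ModelConfig(
            gnn_dims=(4, 5, 6), seq_out_dim=8, projection_dim=7, fc_hidden=6,
            dropout=0.0,
        )
        model = AffinityModel(cfg, seed=0)
        batch = tiny_samples[:2]
        y = np.array([[s.affinity] for s in batch])

        def loss_value():
            preds, _ = model.forward_batch(batch)
            return float(((preds.data - y) ** 2).mean())

        model.zero_grad()
        preds, _ = model.forward_batch(batch)
        loss = ((preds - Tensor(y)) ** 2.0).mean()
        loss.backward()
        rng = np.random.default_rng(0)
        for p in model.parameters()[::4]:
            idx = rng.choice(p.data.size, size=min(3, p.data.size), replace=False)
            numeric = numeric_grad(loss_value, p, list(idx))
            for i in idx:
                assert p.grad.ravel()[i] == pytest.approx(
                    numeric[i], rel=2e-4, abs=1e-7
                )
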