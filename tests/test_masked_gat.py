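"""Backbone model: attention, forward passes, masking, losses, training."""

import numpy as np
import pytest

from maskst._autodiff import Tensor
from maskst.data_model import MultiSliceGraph
from maskst.masked_gat import (MaskedGraphAutoencoder, MaskPlan, ModelConfig,
                               apply_mask, apply_remask, attention_coefficients,
                               combined_loss, latent_loss, masked_loss,
                               sample_mask_plan)


def line_graph(n):
    """Path graph with self-edges, node i at position i."""
    pairs = [[i, i] for i in range(n)] + [[i, i + 1] for i in range(n - 1)]
    return MultiSliceGraph(node_index=[("a", str(i)) for i in range(n)],
                          pairs=np.array(pairs),
                          slice_of=np.array(["a"] * n))


class TestAttention:
    def test_single_neighbor_self(self, rng):
        H = rng.normal(size=(1, 3))
        alpha = attention_coefficients(H, np.eye(3), rng.normal(size=6), [[0]])
        assert alpha[0, 0] == pytest.approx(1.0)

    def test_equal_scores_uniform(self):
        H = np.zeros((4, 2))  # all scores equal -> 1/m each
        alpha = attention_coefficients(H, np.eye(2), np.ones(4),
                                       [[0, 1, 2], [1], [2, 0], [3, 1, 2, 0]])
        assert np.allclose(alpha[0, [0, 1, 2]], 1 / 3)
        assert np.allclose(alpha[3, [0, 1, 2, 3]], 1 / 4)

    def test_three_node_star_hand_computed(self):
        # scalar case: W = [[1]], a = (a1, a2); star center 0 with leaves 1, 2
        H = np.array([[1.0], [2.0], [-1.0]])
        a1, a2 = 0.5, -0.3
        alpha = attention_coefficients(H, np.array([[1.0]]),
                                       np.array([a1, a2]), [[0, 1, 2]])
        def sig(x):
            return 1 / (1 + np.exp(-x))
        scores = np.array([sig(a1 * 1 + a2 * 1), sig(a1 * 1 + a2 * 2),
                           sig(a1 * 1 + a2 * -1)])
        expected = np.exp(scores) / np.exp(scores).sum()
        assert np.allclose(alpha[0, :3], expected)

    def test_empty_neighborhood_errors(self):
        with pytest.raises(ValueError, match="empty neighborhood"):
            attention_coefficients(np.ones((2, 2)), np.eye(2), np.ones(4),
                                   [[0], []])

    def test_rows_sum_to_one(self, rng):
        H = rng.normal(size=(6, 4))
        nbrs = [[i] + [j for j in range(6) if j != i][:3] for i in range(6)]
        alpha = attention_coefficients(H, rng.normal(size=(4, 3)),
                                       rng.normal(size=6), nbrs)
        assert np.allclose(alpha.sum(axis=1), 1.0)


def dense_reference_forward(X, graph, layers, activate_last=False):
    """Brute-force evaluation of the layered attention aggregation."""
    nbr_sets = graph.neighbor_sets()
    nbrs = [sorted(s) for s in nbr_sets]
    H = X.copy()
    for li, layer in enumerate(layers):
        head = layer[0]
        W = head["W"].data
        a = np.concatenate([head["a_self"].data.ravel(),
                            head["a_nbr"].data.ravel()])
        alpha = attention_coefficients(H, W, a, nbrs)
        out = alpha @ (H @ W)
        if li < len(layers) - 1 or activate_last:
            out = np.where(out > 0, out, np.expm1(np.minimum(out, 0)))
        H = out
    return H


class TestForward:
    def test_encoder_matches_dense_oracle(self, rng):
        graph = line_graph(4)
        X = rng.normal(size=(4, 5))
        model = MaskedGraphAutoencoder(ModelConfig(hidden_dim=6, latent_dim=3,
                                                   seed=1))
        state = model._init_state(5)
        ops = model._graph_ops(graph)
        H = model._encode(state, Tensor(X), ops).data
        H_ref = dense_reference_forward(X, graph, state.encoder)
        assert np.allclose(H, H_ref, atol=1e-10)

    def test_decoder_matches_dense_oracle(self, rng):
        graph = line_graph(5)
        model = MaskedGraphAutoencoder(ModelConfig(hidden_dim=4, latent_dim=2,
                                                   seed=2))
        state = model._init_state(7)
        ops = model._graph_ops(graph)
        Z = rng.normal(size=(5, 2))
        out = model._decode(state, Tensor(Z), ops).data
        out_ref = dense_reference_forward(Z, graph, state.decoder)
        assert out.shape == (5, 7)
        assert np.allclose(out, out_ref, atol=1e-10)

    def test_zero_weights_constant_output(self):
        graph = line_graph(3)
        model = MaskedGraphAutoencoder(ModelConfig(hidden_dim=4, latent_dim=2))
        state = model._init_state(3)
        for layer in state.encoder:
            for head in layer:
                head["W"].data[:] = 0.0
        ops = model._graph_ops(graph)
        H = model._encode(state, Tensor(np.ones((3, 3))), ops).data
        assert np.allclose(H, 0.0)

    def test_generator_equals_main_with_tied_params(self, rng):
        graph = line_graph(6)
        model = MaskedGraphAutoencoder(ModelConfig(hidden_dim=4, latent_dim=3,
                                                   projector_hidden=5, seed=3))
        state = model._init_state(4)
        # tie generator parameters to the main encoder/projector
        for ls, lg in zip(state.encoder, state.gen_encoder):
            for hs, hg in zip(ls, lg):
                for k in hs:
                    hg[k].data = hs[k].data.copy()
        for ls, lg in zip(state.projector, state.gen_projector):
            lg["W"].data = ls["W"].data.copy()
        ops = model._graph_ops(graph)
        X = Tensor(rng.normal(size=(6, 4)))
        main = model._project(state.projector, model._encode(state, X, ops)).data
        gen = model._generate(state, X, ops).data
        assert np.allclose(main, gen)

    def test_nan_input_fails_fast(self):
        graph = line_graph(3)
        model = MaskedGraphAutoencoder(ModelConfig())
        X = np.ones((3, 4))
        X[1, 2] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            model.fit(X, graph)


class TestMasking:
    def test_zero_rate_is_identity(self, rng):
        cfg = ModelConfig(mask_rate=0.0, remask_rate=0.0)
        plan = sample_mask_plan(50, cfg, rng)
        X = rng.normal(size=(50, 4))
        assert np.array_equal(apply_mask(X, plan), X)

    def test_masked_rows_zero_others_untouched(self, rng):
        X = rng.normal(size=(5, 3))
        plan = MaskPlan(masked_nodes=np.array([1, 3]),
                        remasked_nodes=np.array([0]))
        Xm = apply_mask(X, plan)
        assert np.all(Xm[[1, 3]] == 0.0)
        assert np.array_equal(Xm[[0, 2, 4]], X[[0, 2, 4]])
        Hm = apply_remask(X, plan)
        assert np.all(Hm[0] == 0.0)

    def test_mask_fraction_concentrates(self, rng):
        cfg = ModelConfig(mask_rate=0.5)
        plan = sample_mask_plan(1000, cfg, rng)
        assert 0.45 <= len(plan.masked_nodes) / 1000 <= 0.55

    def test_remask_tensor_path_cuts_gradient(self, rng):
        plan = MaskPlan(masked_nodes=np.array([0]), remasked_nodes=np.array([1]))
        H = Tensor(rng.normal(size=(3, 2)), requires_grad=True)
        out = apply_remask(H, plan)
        assert np.all(out.data[1] == 0.0)


class TestLosses:
    def test_perfect_reconstruction_zero(self, rng):
        X = rng.normal(size=(6, 4))
        assert masked_loss(X, X.copy(), [0, 2], 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_pairs_gamma1(self):
        X = np.array([[1.0, 0.0], [0.0, 2.0]])
        Z = np.array([[0.0, 3.0], [1.0, 0.0]])
        assert masked_loss(X, Z, [0, 1], 1.0) == pytest.approx(1.0)

    def test_hand_computed_gamma2(self):
        X = np.array([[1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        Z = np.array([[1.0, 1.0], [1.0, 0.0], [0.0, 2.0]])
        cos = np.array([1 / np.sqrt(2), 1 / np.sqrt(2), 1.0])
        expected = np.mean((1 - cos) ** 2)
        assert masked_loss(X, Z, [0, 1, 2], 2.0) == pytest.approx(expected)

    def test_zero_norm_row_warns_and_counts_one(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0]])
        Z = np.array([[1.0, 1.0], [1.0, 0.0]])
        with pytest.warns(RuntimeWarning, match="zero-norm"):
            val = masked_loss(X, Z, [0, 1], 1.0)
        assert val == pytest.approx(0.5)  # mean of (1, 0)

    def test_empty_mask_set_errors(self, rng):
        X = rng.normal(size=(3, 2))
        with pytest.raises(ValueError, match="nonempty"):
            masked_loss(X, X, [], 1.0)

    def test_latent_loss_and_reduction(self, rng):
        Zb = rng.normal(size=(4, 3))
        assert latent_loss(Zb, Zb.copy()) == pytest.approx(0.0, abs=1e-12)
        X = rng.normal(size=(4, 3))
        Z = rng.normal(size=(4, 3))
        assert combined_loss(X, Z, [0, 1], Zb, rng.normal(size=(4, 3)),
                             lambda_latent=0.0) == pytest.approx(
            masked_loss(X, Z, [0, 1]))

    def test_latent_matches_rowwise_oracle(self, rng):
        A = rng.normal(size=(4, 3))
        B = rng.normal(size=(4, 3))
        cos = np.array([a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
                        for a, b in zip(A, B)])
        assert latent_loss(A, B, 1.0) == pytest.approx(np.mean(1 - cos))


class TestTraining:
    def test_loss_descends_on_toy_graph(self, tiny_model_config, rng):
        graph = line_graph(30)
        X = np.abs(rng.normal(size=(30, 12)))
        model = MaskedGraphAutoencoder(tiny_model_config)
        model.set_params(epochs_phase1=50, epochs_phase2=0)
        model.fit(X, graph)
        assert model.loss_history_[-1] < model.loss_history_[0]

    def test_phase2_empty_triplets_equals_phase1_step(self, tiny_model_config,
                                                     rng):
        graph = line_graph(10)
        X = np.abs(rng.normal(size=(10, 6)))
        results = []
        for phase in (1, 2):
            model = MaskedGraphAutoencoder(tiny_model_config)
            state = model._init_state(6)
            ops = model._graph_ops(graph)
            loss = model.train_epoch(state, ops, X, [] if phase == 2 else None,
                                     phase=phase)
            results.append(loss)
        assert results[0] == results[1]

    def test_seeded_determinism(self, tiny_model_config, rng):
        graph = line_graph(15)
        X = np.abs(rng.normal(size=(15, 8)))
        runs = []
        for _ in range(2):
            model = MaskedGraphAutoencoder(tiny_model_config)
            model.fit(X, graph)
            runs.append((model.embedding_.copy(), model.loss_history_[-1]))
        assert runs[0][1] == runs[1][1]
        assert np.array_equal(runs[0][0], runs[1][0])

    def test_checkpoint_round_trip(self, tiny_model_config, tmp_path, rng):
        graph = line_graph(12)
        X = np.abs(rng.normal(size=(12, 5)))
        model = MaskedGraphAutoencoder(tiny_model_config)
        model.set_params(epochs_phase1=5, epochs_phase2=0)
        model.fit(X, graph)
        path = str(tmp_path / "ckpt.npz")
        model.save_checkpoint(path)
        back = MaskedGraphAutoencoder.load_checkpoint(path, 5)
        assert np.array_equal(back.transform(X, graph), model.transform(X))

    def test_get_set_params(self):
        model = MaskedGraphAutoencoder()
        assert model.get_params()["gamma"] == 1.0
        model.set_params(gamma=2.0)
        assert model.config.gamma == 2.0


class TestConfigValidation:
    @pytest.mark.parametrize("bad", [
        {"mask_rate": 1.0}, {"gamma": 0.5}, {"lambda_latent": -1.0},
        {"margin_alpha": 0.0}, {"lr": 0.0}, {"attention_heads": 0}])
    def test_invalid_values_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelConfig(**bad)
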