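import numpy as np
import pytest

import dbgcnmda._autodiff as ad
from dbgcnmda import (
    AssociationMatrix,
    RunConfig,
    build_hetero_graph,
    decode_and_score,
    forward_scores,
    gcn_layer,
    global_branch,
    init_model_state,
    local_branch,
    normalize_graph,
)
from dbgcnmda.dbgcn_model import GcnLayerParams, ModelState, alpha_loss, build_loss_target

from conftest import random_assoc


def small_config(**kwargs):
    defaults = dict(hidden_dims=[4, 3], n_gcn_layers=2, poly_degree=1,
                    poly_target_dim=4, epochs=5, seed=0)
    defaults.update(kwargs)
    return RunConfig(**defaults)


class TestNormalizedGraph:
    def test_single_edge_hand_computed(self):
        A = AssociationMatrix(["m1"], ["d1"], np.array([[1.0]]))
        G = build_hetero_graph(A)
        np.testing.assert_allclose(G.propagation, [[0.5, 0.5], [0.5, 0.5]], atol=1e-15)

    def test_isolated_node_keeps_self_loop_only(self):
        S = np.zeros((3, 3))
        S[0, 1] = S[1, 0] = 1.0
        G = normalize_graph(S)
        np.testing.assert_allclose(G.propagation[2], [0.0, 0.0, 1.0], atol=1e-15)

    @pytest.mark.parametrize("seed", range(3))
    def test_propagation_symmetric(self, seed):
        A = random_assoc(np.random.default_rng(seed), 6, 4, 8)
        G = build_hetero_graph(A)
        np.testing.assert_allclose(G.propagation, G.propagation.T, atol=1e-15)

    def test_path_graph_matches_degree_weighted_sums(self):
        # 3-node path: brute-force per-node aggregation with 1/sqrt(di*dj)
        S = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        G = normalize_graph(S)
        E = np.ones((3, 2))
        out = gcn_layer(G, E, GcnLayerParams(np.eye(2), activation="identity"))
        S_tilde = S + np.eye(3)
        d = S_tilde.sum(axis=1)
        expected = np.zeros((3, 2))
        for i in range(3):
            for j in range(3):
                expected[i] += S_tilde[i, j] / np.sqrt(d[i] * d[j]) * E[j]
        np.testing.assert_allclose(out, expected, atol=1e-12)


class TestGcnLayer:
    def test_self_loop_identity_passthrough(self):
        G = normalize_graph(np.zeros((1, 1)))
        E = np.array([[1.5, -2.0]])
        out = gcn_layer(G, E, GcnLayerParams(np.eye(2), activation="identity"))
        np.testing.assert_allclose(out, E, atol=1e-15)

    def test_relu_zeroes_negative_preactivations(self):
        G = normalize_graph(np.zeros((2, 2)))
        E = np.ones((2, 2))
        out = gcn_layer(G, E, GcnLayerParams(-np.eye(2), activation="relu"))
        np.testing.assert_array_equal(out, np.zeros((2, 2)))

    def test_width_mismatch_rejected(self):
        G = normalize_graph(np.zeros((2, 2)))
        with pytest.raises(ValueError, match="width"):
            gcn_layer(G, np.ones((2, 3)), GcnLayerParams(np.eye(2)))


class TestBranches:
    def test_zero_layers_returns_projected_inputs(self, rng):
        config = small_config(n_gcn_layers=0)
        state = init_model_state(5, 4, config, "DBGCNMDA", rng)
        A = random_assoc(rng, 3, 2, 3)
        M, D = rng.random((3, 5)), rng.random((2, 4))
        Rm, Rd = global_branch(build_hetero_graph(A), M, D, state)
        np.testing.assert_allclose(Rm, M @ state.microbe_proj, atol=1e-12)
        np.testing.assert_allclose(Rd, D @ state.disease_proj, atol=1e-12)

    def test_global_branch_equals_layer_composition(self, rng):
        config = small_config()
        state = init_model_state(5, 4, config, "GlobalGCNMDA", rng)
        A = random_assoc(rng, 2, 1, 1)
        G = build_hetero_graph(A)
        M, D = rng.random((2, 5)), rng.random((1, 4))
        Rm, Rd = global_branch(G, M, D, state)
        E = np.vstack([M @ state.microbe_proj, D @ state.disease_proj])
        for layer in state.global_layers:
            E = gcn_layer(G, E, layer)
        np.testing.assert_allclose(np.vstack([Rm, Rd]), E, atol=1e-12)

    def test_local_branch_zero_layers_passthrough(self, rng):
        config = small_config(n_gcn_layers=0)
        state = init_model_state(5, 4, config, "DBGCNMDA", rng)
        Gm, Gd = normalize_graph(np.eye(3)), normalize_graph(np.eye(2))
        Em, Ed = rng.random((3, 4)), rng.random((2, 4))
        Rm, Rd = local_branch(Gm, Gd, (Em, Ed), state)
        np.testing.assert_array_equal(Rm, Em)
        np.testing.assert_array_equal(Rd, Ed)

    def test_local_branch_triangle_oracle(self, rng):
        config = small_config(n_gcn_layers=1)
        state = init_model_state(5, 4, config, "LocalGCNMDA", rng)
        S = np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
        Gm = normalize_graph(S)
        Gd = normalize_graph(np.eye(2))
        Em = rng.random((3, 4))
        Ed = rng.random((2, 4))
        Rm, _ = local_branch(Gm, Gd, (Em, Ed), state)
        layer = state.local_microbe_layers[0]
        np.testing.assert_allclose(Rm, gcn_layer(Gm, Em, layer), atol=1e-12)

    def test_permutation_equivariance_end_to_end(self, rng):
        config = small_config()
        A = random_assoc(rng, 6, 3, 7)
        M, D = rng.random((6, 6)), rng.random((3, 3))
        Sm, Sd = np.eye(6), np.eye(3)
        state = init_model_state(6, 3, config, "DBGCNMDA", rng)
        scores = forward_scores(state, build_hetero_graph(A), normalize_graph(Sm),
                                normalize_graph(Sd), M, D)
        perm = rng.permutation(6)
        A_perm = AssociationMatrix([A.microbe_ids[i] for i in perm], A.disease_ids,
                                   A.values[perm])
        scores_perm = forward_scores(state, build_hetero_graph(A_perm),
                                     normalize_graph(Sm[np.ix_(perm, perm)]),
                                     normalize_graph(Sd), M[perm], D)
        np.testing.assert_allclose(scores_perm, scores[perm], atol=1e-10)


class TestDecoder:
    def _identity_decoder_state(self, width, config, variant="FNMDA"):
        state = init_model_state(width, width, config, variant)
        for tag in ("m", "d"):
            for k in range(3):
                state.params[f"dec_{tag}_W{k}"] = np.eye(width)
                state.params[f"dec_{tag}_b{k}"] = np.zeros(width)
        return state

    def test_unit_and_orthogonal_embeddings(self):
        config = small_config(hidden_dims=[2], n_gcn_layers=0)
        state = self._identity_decoder_state(2, config)
        Rm = np.array([[1.0, 0.0], [0.0, 1.0]])
        Rd = np.array([[1.0, 0.0]])
        scores = decode_and_score(Rm, Rd, state)
        assert scores[0, 0] == pytest.approx(1.0)
        assert scores[1, 0] == pytest.approx(0.0)

    def test_matches_double_loop_inner_product_oracle(self, rng):
        config = small_config(hidden_dims=[3], n_gcn_layers=0)
        state = self._identity_decoder_state(3, config)
        Rm, Rd = rng.random((4, 3)), rng.random((2, 3))
        scores = decode_and_score(Rm, Rd, state)
        expected = np.empty((4, 2))
        for i in range(4):
            for j in range(2):
                expected[i, j] = float(np.dot(Rm[i], Rd[j]))
        np.testing.assert_allclose(scores, expected, atol=1e-12)

    def test_zero_layer_identity_decoder_reduces_to_projected_inner_product(self, rng):
        # with no propagation and an identity decoder the whole model is
        # an inner product of linearly projected input features
        config = small_config(hidden_dims=[3], n_gcn_layers=0)
        state = self._identity_decoder_state(3, config, variant="DBGCNMDA")
        M, D = rng.random((4, 5)), rng.random((2, 5))
        # nonnegative projections keep the decoder's hidden ReLUs inactive,
        # so the identity decoder is exactly the identity map
        state.params["microbe_proj"] = rng.random((5, 3))
        state.params["disease_proj"] = rng.random((5, 3))
        A = random_assoc(rng, 4, 2, 3)
        scores = forward_scores(state, build_hetero_graph(A),
                                normalize_graph(np.eye(4)), normalize_graph(np.eye(2)),
                                M, D)
        direct = (M @ state.params["microbe_proj"]) @ (D @ state.params["disease_proj"]).T
        np.testing.assert_allclose(scores, direct, atol=1e-12)


class TestAlphaLoss:
    def test_perfect_prediction_zero_weight_loss(self, rng):
        A = random_assoc(rng, 3, 2, 2)
        config = small_config()
        state = init_model_state(3, 2, config, "FNMDA", rng)
        for k in state.params:
            state.params[k] = np.zeros_like(state.params[k])
        target = build_loss_target(A, [], config.alpha)
        assert alpha_loss(target, A, [], config.alpha, config.mu, state) == 0.0

    def test_zero_prediction_closed_form(self, rng):
        A = random_assoc(rng, 3, 2, 3)
        config = small_config(alpha=1.7, mu=0.01)
        state = init_model_state(3, 2, config, "FNMDA", rng)
        w2 = sum(float(np.sum(v**2)) for v in state.params.values())
        expected = 3 * 1.7**2 + 0.01 * w2
        loss = alpha_loss(np.zeros((3, 2)), A, [], 1.7, 0.01, state)
        assert loss == pytest.approx(expected, rel=1e-12)

    def test_holdout_positives_become_zero_targets(self, rng):
        A = random_assoc(rng, 3, 2, 3)
        pos = [tuple(p) for p in np.argwhere(A.values == 1)]
        target = build_loss_target(A, pos[:1], 2.0)
        assert target[pos[0]] == 0.0
        assert all(target[p] == 2.0 for p in pos[1:])

    def test_invalid_alpha_rejected(self, rng):
        A = random_assoc(rng, 2, 2, 1)
        state = init_model_state(2, 2, small_config(), "FNMDA", rng)
        with pytest.raises(ValueError, match="alpha"):
            alpha_loss(np.zeros((2, 2)), A, [], 0.0, 0.0, state)


class TestGradients:
    def test_finite_difference_gradient_agreement(self, rng):
        # full forward + loss on a 3x2 toy, every parameter checked by
        # central differences
        from dbgcnmda.dbgcn_model import _forward_scores_t

        config = small_config(hidden_dims=[3, 2], n_gcn_layers=1, mu=0.01)
        A = random_assoc(rng, 3, 2, 2)
        state = init_model_state(4, 3, config, "DBGCNMDA", rng)
        for k in state.params:  # jitter off exact ReLU kinks (zero biases)
            state.params[k] = state.params[k] + 0.05 * rng.standard_normal(
                state.params[k].shape
            )
        M, D = rng.random((3, 4)), rng.random((2, 3))
        G_het = build_hetero_graph(A)
        G_sm = normalize_graph(np.eye(3))
        G_sd = normalize_graph(np.eye(2))
        target = build_loss_target(A, [], config.alpha)

        def loss_value():
            params = {k: ad.parameter(v) for k, v in state.params.items()}
            scores = _forward_scores_t(params, state, G_het, G_sm, G_sd, M, D)
            total = ad.add(ad.masked_sq_error(scores, target),
                           ad.l2_penalty(list(params.values()), config.mu))
            return params, total

        params, total = loss_value()
        total.backward()
        eps = 1e-6
        for name in state.params:
            grad = params[name].grad
            flat = state.params[name].ravel()
            for idx in range(0, flat.size, max(1, flat.size // 5)):
                orig = flat[idx]
                flat[idx] = orig + eps
                _, up = loss_value()
                flat[idx] = orig - eps
                _, down = loss_value()
                flat[idx] = orig
                numeric = (float(up.value) - float(down.value)) / (2 * eps)
                analytic = grad.ravel()[idx]
                assert analytic == pytest.approx(numeric, rel=1e-5, abs=1e-8), name

    def test_forward_deterministic(self, rng):
        config = small_config()
        A = random_assoc(rng, 4, 3, 4)
        state = init_model_state(4, 3, config, "DBGCNMDA", rng)
        args = (state, build_hetero_graph(A), normalize_graph(np.eye(4)),
                normalize_graph(np.eye(3)), rng.random((4, 4)), rng.random((3, 3)))
        s1 = forward_scores(*args)
        s2 = forward_scores(*args)
        np.testing.assert_array_equal(s1, s2)

    def test_one_adam_step_decreases_loss(self, rng):
        from dbgcnmda.dbgcn_model import _forward_scores_t

        config = small_config(hidden_dims=[3, 2], n_gcn_layers=1, learning_rate=1e-4)
        A = random_assoc(rng, 3, 2, 2)
        state = init_model_state(4, 3, config, "DBGCNMDA", rng)
        M, D = rng.random((3, 4)), rng.random((2, 3))
        G_het = build_hetero_graph(A)
        G_sm, G_sd = normalize_graph(np.eye(3)), normalize_graph(np.eye(2))
        target = build_loss_target(A, [], config.alpha)
        params = {k: ad.parameter(v) for k, v in state.params.items()}
        opt = ad.Adam(list(params.values()), lr=config.learning_rate)
        losses = []
        for _ in range(2):
            scores = _forward_scores_t(params, state, G_het, G_sm, G_sd, M, D)
            total = ad.add(ad.masked_sq_error(scores, target),
                           ad.l2_penalty(list(params.values()), config.mu))
            losses.append(float(total.value))
            total.backward()
            opt.step()
        assert losses[1] < losses[0]


class TestModelState:
    def test_fnmda_has_no_propagation_weights(self, rng):
        state = init_model_state(5, 4, small_config(n_gcn_layers=3), "FNMDA", rng)
        assert state.global_layers == []
        assert state.local_microbe_layers == []
        assert state.local_disease_layers == []

    def test_rejects_non_finite_weights(self, rng):
        state = init_model_state(3, 3, small_config(), "DBGCNMDA", rng)
        params = dict(state.params)
        params["microbe_proj"] = params["microbe_proj"].copy()
        params["microbe_proj"][0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            ModelState(params=params, config=state.config)

    def test_unknown_variant_rejected(self, rng):
        with pytest.raises(ValueError, match="variant"):
            init_model_state(3, 3, small_config(), "Bogus", rng)
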