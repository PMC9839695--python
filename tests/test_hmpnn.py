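"""Message-passing layer semantics, oracle equivalence and gradients."""

import math

import numpy as np
import pytest

from molhnn.autodiff import Tensor
from molhnn.hmpnn import (
    HnnConfig, HnnModel, LayerParams, LayerState, LinearMap,
    aggregate_to_edges, edge_messages, edge_update, init_layer_params,
    layer_forward, node_messages, node_update, run_layers,
)


def np_params(rng, d_v, d_w, d_h):
    return init_layer_params(rng, d_v, d_w, d_h, trainable=False)


def zero_params(d_v, d_w, d_h):
    def zmap(i, o):
        return LinearMap(np.zeros((i, o)), np.zeros(o))
    return LayerParams(L_fv=zmap(d_v, d_h), L_fw=zmap(d_w + d_h, d_h),
                       L_gv=zmap(d_v, d_h), L_gw=zmap(d_w, d_h))


def naive_layer(X, W, members, params):
    """Double-loop reference implementation of one layer."""
    sig = lambda z: 1.0 / (1.0 + np.exp(-z))
    n_v, n_e = X.shape[0], W.shape[0]
    M_v = np.array([sig(params.L_fv.b + x @ params.L_fv.W) for x in X])
    agg = np.zeros((n_e, params.d_h))
    for e, mem in enumerate(members):
        for v in mem:
            agg[e] += M_v[v]
    W_next = np.array([params.L_gw.b + W[e] @ params.L_gw.W + agg[e]
                       for e in range(n_e)])
    M_e = np.array([
        sig(params.L_fw.b + np.concatenate([W[e], agg[e]]) @ params.L_fw.W)
        for e in range(n_e)
    ])
    X_next = np.zeros((n_v, params.d_h))
    for v in range(n_v):
        incoming = np.zeros(params.d_h)
        for e, mem in enumerate(members):
            if v in mem:
                incoming += M_e[e]
        X_next[v] = params.L_gv.b + X[v] @ params.L_gv.W + incoming
    return X_next, W_next


def members_to_B(members, n_v):
    B = np.zeros((len(members), n_v))
    for e, mem in enumerate(members):
        B[e, list(mem)] = 1.0
    return B


class TestMessageSteps:
    def test_zero_map_messages_are_half(self):
        params = zero_params(2, 5, 4)
        M = node_messages(np.zeros((3, 2)), params)
        np.testing.assert_allclose(M, 0.5)

    def test_identity_map_on_zero_input(self):
        params = zero_params(2, 5, 2)
        params.L_fv.W[:] = np.eye(2)
        np.testing.assert_allclose(node_messages(np.zeros((1, 2)), params),
                                   [[0.5, 0.5]])

    def test_log3_bias_gives_three_quarters(self):
        params = zero_params(2, 5, 2)
        params.L_fv.W[:] = np.eye(2)
        params.L_fv.b[:] = [math.log(3.0), 0.0]
        np.testing.assert_allclose(node_messages(np.zeros((1, 2)), params),
                                   [[0.75, 0.5]])

    def test_aggregation_sums_member_rows(self):
        B = members_to_B([(0, 1)], 2)
        agg = aggregate_to_edges(np.full((2, 3), 0.5), B)
        np.testing.assert_allclose(agg, [[1.0, 1.0, 1.0]])

    def test_aggregation_of_four_identical_rows(self):
        B = members_to_B([(0, 1, 2, 3)], 4)
        m = np.array([0.2, 0.7])
        agg = aggregate_to_edges(np.tile(m, (4, 1)), B)
        np.testing.assert_allclose(agg, [4 * m])

    def test_aggregation_matches_membership_loop(self, rng):
        members = [(0, 1), (1, 2, 3), (0, 2, 3, 4)]
        B = members_to_B(members, 5)
        M = rng.random((5, 4))
        agg = aggregate_to_edges(M, B)
        for e, mem in enumerate(members):
            np.testing.assert_allclose(agg[e], sum(M[v] for v in mem),
                                       rtol=1e-12)

    def test_edge_update_with_zero_linear_is_aggregate(self, rng):
        params = zero_params(2, 5, 3)
        agg = rng.random((4, 3))
        np.testing.assert_array_equal(
            edge_update(rng.random((4, 5)), agg, params), agg)

    def test_edge_update_scalar_hand_case(self):
        # L_gw(x) = 2x + 1, W_e = 3, agg = 1  ->  8
        params = zero_params(1, 1, 1)
        params.L_gw.W[:] = [[2.0]]
        params.L_gw.b[:] = [1.0]
        out = edge_update(np.array([[3.0]]), np.array([[1.0]]), params)
        assert out[0, 0] == pytest.approx(8.0)

    def test_edge_messages_zero_map(self):
        params = zero_params(2, 5, 3)
        M = edge_messages(np.zeros((2, 5)), np.zeros((2, 3)), params)
        np.testing.assert_allclose(M, 0.5)

    def test_node_update_zero_linear_is_message_sum(self, rng):
        params = zero_params(2, 5, 3)
        members = [(0, 1), (1, 2)]
        B = members_to_B(members, 3)
        M_e = rng.random((2, 3))
        out = node_update(rng.random((3, 2)), M_e, B, params)
        np.testing.assert_allclose(out[1], M_e[0] + M_e[1], rtol=1e-12)

    def test_isolated_vertex_gets_only_linear_part(self, rng):
        params = np_params(rng, 2, 5, 3)
        B = members_to_B([(0, 1)], 3)      # vertex 2 isolated
        X = rng.random((3, 2))
        M_e = np.full((1, 3), 0.5)
        out = node_update(X, M_e, B, params)
        np.testing.assert_allclose(out[2], params.L_gv(X[2]), rtol=1e-12)

    def test_shape_error_names_layer(self):
        params = zero_params(2, 5, 3)
        with pytest.raises(ValueError, match="L_fv"):
            node_messages(np.zeros((3, 4)), params)


class TestLayerForward:
    def test_golden_two_vertex_one_bond(self):
        """Hand-worked single layer on a 2-vertex, 1-bond hypergraph.

        X = [[0,1],[1,-1]], W = [[1,0,0,0,0]], L_fv = identity with bias
        [ln 3, 0], L_gw = first-two-columns projection with bias
        [0.5,-0.5], L_fw = all-0.5 weights with bias [0,1], L_gv = 2*I.
        Every number below was derived step by step with scalar
        arithmetic (sigma(ln 3) = 3/4 etc.) and frozen.
        """
        params = zero_params(2, 5, 2)
        params.L_fv.W[:] = np.eye(2)
        params.L_fv.b[:] = [math.log(3.0), 0.0]
        params.L_gw.W[:2, :] = np.eye(2)
        params.L_gw.b[:] = [0.5, -0.5]
        params.L_fw.W[:] = 0.5
        params.L_fw.b[:] = [0.0, 1.0]
        params.L_gv.W[:] = 2 * np.eye(2)
        X = np.array([[0.0, 1.0], [1.0, -1.0]])
        W = np.array([[1.0, 0, 0, 0, 0]])
        B = members_to_B([(0, 1)], 2)
        out = layer_forward(LayerState(X=X, W=W), B, params)
        np.testing.assert_allclose(
            out.W, [[3.140768227426964, 0.5]], rtol=1e-15)
        np.testing.assert_allclose(
            out.X,
            [[0.8606122112540338, 2.9437674549880066],
             [2.8606122112540335, -1.0562325450119934]],
            rtol=1e-14)

    def test_matches_naive_double_loop(self, rng):
        """All small random hypergraphs equal the double-loop oracle."""
        cases = [
            [(0, 1)],
            [(0, 1), (1, 2, 3)],
            [(0, 1), (0, 2), (1, 2, 3), (0, 1, 2, 3)],
            [(2, 3), (0, 1, 2), (0, 3)],
        ]
        for members in cases:
            n_v = 1 + max(v for mem in members for v in mem)
            params = np_params(rng, 2, 5, 3)
            X = rng.standard_normal((n_v, 2))
            W = rng.standard_normal((len(members), 5))
            B = members_to_B(members, n_v)
            out = layer_forward(LayerState(X=X, W=W), B, params)
            Xn, Wn = naive_layer(X, W, members, params)
            np.testing.assert_allclose(out.X, Xn, atol=1e-10)
            np.testing.assert_allclose(out.W, Wn, atol=1e-10)

    def test_two_stacked_layers_match_unrolled_oracle(self, rng):
        members = [(0, 1), (1, 2, 3)]
        p1 = np_params(rng, 2, 5, 3)
        p2 = np_params(rng, 3, 3, 3)
        X = rng.standard_normal((4, 2))
        W = rng.standard_normal((2, 5))
        B = members_to_B(members, 4)
        out = run_layers(X, W, B, [p1, p2])
        X1, W1 = naive_layer(X, W, members, p1)
        X2, W2 = naive_layer(X1, W1, members, p2)
        np.testing.assert_allclose(out.X, X2, atol=1e-10)
        np.testing.assert_allclose(out.W, W2, atol=1e-10)

    def test_equal_inputs_give_equal_outputs(self, rng):
        """Symmetric vertices stay symmetric under zero-information W."""
        params = np_params(rng, 2, 5, 4)
        members = [(0, 1)]
        X = np.tile(rng.standard_normal(2), (2, 1))
        W = rng.standard_normal((1, 5))
        out = layer_forward(LayerState(X=X, W=W), members_to_B(members, 2),
                            params)
        np.testing.assert_allclose(out.X[0], out.X[1], rtol=1e-12)

    def test_permutation_equivariance(self, rng):
        members = [(0, 1), (1, 2, 3), (0, 2)]
        n_v = 4
        params = np_params(rng, 2, 5, 3)
        X = rng.standard_normal((n_v, 2))
        W = rng.standard_normal((3, 5))
        out = layer_forward(LayerState(X=X, W=W), members_to_B(members, n_v),
                            params)
        perm = np.array([2, 0, 3, 1])      # new index of old vertex i
        members_p = [tuple(perm[v] for v in mem) for mem in members]
        X_p = np.empty_like(X)
        X_p[perm] = X
        out_p = layer_forward(LayerState(X=X_p, W=W),
                              members_to_B(members_p, n_v), params)
        np.testing.assert_allclose(out_p.X[perm], out.X, atol=1e-12)
        np.testing.assert_allclose(out_p.W, out.W, atol=1e-12)

    def test_locality_one_layer(self, rng):
        """Perturbing vertex 3 cannot affect vertex 0 if they share no edge."""
        members = [(0, 1), (2, 3)]
        params = np_params(rng, 2, 5, 3)
        X = rng.standard_normal((4, 2))
        W = rng.standard_normal((2, 5))
        B = members_to_B(members, 4)
        base = layer_forward(LayerState(X=X, W=W), B, params)
        X2 = X.copy()
        X2[3] += 1.0
        moved = layer_forward(LayerState(X=X2, W=W), B, params)
        np.testing.assert_array_equal(moved.X[0], base.X[0])
        np.testing.assert_array_equal(moved.X[1], base.X[1])
        assert not np.allclose(moved.X[2], base.X[2])

    def test_messages_strictly_in_unit_interval(self, rng):
        params = np_params(rng, 2, 5, 8)
        X = 5 * rng.standard_normal((6, 2))
        M = node_messages(X, params)
        assert np.all(M > 0) and np.all(M < 1)

    def test_deterministic_for_fixed_params(self, rng):
        params = np_params(rng, 2, 5, 3)
        X = rng.standard_normal((3, 2))
        W = rng.standard_normal((2, 5))
        B = members_to_B([(0, 1), (1, 2)], 3)
        a = layer_forward(LayerState(X=X, W=W), B, params)
        b = layer_forward(LayerState(X=X, W=W), B, params)
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.W, b.W)


class TestModelContainer:
    def test_seeded_init_reproducible(self):
        m1 = HnnModel(HnnConfig(seed=5))
        m2 = HnnModel(HnnConfig(seed=5))
        for a, b in zip(m1.parameters(), m2.parameters()):
            np.testing.assert_array_equal(a.data, b.data)

    def test_save_load_roundtrip(self, tmp_path):
        model = HnnModel(HnnConfig(seed=3, d_h=4, k_points=2))
        model.points = np.arange(12.0).reshape(2, 6)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = HnnModel.load(path)
        assert loaded.config == model.config
        for a, b in zip(model.parameters(), loaded.parameters()):
            np.testing.assert_array_equal(a.data, b.data)
        np.testing.assert_array_equal(loaded.points, model.points)

    def test_gradients_flow_through_both_layers(self, rng):
        model = HnnModel(HnnConfig(seed=0, d_h=3))
        X = rng.standard_normal((3, 2))
        W = rng.standard_normal((2, 5))
        B = members_to_B([(0, 1), (1, 2)], 3)
        state = run_layers(X, W, B, model.layers)
        loss = (state.X.norm() + state.W.norm())
        loss.backward()
        for t, layer in enumerate(model.layers):
            for name, lin in layer.maps().items():
                assert lin.W.grad is not None, f"layer{t}.{name}"
                assert np.any(lin.W.grad != 0), f"layer{t}.{name}"
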