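"""Network math: aggregation, layers, sharing, combiners, batching, IO."""

import numpy as np
import pytest

from conftest import random_graph
from ddgraph import network as net
from ddgraph.graphs import ProteinGraph
from ddgraph.network import (
    ModelConfig,
    count_parameters,
    encode_graph,
    init_params,
    load_checkpoint,
    predict_ddg,
    sage_layer,
    save_checkpoint,
    weighted_mean_aggregate,
    zero_head_biases,
)


def two_node_graph(h=((2.0,), (4.0,)), weight=0.5):
    return (
        ProteinGraph(
            node_features=np.asarray(h, dtype=float),
            edges=np.array([[0, 1]]),
            edge_weights=np.array([weight]),
        ),
        np.asarray(h, dtype=float),
    )


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def test_isolated_node_aggregates_to_zero():
    g = ProteinGraph(np.ones((3, 2)), np.array([[0, 1]]), np.array([0.7]))
    assert weighted_mean_aggregate(2, g, g.node_features).tolist() == [0.0, 0.0]


def test_weighted_mean_hand_example():
    g = ProteinGraph(
        np.array([[1.0], [2.0], [0.0]]),
        np.array([[0, 2], [1, 2]]),
        np.array([0.2, 0.8]),
    )
    agg = weighted_mean_aggregate(2, g, g.node_features)
    assert agg[0] == pytest.approx((0.2 * 1 + 0.8 * 2) / 1.0)  # = 1.8


def test_equal_weights_reduce_to_plain_mean(rng):
    g = random_graph(10, rng)
    g.edge_weights[:] = 0.37
    h = g.node_features
    for v in range(10):
        assert weighted_mean_aggregate(v, g, h) == pytest.approx(
            weighted_mean_aggregate(v, g, h, use_edge_weights=False)
        )


# ---------------------------------------------------------------------------
# sage layer
# ---------------------------------------------------------------------------


def test_sage_layer_two_node_hand_computation():
    g, h = two_node_graph()
    out = sage_layer(g, h, np.array([[1.0]]), np.array([[1.0]]), np.zeros(1))
    assert out.tolist() == [[6.0], [6.0]]  # 2 + 4 and 4 + 2


def test_sage_layer_neighbor_weights_zero_gives_affine_map(rng):
    g = random_graph(6, rng, f=3)
    w_self = rng.standard_normal((3, 4))
    b = rng.standard_normal(4)
    out = sage_layer(g, g.node_features, w_self, np.zeros((3, 4)), b)
    assert out == pytest.approx(g.node_features @ w_self + b)


def test_sage_layer_permutation_covariant(rng):
    for _ in range(100):
        n = int(rng.integers(2, 12))
        g = random_graph(n, rng, f=3)
        w_self = rng.standard_normal((3, 3))
        w_neigh = rng.standard_normal((3, 3))
        b = rng.standard_normal(3)
        out = sage_layer(g, g.node_features, w_self, w_neigh, b, activation=np.tanh)
        perm = rng.permutation(n)
        label = {old: new for new, old in enumerate(perm)}
        pedges = []
        for i, j in g.edges.tolist():
            a, c = sorted((label[i], label[j]))
            pedges.append((a, c))
        order = np.argsort([a * n + c for a, c in pedges])
        pg = ProteinGraph(
            g.node_features[perm],
            np.array([pedges[k] for k in order]).reshape(-1, 2),
            g.edge_weights[order],
        )
        pout = sage_layer(pg, pg.node_features, w_self, w_neigh, b, activation=np.tanh)
        assert pout == pytest.approx(out[perm], abs=1e-10)


# ---------------------------------------------------------------------------
# encoding and pooling
# ---------------------------------------------------------------------------


def test_single_node_graph_pools_to_its_state():
    g = ProteinGraph(np.array([[1.0, 2.0]]), np.empty((0, 2)), np.empty(0))
    cfg = ModelConfig(hidden_dim=4, n_conv_layers=1, l2_normalize_nodes=True, seed=3)
    params = init_params(cfg, 2)
    pooled = encode_graph(g, params, cfg)
    layer = sage_layer(
        g,
        g.node_features,
        params["enc.layer0.W_self"].value,
        params["enc.layer0.W_neigh"].value,
        params["enc.layer0.b"].value,
        activation=lambda x: np.maximum(x, 0.0),
        l2_normalize=True,
    )
    assert pooled == pytest.approx(layer[0])


def test_pooling_invariant_to_disjoint_duplication(rng):
    g = random_graph(7, rng, f=5)
    cfg = ModelConfig(hidden_dim=8, seed=1)
    params = init_params(cfg, 5)
    single = encode_graph(g, params, cfg)
    double = ProteinGraph(
        np.vstack([g.node_features, g.node_features]),
        np.vstack([g.edges, g.edges + 7]),
        np.concatenate([g.edge_weights, g.edge_weights]),
    )
    assert encode_graph(double, params, cfg) == pytest.approx(single, abs=1e-12)


def test_encode_empty_graph_raises():
    g = ProteinGraph(np.empty((0, 5)), np.empty((0, 2)), np.empty(0))
    cfg = ModelConfig()
    with pytest.raises(ValueError):
        encode_graph(g, init_params(cfg, 5), cfg)


def test_batched_forward_matches_single(rng):
    cfg = ModelConfig(hidden_dim=8, seed=5)
    params = init_params(cfg, 6)
    graphs = [random_graph(int(rng.integers(3, 15)), rng, f=6) for _ in range(8)]
    batch = net.make_batch([net.pack_graph(g, cfg) for g in graphs])
    pooled = net.encode_batch(batch, params, cfg, "enc").value
    for k, g in enumerate(graphs):
        assert np.array_equal(pooled[k], encode_graph(g, params, cfg))


# ---------------------------------------------------------------------------
# sharing, combiners, determinism
# ---------------------------------------------------------------------------


def test_shared_paths_are_bit_identical(rng):
    cfg = ModelConfig(share_weights=True, seed=2)
    params = init_params(cfg, 6)
    g = random_graph(9, rng, f=6)
    assert np.array_equal(
        encode_graph(g, params, cfg, "enc"), encode_graph(g, params, cfg, "enc")
    )
    # mutating the shared parameters changes both paths (same objects)
    pw, pm = net.encoder_prefixes(cfg)
    assert pw == pm == "enc"


def test_unshared_paths_differ(rng):
    cfg = ModelConfig(share_weights=False, seed=2)
    params = init_params(cfg, 6)
    g = random_graph(9, rng, f=6)
    a = encode_graph(g, params, cfg, "enc_w")
    b = encode_graph(g, params, cfg, "enc_m")
    assert not np.allclose(a, b)


def test_shared_conv_parameter_count_is_half():
    shared = init_params(ModelConfig(share_weights=True), 20)
    unshared = init_params(ModelConfig(share_weights=False), 20)
    assert count_parameters(unshared, "enc") == 2 * count_parameters(shared, "enc")
    # head is identical in both configurations
    assert count_parameters(unshared, "head") == count_parameters(shared, "head")


def test_diff_combiner_antisymmetric_with_zero_bias(rng):
    cfg = ModelConfig(combiner="diff", dropout=0.0, seed=4)
    params = init_params(cfg, 6)
    zero_head_biases(params)
    for _ in range(10):
        gw = random_graph(int(rng.integers(3, 12)), rng, f=6)
        gm = random_graph(int(rng.integers(3, 12)), rng, f=6)
        fwd = predict_ddg(gw, gm, params, cfg)
        bwd = predict_ddg(gm, gw, params, cfg)
        assert fwd == pytest.approx(-bwd, abs=1e-12)


def test_diff_combiner_pair_sum_is_twice_head_of_zero(rng):
    cfg = ModelConfig(combiner="diff", dropout=0.0, seed=4)
    params = init_params(cfg, 6)  # biases left at their trained/initial values
    gw = random_graph(8, rng, f=6)
    gm = random_graph(5, rng, f=6)
    same = predict_ddg(gw, gw, params, cfg)  # z = 0 for identical graphs
    assert predict_ddg(gw, gm, params, cfg) + predict_ddg(gm, gw, params, cfg) == pytest.approx(
        2 * same, abs=1e-12
    )


def test_inference_is_deterministic(rng):
    cfg = ModelConfig(dropout=0.5, seed=6)  # dropout must not act at inference
    params = init_params(cfg, 6)
    gw = random_graph(10, rng, f=6)
    gm = random_graph(11, rng, f=6)
    assert predict_ddg(gw, gm, params, cfg) == predict_ddg(gw, gm, params, cfg)


def test_checkpoint_round_trip_and_byte_determinism(tmp_path):
    cfg = ModelConfig(seed=8)
    params = init_params(cfg, 20)
    p1, p2 = tmp_path / "a.npz", tmp_path / "b.npz"
    save_checkpoint(p1, params, cfg, 20)
    save_checkpoint(p2, params, cfg, 20)
    assert p1.read_bytes() == p2.read_bytes()
    loaded, cfg2, in_dim = load_checkpoint(p1)
    assert cfg2 == cfg and in_dim == 20
    for k in params:
        assert np.array_equal(loaded[k].value, params[k].value)
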