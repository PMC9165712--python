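"""Nested graph structure, baselines, pruning, ensembling, parameter counts."""

import numpy as np
import pytest

from conftest import zero_parameters
from r2upp.blocks import ConfigurationError
from r2upp.network import (
    NetworkConfig,
    NodeId,
    build_baseline,
    build_r2upp,
    count_parameters,
    ensemble_predict,
    extract_pruned,
    load_checkpoint,
    node_inputs,
    save_checkpoint,
    skip_blocks_between,
    summary_dict,
    summary_text,
)


# ---------------------------------------------------------------------------
# analytic parameter-count oracle (independent closed-form enumeration)
# ---------------------------------------------------------------------------


def conv_params(cin, cout, k):
    return k * k * cin * cout + cout


def bn_params(c):
    return 2 * c


def rcl_params(cin, cout, t):
    return (
        conv_params(cin, cout, 3)
        + (t - 1) * conv_params(cout, cout, 3)
        + t * bn_params(cout)
    )


def rrcl_params(cin, f, t):
    total = rcl_params(cin, f, t) + rcl_params(f, f, t)
    if cin != f:
        total += conv_params(cin, f, 1)
    return total


def expected_nested_params(filters, t, in_ch=1, n_classes=1, deep_supervision=True):
    depth = len(filters) - 1
    total = 0
    for m in range(depth + 1):
        for n in range(depth - m + 1):
            cin = in_ch if (m, n) == (0, 0) else (filters[m - 1] if n == 0 else (n + 1) * filters[m])
            total += rrcl_params(cin, filters[m], t)
            if n > 0:  # transposed-conv up edge
                total += 4 * filters[m + 1] * filters[m] + filters[m]
    heads = depth if deep_supervision else 1
    total += heads * (filters[0] * n_classes + n_classes)
    return total


def test_node_inputs_examples():
    assert node_inputs(NodeId(0, 2), 4) == [
        ("same", NodeId(0, 0)),
        ("same", NodeId(0, 1)),
        ("up", NodeId(1, 1)),
    ]
    assert node_inputs(NodeId(0, 0), 4) == [("input", None)]
    assert node_inputs(NodeId(3, 1), 4) == [("same", NodeId(3, 0)), ("up", NodeId(4, 0))]
    assert node_inputs(NodeId(2, 0), 4) == [("down", NodeId(1, 0))]
    with pytest.raises(ConfigurationError):
        node_inputs(NodeId(3, 2), 4)


@pytest.mark.parametrize(
    "encoder,decoder,expected",
    [((0, 0), (0, 4), 3), ((0, 0), (0, 1), 0), ((1, 0), (1, 3), 2)],
)
def test_skip_blocks_between(encoder, decoder, expected):
    assert skip_blocks_between(NodeId(*encoder), NodeId(*decoder)) == expected


@pytest.mark.parametrize("depth,filters", [(2, (4, 8, 16)), (3, (4, 8, 16, 32))])
def test_node_count_and_channel_bookkeeping(depth, filters):
    net = build_r2upp(NetworkConfig(depth=depth, base_filters=filters, time_steps=1))
    assert len(net.nodes) == (depth + 1) * (depth + 2) // 2
    for node, block in net.nodes.items():
        m, n = node
        expected_in = 1 if node == (0, 0) else (filters[m - 1] if n == 0 else (n + 1) * filters[m])
        assert block.cfg.rcl1.in_channels == expected_in
        assert block.cfg.rcl2.out_channels == filters[m]


def test_forward_shapes_and_range(small_net):
    x = np.random.default_rng(0).random((2, 16, 16)).astype(np.float32)
    heads = small_net.predict_proba(x)
    assert sorted(heads) == [1, 2]
    for out in heads.values():
        assert out.shape == (2, 1, 16, 16)
        assert out.min() >= 0.0 and out.max() <= 1.0


def test_indivisible_input_raises(small_net):
    with pytest.raises(ConfigurationError, match="divisible by 2\\^depth"):
        small_net.predict_proba(np.zeros((18, 16), dtype=np.float32))


@pytest.mark.parametrize("level", [1, 2])
def test_pruned_submodel_matches_parent_head(small_net, level):
    """The embedded depth-q model must reproduce head q bit-for-bit in eval mode."""
    x = np.random.default_rng(level).random((1, 16, 16)).astype(np.float32)
    parent = small_net.predict_proba(x)[level]
    pruned = extract_pruned(small_net, level)
    np.testing.assert_array_equal(pruned.predict_proba(x)[level], parent)


def test_pruned_level_one_runs_three_nodes(small_cfg):
    net = build_r2upp(small_cfg, seed=1)
    pruned = extract_pruned(net, 1)
    x = np.random.default_rng(0).random((1, 16, 16)).astype(np.float32)
    feats = net._run_graph(net._as_batch(x), 1)
    assert set(feats) == {NodeId(0, 0), NodeId(1, 0), NodeId(0, 1)}
    assert pruned.head_levels() == [1]


def test_extract_pruned_out_of_range(small_net):
    with pytest.raises(ConfigurationError):
        extract_pruned(small_net, 5)


def test_ensemble_is_mean_of_heads(small_net):
    x = np.random.default_rng(7).random((2, 16, 16)).astype(np.float32)
    heads = small_net.predict_proba(x)
    manual = np.mean([heads[q] for q in sorted(heads)], axis=0)
    np.testing.assert_allclose(ensemble_predict(small_net, x), manual, rtol=0, atol=0)


def test_single_head_without_deep_supervision():
    cfg = NetworkConfig(depth=2, base_filters=(4, 8, 16), deep_supervision=False)
    net = build_r2upp(cfg)
    assert net.head_levels() == [2]
    heads = net.predict_proba(np.zeros((16, 16), dtype=np.float32))
    assert list(heads) == [2]


def test_parameter_count_matches_analytic_enumeration():
    filters = (4, 8, 16)
    for t in (1, 2):
        net = build_r2upp(NetworkConfig(depth=2, base_filters=filters, time_steps=t))
        assert count_parameters(net) == expected_nested_params(filters, t)


def test_parameter_count_orderings():
    f = (4, 8, 16)
    t1 = count_parameters(build_r2upp(NetworkConfig(depth=2, base_filters=f, time_steps=1)))
    t2 = count_parameters(build_r2upp(NetworkConfig(depth=2, base_filters=f, time_steps=2)))
    assert t2 > t1
    unet = count_parameters(build_baseline("unet", NetworkConfig(depth=2, base_filters=f)))
    unetpp = count_parameters(build_baseline("unetpp", NetworkConfig(depth=2, base_filters=f)))
    assert unetpp > unet


def test_summary_components_sum_to_total(small_net):
    d = summary_dict(small_net)
    assert sum(r["params"] for r in d["components"]) == d["total_params"] == count_parameters(small_net)
    assert "total params" in summary_text(small_net)


def test_baseline_topologies():
    cfg = NetworkConfig(depth=2, base_filters=(4, 8, 16), deep_supervision=False)
    for kind in ("unet", "r2unet"):
        net = build_baseline(kind, cfg)
        heads = net.predict_proba(np.zeros((16, 16), dtype=np.float32))
        assert list(heads) == [2]
    with pytest.raises(ConfigurationError):
        build_baseline("segnet", cfg)


def test_checkpoint_round_trip(tmp_path, small_cfg):
    net = build_r2upp(small_cfg, seed=5)
    x = np.random.default_rng(0).random((1, 16, 16)).astype(np.float32)
    before = net.predict_proba(x)
    path = tmp_path / "model.npz"
    save_checkpoint(net, path)
    restored = load_checkpoint(path)
    after = restored.predict_proba(x)
    for q in before:
        np.testing.assert_array_equal(before[q], after[q])


def test_zeroed_network_predicts_half(small_cfg):
    net = build_r2upp(small_cfg, seed=2)
    zero_parameters(net)
    heads = net.predict_proba(np.random.default_rng(0).random((16, 16)).astype(np.float32))
    for out in heads.values():
        np.testing.assert_allclose(out, 0.5, atol=1e-7)


def test_config_validation():
    with pytest.raises(ConfigurationError):
        NetworkConfig(depth=2, base_filters=(4, 8))
    with pytest.raises(ConfigurationError):
        NetworkConfig(num_classes=0)
    with pytest.raises(ConfigurationError):
        NetworkConfig(upsample="bicubic")
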