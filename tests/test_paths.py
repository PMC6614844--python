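import itertools
import math

import numpy as np
import pytest

from signalflip.errors import InputError, ParameterError
from signalflip.network import SignedEdge, SignedNetwork
from signalflip.paths import (
    NodeProbabilities,
    ScoredGraph,
    edge_weights,
    molecule_profiles,
    mpp,
    path_sign,
)

from conftest import random_signed_network

SIG = "Phosphorylation"


def net_of(edges):
    net = SignedNetwork(kind="signalling")
    for u, v, s in edges:
        net.add_edge(SignedEdge(u, v, s, SIG))
    return net


def brute_force_mpp(graph: ScoredGraph, source: str, target: str):
    """Exhaustive simple-path enumeration, accumulating costs exactly as the
    search does (left-associated sums of the same per-edge floats)."""
    length_penalty = 1.0 if graph.variant == "length" else 0.0
    best = None
    stack = [(source, (source,), 0.0, 1)]
    while stack:
        node, path, cost, sign = stack.pop()
        if node == target:
            key = (cost, len(path) - 1, path)
            if best is None or key < best[0]:
                best = (key, sign)
            continue
        for v, (edge_cost, edge_sign, _) in sorted(graph.adj.get(node, {}).items()):
            if v in path:
                continue
            if v == target:
                step = length_penalty
            else:
                if edge_cost == math.inf or graph.probs[v] == 0.0:
                    continue
                step = edge_cost + length_penalty
            stack.append((v, path + (v,), cost + step, sign * edge_sign))
    if best is None:
        return None
    (cost, n_edges, path), sign = best
    return math.exp(-cost), sign, path


class TestEdgeWeights:
    def test_no_correlation_table_base_contributions(self):
        net = net_of([("a", "b", 1)])
        probs = NodeProbabilities({"a": 0.9, "b": 0.4})
        g = edge_weights(net, probs, "correlation")
        cost, sign, tie = g.adj["a"]["b"]
        assert math.exp(-cost) == pytest.approx(0.4) and sign == 1 and not tie

    def test_matching_correlation_boosts(self):
        net = net_of([("a", "b", 1)])
        probs = NodeProbabilities({"a": 0.9, "b": 0.4})
        g = edge_weights(net, probs, "correlation", correlations={("a", "b"): 0.9})
        cost, _, _ = g.adj["a"]["b"]
        assert math.exp(-cost) == pytest.approx(0.9)

    def test_sign_mismatch_no_boost(self):
        net = net_of([("a", "b", 1)])
        probs = NodeProbabilities({"a": 0.9, "b": 0.4})
        g = edge_weights(net, probs, "correlation", correlations={("a", "b"): -0.9})
        cost, _, _ = g.adj["a"]["b"]
        assert math.exp(-cost) == pytest.approx(0.4)

    def test_below_threshold_no_boost(self):
        net = net_of([("a", "b", 1)])
        probs = NodeProbabilities({"a": 0.9, "b": 0.4})
        g = edge_weights(net, probs, "correlation", correlations={("a", "b"): 0.6})
        cost, _, _ = g.adj["a"]["b"]
        assert math.exp(-cost) == pytest.approx(0.4)

    def test_sign_zero_edges_dropped(self):
        net = net_of([("a", "b", 0)])
        g = edge_weights(net, NodeProbabilities({}), "correlation")
        assert g.adj == {}

    def test_parallel_opposite_sign_tie_prefers_activation(self):
        net = net_of([("a", "b", 1), ("a", "b", -1)])
        g = edge_weights(net, NodeProbabilities({"b": 0.5}), "correlation")
        cost, sign, tie = g.adj["a"]["b"]
        assert sign == 1 and tie

    def test_bad_variant_errors(self):
        with pytest.raises(ParameterError):
            edge_weights(net_of([]), NodeProbabilities({}), "nope")

    def test_bad_probability_errors(self):
        with pytest.raises(ParameterError):
            NodeProbabilities({"a": 1.5})


class TestMPP:
    def test_direct_edge_probabilities(self):
        net = net_of([("x", "y", 1)])
        probs = NodeProbabilities({"x": 0.9, "y": 0.2})
        corr = mpp(edge_weights(net, probs, "correlation"), "x", "y")
        length = mpp(edge_weights(net, probs, "length"), "x", "y")
        assert corr.probability == pytest.approx(1.0)  # no intermediates
        assert length.probability == pytest.approx(math.exp(-1))

    def test_variant_disagreement_example(self):
        # 2-hop through p=0.8 vs 3-hop through 0.95*0.95
        net = net_of([("x", "a", 1), ("a", "y", 1), ("x", "b", 1), ("b", "c", 1), ("c", "y", 1)])
        probs = NodeProbabilities({"a": 0.8, "b": 0.95, "c": 0.95, "x": 1.0, "y": 1.0})
        corr = mpp(edge_weights(net, probs, "correlation"), "x", "y")
        assert corr.path == ("x", "b", "c", "y")
        assert corr.probability == pytest.approx(0.9025, abs=1e-12)
        length = mpp(edge_weights(net, probs, "length"), "x", "y")
        assert length.path == ("x", "a", "y")
        assert length.probability == pytest.approx(0.8 * math.exp(-2), abs=1e-12)

    def test_unreachable_returns_none(self):
        net = net_of([("x", "a", 1), ("y", "b", 1)])
        assert mpp(edge_weights(net, NodeProbabilities({}), "correlation"), "x", "y") is None

    def test_zero_probability_intermediate_blocks(self):
        net = net_of([("x", "a", 1), ("a", "y", 1)])
        probs = NodeProbabilities({"a": 0.0})
        assert mpp(edge_weights(net, probs, "correlation"), "x", "y") is None

    def test_source_equals_target_errors(self):
        net = net_of([("x", "y", 1)])
        with pytest.raises(InputError):
            mpp(edge_weights(net, NodeProbabilities({}), "correlation"), "x", "x")

    def test_sign_is_product_of_edge_signs(self):
        net = net_of([("x", "a", -1), ("a", "b", -1), ("b", "y", -1)])
        res = mpp(edge_weights(net, NodeProbabilities({}, default=0.9), "correlation"), "x", "y")
        assert res.sign == -1
        assert path_sign(res.path, edge_weights(net, NodeProbabilities({}, default=0.9), "correlation")) == -1

    @pytest.mark.parametrize("variant", ["correlation", "length"])
    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_on_random_graphs(self, seed, variant):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        net = random_signed_network(rng, n, int(rng.integers(n, 3 * n)))
        probs = NodeProbabilities(
            {f"N{i}": float(rng.uniform(0.05, 1.0)) for i in range(n)}
        )
        graph = edge_weights(net, probs, variant)
        nodes = sorted(net.nodes)
        for source, target in itertools.islice(
            itertools.permutations(nodes, 2), 20
        ):
            got = mpp(graph, source, target)
            expected = brute_force_mpp(graph, source, target)
            if expected is None:
                assert got is None
            else:
                prob, sign, path = expected
                assert got.probability == pytest.approx(prob, abs=1e-12)
                assert got.sign == sign
                assert got.path == path

    def test_length_variant_is_exp_minus_n_times_plain_score(self):
        net = net_of([("x", "a", 1), ("a", "b", -1), ("b", "y", 1)])
        probs = NodeProbabilities({"a": 0.7, "b": 0.6})
        corr = mpp(edge_weights(net, probs, "correlation"), "x", "y")
        length = mpp(edge_weights(net, probs, "length"), "x", "y")
        n = len(length.path) - 1
        assert length.probability == pytest.approx(
            corr.probability * math.exp(-n), rel=1e-12
        )

    def test_raising_intermediate_probability_never_hurts(self):
        net = net_of([("x", "a", 1), ("a", "y", 1), ("x", "b", 1), ("b", "y", 1)])
        for pa in (0.2, 0.5, 0.9):
            low = mpp(
                edge_weights(net, NodeProbabilities({"a": pa, "b": 0.5}), "correlation"),
                "x", "y",
            )
            high = mpp(
                edge_weights(net, NodeProbabilities({"a": pa + 0.05, "b": 0.5}), "correlation"),
                "x", "y",
            )
            assert high.probability >= low.probability - 1e-15


class TestMoleculeProfiles:
    def test_two_target_normalization_and_sign_flip(self):
        net = net_of([("x", "a", 1), ("a", "y", 1), ("x", "b", -1), ("b", "z", 1)])
        probs = NodeProbabilities({"a": 0.8, "b": 0.2})
        graph = edge_weights(net, probs, "correlation")
        act, inh = molecule_profiles(graph, "x", ["y", "z"])
        assert act.p[("y", 1)] == pytest.approx(0.8)
        assert act.p[("z", 0)] == pytest.approx(0.2)
        assert inh.p[("y", 0)] == pytest.approx(0.8)
        assert inh.p[("z", 1)] == pytest.approx(0.2)

    def test_single_target_degenerate(self):
        net = net_of([("x", "y", 1)])
        graph = edge_weights(net, NodeProbabilities({}), "correlation")
        act, _ = molecule_profiles(graph, "x", ["y"])
        assert act.p == {("y", 1): 1.0}

    def test_unreachable_gives_empty_profiles(self):
        net = net_of([("x", "a", 1)])
        graph = edge_weights(net, NodeProbabilities({}), "correlation")
        act, inh = molecule_profiles(graph, "x", ["y"])
        assert act.empty and inh.empty

    @pytest.mark.parametrize("seed", range(10))
    def test_profiles_sum_to_one_and_are_complementary(self, seed):
        rng = np.random.default_rng(seed)
        net = random_signed_network(rng, 10, 25)
        probs = NodeProbabilities(
            {f"N{i}": float(rng.uniform(0.1, 1.0)) for i in range(10)}
        )
        graph = edge_weights(net, probs, "correlation")
        tfs = ["N7", "N8", "N9"]
        for mol in ("N0", "N1", "N2"):
            act, inh = molecule_profiles(graph, mol, tfs)
            if act.empty:
                assert inh.empty
                continue
            assert sum(act.p.values()) == pytest.approx(1.0, abs=1e-12)
            assert sum(inh.p.values()) == pytest.approx(1.0, abs=1e-12)
            for (tf, state), p in act.p.items():
                assert inh.p[(tf, 1 - state)] == p
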