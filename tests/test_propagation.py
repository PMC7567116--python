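"""Node scoring, the diffusion kernel, subnetwork extraction, consensus."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from actnet.longitudinal import DynamicFit
from actnet.propagation import (
    DrugSubnetwork,
    NodeScoreVector,
    PropagationConfig,
    build_consensus,
    build_transition,
    derive_delta_candidates,
    diffuse,
    extract_subnetworks,
    integrate_scores,
    score_nodes,
    subnetworks_at_all_deltas,
)


def _fit(feature, p=(0.5, 0.5, 0.5), dynamic=True, failed=False):
    return DynamicFit(
        feature=feature, beta_C=(0, 0, 0), beta_TvsC=(0, 0, 0),
        p_TvsC=p, global_p=0.01, r_squared=0.9, n_obs=42,
        residual_sd=0.1, is_dynamic=dynamic, failed=failed,
    )


class TestScoreNodes:
    def test_log10_sum(self):
        fits = {"a": _fit("a", p=(0.1, 0.01, 0.001))}
        sv = score_nodes(fits, ("DOX", "therapeutic", "proteome"))
        assert sv.scores["a"] == pytest.approx(6.0)

    def test_non_dynamic_scores_zero(self):
        fits = {"a": _fit("a", p=(1e-10, 1e-10, 1e-10), dynamic=False)}
        sv = score_nodes(fits, ("DOX", "therapeutic", "proteome"))
        assert sv.scores["a"] == 0.0

    def test_all_p_one_scores_zero(self):
        fits = {"a": _fit("a", p=(1.0, 1.0, 1.0))}
        assert score_nodes(fits, ("d", "x", "y")).scores["a"] == pytest.approx(0.0)

    def test_invalid_p_raises(self):
        fits = {"a": _fit("a", p=(0.0, 0.5, 0.5))}
        with pytest.raises(ValueError):
            score_nodes(fits, ("d", "x", "y"))


class TestIntegrateScores:
    def test_sum_and_single_layer_passthrough(self):
        prot = NodeScoreVector({"a": 6.0, "b": 3.0}, ("DOX", "th", "proteome"))
        rna = NodeScoreVector({"a": 2.0, "c": 1.0}, ("DOX", "th", "transcriptome"))
        merged = integrate_scores(prot, rna)
        assert merged.scores == {"a": 8.0, "b": 3.0, "c": 1.0}
        assert merged.stratum == ("DOX", "th", "integrated")

    def test_stratum_mismatch_raises(self):
        prot = NodeScoreVector({}, ("DOX", "th", "proteome"))
        rna = NodeScoreVector({}, ("EPI", "th", "transcriptome"))
        with pytest.raises(ValueError):
            integrate_scores(prot, rna)


class TestBuildTransition:
    def test_path_graph_columns(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        W, nodes = build_transition(g)
        W = W.toarray()
        j = nodes.index("b")
        assert W[nodes.index("a"), j] == pytest.approx(0.5)
        assert W[nodes.index("c"), j] == pytest.approx(0.5)
        assert np.allclose(W.sum(axis=0), 1.0)

    def test_two_clique(self):
        W, _ = build_transition(nx.Graph([("a", "b")]))
        assert np.allclose(W.toarray(), [[0, 1], [1, 0]])

    def test_isolated_node_dropped(self):
        g = nx.Graph([("a", "b")])
        g.add_node("loner")
        W, nodes = build_transition(g)
        assert "loner" not in nodes

    def test_empty_graph_raises(self):
        with pytest.raises(ValueError):
            build_transition(nx.empty_graph(3))


class TestDiffuse:
    def test_two_clique_closed_form(self):
        # F = b (I - (1-b) W)^-1 with W=[[0,1],[1,0]], b=0.5:
        # (I - 0.5 W)^-1 = (1/0.75) [[1, .5], [.5, 1]] -> F = [[2/3,1/3],[1/3,2/3]]
        W, nodes = build_transition(nx.Graph([("a", "b")]))
        sv = NodeScoreVector({"a": 1.0, "b": 1.0}, ("d", "x", "y"))
        E = diffuse(W, nodes, sv, restart_prob=0.5)
        assert np.allclose(E, [[2 / 3, 1 / 3], [1 / 3, 2 / 3]])

    def test_zero_scores_zero_heat(self):
        W, nodes = build_transition(nx.path_graph(5))
        sv = NodeScoreVector({}, ("d", "x", "y"))
        E = diffuse(W, nodes, sv)
        assert np.allclose(E, 0.0)

    def test_column_sums_equal_scores(self, rng):
        g = nx.gnp_random_graph(50, 0.1, seed=5)
        g.remove_nodes_from(list(nx.isolates(g)))
        W, nodes = build_transition(g)
        scores = {n: float(rng.random()) for n in nodes}
        E = diffuse(W, nodes, NodeScoreVector(scores, ("d", "x", "y")), 0.4)
        expected = np.array([scores[n] for n in nodes])
        assert np.allclose(E.sum(axis=0), expected, atol=1e-10)

    def test_dense_and_sparse_agree(self, rng):
        g = nx.gnp_random_graph(80, 0.08, seed=6)
        g.remove_nodes_from(list(nx.isolates(g)))
        W, nodes = build_transition(g)
        sv = NodeScoreVector({n: float(rng.random()) for n in nodes}, ("d", "x", "y"))
        E_dense = diffuse(W, nodes, sv, 0.4, dense_limit=10_000)
        E_sparse = diffuse(W, nodes, sv, 0.4, dense_limit=1)
        assert np.max(np.abs(E_dense - E_sparse)) < 1e-8

    def test_locality_geometric_decay(self):
        """Single source on a path: heat at distance d <= (1-b)^d * score."""
        g = nx.path_graph(10)
        W, nodes = build_transition(g)
        beta = 0.4
        sv = NodeScoreVector({0: 1.0}, ("d", "x", "y"))
        E = diffuse(W, nodes, sv, beta)
        j = nodes.index(0)
        for d in range(1, 10):
            i = nodes.index(d)
            assert E[i, j] <= (1 - beta) ** d + 1e-12

    def test_scores_off_network_dropped(self):
        W, nodes = build_transition(nx.Graph([("a", "b")]))
        sv = NodeScoreVector({"a": 1.0, "ghost": 5.0}, ("d", "x", "y"))
        E = diffuse(W, nodes, sv, 0.5)
        assert E.sum() == pytest.approx(1.0)  # ghost's heat not injected


class TestExtractSubnetworks:
    def _setup(self, rng, n=40):
        g = nx.gnp_random_graph(n, 0.15, seed=int(rng.integers(1e6)))
        g.remove_nodes_from(list(nx.isolates(g)))
        W, nodes = build_transition(g)
        scores = {v: float(rng.random() * 5) for v in nodes}
        E = diffuse(W, nodes, NodeScoreVector(scores, ("d", "x", "y")), 0.4)
        return E, nodes

    def test_huge_delta_empty(self, rng):
        E, nodes = self._setup(rng)
        cfg = PropagationConfig(delta_candidates=(float(E.max() + 1),))
        sub = extract_subnetworks(E, nodes, cfg)
        assert sub.nodes == set()

    def test_tiny_delta_all_connected_nodes(self, rng):
        E, nodes = self._setup(rng)
        cfg = PropagationConfig(delta_candidates=(1e-12,))
        sub = extract_subnetworks(E, nodes, cfg)
        assert sub.nodes == set(nodes)

    def test_minimal_delta_chosen(self, rng):
        E, nodes = self._setup(rng)
        sub = extract_subnetworks(E, nodes)
        assert sub.chosen_delta == min(sub.delta_candidates)
        assert len(sub.delta_candidates) == 4

    @pytest.mark.parametrize("trial", range(5))
    def test_delta_monotonicity(self, rng, trial):
        E, nodes = self._setup(rng)
        by_delta = subnetworks_at_all_deltas(E, nodes)
        deltas = sorted(by_delta)
        for lo, hi in zip(deltas, deltas[1:]):
            assert by_delta[hi] <= by_delta[lo]

    def test_component_size_floor(self, rng):
        E, nodes = self._setup(rng)
        sub = extract_subnetworks(E, nodes)
        if sub.nodes:
            g = nx.DiGraph(list(sub.edges))
            for comp in nx.strongly_connected_components(g):
                assert len(comp) >= 3


class TestBuildConsensus:
    def _sub(self, drug, nodes, edges):
        return DrugSubnetwork(
            drug=drug, dose="th", nodes=set(nodes),
            edges={tuple(e) for e in edges},
            chosen_delta=0.1, delta_candidates=(0.1,),
        )

    def test_single_occurrence_excluded(self):
        subs = [
            self._sub("d1", ["a", "b"], [("a", "b")]),
            self._sub("d2", ["a", "b"], [("a", "b")]),
            self._sub("d3", ["c", "d"], [("c", "d")]),
            self._sub("d4", ["x", "y"], [("x", "y")]),
        ]
        cons = build_consensus(subs)
        assert cons.nodes == {"a", "b"}
        assert "c" not in cons.nodes  # appears only once

    def test_identical_subnetworks(self):
        subs = [self._sub(f"d{i}", ["a", "b", "c"], [("a", "b"), ("b", "c")]) for i in range(4)]
        cons = build_consensus(subs)
        assert cons.nodes == {"a", "b", "c"}
        assert set(cons.node_occurrence.values()) == {4}
        assert set(cons.edge_occurrence.values()) == {4}

    def test_against_brute_force_counts(self, rng):
        universe = [f"n{i}" for i in range(12)]
        subs = []
        for i in range(4):
            nodes = list(rng.choice(universe, size=6, replace=False))
            edges = set()
            for _ in range(6):
                a, b = rng.choice(nodes, size=2, replace=False)
                edges.add(tuple(sorted((a, b))))
            subs.append(self._sub(f"d{i}", nodes, edges))
        cons = build_consensus(subs, min_occurrence=2)
        # brute force over every node and undirected edge
        for v in universe:
            count = sum(v in s.nodes for s in subs)
            assert (v in cons.nodes) == (count >= 2)
        all_edges = {tuple(sorted(e)) for s in subs for e in s.edges}
        for e in all_edges:
            count = sum(tuple(sorted(e)) in {tuple(sorted(x)) for x in s.edges} for s in subs)
            expected = count >= 2 and e[0] in cons.nodes and e[1] in cons.nodes
            assert (e in cons.edges) == expected

    def test_consensus_subset_of_union(self, rng):
        subs = [
            self._sub(f"d{i}", rng.choice(20, size=8, replace=False).tolist(), [])
            for i in range(4)
        ]
        cons = build_consensus(subs)
        union = set().union(*(s.nodes for s in subs))
        assert cons.nodes <= union

    def test_too_few_subnetworks_raise(self):
        with pytest.raises(ValueError):
            build_consensus([self._sub("d1", ["a"], [])], min_occurrence=2)


def test_derive_delta_candidates_sorted_positive(rng):
    E = np.abs(rng.normal(size=(30, 30)))
    deltas = derive_delta_candidates(E)
    assert list(deltas) == sorted(deltas)
    assert all(d > 0 for d in deltas)
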