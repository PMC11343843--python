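"""Naive-network construction and sign-coherent ILP optimization."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from oracles import brute_force_optimize, random_ilp_instance
from signaflow.network import (ILPInstance, NaiveNetwork, SignalingModel,
                               build_naive_network, ilp_optimize,
                               run_multishot, validate_edges_with_phospho)
from signaflow.pkn import CausalEdge, PKNGraph


def graph_from(edges):
    g = nx.DiGraph()
    for u, v, s in edges:
        g.add_edge(u, v, sign=s, mechanism="", residue="")
    return g


def activities_frame(mapping):
    return pd.DataFrame([{"gene_name": g, "mf": mf, "final_score": 1.0,
                          "activity": 1, "p_value": 0.01,
                          "method": "footprint", "flags": ""}
                         for g, mf in mapping.items()])


def layered_pkn():
    edges = [CausalEdge("S", "K1", 1), CausalEdge("S", "X", 1),
             CausalEdge("X", "K2", -1), CausalEdge("K1", "O1", 1),
             CausalEdge("K2", "O1", -1), CausalEdge("O1", "T1", 1),
             CausalEdge("K1", "T1", -1)]
    attrs = {"S": {"molecular_function": "OTHER", "entity_type": "protein"},
             "K1": {"molecular_function": "KIN", "entity_type": "protein"},
             "K2": {"molecular_function": "KIN", "entity_type": "protein"},
             "X": {"molecular_function": "OTHER", "entity_type": "protein"},
             "O1": {"molecular_function": "OTHER", "entity_type": "protein"},
             "T1": {"molecular_function": "TF", "entity_type": "protein"}}
    return PKNGraph(edges=edges, node_attrs=attrs)


class TestBuildNaiveNetwork:
    acts = activities_frame({"K1": "KIN", "K2": "KIN", "O1": "OTHER",
                             "T1": "TF"})

    def test_direct_edge_within_max_len(self):
        naive = build_naive_network(layered_pkn(), ["S"], self.acts,
                                    layout="three", max_len=1)
        assert naive.graph.has_edge("S", "K1")

    def test_two_hop_path_needs_max_len_two(self):
        short = build_naive_network(layered_pkn(), ["S"], self.acts,
                                    layout="three", max_len=1)
        assert "X" not in short.graph  # S -> X -> K2 needs two hops
        longer = build_naive_network(layered_pkn(), ["S"], self.acts,
                                     layout="three", max_len=2)
        assert longer.graph.has_edge("X", "K2")

    def test_connect_all_adds_cross_path_edge(self):
        base = build_naive_network(layered_pkn(), ["S"], self.acts,
                                   layout="three", max_len=2)
        # K1 -> T1 skips a layer: only reachable via connect_all
        assert not base.graph.has_edge("K1", "T1")
        full = build_naive_network(layered_pkn(), ["S"], self.acts,
                                   layout="three", max_len=2,
                                   connect_all=True)
        assert full.graph.has_edge("K1", "T1")
        assert full.graph.number_of_edges() == \
            base.graph.number_of_edges() + 1

    def test_empty_when_no_paths(self):
        acts = activities_frame({"T1": "TF"})
        pkn = PKNGraph(edges=[CausalEdge("A", "B", 1)],
                       node_attrs={"T1": {"molecular_function": "TF"}})
        naive = build_naive_network(pkn, ["A"], acts, layout="one")
        assert naive.graph.number_of_edges() == 0

    def test_layouts_assign_segments(self):
        for layout, n_seg in (("one", 1), ("two", 2), ("three", 3)):
            naive = build_naive_network(layered_pkn(), ["S"], self.acts,
                                        layout=layout, max_len=3)
            assert len(naive.segments) == n_seg


class TestILPOptimize:
    def test_coherent_chain_fully_selected(self):
        g = graph_from([("A", "B", 1), ("B", "C", 1)])
        m = ilp_optimize(g, ILPInstance(measured={"C": 1}, sources={"A": 1},
                                        beta=0.2))
        assert m.node_states == {"A": 1, "B": 1, "C": 1}
        assert m.graph.number_of_edges() == 2
        assert m.objective == pytest.approx(0.4)  # 2 edges * beta

    def test_mismatched_target_left_unexplained(self):
        g = graph_from([("A", "B", 1)])
        m = ilp_optimize(g, ILPInstance(measured={"B": -1}, sources={"A": 1},
                                        beta=0.2))
        # excluding the edge costs 1; including costs 2 + beta
        assert m.node_states["B"] == 0
        assert m.objective == pytest.approx(1.0)

    def test_inhibition_propagates_sign(self):
        g = graph_from([("A", "B", -1), ("B", "C", -1)])
        m = ilp_optimize(g, ILPInstance(measured={"C": 1}, sources={"A": 1},
                                        beta=0.1))
        assert m.node_states == {"A": 1, "B": -1, "C": 1}

    def test_vanilla_requires_source(self):
        g = graph_from([("A", "B", 1)])
        with pytest.raises(ValueError, match="source"):
            ilp_optimize(g, ILPInstance(measured={"B": 1}))

    def test_inverse_flavor_picks_sign_free_perturbation(self):
        g = graph_from([("R", "B", 1)])
        inst = ILPInstance(measured={"B": -1}, receptors={"R"}, beta=0.1)
        m = ilp_optimize(g, inst, flavor="inverse")
        # artificial node can inhibit R, making B = -1 reachable
        assert m.node_states["B"] == -1
        assert m.check_sign_coherence()

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            ILPInstance(measured={"B": 1}, sources={"A": 1}, beta=-0.5)

    @pytest.mark.parametrize("seed", range(25))
    def test_objective_equals_brute_force(self, seed):
        """ILP optimum matches exhaustive enumeration on random
        6-node / 8-edge instances."""
        edges, measured, sources, beta = random_ilp_instance(seed)
        g = graph_from(edges)
        inst = ILPInstance(measured=measured, sources=sources, beta=beta)
        model = ilp_optimize(g, inst)
        expected = brute_force_optimize(edges, measured, sources, beta)
        assert model.objective == pytest.approx(expected, abs=1e-9)
        assert model.check_sign_coherence()
        assert model.is_acyclic()

    def test_beta_monotonicity(self):
        """Raising the edge penalty never increases the edge count."""
        edges, measured, sources, _ = random_ilp_instance(3)
        g = graph_from(edges)
        counts = []
        for beta in (0.0, 0.1, 0.3, 0.6, 1.0, 2.5):
            m = ilp_optimize(g, ILPInstance(measured=measured,
                                            sources=sources, beta=beta))
            counts.append(m.graph.number_of_edges())
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestMultiShot:
    def chain_naive(self):
        seg1 = graph_from([("R", "K", 1)])
        seg2 = graph_from([("K", "O", -1)])
        g = nx.compose(seg1, seg2)
        layers = {"R": "source", "K": "kinase_phosphatase", "O": "other"}
        return NaiveNetwork(graph=g, layers=layers, segments=[seg1, seg2])

    def test_single_shot_reduces_to_plain_ilp(self):
        naive = self.chain_naive()
        inst = ILPInstance(measured={"K": 1, "O": -1}, sources={"R": 1},
                           beta=0.2)
        one = run_multishot(naive, inst, shots=1)
        direct = ilp_optimize(naive, inst)
        assert one.node_states == direct.node_states
        assert one.objective == pytest.approx(direct.objective)

    def test_multishot_recovers_pruned_downstream_layer(self):
        """A mid-layer mismatch prunes the single ILP; per-layer shots
        re-seed from the measured mid node and keep more of the model."""
        naive = self.chain_naive()
        inst = ILPInstance(measured={"K": -1, "O": 1}, sources={"R": 1},
                           beta=0.2)
        one = run_multishot(naive, inst, shots=1)
        three = run_multishot(naive, inst, shots=3)
        n_one = sum(1 for s in one.node_states.values() if s != 0)
        n_three = sum(1 for s in three.node_states.values() if s != 0)
        assert n_three >= n_one
        assert n_three == 3  # R, K (measured seed), O
        assert three.check_sign_coherence()
        assert three.is_acyclic()

    def test_disjoint_shots_union_without_conflicts(self):
        seg1 = graph_from([("R", "K", 1)])
        seg2 = graph_from([("K2", "O", 1)])
        g = nx.compose(seg1, seg2)
        naive = NaiveNetwork(graph=g, layers={}, segments=[seg1, seg2])
        inst = ILPInstance(measured={"K": 1, "K2": 1, "O": 1},
                           sources={"R": 1}, beta=0.1)
        m = run_multishot(naive, inst, shots=2)
        assert m.check_sign_coherence()


class TestPhosphoValidation:
    def test_sign_ratio_hand_count(self):
        # 10 edges, 3 matching sites, 2 significant -> SignRatio 0.2
        g = nx.DiGraph()
        for i in range(10):
            mech = "phosphorylation" if i < 5 else "binding"
            g.add_edge(f"U{i}", f"V{i}", sign=1, mechanism=mech,
                       residue=f"S{i}" if i < 5 else "")
        states = {n: 1 for n in g.nodes}
        model = SignalingModel(graph=g, node_states=states, objective=0.0)
        ph = pd.DataFrame({"gene_name": ["V0", "V1", "V2"],
                           "residue": ["S0", "S1", "S2"],
                           "difference": [1.0, 2.0, 3.0],
                           "significant": [True, True, False]})
        out = validate_edges_with_phospho(model, ph)
        assert out.sign_ratio == pytest.approx(0.2)
        flags = nx.get_edge_attributes(out.graph, "phospho_quantified")
        assert sum(flags.values()) == 3

    def test_non_ptm_edges_never_flagged(self):
        g = nx.DiGraph()
        g.add_edge("A", "B", sign=1, mechanism="binding", residue="")
        model = SignalingModel(graph=g, node_states={"A": 1, "B": 1},
                               objective=0.0)
        ph = pd.DataFrame({"gene_name": ["B"], "residue": [""],
                           "difference": [1.0], "significant": [True]})
        out = validate_edges_with_phospho(model, ph)
        assert not out.graph.edges["A", "B"]["phospho_quantified"]
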