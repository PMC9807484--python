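import math

import networkx as nx
import numpy as np
import pytest

from mirameta.impact import (AugmentedPathway, PathwayGraph, PerturbationInput,
                             augment_pathway, fisher_product_p, impact_analysis,
                             ora_p, propagate, read_pathways_tsv,
                             write_pathways_tsv)
from mirameta.interactions import RobustInteractionSet


def graph_from_edges(edges):
    g = nx.DiGraph()
    for src, dst, beta in edges:
        g.add_edge(src, dst, beta=float(beta),
                   relation="activation" if beta > 0 else "inhibition")
    return g


def pathway(edges, pid="pw"):
    return PathwayGraph(pid, pid, graph_from_edges(edges))


def robust_from_pairs(pairs):
    return RobustInteractionSet(pairs=set(pairs),
                                provenance={p: (frozenset(), frozenset()) for p in pairs})


def aug(edges):
    pw = pathway(edges)
    return AugmentedPathway(pw, set(), pw.graph)


def topological_propagation(g: nx.DiGraph, delta_e: dict) -> dict:
    """Independent oracle: accumulate PF in topological order (DAGs only)."""
    pf = {}
    for node in nx.topological_sort(g):
        upstream = sum(g.edges[u, node]["beta"] / g.out_degree(u) * pf[u]
                       for u in g.predecessors(node))
        pf[node] = delta_e.get(node, 0.0) + upstream
    return pf


class TestAugmentation:
    def test_only_on_pathway_targets_added(self):
        pw = pathway([("A", "B", 1), ("B", "C", -1)])
        robust = robust_from_pairs([("m1", "A"), ("m1", "B"), ("m2", "D")])
        a = augment_pathway(pw, robust)
        assert a.mirna_nodes == {"m1"}
        assert a.graph.has_edge("m1", "A") and a.graph.has_edge("m1", "B")
        assert "m2" not in a.graph
        assert a.graph.edges["m1", "A"]["beta"] == -1.0

    def test_empty_robust_set_identity(self):
        pw = pathway([("A", "B", 1)])
        a = augment_pathway(pw, robust_from_pairs([]))
        assert set(a.graph.edges) == set(pw.graph.edges)

    def test_idempotent(self):
        pw = pathway([("A", "B", 1)])
        robust = robust_from_pairs([("m1", "A"), ("m1", "A")])
        a1 = augment_pathway(pw, robust)
        a2 = augment_pathway(PathwayGraph(pw.pathway_id, pw.name, a1.graph), robust)
        assert set(a1.graph.edges) == set(a2.graph.edges)


class TestPropagation:
    def test_zero_input_zero_everything(self):
        a = aug([("A", "B", 1), ("B", "C", -1)])
        pf, acc, t_a, _ = propagate(a, {})
        assert all(v == 0 for v in pf.values()) and t_a == 0.0

    def test_chain_hand_example(self):
        a = aug([("m", "A", -1), ("A", "B", 1)])
        pf, acc, t_a, damped = propagate(a, {"m": 2.0})
        assert (pf["m"], pf["A"], pf["B"]) == (2.0, -2.0, -2.0)
        assert (acc["m"], acc["A"], acc["B"]) == (0.0, -2.0, -2.0)
        assert t_a == -4.0 and not damped

    def test_cycle_damped(self):
        a = aug([("A", "B", 1), ("B", "A", 1)])
        pf, _, _, damped = propagate(a, {"A": 1.0})
        assert damped
        assert pf["A"] == pytest.approx(1 / (1 - 0.81))
        assert pf["B"] == pytest.approx(0.9 / (1 - 0.81))

    def test_linearity_in_input(self):
        a = aug([("m", "A", -1), ("A", "B", 1), ("A", "C", -1)])
        pf1, _, t1, _ = propagate(a, {"m": 1.0})
        pf3, _, t3, _ = propagate(a, {"m": 3.0})
        assert t3 == pytest.approx(3 * t1, abs=1e-12)
        for n in pf1:
            assert pf3[n] == pytest.approx(3 * pf1[n], abs=1e-12)

    @pytest.mark.parametrize("seed", range(50))
    def test_dag_oracle(self, seed):
        """Linear solve matches topological-order propagation on random DAGs."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 25))
        nodes = [f"n{i}" for i in range(n)]
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        for i in range(1, n):
            for p in rng.choice(i, size=min(int(rng.integers(1, 3)), i), replace=False):
                g.add_edge(nodes[int(p)], nodes[i],
                           beta=float(rng.choice([1.0, -1.0])), relation="x")
        delta = {nodes[int(i)]: float(rng.normal())
                 for i in rng.choice(n, size=3, replace=False)}
        a = AugmentedPathway(PathwayGraph("t", "t", g), set(), g)
        pf, acc, t_a, damped = propagate(a, delta)
        assert not damped
        oracle = topological_propagation(g, delta)
        for node in nodes:
            assert pf[node] == pytest.approx(oracle[node], abs=1e-10)

    def test_unknown_node_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            propagate(aug([("A", "B", 1)]), {"zzz": 1.0})


class TestEnrichmentStats:
    def test_hypergeometric_example(self):
        assert ora_p(20, 5, 4, 3) == pytest.approx(155 / 4845, rel=1e-10)

    def test_zero_overlap_is_one(self):
        assert ora_p(20, 5, 4, 0) == pytest.approx(1.0)

    def test_saturated_de_forces_p_one(self):
        assert ora_p(20, 20, 4, 4) == pytest.approx(1.0)

    def test_impossible_configuration_rejected(self):
        with pytest.raises(ValueError):
            ora_p(20, 5, 4, 5)

    def test_fisher_combination(self):
        assert fisher_product_p(0.01, 0.02) == pytest.approx(1.9034e-3, rel=1e-4)
        assert fisher_product_p(1.0, 1.0) == 1.0


class TestImpactAnalysis:
    def _setup(self):
        pw = pathway([("A", "B", 1), ("B", "C", -1)], pid="target")
        null = pathway([("X", "Y", 1), ("Y", "Z", -1)], pid="null")
        robust = robust_from_pairs([("m1", "A"), ("m2", "B"), ("m3", "X")])
        augs = [augment_pathway(pw, robust), augment_pathway(null, robust)]
        pert = PerturbationInput(delta_e={"m1": 2.0, "m2": -1.0},
                                 measured_universe={"m1", "m2", "m3", "m4"},
                                 de_set={"m1", "m2"})
        return augs, pert

    def test_seed_reproducibility(self):
        augs, pert = self._setup()
        r1 = impact_analysis(augs, pert, n_perm=200, seed=5)
        r2 = impact_analysis(augs, pert, n_perm=200, seed=5)
        assert [(x.p_acc, x.p_g) for x in r1] == [(x.p_acc, x.p_g) for x in r2]

    def test_p_acc_bounds(self):
        augs, pert = self._setup()
        for r in impact_analysis(augs, pert, n_perm=200, seed=5):
            assert 1 / 201 <= r.p_acc <= 1.0

    def test_acc_identity_and_adjustment_monotone(self):
        augs, pert = self._setup()
        for r in impact_analysis(augs, pert, n_perm=200, seed=5):
            for n in r.pf:
                assert r.acc[n] == pytest.approx(r.pf[n] - pert.delta_e.get(n, 0.0))
            assert r.p_g_adj >= r.p_g

    def test_pathway_without_measurement_flagged(self):
        pw = pathway([("Q", "R", 1)], pid="empty")
        augs = [augment_pathway(pw, robust_from_pairs([]))]
        pert = PerturbationInput({"m1": 1.0}, {"m1"}, {"m1"})
        (r,) = impact_analysis(augs, pert, n_perm=200, seed=1)
        assert r.no_measured and r.p_g == 1.0

    def test_seed_required(self):
        augs, pert = self._setup()
        with pytest.raises(ValueError, match="seed"):
            impact_analysis(augs, pert, n_perm=200, seed=None)


def test_pathway_tsv_roundtrip(tmp_path):
    pws = [pathway([("A", "B", 1), ("B", "C", -1)], pid="p1"),
           pathway([("X", "Y", -1)], pid="p2")]
    path = tmp_path / "pathways.tsv"
    write_pathways_tsv(pws, path)
    back = read_pathways_tsv(path)
    assert {p.pathway_id for p in back} == {"p1", "p2"}
    p1 = next(p for p in back if p.pathway_id == "p1")
    assert p1.graph.edges["B", "C"]["beta"] == -1.0
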