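"""Graph types, closure, classification: unit and property tests.

networkx serves as the independent oracle for cycle detection and
transitive closure.
"""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dagiv.graph import (
    AncestralRelationGraph,
    HypothesisSpec,
    InterventionDAG,
    arg_of_dag,
    classify_hypothesis,
    classify_interventions,
    is_acyclic,
    read_edge_tsv,
    transitive_closure,
    write_edge_tsv,
)
from dagiv.simulate import intervention_W, random_graph_U


def edges_of(U):
    return {(int(k) + 1, int(j) + 1) for k, j in zip(*np.nonzero(U))}


@st.composite
def random_dag_edges(draw, max_p=7):
    """Random DAG as an upper-triangular edge set under a permutation."""
    p = draw(st.integers(2, max_p))
    perm = draw(st.permutations(range(1, p + 1)))
    pairs = [(a, b) for i, a in enumerate(perm) for b in perm[i + 1 :]]
    chosen = draw(st.lists(st.sampled_from(pairs), unique=True, max_size=len(pairs)))
    return set(chosen), p


class TestAcyclicity:
    def test_empty_graph_is_acyclic(self):
        assert is_acyclic(set(), 3)

    def test_two_cycle(self):
        assert not is_acyclic({(1, 2), (2, 1)}, 2)

    def test_out_of_range_raises(self):
        with pytest.raises(IndexError):
            is_acyclic({(1, 4)}, 3)

    @settings(deadline=None, max_examples=60)
    @given(random_dag_edges())
    def test_random_dags_match_networkx(self, ew):
        edges, p = ew
        g = nx.DiGraph(edges)
        g.add_nodes_from(range(1, p + 1))
        assert is_acyclic(edges, p) == nx.is_directed_acyclic_graph(g)

    def test_cycle_detected_like_networkx(self):
        edges = {(1, 2), (2, 3), (3, 1)}
        assert not is_acyclic(edges, 3)


class TestTransitiveClosure:
    def test_chain(self):
        assert transitive_closure({(1, 2), (2, 3)}, 3) == {(1, 2), (2, 3), (1, 3)}

    def test_empty(self):
        assert transitive_closure(set(), 4) == set()

    def test_cyclic_input_rejected(self):
        with pytest.raises(ValueError):
            transitive_closure({(1, 2), (2, 1)}, 2)

    def test_matrix_power_oracle(self):
        # sum of boolean adjacency powers as the independent route
        rng = np.random.default_rng(3)
        p = 7
        A = np.triu(rng.random((p, p)) < 0.4, k=1)
        reach = np.zeros_like(A)
        Ak = np.eye(p, dtype=bool)
        for _ in range(p):
            Ak = Ak @ A
            reach |= Ak
        expected = {(i + 1, j + 1) for i, j in zip(*np.nonzero(reach))}
        assert transitive_closure(edges_of(A), p) == expected

    @settings(deadline=None, max_examples=60)
    @given(random_dag_edges())
    def test_idempotent(self, ew):
        edges, p = ew
        once = transitive_closure(edges, p)
        assert transitive_closure(once, p) == once


class TestArgOfDag:
    def test_chain_with_instruments(self):
        g = InterventionDAG(2, 2, {(1, 2)}, {(1, 1), (2, 2)})
        arg = arg_of_dag(g)
        assert set(arg.ancestral_edges) == {(1, 2)}
        assert set(arg.candidate_intervention_edges) == {(1, 1), (1, 2), (2, 2)}

    def test_no_primary_edges(self):
        g = InterventionDAG(2, 1, set(), {(1, 1)})
        arg = arg_of_dag(g)
        assert set(arg.ancestral_edges) == set()
        assert set(arg.candidate_intervention_edges) == {(1, 1)}

    @pytest.mark.parametrize("seed", range(25))
    def test_path_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p, q = 6, 10
        U = np.triu(rng.random((p, p)) < 0.35, k=1).astype(float)
        W = (rng.random((q, p)) < 0.25).astype(float)
        g = InterventionDAG(p, q, edges_of(U), edges_of(W))
        arg = arg_of_dag(g)
        nxg = nx.DiGraph(edges_of(U))
        nxg.add_nodes_from(range(1, p + 1))
        expected_anc = {
            (k, j) for j in range(1, p + 1) for k in nx.ancestors(nxg, j)
        }
        assert set(arg.ancestral_edges) == expected_anc
        expected_cand = set()
        for j in range(1, p + 1):
            closure = nx.ancestors(nxg, j) | {j}
            for k in closure:
                for l in g.interventions_on(k):
                    expected_cand.add((l, j))
        assert set(arg.candidate_intervention_edges) == expected_cand

    @pytest.mark.parametrize("seed", range(0, 1000, 10))
    def test_output_satisfies_arg_invariants(self, seed):
        rng = np.random.default_rng(seed)
        p, q = int(rng.integers(2, 8)), int(rng.integers(1, 12))
        U = np.triu(rng.random((p, p)) < 0.4, k=1)
        W = rng.random((q, p)) < 0.3
        arg = arg_of_dag(InterventionDAG(p, q, edges_of(U), edges_of(W)))
        # constructor re-validates acyclicity + closedness
        AncestralRelationGraph(p, q, arg.ancestral_edges, arg.candidate_intervention_edges)


class TestClassifyInterventions:
    def test_setup_a_roles(self):
        W = intervention_W("A", 3, 8)
        g = InterventionDAG(3, 8, set(), edges_of(W))
        cls = classify_interventions(g)
        assert [cls.roles[l] for l in range(1, 4)] == ["instrument"] * 3
        assert [cls.roles[l] for l in (4, 5)] == ["invalid_instrument"] * 2
        assert [cls.roles[l] for l in (6, 7, 8)] == ["inactive"] * 3
        assert cls.all_primary_instrumented

    def test_setup_b_only_last_instrument(self):
        W = intervention_W("B", 3, 8)
        g = InterventionDAG(3, 8, set(), edges_of(W))
        cls = classify_interventions(g)
        instruments = [l for l, r in cls.roles.items() if r == "instrument"]
        assert instruments == [3]
        assert not cls.all_primary_instrumented

    def test_all_inactive_when_w_zero(self):
        g = InterventionDAG(3, 4, set(), set())
        cls = classify_interventions(g)
        assert set(cls.roles.values()) == {"inactive"}


class TestClassifyHypothesis:
    def arg(self, edges, p=5, q=1):
        return AncestralRelationGraph(p, q, transitive_closure(edges, p), set())

    def test_reverse_edge_degenerate(self):
        cls = classify_hypothesis(HypothesisSpec(((2, 1),)), self.arg({(1, 2)}))
        assert cls.degenerate and cls.regular and cls.nondegenerate_edges == ()

    def test_fresh_edge_nondegenerate(self):
        cls = classify_hypothesis(HypothesisSpec(((3, 1),)), self.arg({(1, 2)}))
        assert cls.nondegenerate_edges == ((3, 1),) and cls.regular

    def test_jointly_cyclic_is_irregular(self):
        cls = classify_hypothesis(
            HypothesisSpec(((4, 5), (5, 3))), self.arg({(3, 4)})
        )
        assert set(cls.nondegenerate_edges) == {(4, 5), (5, 3)}
        assert not cls.regular and not cls.degenerate

    @pytest.mark.parametrize("seed", range(20))
    def test_d_from_edges_equals_d_from_closure(self, seed):
        # nondegeneracy wrt the raw edge set and wrt its closure agree
        rng = np.random.default_rng(seed)
        p = 6
        U = np.triu(rng.random((p, p)) < 0.4, k=1)
        edges = edges_of(U)
        closure = transitive_closure(edges, p)
        hyp = HypothesisSpec(
            tuple(
                (a, b)
                for a in range(1, p + 1)
                for b in range(1, p + 1)
                if a != b and rng.random() < 0.3
            )
            or ((1, 2),)
        )
        nondeg_raw = tuple(
            e for e in hyp.edges if is_acyclic(edges | {e}, p)
        )
        arg = AncestralRelationGraph(p, 1, closure, set())
        assert classify_hypothesis(hyp, arg).nondegenerate_edges == nondeg_raw

    @pytest.mark.parametrize("seed", range(10))
    def test_removing_nondegenerate_edge_keeps_regularity(self, seed):
        rng = np.random.default_rng(100 + seed)
        p = 6
        U = np.triu(rng.random((p, p)) < 0.4, k=1)
        arg = AncestralRelationGraph(p, 1, transitive_closure(edges_of(U), p), set())
        all_pairs = [(a, b) for a in range(1, p + 1) for b in range(1, p + 1) if a != b]
        idx = rng.choice(len(all_pairs), size=4, replace=False)
        hyp = HypothesisSpec(tuple(all_pairs[i] for i in idx))
        cls = classify_hypothesis(hyp, arg)
        if cls.regular and not cls.degenerate and len(cls.nondegenerate_edges) > 1:
            for drop in cls.nondegenerate_edges:
                sub = HypothesisSpec(
                    tuple(e for e in cls.nondegenerate_edges if e != drop)
                )
                assert classify_hypothesis(sub, arg).regular


class TestSerialization:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "edges.tsv"
        pe, ie = {(1, 2), (2, 3)}, {(1, 1), (4, 3)}
        write_edge_tsv(path, pe, ie)
        assert read_edge_tsv(path) == (pe, ie)

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("a\tb\tc\nY\t1\t2\n")
        with pytest.raises(ValueError):
            read_edge_tsv(path)


class TestInvariantEnforcement:
    def test_cyclic_primary_edges_rejected(self):
        with pytest.raises(ValueError):
            InterventionDAG(2, 0, {(1, 2), (2, 1)}, set())

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            InterventionDAG(2, 0, {(1, 1)}, set())

    def test_non_closed_arg_rejected(self):
        with pytest.raises(ValueError):
            AncestralRelationGraph(3, 0, {(1, 2), (2, 3)}, set())

    def test_random_graph_upper_triangular_is_acyclic(self):
        U = random_graph_U(20, seed=0)
        assert is_acyclic(edges_of(U), 20)
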