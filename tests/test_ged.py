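"""Cost model, BP cost matrix, BP-GED vs the exact oracle, distance matrices."""

import networkx as nx
import numpy as np
import pytest

from graphmcs.ged import (
    DELETE,
    CostModel,
    EditAssignment,
    bp_cost_matrix,
    bp_ged,
    exact_ged,
    induced_edit_cost,
    pairwise_distances,
)
from graphmcs.graphs import CONSTANT_LABEL, GraphDataset, LabeledGraph
from graphmcs.synthetic import SyntheticSpec, generate_dataset

from conftest import path_graph, random_labeled_graph


def nx_exact_ged(g1, g2, cm):
    """Independent cross-check: networkx exact GED with alpha-weighted costs."""
    return nx.graph_edit_distance(
        g1.to_networkx(),
        g2.to_networkx(),
        node_subst_cost=lambda a, b: cm.alpha * cm.node_cost(a["label"], b["label"]),
        node_del_cost=lambda a: cm.alpha * cm.tau_node,
        node_ins_cost=lambda a: cm.alpha * cm.tau_node,
        edge_subst_cost=lambda a, b: (1 - cm.alpha) * cm.edge_cost(a["label"], b["label"]),
        edge_del_cost=lambda a: (1 - cm.alpha) * cm.tau_edge,
        edge_ins_cost=lambda a: (1 - cm.alpha) * cm.tau_edge,
    )


class TestCostModel:
    def test_dirac_and_euclidean_defaults(self, cm):
        assert cm.node_cost("a", "a") == 0.0
        assert cm.node_cost("a", "b") == 2.0 * cm.tau_node
        assert cm.node_cost((0.0, 0.0), (3.0, 4.0)) == pytest.approx(5.0)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            CostModel(alpha=0.0)
        with pytest.raises(ValueError):
            CostModel(tau_node=-1.0)


class TestBpCostMatrix:
    def test_identical_single_nodes_zero_substitution(self, cm):
        g = LabeledGraph("g", ("a",), (), ())
        c = bp_cost_matrix(g, g, cm)
        assert c.shape == (2, 2)
        assert c[0, 0] == 0.0

    def test_isolated_node_deletion_entry(self, cm):
        g = LabeledGraph("g", ("a",), (), ())
        c = bp_cost_matrix(g, g, cm)
        assert c[0, 1] == pytest.approx(0.5)  # alpha * tau_node, degree 0
        assert c[1, 0] == pytest.approx(0.5)
        assert c[1, 1] == 0.0

    def test_degree_two_deletion_entry(self, cm):
        g1 = path_graph(["a", "b", "c"])  # node 1 has degree 2
        empty = LabeledGraph("e", (), (), ())
        c = bp_cost_matrix(g1, empty, cm)
        assert c.shape == (3, 3)
        assert c[1, 1] == pytest.approx(0.5 * 1 + 0.5 * 2 * 1)  # 1.5

    def test_big_m_dominates_off_diagonal(self, cm, rng):
        g1 = random_labeled_graph(rng, n_min=3, n_max=5, graph_id="a")
        g2 = random_labeled_graph(rng, n_min=3, n_max=5, graph_id="b")
        c = bp_cost_matrix(g1, g2, cm)
        n1, n2 = g1.n_nodes, g2.n_nodes
        big = c[:n1, n2:][~np.eye(n1, dtype=bool)]
        if big.size:
            finite_sum = c[:n1, :n2].sum() + np.diag(c[:n1, n2:]).sum() + np.diag(c[n1:, :n2]).sum()
            assert np.all(big > finite_sum)


class TestBpGed:
    def test_identity_is_zero(self, rng):
        cm = CostModel(alpha=0.5)
        for i in range(10):
            g = random_labeled_graph(rng, n_min=1, n_max=7, graph_id=f"g{i}")
            d, asg = bp_ged(g, g, cm)
            assert d == 0.0
            assert asg.mapping == tuple(range(g.n_nodes))

    def test_empty_versus_graph_forced_insertions(self, cm, rng):
        empty = LabeledGraph("e", (), (), ())
        for i in range(5):
            g = random_labeled_graph(rng, n_min=1, n_max=6, graph_id=f"g{i}")
            want = cm.alpha * g.n_nodes * cm.tau_node + (1 - cm.alpha) * g.n_edges * cm.tau_edge
            assert bp_ged(empty, g, cm)[0] == pytest.approx(want)
            assert bp_ged(g, empty, cm)[0] == pytest.approx(want)

    def test_upper_bounds_exact_with_some_equality(self, rng):
        cm = CostModel(alpha=0.5)
        equal = 0
        for i in range(60):
            g1 = random_labeled_graph(rng, n_min=1, n_max=6, graph_id=f"a{i}")
            g2 = random_labeled_graph(rng, n_min=1, n_max=6, graph_id=f"b{i}")
            bp = bp_ged(g1, g2, cm)[0]
            ex = exact_ged(g1, g2, cm)
            assert bp >= ex - 1e-9
            if abs(bp - ex) < 1e-9:
                equal += 1
        assert equal > 0

    def test_assignment_is_injective_and_consistent(self, cm, rng):
        for i in range(10):
            g1 = random_labeled_graph(rng, n_min=2, n_max=6, graph_id=f"a{i}")
            g2 = random_labeled_graph(rng, n_min=2, n_max=6, graph_id=f"b{i}")
            d, asg = bp_ged(g1, g2, cm)
            EditAssignment(asg.mapping, asg.inserted, asg.cost)  # re-validate invariants
            assert d == pytest.approx(induced_edit_cost(g1, g2, asg.mapping, cm))

    def test_homogeneity_in_tau(self, cm, rng):
        g1 = random_labeled_graph(rng, n_min=3, n_max=6, graph_id="a")
        g2 = random_labeled_graph(rng, n_min=3, n_max=6, graph_id="b")
        base = bp_ged(g1, g2, cm)[0]
        for c in (0.5, 3.0):
            assert bp_ged(g1, g2, cm.scaled(c))[0] == pytest.approx(c * base)


class TestExactGed:
    def test_identity_zero(self, cm, rng):
        g = random_labeled_graph(rng, n_min=1, n_max=5)
        assert exact_ged(g, g, cm) == 0.0

    def test_label_substitution_versus_delete_insert(self):
        cm = CostModel(tau_node=1.0, alpha=0.5)
        g1 = LabeledGraph("a", ("x",), (), ())
        g2 = LabeledGraph("b", ("y",), (), ())
        # substitute: 0.5 * 2 = 1.0; delete + insert: 0.5 + 0.5 = 1.0
        assert exact_ged(g1, g2, cm) == pytest.approx(1.0)

    def test_path_to_single_node(self, cm):
        g1 = path_graph(["a", "b"])
        g2 = LabeledGraph("s", ("a",), (), ())
        assert exact_ged(g1, g2, cm) == pytest.approx(1.0)  # delete node b and its edge

    def test_size_guard(self, cm):
        g = path_graph(list("abcdefg"))
        with pytest.raises(ValueError, match="guard"):
            exact_ged(g, g, cm)

    def test_agrees_with_networkx_oracle(self, rng):
        cm = CostModel(alpha=0.4, tau_node=1.0, tau_edge=0.8)
        for i in range(8):
            g1 = random_labeled_graph(rng, n_min=1, n_max=4, graph_id=f"a{i}",
                                      edge_alphabet=("u", "w"))
            g2 = random_labeled_graph(rng, n_min=1, n_max=4, graph_id=f"b{i}",
                                      edge_alphabet=("u", "w"))
            assert exact_ged(g1, g2, cm) == pytest.approx(nx_exact_ged(g1, g2, cm), abs=1e-9)


class TestDistanceMatrix:
    def test_self_matrix_symmetric_zero_diagonal(self, cm):
        ds = generate_dataset(SyntheticSpec(n_per_class=3, size_range=(4, 8), seed=6))
        m = pairwise_distances(ds, ds, cm)
        assert m.values.shape == (6, 6)
        assert np.allclose(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 0.0)
        assert np.all(m.values >= 0)

    def test_rectangular_block(self, cm):
        ds = generate_dataset(SyntheticSpec(n_per_class=4, size_range=(4, 7), seed=6))
        q = ds.subset(ds.graph_ids[:3], name="q")
        r = ds.subset(ds.graph_ids[3:], name="r")
        m = pairwise_distances(q, r, cm)
        assert m.values.shape == (3, 5)
        assert np.all(m.values >= 0)

    def test_tsv_round_trip(self, cm, tmp_path):
        ds = generate_dataset(SyntheticSpec(n_per_class=2, size_range=(4, 6), seed=3))
        m = pairwise_distances(ds, ds, cm, level=("pagerank", 0.6))
        m.to_tsv(tmp_path / "d.tsv")
        back = m.from_tsv(tmp_path / "d.tsv")
        assert back.row_ids == m.row_ids and back.col_ids == m.col_ids
        assert np.allclose(back.values, m.values)
        assert back.level == ("pagerank", 0.6)

    def test_reduced_level_is_faster(self, cm):
        """Matching 0.2-reduced graphs must cost less wall-clock than originals."""
        import time

        from graphmcs.reduction import ReductionPlan, build_subspaces

        ds = generate_dataset(SyntheticSpec(n_per_class=10, size_range=(16, 24), seed=8))
        stack = build_subspaces(ds, ReductionPlan(("pagerank",), (1.0, 0.2)))
        t0 = time.perf_counter()
        pairwise_distances(stack[("original", 1.0)], stack[("original", 1.0)], cm)
        t_full = time.perf_counter() - t0
        t0 = time.perf_counter()
        pairwise_distances(stack[("pagerank", 0.2)], stack[("pagerank", 0.2)], cm)
        t_reduced = time.perf_counter() - t0
        assert t_reduced < t_full
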