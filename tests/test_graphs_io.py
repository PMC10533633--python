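"""Graph containers, GXL/CXL and TUDataset readers, stratified splitting."""

import numpy as np
import pytest

from graphmcs.graphs import (
    CONSTANT_LABEL,
    GraphDataset,
    LabeledGraph,
    load_gxl_collection,
    load_gxl_file,
    load_tudataset,
    stratified_split,
    write_cxl_collection,
    write_gxl,
    write_tudataset,
)
from graphmcs.synthetic import SyntheticSpec, generate_dataset


def gxl_text(n_nodes, edges, labels=None, edgemode="undirected"):
    labels = labels or [f"L{i}" for i in range(n_nodes)]
    nodes = "".join(
        f'<node id="n{i}"><attr name="symbol"><string>{labels[i]}</string></attr></node>'
        for i in range(n_nodes)
    )
    es = "".join(f'<edge from="n{u}" to="n{v}"/>' for u, v in edges)
    return (
        '<?xml version="1.0"?><gxl>'
        f'<graph id="g" edgeids="false" edgemode="{edgemode}">{nodes}{es}</graph></gxl>'
    )


class TestLabeledGraph:
    def test_invariants_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            LabeledGraph("g", ("a", "b"), ((0, 0),), ("x",))
        with pytest.raises(ValueError, match="outside nodes"):
            LabeledGraph("g", ("a",), ((0, 1),), ("x",))
        with pytest.raises(ValueError, match="duplicate edge"):
            LabeledGraph("g", ("a", "b"), ((0, 1), (0, 1)), ("x", "x"))

    def test_induced_subgraph_tracks_source_ids(self):
        g = LabeledGraph("g", ("a", "b", "c"), ((0, 1), (1, 2)), ("x", "y"))
        sub = g.induced_subgraph([0, 2])
        assert sub.n_nodes == 2 and sub.n_edges == 0
        assert sub.original_ids == ("0", "2")

    def test_networkx_round_trip(self):
        g = LabeledGraph("g", ("a", "b", "c"), ((0, 1), (1, 2)), ("x", "y"))
        back = LabeledGraph.from_networkx(g.to_networkx(), "g")
        assert back.node_labels == g.node_labels
        assert back.edges == g.edges and back.edge_labels == g.edge_labels


class TestGxl:
    def test_collection_counts_and_classes(self, tmp_path):
        for i in range(3):
            (tmp_path / f"g{i}.gxl").write_text(gxl_text(2, [(0, 1)]))
        (tmp_path / "idx.cxl").write_text(
            '<?xml version="1.0"?><GraphCollection><graphs>'
            '<print file="g0.gxl" class="a"/><print file="g1.gxl" class="a"/>'
            '<print file="g2.gxl" class="b"/></graphs></GraphCollection>'
        )
        ds = load_gxl_collection(tmp_path / "idx.cxl")
        assert len(ds) == 3 and ds.classes == ["a", "b"]

    def test_parser_fidelity_node_edge_counts(self, tmp_path):
        edges = [(i, i + 1) for i in range(13)] + [(0, 13), (2, 7)]  # 14 nodes, 15 edges
        (tmp_path / "g.gxl").write_text(gxl_text(14, edges))
        g = load_gxl_file(tmp_path / "g.gxl")
        assert g.n_nodes == 14 and g.n_edges == 15

    def test_reverse_duplicate_edge_collapses(self, tmp_path):
        (tmp_path / "g.gxl").write_text(gxl_text(3, [(1, 2), (2, 1)]))
        g = load_gxl_file(tmp_path / "g.gxl")
        assert g.edges == ((1, 2),)

    def test_missing_and_malformed_files_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope.gxl"):
            load_gxl_file(tmp_path / "nope.gxl")
        (tmp_path / "bad.gxl").write_text("<gxl><graph>")
        with pytest.raises(ValueError, match="malformed XML"):
            load_gxl_file(tmp_path / "bad.gxl")

    def test_numeric_attributes_become_vectors(self, tmp_path):
        (tmp_path / "g.gxl").write_text(
            '<gxl><graph id="g" edgemode="undirected">'
            '<node id="n0"><attr name="x"><float>1.5</float></attr>'
            '<attr name="y"><float>2.0</float></attr></node></graph></gxl>'
        )
        g = load_gxl_file(tmp_path / "g.gxl")
        assert g.node_labels == ((1.5, 2.0),)

    def test_write_read_round_trip(self, tmp_path):
        ds = generate_dataset(SyntheticSpec(n_per_class=3, size_range=(4, 7), seed=5))
        index = write_cxl_collection(ds, tmp_path)
        back = load_gxl_collection(index)
        assert back.graph_ids == ds.graph_ids
        for g, h in zip(ds.graphs, back.graphs):
            assert g.node_labels == h.node_labels
            assert g.edges == h.edges and g.edge_labels == h.edge_labels
        assert {k: str(v) for k, v in ds.labels.items()} == back.labels


class TestTUDataset:
    def _write(self, d, indicator, a_rows, graph_labels, node_labels=None):
        (d / "DS_graph_indicator.txt").write_text("\n".join(map(str, indicator)) + "\n")
        (d / "DS_A.txt").write_text("\n".join(f"{u}, {v}" for u, v in a_rows) + "\n")
        (d / "DS_graph_labels.txt").write_text("\n".join(map(str, graph_labels)) + "\n")
        if node_labels is not None:
            (d / "DS_node_labels.txt").write_text("\n".join(map(str, node_labels)) + "\n")

    def test_partition_and_edge_collapse(self, tmp_path):
        self._write(tmp_path, [1, 1, 1, 2, 2],
                    [(1, 2), (2, 1), (2, 3), (3, 2), (4, 5), (5, 4)], [0, 1])
        ds = load_tudataset(tmp_path)
        assert [g.n_nodes for g in ds.graphs] == [3, 2]
        assert [g.n_edges for g in ds.graphs] == [2, 1]
        assert ds.classes == ["0", "1"]

    def test_node_labels_attached(self, tmp_path):
        self._write(tmp_path, [1, 1, 2], [(1, 2), (2, 1)], [0, 1], node_labels=[7, 8, 9])
        ds = load_tudataset(tmp_path)
        assert ds.graphs[0].node_labels == ("7", "8")
        assert ds.graphs[1].node_labels == ("9",)

    def test_unlabeled_nodes_get_constant_label(self, tmp_path):
        self._write(tmp_path, [1, 1], [(1, 2), (2, 1)], [0])
        # single-class dataset is fine at load time
        ds = load_tudataset(tmp_path)
        assert ds.graphs[0].node_labels == (CONSTANT_LABEL, CONSTANT_LABEL)

    def test_inconsistent_counts_fatal(self, tmp_path):
        self._write(tmp_path, [1, 1], [(1, 2), (2, 1)], [0, 1])  # 2 labels, 1 graph
        with pytest.raises(ValueError, match="graph labels"):
            load_tudataset(tmp_path)

    def test_cross_block_edge_fatal(self, tmp_path):
        self._write(tmp_path, [1, 2], [(1, 2), (2, 1)], [0, 1])
        with pytest.raises(ValueError, match="crosses graph blocks"):
            load_tudataset(tmp_path)

    def test_write_read_round_trip(self, tmp_path):
        ds = generate_dataset(SyntheticSpec(n_per_class=3, size_range=(4, 7), seed=2))
        write_tudataset(ds, tmp_path, name="RT")
        back = load_tudataset(tmp_path)
        assert [g.n_nodes for g in back.graphs] == [g.n_nodes for g in ds.graphs]
        assert [g.edges for g in back.graphs] == [g.edges for g in ds.graphs]


class TestStratifiedSplit:
    def _dataset(self, n=100):
        graphs, labels = [], {}
        for i in range(n):
            g = LabeledGraph(f"g{i}", ("a", "b"), ((0, 1),), (CONSTANT_LABEL,))
            graphs.append(g)
            labels[f"g{i}"] = "pos" if i < n // 2 else "neg"
        return GraphDataset(graphs, labels)

    def test_exact_divisibility(self):
        sp = stratified_split(self._dataset(100), (0.6, 0.2, 0.2), seed=7)
        for part, want in ((sp.train, 60), (sp.validation, 20), (sp.test, 20)):
            assert len(part) == want
            per_class = [sum(1 for g in part if part.labels[g.graph_id] == c)
                         for c in ("pos", "neg")]
            assert per_class == [want // 2, want // 2]

    def test_deterministic_membership(self):
        ds = self._dataset(40)
        a = stratified_split(ds, (0.6, 0.2, 0.2), seed=7)
        b = stratified_split(ds, (0.6, 0.2, 0.2), seed=7)
        assert a.train.graph_ids == b.train.graph_ids
        assert a.test.graph_ids == b.test.graph_ids
        c = stratified_split(ds, (0.6, 0.2, 0.2), seed=8)
        assert set(a.train.graph_ids) != set(c.train.graph_ids)

    def test_degenerate_fractions_fatal(self):
        with pytest.raises(ValueError):
            stratified_split(self._dataset(10), (0.5, 0.5, 0.0), seed=0)
        with pytest.raises(ValueError, match="sum to 1"):
            stratified_split(self._dataset(10), (0.5, 0.3, 0.1), seed=0)

    def test_small_class_fatal(self):
        ds = self._dataset(4)
        with pytest.raises(ValueError, match="need >= 3"):
            stratified_split(ds, (0.6, 0.2, 0.2), seed=0)


def test_loaded_datasets_pass_validator(tmp_path):
    """Every parsed graph satisfies the simple-undirected invariants."""
    ds = generate_dataset(SyntheticSpec(n_per_class=5, seed=11))
    index = write_cxl_collection(ds, tmp_path)
    load_gxl_collection(index).validate()
    write_tudataset(ds, tmp_path / "tu")
    load_tudataset(tmp_path / "tu").validate()
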