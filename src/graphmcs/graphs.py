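"""Labeled-graph containers, benchmark-format readers and dataset splitting.

The unit of all computation is :class:`LabeledGraph`, a simple undirected
graph with per-node and per-edge labels.  Node identifiers are normalized to
dense 0-based integers in file order; the original identifiers are retained
in :attr:`LabeledGraph.original_ids` so that provenance (and, after
reduction, membership in the source graph) remains checkable.

Two on-disk formats are supported: the IAM CXL/GXL XML collections and the
TUDataset flat-file layout (``DS_A.txt``, ``DS_graph_indicator.txt``,
``DS_graph_labels.txt`` plus optional node/edge label and attribute files).
Both readers enforce the simple-undirected invariants: no self-loops, at
most one edge per node pair, edge direction ignored.
"""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "LabeledGraph",
    "GraphDataset",
    "DatasetSplit",
    "load_gxl_collection",
    "load_gxl_file",
    "load_tudataset",
    "stratified_split",
    "write_gxl",
    "write_cxl_collection",
    "write_tudataset",
]

#: constant label used for unlabeled nodes/edges (degenerate Dirac cost)
CONSTANT_LABEL = "·"

Label = object  # symbolic token (str), number, or tuple of numbers


def _canon_edge(u: int, v: int) -> tuple[int, int]:
    return (u, v) if u < v else (v, u)


@dataclass(frozen=True)
class LabeledGraph:
    """Simple undirected graph with labels on nodes and edges.

    Nodes are the dense integers ``0 .. n_nodes-1``; this ordering is stable
    across runs and is the tie-break order used by reduction and matching.

    Parameters
    ----------
    graph_id : str
        Opaque identifier, unique within a dataset.
    node_labels : tuple
        ``node_labels[i]`` is the label of node ``i`` — a symbolic token
        (str), a float, or a tuple of floats for vector attributes.
    edges : tuple of (int, int)
        Each pair ``(u, v)`` with ``u < v``; no duplicates, no self-loops.
    edge_labels : tuple
        Aligned with ``edges``; use :data:`CONSTANT_LABEL` when the
        collection carries no edge information.
    original_ids : tuple of str, optional
        Source identifiers of the nodes (file ids, or source node indices
        for reduced graphs).
    """

    graph_id: str
    node_labels: tuple
    edges: tuple
    edge_labels: tuple
    original_ids: tuple = None

    def __post_init__(self):
        n = len(self.node_labels)
        seen = set()
        for (u, v) in self.edges:
            if u == v:
                raise ValueError(f"{self.graph_id}: self-loop at node {u}")
            if not (0 <= u < n and 0 <= v < n):
                raise ValueError(f"{self.graph_id}: edge ({u},{v}) endpoint outside nodes")
            if u > v:
                raise ValueError(f"{self.graph_id}: edge ({u},{v}) not canonically ordered")
            if (u, v) in seen:
                raise ValueError(f"{self.graph_id}: duplicate edge ({u},{v})")
            seen.add((u, v))
        if len(self.edge_labels) != len(self.edges):
            raise ValueError(f"{self.graph_id}: edge label count mismatch")
        if self.original_ids is not None and len(self.original_ids) != n:
            raise ValueError(f"{self.graph_id}: original_ids length mismatch")

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def nodes(self) -> range:
        return range(self.n_nodes)

    def degree(self, u: int) -> int:
        return sum(1 for (a, b) in self.edges if a == u or b == u)

    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n_nodes, dtype=int)
        for (u, v) in self.edges:
            d[u] += 1
            d[v] += 1
        return d

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes))
        for (u, v) in self.edges:
            a[u, v] = a[v, u] = 1.0
        return a

    def neighbors(self, u: int) -> list[int]:
        out = []
        for (a, b) in self.edges:
            if a == u:
                out.append(b)
            elif b == u:
                out.append(a)
        return sorted(out)

    def edge_set(self) -> frozenset:
        return frozenset(self.edges)

    def incident_edge_labels(self, u: int) -> list:
        return [lab for (a, b), lab in zip(self.edges, self.edge_labels) if u in (a, b)]

    def has_edge(self, u: int, v: int) -> bool:
        return _canon_edge(u, v) in set(self.edges)

    def to_networkx(self):
        """Export to a :class:`networkx.Graph` with ``label`` attributes."""
        import networkx as nx

        g = nx.Graph(graph_id=self.graph_id)
        for i, lab in enumerate(self.node_labels):
            g.add_node(i, label=lab)
        for (u, v), lab in zip(self.edges, self.edge_labels):
            g.add_edge(u, v, label=lab)
        return g

    @classmethod
    def from_networkx(cls, g, graph_id: str = "g") -> "LabeledGraph":
        order = {n: i for i, n in enumerate(g.nodes())}
        node_labels = tuple(g.nodes[n].get("label", CONSTANT_LABEL) for n in g.nodes())
        edges, elabs = [], []
        for u, v, data in g.edges(data=True):
            if order[u] == order[v]:
                continue
            edges.append(_canon_edge(order[u], order[v]))
            elabs.append(data.get("label", CONSTANT_LABEL))
        idx = sorted(range(len(edges)), key=lambda i: edges[i])
        return cls(
            graph_id=graph_id,
            node_labels=node_labels,
            edges=tuple(edges[i] for i in idx),
            edge_labels=tuple(elabs[i] for i in idx),
            original_ids=tuple(str(n) for n in g.nodes()),
        )

    def induced_subgraph(self, keep: Sequence[int], graph_id: str | None = None) -> "LabeledGraph":
        """Induced subgraph on ``keep`` (source node indices), renumbered densely.

        ``original_ids`` of the result records the kept source indices (or
        the source's own original ids when present), so nested reductions
        remain traceable to the root graph.
        """
        keep = sorted(keep)
        remap = {u: i for i, u in enumerate(keep)}
        keepset = set(keep)
        edges, elabs = [], []
        for (u, v), lab in zip(self.edges, self.edge_labels):
            if u in keepset and v in keepset:
                edges.append(_canon_edge(remap[u], remap[v]))
                elabs.append(lab)
        src_ids = self.original_ids if self.original_ids is not None else tuple(
            str(i) for i in range(self.n_nodes)
        )
        return LabeledGraph(
            graph_id=graph_id or self.graph_id,
            node_labels=tuple(self.node_labels[u] for u in keep),
            edges=tuple(edges),
            edge_labels=tuple(elabs),
            original_ids=tuple(src_ids[u] for u in keep),
        )


@dataclass
class GraphDataset:
    """An ordered collection of labeled graphs with one class label each."""

    graphs: list
    labels: dict
    name: str = "dataset"

    def __post_init__(self):
        ids = [g.graph_id for g in self.graphs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.name}: duplicate graph_id")
        if set(ids) != set(self.labels):
            raise ValueError(f"{self.name}: labels do not cover graphs exactly")

    def __len__(self) -> int:
        return len(self.graphs)

    def __iter__(self):
        return iter(self.graphs)

    @property
    def graph_ids(self) -> list:
        return [g.graph_id for g in self.graphs]

    @property
    def classes(self) -> list:
        return sorted(set(self.labels.values()), key=str)

    def subset(self, ids: Iterable[str], name: str | None = None) -> "GraphDataset":
        wanted = set(ids)
        graphs = [g for g in self.graphs if g.graph_id in wanted]
        return GraphDataset(
            graphs=graphs,
            labels={g.graph_id: self.labels[g.graph_id] for g in graphs},
            name=name or self.name,
        )

    def validate(self) -> None:
        """Re-check every simple-undirected invariant; raise on violation."""
        for g in self.graphs:
            LabeledGraph(g.graph_id, g.node_labels, g.edges, g.edge_labels, g.original_ids)


@dataclass
class DatasetSplit:
    train: GraphDataset
    validation: GraphDataset
    test: GraphDataset

    def __post_init__(self):
        parts = [set(self.train.graph_ids), set(self.validation.graph_ids), set(self.test.graph_ids)]
        total = sum(len(p) for p in parts)
        if len(parts[0] | parts[1] | parts[2]) != total:
            raise ValueError("split parts are not disjoint by graph_id")


# ---------------------------------------------------------------------------
# GXL / CXL (IAM graph database layout)
# ---------------------------------------------------------------------------

def _parse_gxl_value(elem) -> Label:
    """Parse one GXL attribute value element (<int>, <float>, <string>, ...)."""
    tag = elem.tag.lower()
    text = (elem.text or "").strip()
    if tag in ("int", "integer"):
        return float(int(text))
    if tag in ("float", "double"):
        return float(text)
    if tag == "bool":
        return text
    return text  # string / enum -> symbolic token


def _combine_attrs(attrs: list) -> Label:
    """Collapse GXL <attr> values into a single label.

    No attributes -> the constant label; one -> the value itself; several ->
    a tuple in declared order (all-numeric tuples stay numeric vectors).
    """
    if not attrs:
        return CONSTANT_LABEL
    if len(attrs) == 1:
        return attrs[0]
    return tuple(attrs)


def load_gxl_file(path, graph_id: str | None = None) -> LabeledGraph:
    """Parse one GXL file into a :class:`LabeledGraph`.

    Edge direction is ignored; a pair declared in both directions collapses
    to a single undirected edge (first declaration's label wins).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"GXL file not found: {path}")
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as exc:
        raise ValueError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()
    gelem = root.find("graph")
    if gelem is None:
        raise ValueError(f"{path}: no <graph> element")

    node_ids, node_labels = [], []
    for nelem in gelem.findall("node"):
        nid = nelem.get("id")
        attrs = [_parse_gxl_value(list(a)[0]) for a in nelem.findall("attr") if len(list(a))]
        node_ids.append(nid)
        node_labels.append(_combine_attrs(attrs))
    index = {nid: i for i, nid in enumerate(node_ids)}
    if len(index) != len(node_ids):
        raise ValueError(f"{path}: duplicate node id")

    edges: dict = {}
    for eelem in gelem.findall("edge"):
        u, v = eelem.get("from"), eelem.get("to")
        if u not in index or v not in index:
            raise ValueError(f"{path}: edge endpoint {u!r}/{v!r} not a declared node")
        a, b = index[u], index[v]
        if a == b:
            raise ValueError(f"{path}: self-loop at node {u!r}")
        attrs = [_parse_gxl_value(list(x)[0]) for x in eelem.findall("attr") if len(list(x))]
        key = _canon_edge(a, b)
        if key not in edges:  # duplicate/reverse declarations collapse
            edges[key] = _combine_attrs(attrs)
    keys = sorted(edges)
    return LabeledGraph(
        graph_id=graph_id or path.stem,
        node_labels=tuple(node_labels),
        edges=tuple(keys),
        edge_labels=tuple(edges[k] for k in keys),
        original_ids=tuple(node_ids),
    )


def load_gxl_collection(index_path, data_dir=None, name: str | None = None) -> GraphDataset:
    """Load an IAM-style CXL index plus its per-graph GXL files.

    The CXL index is an XML document whose ``<print file="..." class="..."/>``
    entries name the member GXL files and their class labels.
    """
    index_path = Path(index_path)
    data_dir = Path(data_dir) if data_dir is not None else index_path.parent
    if not index_path.exists():
        raise FileNotFoundError(f"CXL index not found: {index_path}")
    try:
        tree = ET.parse(str(index_path))
    except ET.ParseError as exc:
        raise ValueError(f"malformed XML in {index_path}: {exc}") from exc
    entries = tree.getroot().iter("print")
    graphs, labels = [], {}
    for entry in entries:
        fname, cls = entry.get("file"), entry.get("class")
        if fname is None or cls is None:
            raise ValueError(f"{index_path}: <print> entry missing file/class")
        g = load_gxl_file(data_dir / fname)
        if g.graph_id in labels:
            raise ValueError(f"{index_path}: duplicate graph_id {g.graph_id!r}")
        graphs.append(g)
        labels[g.graph_id] = cls
    return GraphDataset(graphs=graphs, labels=labels, name=name or index_path.stem)


def write_gxl(g: LabeledGraph, path) -> None:
    """Serialize a graph to GXL (attribute name ``label``; numeric vs string inferred)."""
    root = ET.Element("gxl")
    ge = ET.SubElement(root, "graph", id=g.graph_id, edgeids="false", edgemode="undirected")

    def emit_attr(parent, value):
        if isinstance(value, tuple):
            for i, v in enumerate(value):
                a = ET.SubElement(parent, "attr", name=f"label{i}")
                t = ET.SubElement(a, "float" if isinstance(v, (int, float)) else "string")
                t.text = repr(float(v)) if isinstance(v, (int, float)) else str(v)
        else:
            a = ET.SubElement(parent, "attr", name="label")
            t = ET.SubElement(a, "float" if isinstance(value, (int, float)) else "string")
            t.text = repr(float(value)) if isinstance(value, (int, float)) else str(value)

    for i, lab in enumerate(g.node_labels):
        ne = ET.SubElement(ge, "node", id=f"n{i}")
        emit_attr(ne, lab)
    for (u, v), lab in zip(g.edges, g.edge_labels):
        ee = ET.SubElement(ge, "edge", attrib={"from": f"n{u}", "to": f"n{v}"})
        emit_attr(ee, lab)
    ET.ElementTree(root).write(str(path), encoding="unicode", xml_declaration=True)


def write_cxl_collection(ds: GraphDataset, out_dir) -> Path:
    """Write a dataset as a CXL index + one GXL file per graph; return index path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root = ET.Element("GraphCollection")
    coll = ET.SubElement(root, "graphs", count=str(len(ds)))
    for g in ds.graphs:
        fname = f"{g.graph_id}.gxl"
        write_gxl(g, out_dir / fname)
        ET.SubElement(coll, "print", file=fname, attrib={"class": str(ds.labels[g.graph_id])})
    # ElementTree merges attrib dicts; rebuild with both attributes explicit
    for p, g in zip(coll.iter("print"), ds.graphs):
        p.set("file", f"{g.graph_id}.gxl")
        p.set("class", str(ds.labels[g.graph_id]))
    index_path = out_dir / f"{ds.name}.cxl"
    ET.ElementTree(root).write(str(index_path), encoding="unicode", xml_declaration=True)
    return index_path


# ---------------------------------------------------------------------------
# TUDataset flat-file layout
# ---------------------------------------------------------------------------

def _symbolic_token(field: str) -> str:
    """Node/edge label field -> symbolic token (integers canonicalized)."""
    field = field.strip()
    try:
        return str(int(field))
    except ValueError:
        return field


def _read_rows(path: Path) -> list:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def load_tudataset(data_dir, name: str | None = None) -> GraphDataset:
    """Load a dataset in the TUDataset flat-file layout.

    Expects ``<DS>_A.txt``, ``<DS>_graph_indicator.txt`` and
    ``<DS>_graph_labels.txt``; ``<DS>_node_labels.txt``,
    ``<DS>_edge_labels.txt`` and ``<DS>_node_attributes.txt`` are attached
    when present, otherwise nodes/edges get the constant label.  Symmetric
    adjacency pairs collapse to one undirected edge.
    """
    data_dir = Path(data_dir)
    prefixes = sorted({p.name.rsplit("_", 1)[0] for p in data_dir.glob("*_A.txt")})
    if not prefixes:
        raise FileNotFoundError(f"no *_A.txt found under {data_dir}")
    ds_name = prefixes[0]

    def p(suffix):
        return data_dir / f"{ds_name}_{suffix}.txt"

    for required in ("A", "graph_indicator", "graph_labels"):
        if not p(required).exists():
            raise FileNotFoundError(f"missing {p(required)}")

    indicator = [int(x) for x in _read_rows(p("graph_indicator"))]
    graph_labels = _read_rows(p("graph_labels"))
    n_graphs = max(indicator)
    if len(graph_labels) != n_graphs:
        raise ValueError(
            f"{ds_name}: {len(graph_labels)} graph labels but indicator names {n_graphs} graphs"
        )

    node_labels: list = [None] * len(indicator)
    if p("node_labels").exists():
        rows = _read_rows(p("node_labels"))
        if len(rows) != len(indicator):
            raise ValueError(f"{ds_name}: node_labels row count != node count")
        node_labels = [_symbolic_token(r.split(",")[0]) for r in rows]
    elif p("node_attributes").exists():
        rows = _read_rows(p("node_attributes"))
        if len(rows) != len(indicator):
            raise ValueError(f"{ds_name}: node_attributes row count != node count")
        node_labels = [tuple(float(x) for x in r.split(",")) for r in rows]
    else:
        node_labels = [CONSTANT_LABEL] * len(indicator)

    a_rows = _read_rows(p("A"))
    edge_labels_raw: list = [CONSTANT_LABEL] * len(a_rows)
    if p("edge_labels").exists():
        rows = _read_rows(p("edge_labels"))
        if len(rows) != len(a_rows):
            raise ValueError(f"{ds_name}: edge_labels row count != adjacency row count")
        edge_labels_raw = [_symbolic_token(r.split(",")[0]) for r in rows]

    # 1-based global node index -> (graph index, local 0-based index)
    first_node: dict = {}
    local_index: list = []
    counts = [0] * (n_graphs + 1)
    for gi in indicator:
        local_index.append(counts[gi])
        counts[gi] += 1

    per_graph_edges: list = [dict() for _ in range(n_graphs + 1)]
    for row, elab in zip(a_rows, edge_labels_raw):
        parts = row.replace(" ", "").split(",")
        u, v = int(parts[0]), int(parts[1])
        if not (1 <= u <= len(indicator) and 1 <= v <= len(indicator)):
            raise ValueError(f"{ds_name}: adjacency row references node outside range: {row}")
        gu, gv = indicator[u - 1], indicator[v - 1]
        if gu != gv:
            raise ValueError(f"{ds_name}: edge ({u},{v}) crosses graph blocks {gu}/{gv}")
        if u == v:
            raise ValueError(f"{ds_name}: self-loop at global node {u}")
        key = _canon_edge(local_index[u - 1], local_index[v - 1])
        per_graph_edges[gu].setdefault(key, elab)

    graphs, labels = [], {}
    for gi in range(1, n_graphs + 1):
        nl = [node_labels[i] for i in range(len(indicator)) if indicator[i] == gi]
        keys = sorted(per_graph_edges[gi])
        gid = f"{ds_name}_{gi}"
        graphs.append(
            LabeledGraph(
                graph_id=gid,
                node_labels=tuple(nl),
                edges=tuple(keys),
                edge_labels=tuple(per_graph_edges[gi][k] for k in keys),
            )
        )
        labels[gid] = graph_labels[gi - 1]
    return GraphDataset(graphs=graphs, labels=labels, name=name or ds_name)


def write_tudataset(ds: GraphDataset, out_dir, name: str | None = None) -> Path:
    """Write a dataset in the TUDataset flat layout (both edge directions emitted)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ds_name = name or ds.name
    offset = 0
    a_rows, ind_rows, nlab_rows, glab_rows = [], [], [], []
    symbolic_nodes = all(isinstance(l, str) for g in ds for l in g.node_labels)
    for gi, g in enumerate(ds.graphs, start=1):
        for lab in g.node_labels:
            ind_rows.append(str(gi))
            if symbolic_nodes and lab != CONSTANT_LABEL:
                nlab_rows.append(str(int(lab)) if lab.isdigit() else lab)
        for (u, v) in g.edges:
            a_rows.append(f"{u + 1 + offset}, {v + 1 + offset}")
            a_rows.append(f"{v + 1 + offset}, {u + 1 + offset}")
        glab_rows.append(str(ds.labels[g.graph_id]))
        offset += g.n_nodes
    (out_dir / f"{ds_name}_A.txt").write_text("\n".join(a_rows) + "\n")
    (out_dir / f"{ds_name}_graph_indicator.txt").write_text("\n".join(ind_rows) + "\n")
    (out_dir / f"{ds_name}_graph_labels.txt").write_text("\n".join(glab_rows) + "\n")
    if nlab_rows and len(nlab_rows) == len(ind_rows):
        (out_dir / f"{ds_name}_node_labels.txt").write_text("\n".join(nlab_rows) + "\n")
    return out_dir


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def stratified_split(
    ds: GraphDataset,
    fractions: tuple = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> DatasetSplit:
    """Deterministic stratified train/validation/test split.

    Per class, members are shuffled with the seeded generator and allocated
    to the three parts by largest-remainder rounding of ``fractions``.
    Every part receives at least one member of every class, so every class
    needs at least three members.
    """
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("fractions must be three positive proportions")
    if abs(sum(fractions) - 1.0) > 1e-8:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    rng = np.random.default_rng(seed)
    parts: list = [[], [], []]
    for cls in ds.classes:
        members = [g.graph_id for g in ds.graphs if ds.labels[g.graph_id] == cls]
        if len(members) < 3:
            raise ValueError(f"class {cls!r} has {len(members)} members; need >= 3")
        members = list(np.array(members, dtype=object)[rng.permutation(len(members))])
        quotas = [f * len(members) for f in fractions]
        counts = [int(q) for q in quotas]
        # largest remainder, then force every part nonempty
        rema = sorted(range(3), key=lambda i: quotas[i] - counts[i], reverse=True)
        for i in rema[: len(members) - sum(counts)]:
            counts[i] += 1
        for i in range(3):
            if counts[i] == 0:
                j = max(range(3), key=lambda x: counts[x])
                counts[j] -= 1
                counts[i] += 1
        pos = 0
        for i in range(3):
            parts[i].extend(members[pos : pos + counts[i]])
            pos += counts[i]
    return DatasetSplit(
        train=ds.subset(parts[0], name=f"{ds.name}-train"),
        validation=ds.subset(parts[1], name=f"{ds.name}-validation"),
        test=ds.subset(parts[2], name=f"{ds.name}-test"),
    )
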