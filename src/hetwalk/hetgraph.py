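"""Assembly of the heterogeneous lncRNA/disease/miRNA network.

The network has three node types and exactly three edge types:
lncRNA-disease and lncRNA-miRNA edges come from the binary association
matrices (weight 1); lncRNA-lncRNA edges come from the functional similarity
matrix, sparsified to each lncRNA's top-k most similar partners (weight =
similarity) so that the similarity layer does not become a near-clique that
dominates random walks. Edges are stored once and traversed bidirectionally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_io import AssociationMatrix, LabeledMatrix

LNCRNA = "lncRNA"
DISEASE = "disease"
MIRNA = "miRNA"
NODE_TYPES = (LNCRNA, DISEASE, MIRNA)

EDGE_LD = "lncRNA-disease"
EDGE_LL = "lncRNA-lncRNA"
EDGE_LM = "lncRNA-miRNA"
EDGE_TYPES = (EDGE_LD, EDGE_LL, EDGE_LM)

_ALLOWED = {
    frozenset((LNCRNA, DISEASE)): EDGE_LD,
    frozenset((LNCRNA,)): EDGE_LL,
    frozenset((LNCRNA, MIRNA)): EDGE_LM,
}


@dataclass
class HeteroGraph:
    """Typed, weighted, undirected heterogeneous network."""

    nodes: list[str] = field(default_factory=list)
    node_type: dict[str, str] = field(default_factory=dict)
    edges: list[tuple[str, str, float, str]] = field(default_factory=list)
    adj: dict[str, list[tuple[str, float]]] = field(default_factory=dict)

    def add_node(self, node: str, ntype: str) -> None:
        if ntype not in NODE_TYPES:
            raise ValueError(f"unknown node type {ntype!r}")
        if node in self.node_type:
            if self.node_type[node] != ntype:
                raise ValueError(f"node {node!r} re-added with a different type")
            return
        self.nodes.append(node)
        self.node_type[node] = ntype
        self.adj[node] = []

    def add_edge(self, u: str, v: str, weight: float = 1.0) -> None:
        if u == v:
            raise ValueError(f"self-loop on {u!r}")
        if weight <= 0:
            raise ValueError(f"edge weight must be positive, got {weight}")
        key = frozenset((self.node_type[u], self.node_type[v]))
        if key not in _ALLOWED:
            raise ValueError(
                f"edge {self.node_type[u]}--{self.node_type[v]} is not part of this network"
            )
        self.edges.append((u, v, float(weight), _ALLOWED[key]))
        self.adj[u].append((v, float(weight)))
        self.adj[v].append((u, float(weight)))

    def degree(self, node: str) -> int:
        return len(self.adj[node])

    def neighbors(self, node: str) -> list[tuple[str, float]]:
        return self.adj[node]

    def isolated_nodes(self) -> list[str]:
        return [n for n in self.nodes if not self.adj[n]]

    def nodes_of_type(self, ntype: str) -> list[str]:
        return [n for n in self.nodes if self.node_type[n] == ntype]

    def write_edge_list(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("u\tv\tweight\tedge_type\n")
            for u, v, w, et in self.edges:
                fh.write(f"{u}\t{v}\t{w:.12g}\t{et}\n")


def topk_similarity_edges(
    lfs: LabeledMatrix, k: int, threshold: float | None = None
) -> list[tuple[str, str, float]]:
    """Per-lncRNA top-k similarity partners (union over rows, self excluded).

    Ties on similarity are broken by identifier order; with ``threshold`` set,
    partners below it are dropped even inside the top-k (threshold mode).
    """
    ids = lfs.ids
    n = len(ids)
    chosen: set[tuple[int, int]] = set()
    for i in range(n):
        sims = lfs.values[i].copy()
        sims[i] = -np.inf  # exclude self
        # sort by similarity descending, identifier ascending
        order = sorted(range(n), key=lambda j: (-sims[j], ids[j]))
        for j in order[:k]:
            s = sims[j]
            if s <= 0 or (threshold is not None and s < threshold):
                continue
            chosen.add((min(i, j), max(i, j)))
    return [(ids[i], ids[j], float(lfs.values[i, j])) for i, j in sorted(chosen)]


def build_hetero_graph(
    lfs: LabeledMatrix,
    ld: AssociationMatrix,
    lm: AssociationMatrix,
    lnc_topk: int = 10,
    similarity_threshold: float | None = None,
) -> HeteroGraph:
    """Build the three-layer network from LFS, LD and LM.

    The lncRNA label sets of the three inputs must be identical (and in the
    same order). Isolated nodes trigger a warning: walks cannot start there.
    """
    if not (lfs.ids == ld.row_ids == lm.row_ids):
        raise ValueError("lncRNA label lists of LFS, LD and LM must be identical")
    g = HeteroGraph()
    for l in ld.row_ids:
        g.add_node(l, LNCRNA)
    for d in ld.col_ids:
        g.add_node(d, DISEASE)
    for m in lm.col_ids:
        g.add_node(m, MIRNA)
    for u, v in ld.ones():
        g.add_edge(u, v, 1.0)
    for u, v in lm.ones():
        g.add_edge(u, v, 1.0)
    for u, v, w in topk_similarity_edges(lfs, lnc_topk, similarity_threshold):
        g.add_edge(u, v, w)
    iso = g.isolated_nodes()
    if iso:
        warnings.warn(
            f"{len(iso)} isolated node(s) cannot be reached by walks, e.g. {iso[:5]}"
        )
    return g


def degree_report(graph: HeteroGraph) -> dict[str, dict]:
    """Per-type degree summary: min/median/max and the isolated-node list."""
    report: dict[str, dict] = {}
    for ntype in NODE_TYPES:
        nodes = graph.nodes_of_type(ntype)
        degs = [graph.degree(n) for n in nodes]
        if degs:
            report[ntype] = {
                "n": len(nodes),
                "min": int(min(degs)),
                "median": float(np.median(degs)),
                "max": int(max(degs)),
                "isolated": [n for n, d in zip(nodes, degs) if d == 0],
            }
        else:
            report[ntype] = {"n": 0, "min": 0, "median": 0.0, "max": 0, "isolated": []}
    return report
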