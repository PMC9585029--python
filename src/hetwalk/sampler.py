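"""Restart-random-walk neighbor sampling.

For every node a walk repeatedly either jumps back to its start node (with
probability ``p``) or moves to a weighted random neighbor, with an optional
node2vec-style in-out bias ``q`` (second-order: advancing to a node not
adjacent to the previous position is down-weighted by 1/q; q=1 recovers the
pure restart walk). Visited nodes are banked until a fixed number has been
collected and every node type is represented, then the most frequently
visited neighbors of each type form the node's typed "strong correlation"
neighborhood. The walk sequences double as the skip-gram training corpus.
"""

from __future__ import annotations

from bisect import bisect_left
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .hetgraph import NODE_TYPES, HeteroGraph


@dataclass
class WalkConfig:
    p: float = 0.5              # restart probability
    q: float = 1.0              # in-out bias; >1 breadth-first, <1 depth-first
    collect_size: int = 100     # banked visits required to stop
    min_per_type: int = 5       # minimum banked visits per node type
    k_lnc: int = 10             # per-type neighbor budgets k_t
    k_dis: int = 10
    k_mi: int = 6
    max_steps: int | None = None  # defaults to 10 * collect_size
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"restart probability p must be in [0,1], got {self.p}")
        if self.q <= 0:
            raise ValueError(f"bias q must be positive, got {self.q}")
        if 3 * self.min_per_type > self.collect_size:
            raise ValueError("3*min_per_type must not exceed collect_size")
        if self.max_steps is None:
            self.max_steps = 10 * self.collect_size

    def k_for(self, ntype: str) -> int:
        return {"lncRNA": self.k_lnc, "disease": self.k_dis, "miRNA": self.k_mi}[ntype]


@dataclass
class TypedNeighborSet:
    """Per-type frequency-ranked neighbors of one center node.

    Each list has length exactly k_t (padded by cycling when fewer distinct
    neighbors of that type were sampled); a type never visited at all yields
    an empty list and the model substitutes the center's own embedding.
    """

    center: str
    neighbors: dict[str, list[tuple[str, int]]]
    flagged: bool = False  # walk hit max_steps before filling its type quota

    def ids(self, ntype: str) -> list[str]:
        return [n for n, _ in self.neighbors[ntype]]


@dataclass
class WalkResult:
    start: str
    visits: Counter            # banked multiset, start excluded
    sequence: list[str]        # every position of the walk, start included
    flagged: bool


class _WalkIndex:
    """Per-graph cache of neighbor arrays and cumulative weights."""

    def __init__(self, graph: HeteroGraph):
        self.graph = graph
        self.nbrs: dict[str, list[str]] = {}
        self.cum: dict[str, list[float]] = {}
        self.nbr_sets: dict[str, set[str]] = {}
        for node in graph.nodes:
            pairs = graph.adj[node]
            self.nbrs[node] = [v for v, _ in pairs]
            acc, tot = [], 0.0
            for _, w in pairs:
                tot += w
                acc.append(tot)
            self.cum[node] = acc
            self.nbr_sets[node] = {v for v, _ in pairs}

    def step(self, cur: str, prev: str | None, q: float, rng: np.random.Generator) -> str:
        if q == 1.0 or prev is None:
            cum = self.cum[cur]
            r = rng.random() * cum[-1]
            return self.nbrs[cur][bisect_left(cum, r)]
        prev_adj = self.nbr_sets[prev]
        weights = []
        tot = 0.0
        for v, w in self.graph.adj[cur]:
            bias = 1.0 if (v == prev or v in prev_adj) else 1.0 / q
            tot += w * bias
            weights.append(tot)
        r = rng.random() * tot
        return self.nbrs[cur][bisect_left(weights, r)]


def restart_random_walk(
    graph: HeteroGraph,
    start: str,
    cfg: WalkConfig,
    rng: np.random.Generator,
    index: _WalkIndex | None = None,
) -> WalkResult:
    """Run one restart walk from ``start`` until its collection quota is met.

    Banks every visited node except the start itself (the start's own content
    enters the model through its content embedding, not its neighborhood).
    Returns a flagged result if ``max_steps`` is hit with the per-type quota
    unmet; downstream padding then applies.
    """
    if start not in graph.node_type:
        raise ValueError(f"unknown start node {start!r}")
    if not graph.adj[start]:
        raise ValueError(f"start node {start!r} is isolated")
    idx = index or _WalkIndex(graph)
    visits: Counter = Counter()
    type_counts = dict.fromkeys(NODE_TYPES, 0)
    sequence = [start]
    cur, prev = start, None
    total = 0
    for _ in range(cfg.max_steps):
        if rng.random() < cfg.p:
            cur, prev = start, None
        else:
            cur, prev = idx.step(cur, prev, cfg.q, rng), cur
        sequence.append(cur)
        if cur != start:
            visits[cur] += 1
            type_counts[graph.node_type[cur]] += 1
            total += 1
        if total >= cfg.collect_size and all(
            type_counts[t] >= cfg.min_per_type for t in NODE_TYPES
        ):
            return WalkResult(start, visits, sequence, flagged=False)
    return WalkResult(start, visits, sequence, flagged=True)


def exact_visit_distribution(
    graph: HeteroGraph,
    start: str,
    p: float,
    tol: float = 1e-10,
    max_iter: int = 200_000,
) -> dict[str, float]:
    """Stationary visiting distribution of the pure restart walk (q = 1).

    Solves pi = p * e_start + (1-p) * pi @ W by power iteration, where W is the
    edge-weight-normalized transition matrix restricted to the component
    reachable from ``start``. Serves as the independent oracle for the sampler.
    """
    # reachable component
    comp = [start]
    seen = {start}
    qu = [start]
    while qu:
        u = qu.pop()
        for v, _ in graph.adj[u]:
            if v not in seen:
                seen.add(v)
                comp.append(v)
                qu.append(v)
    pos = {n: i for i, n in enumerate(comp)}
    n = len(comp)
    W = np.zeros((n, n))
    for u in comp:
        tot = sum(w for _, w in graph.adj[u])
        for v, w in graph.adj[u]:
            W[pos[u], pos[v]] = w / tot
    e = np.zeros(n)
    e[pos[start]] = 1.0
    pi = e.copy()
    # damped (lazy) iteration: same fixed point, converges even for periodic
    # chains (e.g. bipartite graphs at p = 0)
    for _ in range(max_iter):
        target = p * e + (1.0 - p) * (pi @ W)
        if np.abs(target - pi).sum() <= tol:
            pi = target
            break
        pi = 0.5 * pi + 0.5 * target
    else:
        raise RuntimeError(f"power iteration did not converge within {max_iter} iterations")
    pi = pi / pi.sum()
    return {node: float(pi[pos[node]]) for node in comp}


def select_typed_neighbors(
    center: str,
    visits: Counter,
    graph: HeteroGraph,
    cfg: WalkConfig,
    flagged: bool = False,
) -> TypedNeighborSet:
    """Group banked visits by node type and keep the top-k_t most frequent.

    Ties break by identifier; fewer than k_t distinct neighbors of a type are
    padded by cycling that type's ranked list; a never-sampled type stays empty.
    """
    if not visits:
        return TypedNeighborSet(center, {t: [] for t in NODE_TYPES}, flagged=flagged)
    by_type: dict[str, list[tuple[str, int]]] = {t: [] for t in NODE_TYPES}
    for node, freq in visits.items():
        by_type[graph.node_type[node]].append((node, freq))
    selected: dict[str, list[tuple[str, int]]] = {}
    for ntype in NODE_TYPES:
        ranked = sorted(by_type[ntype], key=lambda nf: (-nf[1], nf[0]))
        k = cfg.k_for(ntype)
        if not ranked:
            selected[ntype] = []
        elif len(ranked) >= k:
            selected[ntype] = ranked[:k]
        else:
            selected[ntype] = [ranked[i % len(ranked)] for i in range(k)]
    return TypedNeighborSet(center, selected, flagged=flagged)


def sample_all(
    graph: HeteroGraph, cfg: WalkConfig
) -> tuple[dict[str, TypedNeighborSet], list[list[str]], list[str]]:
    """Typed neighbor sets + walk corpus for every non-isolated node.

    Each node's walk uses an independent RNG stream derived from
    (cfg.seed, node position), so the output is reproducible and insensitive
    to how other nodes' walks consume randomness. Returns
    (neighbor sets, walk sequences, skipped isolated nodes).
    """
    index = _WalkIndex(graph)
    neighbor_sets: dict[str, TypedNeighborSet] = {}
    corpus: list[list[str]] = []
    skipped: list[str] = []
    for i, node in enumerate(graph.nodes):
        if not graph.adj[node]:
            skipped.append(node)
            continue
        rng = np.random.default_rng([cfg.seed, i])
        res = restart_random_walk(graph, node, cfg, rng, index=index)
        neighbor_sets[node] = select_typed_neighbors(
            node, res.visits, graph, cfg, flagged=res.flagged
        )
        corpus.append(res.sequence)
    return neighbor_sets, corpus, skipped


def write_neighbor_table(neighbor_sets: dict[str, TypedNeighborSet], path) -> None:
    """Dump typed neighbor sets as TSV: center, type, rank, neighbor, frequency."""
    with open(path, "w") as fh:
        fh.write("center\ttype\trank\tneighbor\tfrequency\n")
        for center in sorted(neighbor_sets):
            ns = neighbor_sets[center]
            for ntype in NODE_TYPES:
                for rank, (nbr, freq) in enumerate(ns.neighbors[ntype], start=1):
                    fh.write(f"{center}\t{ntype}\t{rank}\t{nbr}\t{freq}\n")


def write_corpus(corpus: list[list[str]], path) -> None:
    with open(path, "w") as fh:
        for seq in corpus:
            fh.write(" ".join(seq) + "\n")


def read_corpus(path) -> list[list[str]]:
    with open(path) as fh:
        return [line.split() for line in fh if line.strip()]
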