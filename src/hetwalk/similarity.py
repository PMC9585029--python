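"""Disease semantic similarity (DSS) and lncRNA functional similarity (LFS).

DSS follows the Wang-style DAG measure: each disease term contributes 1 to
itself, and a semantic contribution that decays by a factor ``delta`` per
edge when walking up its ancestor DAG; similarity of two diseases is the
overlap of their ancestor contributions normalized by their total semantic
values. LFS is then the best-match average of DSS over the two lncRNAs'
associated-disease sets — the standard "guilt by shared disease" measure.
DSS may also be supplied directly as a matrix, since curated similarity
matrices are often distributed without the underlying ontology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_io import AssociationMatrix, LabeledMatrix


@dataclass
class DiseaseOntology:
    """A disease DAG given as child -> parent edges, plus the decay factor delta."""

    terms: set[str]
    edges: list[tuple[str, str]]  # (child, parent)
    delta: float = 0.5

    parents: dict[str, list[str]] = field(init=False)
    children: dict[str, list[str]] = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.delta < 1.0):
            raise ValueError(f"delta must lie strictly in (0,1), got {self.delta}")
        self.parents = {t: [] for t in self.terms}
        self.children = {t: [] for t in self.terms}
        for child, parent in self.edges:
            if child not in self.terms or parent not in self.terms:
                raise ValueError(f"edge ({child}, {parent}) references an unknown term")
            self.parents[child].append(parent)
            self.children[parent].append(child)
        self._check_acyclic()

    @classmethod
    def from_edges(cls, edges: list[tuple[str, str]], delta: float = 0.5,
                   extra_terms: set[str] | None = None) -> "DiseaseOntology":
        terms = {t for e in edges for t in e} | (extra_terms or set())
        return cls(terms=terms, edges=list(edges), delta=delta)

    def _check_acyclic(self) -> None:
        # Kahn's algorithm, peeling leaves upward; leftovers mean a cycle.
        indeg = {t: len(self.children[t]) for t in self.terms}
        queue = [t for t in self.terms if indeg[t] == 0]
        seen = 0
        while queue:
            t = queue.pop()
            seen += 1
            for p in self.parents[t]:
                indeg[p] -= 1
                if indeg[p] == 0:
                    queue.append(p)
        if seen != len(self.terms):
            raise ValueError("cycle detected in disease ontology")

    def contributions(self, disease: str) -> dict[str, float]:
        """Semantic contribution of every ancestor term t to ``disease``.

        D_d(d) = 1; D_d(t) = delta * max over children t' of t lying on a path
        toward d of D_d(t').
        """
        if disease not in self.terms:
            raise ValueError(f"unknown term {disease!r}")
        contrib = {disease: 1.0}
        # breadth-first up the DAG; a term may be reached along several paths,
        # so keep the max and re-relax until stable (DAG => terminates).
        frontier = [disease]
        while frontier:
            nxt: list[str] = []
            for t in frontier:
                for p in self.parents[t]:
                    cand = self.delta * contrib[t]
                    if cand > contrib.get(p, 0.0):
                        contrib[p] = cand
                        nxt.append(p)
            frontier = nxt
        return contrib


def compute_dss(ontology: DiseaseOntology) -> LabeledMatrix:
    """Semantic similarity matrix over all ontology terms (Wang-style measure)."""
    ids = sorted(ontology.terms)
    contribs = {d: ontology.contributions(d) for d in ids}
    dv = {d: sum(c.values()) for d, c in contribs.items()}
    n = len(ids)
    values = np.zeros((n, n))
    for i, a in enumerate(ids):
        ca = contribs[a]
        values[i, i] = 1.0
        for j in range(i + 1, n):
            b = ids[j]
            cb = contribs[b]
            shared = ca.keys() & cb.keys()
            if shared:
                s = sum(ca[t] + cb[t] for t in shared) / (dv[a] + dv[b])
                values[i, j] = values[j, i] = s
    return LabeledMatrix(ids, values)


def lncrna_pair_similarity(d1: list[str] | set[str], d2: list[str] | set[str],
                           dss: LabeledMatrix) -> float:
    """Best-match-average similarity between two associated-disease sets.

    S = (sum_i max_j DSS(d1i, d2j) + sum_j max_i DSS(d2j, d1i)) / (m + n).
    Both sets empty yields 0 with a warning (nothing to match on).
    """
    d1 = sorted(set(d1))
    d2 = sorted(set(d2))
    m, n = len(d1), len(d2)
    if m + n == 0:
        warnings.warn("both disease sets empty; defining pair similarity as 0")
        return 0.0
    if m == 0 or n == 0:
        return 0.0
    block = dss.submatrix(d1, d2)  # m x n
    return float(block.max(axis=1).sum() + block.max(axis=0).sum()) / (m + n)


def build_lfs(ld: AssociationMatrix, dss: LabeledMatrix) -> LabeledMatrix:
    """lncRNA functional similarity from the LD association matrix and DSS.

    Every disease that appears in LD must be present in DSS. The diagonal is
    fixed at 1 (including lncRNAs with no known disease, whose off-diagonal
    similarities are 0 by convention).
    """
    missing = sorted(set(ld.col_ids) - set(dss.ids))
    if missing:
        raise ValueError(f"diseases absent from DSS: {missing[:5]}")
    lnc_ids = list(ld.row_ids)
    disease_sets = [ld.row_partners(l) for l in lnc_ids]
    n = len(lnc_ids)
    values = np.eye(n)
    with warnings.catch_warnings():
        # empty-vs-empty pairs would warn per pair; the convention is documented
        warnings.simplefilter("ignore")
        for i in range(n):
            for j in range(i + 1, n):
                values[i, j] = values[j, i] = lncrna_pair_similarity(
                    disease_sets[i], disease_sets[j], dss
                )
    n_empty = sum(1 for s in disease_sets if not s)
    if n_empty:
        warnings.warn(f"{n_empty} lncRNA(s) have no known disease; their similarity rows are 0")
    return LabeledMatrix(lnc_ids, values)
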