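"""Synthetic benchmark data with planted community structure.

The generator emulates the statistical premise of similarity-driven
association prediction: similar diseases tend to be associated with
functionally similar lncRNAs. Nodes of all three types are assigned to
blocks; lncRNA-disease and lncRNA-miRNA associations appear with
probability ``p_in`` inside a block and ``p_out`` across blocks, and the
disease semantic similarity matrix is ``dss_in`` within a disease block and
``dss_out`` across (diagonal 1). DSS is emitted directly for speed; an
optional DAG emitter produces a disease ontology whose Wang-style
similarity shows the same block contrast, for testing the DSS computation
end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import AssociationMatrix, LabeledMatrix
from .similarity import DiseaseOntology


@dataclass
class SyntheticConfig:
    n_lnc: int = 60
    n_dis: int = 80
    n_mi: int = 50
    n_blocks: int = 4
    p_in: float = 0.30      # association probability within a block
    p_out: float = 0.01     # association probability across blocks
    dss_in: float = 0.8     # disease similarity within a block
    dss_out: float = 0.1    # disease similarity across blocks
    holdout_frac: float = 0.0  # fraction of LD positives removed into the truth list
    seed: int = 1

    def __post_init__(self) -> None:
        if not (self.p_in > self.p_out >= 0.0):
            raise ValueError("require p_in > p_out >= 0")
        if not (self.dss_in > self.dss_out >= 0.0):
            raise ValueError("require dss_in > dss_out >= 0")
        if not (0.0 <= self.holdout_frac < 1.0):
            raise ValueError("holdout_frac must lie in [0,1)")
        for n in (self.n_lnc, self.n_dis, self.n_mi):
            if n < self.n_blocks:
                raise ValueError("each node type needs at least one node per block")

    def expected_positives(self) -> float:
        """Analytic expectation of the number of 1-cells in LD."""
        blocks = _block_assignment(self.n_lnc, self.n_blocks)
        dblocks = _block_assignment(self.n_dis, self.n_blocks)
        same = sum(
            (blocks == b).sum() * (dblocks == b).sum() for b in range(self.n_blocks)
        )
        total = self.n_lnc * self.n_dis
        return same * self.p_in + (total - same) * self.p_out


@dataclass
class SyntheticTruth:
    lnc_block: dict[str, int]
    dis_block: dict[str, int]
    mi_block: dict[str, int]
    full_ld: AssociationMatrix                      # before hold-out removal
    held_out: list[tuple[str, str]] = field(default_factory=list)


def _block_assignment(n: int, n_blocks: int) -> np.ndarray:
    """Contiguous blocks of near-equal size (remainder spread over the first)."""
    sizes = [n // n_blocks + (1 if b < n % n_blocks else 0) for b in range(n_blocks)]
    return np.repeat(np.arange(n_blocks), sizes)


def generate(
    cfg: SyntheticConfig,
) -> tuple[AssociationMatrix, AssociationMatrix, LabeledMatrix, SyntheticTruth]:
    """Draw (LD, LM, DSS, truth) from the planted block model; fully seeded."""
    rng = np.random.default_rng(cfg.seed)
    lnc_ids = [f"L{i:03d}" for i in range(cfg.n_lnc)]
    dis_ids = [f"D{i:03d}" for i in range(cfg.n_dis)]
    mi_ids = [f"M{i:03d}" for i in range(cfg.n_mi)]
    lb = _block_assignment(cfg.n_lnc, cfg.n_blocks)
    db = _block_assignment(cfg.n_dis, cfg.n_blocks)
    mb = _block_assignment(cfg.n_mi, cfg.n_blocks)

    def block_bernoulli(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        same = rows[:, None] == cols[None, :]
        probs = np.where(same, cfg.p_in, cfg.p_out)
        return (rng.random(probs.shape) < probs).astype(np.int8)

    ld_values = block_bernoulli(lb, db)
    lm_values = block_bernoulli(lb, mb)
    if ld_values.sum() == 0 or lm_values.sum() == 0:
        raise ValueError("configuration produced an empty association matrix")

    same_d = db[:, None] == db[None, :]
    dss_values = np.where(same_d, cfg.dss_in, cfg.dss_out).astype(float)
    np.fill_diagonal(dss_values, 1.0)

    full_ld = AssociationMatrix(lnc_ids, dis_ids, ld_values.copy())
    held_out: list[tuple[str, str]] = []
    if cfg.holdout_frac > 0:
        ones = np.argwhere(ld_values == 1)
        n_hold = int(round(cfg.holdout_frac * len(ones)))
        pick = rng.choice(len(ones), size=n_hold, replace=False)
        for i, j in ones[pick]:
            ld_values[i, j] = 0
            held_out.append((lnc_ids[i], dis_ids[j]))

    truth = SyntheticTruth(
        lnc_block=dict(zip(lnc_ids, lb.tolist())),
        dis_block=dict(zip(dis_ids, db.tolist())),
        mi_block=dict(zip(mi_ids, mb.tolist())),
        full_ld=full_ld,
        held_out=sorted(held_out),
    )
    ld = AssociationMatrix(lnc_ids, dis_ids, ld_values)
    lm = AssociationMatrix(lnc_ids, mi_ids, lm_values)
    dss = LabeledMatrix(dis_ids, dss_values)
    return ld, lm, dss, truth


def default_benchmark() -> SyntheticConfig:
    """The repository's canonical desk-scale benchmark configuration."""
    return SyntheticConfig(
        n_lnc=60, n_dis=80, n_mi=50, n_blocks=4,
        p_in=0.30, p_out=0.01, dss_in=0.8, dss_out=0.1, seed=1,
    )


def disease_dag(cfg: SyntheticConfig, delta: float = 0.5) -> DiseaseOntology:
    """A disease DAG whose Wang-style similarity mirrors the block structure.

    Each block gets a root; block diseases are children of their root, and
    all roots are children of one global root, so within-block pairs share a
    near ancestor and cross-block pairs only the distant global root.
    """
    db = _block_assignment(cfg.n_dis, cfg.n_blocks)
    dis_ids = [f"D{i:03d}" for i in range(cfg.n_dis)]
    edges: list[tuple[str, str]] = []
    for b in range(cfg.n_blocks):
        edges.append((f"ROOT_B{b}", "ROOT"))
    for d, b in zip(dis_ids, db):
        edges.append((d, f"ROOT_B{b}"))
    return DiseaseOntology.from_edges(edges, delta=delta)
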