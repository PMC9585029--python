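"""Shared fixtures: toy graphs, a micro dataset for fast end-to-end runs, and
session-scoped benchmark cross-validation results reused by the heavier
acceptance checks."""

from __future__ import annotations

import numpy as np
import pytest

from hetwalk.data_io import AssociationMatrix, LabeledMatrix
from hetwalk.evaluate import ablation_study, benchmark_pipeline_config, embedding_size_sweep
from hetwalk.hetgraph import DISEASE, LNCRNA, MIRNA, HeteroGraph, build_hetero_graph
from hetwalk.pipeline import PipelineConfig
from hetwalk.sampler import WalkConfig
from hetwalk.embedding import SkipgramConfig
from hetwalk.model import ModelConfig
from hetwalk.synthetic import SyntheticConfig, default_benchmark, generate


def mini_world(d=8, seed=0, n_l=4, n_d=4, n_m=2, k=2):
    """Small frozen content table + typed neighbor sets + labeled pairs.

    Labels are driven by the lncRNA side, so they are learnable by a scorer
    that is additive over the two endpoint embeddings."""
    from hetwalk.embedding import ContentEmbeddingTable
    from hetwalk.sampler import TypedNeighborSet

    rng = np.random.default_rng(seed)
    lncs = [f"l{i}" for i in range(n_l)]
    diss = [f"d{i}" for i in range(n_d)]
    mis = [f"m{i}" for i in range(n_m)]
    nodes = lncs + diss + mis
    content = ContentEmbeddingTable(nodes, rng.normal(size=(len(nodes), d)), seed=seed)
    neighbors = {}
    for n in nodes:
        neighbors[n] = TypedNeighborSet(
            n,
            {
                LNCRNA: [(rng.choice(lncs), 1) for _ in range(k)],
                DISEASE: [(rng.choice(diss), 1) for _ in range(k)],
                MIRNA: [(rng.choice(mis), 1) for _ in range(k)],
            },
        )
    pairs = [(l, dd, int(i < n_l // 2)) for i, l in enumerate(lncs) for dd in diss]
    return content, neighbors, pairs


@pytest.fixture
def toy_matrices():
    """2 lncRNAs, 1 disease, 1 miRNA; LD=[[1],[0]], LM=[[0],[1]], LFS off-diag 0.7."""
    ld = AssociationMatrix(["l1", "l2"], ["d1"], np.array([[1], [0]]))
    lm = AssociationMatrix(["l1", "l2"], ["m1"], np.array([[0], [1]]))
    lfs = LabeledMatrix(["l1", "l2"], np.array([[1.0, 0.7], [0.7, 1.0]]))
    return lfs, ld, lm


@pytest.fixture
def toy_graph(toy_matrices) -> HeteroGraph:
    lfs, ld, lm = toy_matrices
    return build_hetero_graph(lfs, ld, lm, lnc_topk=1)


@pytest.fixture
def six_node_graph() -> HeteroGraph:
    """Small connected heterogeneous graph with mixed weights for walk oracles."""
    g = HeteroGraph()
    for n, t in [("l1", LNCRNA), ("l2", LNCRNA), ("d1", DISEASE),
                 ("d2", DISEASE), ("m1", MIRNA), ("m2", MIRNA)]:
        g.add_node(n, t)
    g.add_edge("l1", "d1", 1.0)
    g.add_edge("l1", "d2", 1.0)
    g.add_edge("l2", "d2", 1.0)
    g.add_edge("l1", "l2", 0.5)
    g.add_edge("l1", "m1", 1.0)
    g.add_edge("l2", "m2", 2.0)
    return g


@pytest.fixture(scope="session")
def micro_data():
    """Tiny planted dataset for fast end-to-end pipeline runs."""
    cfg = SyntheticConfig(n_lnc=16, n_dis=20, n_mi=12, n_blocks=2,
                          p_in=0.5, p_out=0.05, seed=7)
    return generate(cfg)


@pytest.fixture(scope="session")
def micro_pipeline_cfg() -> PipelineConfig:
    return PipelineConfig(
        walk=WalkConfig(collect_size=30, min_per_type=2, k_lnc=4, k_dis=4, k_mi=3),
        skipgram=SkipgramConfig(d=16, epochs=2),
        model=ModelConfig(d=16, epochs=5, batch_size=64, lr=5e-3),
        lnc_topk=4,
    )


@pytest.fixture(scope="session")
def benchmark_data():
    return generate(default_benchmark())


@pytest.fixture(scope="session")
def benchmark_cv_results(benchmark_data):
    """Strict 5FCV on the canonical benchmark: all three model variants and the
    d=8 embedding size, each over seeds {1, 2, 3}. Computed once per session;
    this is the expensive fixture behind the end-to-end acceptance checks."""
    ld, lm, dss, _ = benchmark_data
    cfg = benchmark_pipeline_config()
    ablation = ablation_study(ld, lm, dss, cfg, [1, 2, 3])
    sweep = embedding_size_sweep([8], ld, lm, dss, cfg, [1, 2, 3])
    return {
        "ablation": ablation,
        "auc_d8": sweep[8],
        "auc_d64": ablation["full"]["mean_auc"],
    }
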