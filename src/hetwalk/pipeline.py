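"""End-to-end glue: similarity -> graph -> walks -> embeddings -> model.

`PipelineConfig` bundles the per-stage configurations; `fit_pipeline` runs
every stage on a given set of training LD edges and returns a fitted
pipeline that can score arbitrary (lncRNA, disease) pairs. The evaluation
protocols (cross-validation, candidate ranking, novel-disease masking) all
build on these two entry points so that "rebuild everything from the
training edges only" is a single call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_io import AssociationMatrix, LabeledMatrix, edges_to_matrix
from .embedding import ContentEmbeddingTable, SkipgramConfig, table_for_graph, train_skipgram
from .hetgraph import HeteroGraph, build_hetero_graph
from .model import ModelConfig, ModelState, init_state, predict, train
from .sampler import TypedNeighborSet, WalkConfig, sample_all
from .similarity import build_lfs


@dataclass
class PipelineConfig:
    walk: WalkConfig = field(default_factory=WalkConfig)
    skipgram: SkipgramConfig = field(default_factory=SkipgramConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    lnc_topk: int = 10          # per-lncRNA similarity partners kept in the graph

    def __post_init__(self) -> None:
        if self.skipgram.d != self.model.d:
            raise ValueError(
                f"skip-gram d={self.skipgram.d} and model d={self.model.d} must agree"
            )

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Propagate one top-level seed into every stage."""
        return PipelineConfig(
            walk=replace(self.walk, seed=seed),
            skipgram=replace(self.skipgram, seed=seed + 1),
            model=replace(self.model, seed=seed + 2),
            lnc_topk=self.lnc_topk,
        )

    def with_d(self, d: int) -> "PipelineConfig":
        return PipelineConfig(
            walk=self.walk,
            skipgram=replace(self.skipgram, d=d),
            model=replace(self.model, d=d),
            lnc_topk=self.lnc_topk,
        )

    def with_variant(self, variant: str) -> "PipelineConfig":
        return PipelineConfig(
            walk=self.walk,
            skipgram=self.skipgram,
            model=replace(self.model, variant=variant),
            lnc_topk=self.lnc_topk,
        )

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        return cls(
            walk=WalkConfig(**cfg.get("walk", {})),
            skipgram=SkipgramConfig(**cfg.get("skipgram", {})),
            model=ModelConfig(**cfg.get("model", {})),
            lnc_topk=cfg.get("lnc_topk", 10),
        )


@dataclass
class FittedPipeline:
    cfg: PipelineConfig
    graph: HeteroGraph
    neighbors: dict[str, TypedNeighborSet]
    content: ContentEmbeddingTable
    state: ModelState

    def score(self, pairs: list[tuple[str, str]]) -> np.ndarray:
        return predict(self.state, self.content, self.neighbors, pairs)


def build_stage(
    ld_train: AssociationMatrix,
    lm: AssociationMatrix,
    dss: LabeledMatrix,
    cfg: PipelineConfig,
) -> tuple[HeteroGraph, dict[str, TypedNeighborSet], ContentEmbeddingTable]:
    """Similarity, graph, walks and content embeddings from training edges only."""
    lfs = build_lfs(ld_train, dss)
    graph = build_hetero_graph(lfs, ld_train, lm, lnc_topk=cfg.lnc_topk)
    neighbors, corpus, _ = sample_all(graph, cfg.walk)
    table = train_skipgram(corpus, cfg.skipgram)
    content = table_for_graph(table, graph.nodes)
    return graph, neighbors, content


def fit_pipeline(
    ld_train: AssociationMatrix,
    lm: AssociationMatrix,
    dss: LabeledMatrix,
    train_pairs: list[tuple[str, str, int]],
    cfg: PipelineConfig,
) -> FittedPipeline:
    """Run every stage and train the classifier on labeled pairs."""
    graph, neighbors, content = build_stage(ld_train, lm, dss, cfg)
    state = init_state(cfg.model)
    train(state, content, neighbors, train_pairs)
    return FittedPipeline(cfg, graph, neighbors, content, state)


def mask_pairs(
    ld: AssociationMatrix, pairs: list[tuple[str, str]]
) -> AssociationMatrix:
    """Copy of LD with the given (lncRNA, disease) 1-cells set to 0."""
    keep = set(pairs)
    edges = [e for e in ld.ones() if e not in keep]
    return edges_to_matrix(edges, ld.row_ids, ld.col_ids)
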