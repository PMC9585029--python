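"""Skip-gram content embeddings f(v) trained on the walk corpus.

A vectorized numpy implementation of skip-gram with negative sampling
(SGNS): for every (center, context) pair within the window, the center's
input vector is pushed toward the context's output vector and away from
``negatives`` noise vectors drawn from the unigram^0.75 distribution.
Training is single-stream and fully seeded, so identical corpus + seed
gives identical tables.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np


def _stable_hash(s: str) -> int:
    # process-independent (unlike hash()), so fallback vectors are reproducible
    return zlib.crc32(s.encode())


@dataclass
class SkipgramConfig:
    d: int = 128
    window: int = 5
    negatives: int = 5
    epochs: int = 5
    lr: float = 0.025          # linearly decayed to min_lr over training
    min_lr: float = 1e-4
    batch_size: int = 4096  # larger batches over-accumulate hub-node updates
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d < 2:
            raise ValueError(f"embedding size must be >= 2, got {self.d}")


class ContentEmbeddingTable:
    """Ordered node -> d-vector lookup with an optional seeded random fallback."""

    def __init__(self, node_ids: list[str], vectors: np.ndarray, seed: int = 0):
        if len(node_ids) != vectors.shape[0]:
            raise ValueError("one vector per node id required")
        self.node_ids = list(node_ids)
        self.vectors = np.asarray(vectors, dtype=float)
        self.d = self.vectors.shape[1]
        self.seed = seed
        self._index = {n: i for i, n in enumerate(node_ids)}

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def index(self, node: str) -> int:
        return self._index[node]

    def lookup(self, node: str, fallback: bool = False) -> np.ndarray:
        """Stored vector for ``node``; with ``fallback``, unknown nodes get a
        deterministic seeded random vector instead of an error."""
        i = self._index.get(node)
        if i is not None:
            return self.vectors[i]
        if not fallback:
            raise KeyError(f"node {node!r} has no content embedding")
        rng = np.random.default_rng([self.seed, _stable_hash(node)])
        return rng.normal(scale=1.0 / np.sqrt(self.d), size=self.d)

    def matrix_for(self, nodes: list[str]) -> np.ndarray:
        return self.vectors[[self._index[n] for n in nodes]]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for node, vec in zip(self.node_ids, self.vectors):
                fh.write(node + "\t" + "\t".join(f"{x:.17g}" for x in vec) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path, seed: int = 0) -> "ContentEmbeddingTable":
        ids, rows = [], []
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                ids.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        return cls(ids, np.asarray(rows), seed=seed)


def _scatter_add(W: np.ndarray, idx: np.ndarray, upd: np.ndarray) -> None:
    """W[idx] += upd with duplicate indices, via one flattened bincount
    (much faster than np.ufunc.at for the batch sizes used here)."""
    V, d = W.shape
    flat = (idx[:, None] * d + np.arange(d)[None, :]).ravel()
    W += np.bincount(flat, weights=upd.ravel(), minlength=V * d).reshape(V, d)


def _training_pairs(corpus: list[list[int]], window: int) -> tuple[np.ndarray, np.ndarray]:
    centers, contexts = [], []
    for seq in corpus:
        n = len(seq)
        for i, c in enumerate(seq):
            lo, hi = max(0, i - window), min(n, i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(c)
                    contexts.append(seq[j])
    return np.asarray(centers, dtype=np.int64), np.asarray(contexts, dtype=np.int64)


def train_skipgram(
    corpus: list[list[str]], cfg: SkipgramConfig
) -> ContentEmbeddingTable:
    """Train SGNS embeddings over node-id sequences.

    The vocabulary covers every corpus token (min count 1 — walk corpora are
    small and every node matters). Reproducible given cfg.seed.
    """
    if not corpus or any(len(seq) == 0 for seq in corpus):
        raise ValueError("corpus must be non-empty with no empty sequences")
    vocab = sorted({tok for seq in corpus for tok in seq})
    tok2id = {t: i for i, t in enumerate(vocab)}
    V = len(vocab)
    iseqs = [[tok2id[t] for t in seq] for seq in corpus]

    counts = np.zeros(V)
    for seq in iseqs:
        for t in seq:
            counts[t] += 1
    noise = counts ** 0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    rng = np.random.default_rng(cfg.seed)
    W_in = (rng.random((V, cfg.d)) - 0.5) / cfg.d
    W_out = np.zeros((V, cfg.d))

    centers, contexts = _training_pairs(iseqs, cfg.window)
    n_pairs = len(centers)
    total_batches = max(1, cfg.epochs * int(np.ceil(n_pairs / cfg.batch_size)))
    batch_no = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(n_pairs)
        for s in range(0, n_pairs, cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            c, o = centers[idx], contexts[idx]
            B = len(c)
            lr = max(cfg.min_lr, cfg.lr * (1 - batch_no / total_batches))
            batch_no += 1
            neg = np.searchsorted(noise_cdf, rng.random((B, cfg.negatives)))
            vin = W_in[c]                      # (B, d)
            vpos = W_out[o]                    # (B, d)
            vneg = W_out[neg]                  # (B, K, d)
            # positive pair: label 1 (dots clipped: sigmoid saturates anyway)
            dots_p = np.clip(np.einsum("bd,bd->b", vin, vpos), -30, 30)
            spos = 1.0 / (1.0 + np.exp(-dots_p))
            gpos = (spos - 1.0)[:, None]       # dL/dscore
            # negatives: label 0
            dots_n = np.clip(np.einsum("bd,bkd->bk", vin, vneg), -30, 30)
            sneg = 1.0 / (1.0 + np.exp(-dots_n))
            gneg = sneg[..., None]             # (B, K, 1)
            grad_in = gpos * vpos + np.einsum("bkd,bk->bd", vneg, sneg)
            out_idx = np.concatenate([o, neg.ravel()])
            out_upd = np.concatenate(
                [-lr * gpos * vin,
                 -lr * (gneg * vin[:, None, :]).reshape(B * cfg.negatives, cfg.d)]
            )
            _scatter_add(W_out, out_idx, out_upd)
            _scatter_add(W_in, c, -lr * grad_in)
    return ContentEmbeddingTable(vocab, W_in, seed=cfg.seed)


def table_for_graph(
    table: ContentEmbeddingTable, node_ids: list[str], seed: int | None = None
) -> ContentEmbeddingTable:
    """Re-index a trained table onto a full graph node list.

    Nodes absent from the corpus (isolated nodes never walked) receive seeded
    random vectors with a warning, so downstream lookups stay total.
    """
    import warnings

    seed = table.seed if seed is None else seed
    vecs = np.empty((len(node_ids), table.d))
    missing = []
    for i, node in enumerate(node_ids):
        if node in table:
            vecs[i] = table.lookup(node)
        else:
            missing.append(node)
            rng = np.random.default_rng([seed, _stable_hash(node)])
            vecs[i] = rng.normal(scale=1.0 / np.sqrt(table.d), size=table.d)
    if missing:
        warnings.warn(
            f"{len(missing)} node(s) missing from the corpus assigned random "
            f"vectors, e.g. {missing[:3]}"
        )
    return ContentEmbeddingTable(node_ids, vecs, seed=seed)
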