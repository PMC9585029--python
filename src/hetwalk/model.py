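"""The association-prediction network.

For every node v the model combines:

* its frozen content embedding f(v) (skip-gram over walk sequences),
* one Bi-LSTM per node type that aggregates the type's sampled neighbors'
  content vectors (hidden size d/2 per direction; forward and backward
  states are concatenated per position and mean-pooled, giving f^t(v) of
  dimension d),
* an attention layer that softmax-weights {f(v), f^lncRNA(v), f^disease(v),
  f^miRNA(v)} with logits exp(ReLU(q^T [f(v) || f^k(v)])) and returns
  z(v) = ReLU(sum_k beta_k f^k(v)),

and scores a (lncRNA, disease) pair by softmax over a 2-logit linear layer
on [z(l) || z(d)], trained with two-class cross-entropy.

Two ablation variants exist: "noNeigh" uses z(v) = f(v) directly (no
neighbor aggregation at all) and "noAttention" replaces the attention
weights by a learned dense layer over the concatenated type embeddings.

A type that was never sampled for a node falls back to the node's own
content embedding, so the fusion stage always sees all four members.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .embedding import ContentEmbeddingTable
from .hetgraph import NODE_TYPES
from .sampler import TypedNeighborSet

VARIANTS = ("full", "noNeigh", "noAttention")


@dataclass
class ModelConfig:
    d: int = 128                 # embedding size; must be even (d/2 per LSTM direction)
    lr: float = 1e-3             # Adam learning rate
    epochs: int = 50
    batch_size: int = 64
    seed: int = 0
    variant: str = "full"
    fuse_activation: str = "relu"   # outer activation of the fused embedding z(v)
    fine_tune: bool = False         # allow gradients into the content table

    def __post_init__(self) -> None:
        if self.d % 2 != 0 or self.d < 2:
            raise ValueError(f"embedding size must be even and >= 2, got {self.d}")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; pick one of {VARIANTS}")


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    s = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-s, s, size=shape)


class TypeAggregator:
    """Bi-LSTM over one type's neighbor sequence; standard gating with tanh
    candidate cell. Gate blocks are packed [input, forget, output, candidate]
    into single (d x 4H) input and (H x 4H) recurrent matrices per direction."""

    def __init__(self, node_type: str, d: int, rng: np.random.Generator):
        self.node_type = node_type
        self.d = d
        self.hidden = d // 2
        H = self.hidden
        self.W_f = Tensor(_glorot(rng, (d, 4 * H)), requires_grad=True)
        self.U_f = Tensor(_glorot(rng, (H, 4 * H)), requires_grad=True)
        self.b_f = Tensor(np.zeros(4 * H), requires_grad=True)
        self.W_b = Tensor(_glorot(rng, (d, 4 * H)), requires_grad=True)
        self.U_b = Tensor(_glorot(rng, (H, 4 * H)), requires_grad=True)
        self.b_b = Tensor(np.zeros(4 * H), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [self.W_f, self.U_f, self.b_f, self.W_b, self.U_b, self.b_b]

    def _run(self, xs: list[Tensor], W: Tensor, U: Tensor, b: Tensor) -> list[Tensor]:
        H = self.hidden
        B = xs[0].shape[0]
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        out = []
        for x in xs:
            pre = x @ W + h @ U + b
            i = pre.narrow(1, 0, H).sigmoid()
            f = pre.narrow(1, H, H).sigmoid()
            o = pre.narrow(1, 2 * H, H).sigmoid()
            c_tilde = pre.narrow(1, 3 * H, H).tanh()
            c = i * c_tilde + f * c
            h = o * c.tanh()
            out.append(h)
        return out

    def forward(self, xs: list[Tensor]) -> Tensor:
        """Aggregate a neighbor sequence given as k tensors of shape (B, d).

        Concatenates forward and backward hidden states per position and
        mean-pools over the k positions; output shape (B, d).
        """
        h_fwd = self._run(xs, self.W_f, self.U_f, self.b_f)
        h_bwd_rev = self._run(list(reversed(xs)), self.W_b, self.U_b, self.b_b)
        h_bwd = list(reversed(h_bwd_rev))
        per_pos = [ad.concat([hf, hb], axis=1) for hf, hb in zip(h_fwd, h_bwd)]
        total = per_pos[0]
        for t in per_pos[1:]:
            total = total + t
        return total * (1.0 / len(per_pos))


@dataclass
class ModelState:
    """All learnable parameters plus the training configuration."""

    cfg: ModelConfig
    aggregators: dict[str, TypeAggregator]
    q: Tensor                       # attention vector, shape (2d, 1)
    clf_W: Tensor                   # classifier weights, stored (2d, 2)
    clf_b: Tensor                   # classifier bias, shape (2,)
    dense_W: Tensor | None = None   # noAttention fusion layer, (4d, d)
    dense_b: Tensor | None = None
    loss_trajectory: list[float] = field(default_factory=list)

    def parameters(self) -> list[Tensor]:
        if self.cfg.variant == "noNeigh":
            return [self.clf_W, self.clf_b]
        params: list[Tensor] = []
        for t in NODE_TYPES:
            params += self.aggregators[t].parameters()
        if self.cfg.variant == "noAttention":
            params += [self.dense_W, self.dense_b]
        else:
            params += [self.q]
        params += [self.clf_W, self.clf_b]
        return params

    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.parameters())


def init_state(cfg: ModelConfig) -> ModelState:
    rng = np.random.default_rng(cfg.seed)
    d = cfg.d
    aggs = {t: TypeAggregator(t, d, rng) for t in NODE_TYPES}
    q = Tensor(rng.normal(scale=1.0 / np.sqrt(2 * d), size=(2 * d, 1)), requires_grad=True)
    clf_W = Tensor(_glorot(rng, (2 * d, 2)), requires_grad=True)
    clf_b = Tensor(np.zeros(2), requires_grad=True)
    state = ModelState(cfg=cfg, aggregators=aggs, q=q, clf_W=clf_W, clf_b=clf_b)
    if cfg.variant == "noAttention":
        state.dense_W = Tensor(_glorot(rng, (4 * d, d)), requires_grad=True)
        state.dense_b = Tensor(np.zeros(d), requires_grad=True)
    return state


def make_variant(state: ModelState, variant: str) -> ModelState:
    """A ModelState for an ablation variant sharing the seed/config of ``state``.

    "full" returns the state unchanged; the variants are re-initialized from
    the same seed so ablation comparisons differ only in architecture.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; pick one of {VARIANTS}")
    if variant == state.cfg.variant:
        return state
    return init_state(replace(state.cfg, variant=variant))


# --------------------------------------------------------------------------
# forward pieces
# --------------------------------------------------------------------------

def _fuse_activation(t: Tensor, kind: str) -> Tensor:
    if kind == "relu":
        return t.relu()
    if kind == "identity":
        return t
    raise ValueError(f"unknown fuse activation {kind!r}")


def aggregate_type(neighbor_vectors, agg: TypeAggregator,
                   center_vector: np.ndarray | None = None) -> np.ndarray:
    """Single-node type aggregation: (k, d) neighbor vectors -> d-vector f^t(v).

    An empty neighbor list (type never sampled) returns the center's own
    content vector — the documented fallback.
    """
    arr = np.asarray(neighbor_vectors, dtype=float)
    if arr.size == 0:
        if center_vector is None:
            raise ValueError("empty neighbor list requires the center's own vector")
        return np.asarray(center_vector, dtype=float).copy()
    xs = [Tensor(arr[None, s, :]) for s in range(arr.shape[0])]
    return agg.forward(xs).data[0]


def attention_fuse(f_self: np.ndarray, f_types: dict[str, np.ndarray],
                   q: np.ndarray | Tensor,
                   activation: str = "relu") -> tuple[np.ndarray, dict[str, float]]:
    """Single-node attention fusion; returns (z, betas over {'self'} + types)."""
    qt = q if isinstance(q, Tensor) else Tensor(np.asarray(q, dtype=float).reshape(-1, 1))
    members = [("self", Tensor(np.asarray(f_self, dtype=float)[None, :]))]
    for t in sorted(f_types):
        members.append((t, Tensor(np.asarray(f_types[t], dtype=float)[None, :])))
    fs = members[0][1]
    logits = ad.concat([ad.concat([fs, fk], axis=1) @ qt for _, fk in members], axis=1)
    betas = ad.softmax(logits.relu(), axis=1)
    z = None
    for k, (_, fk) in enumerate(members):
        term = betas.narrow(1, k, 1) * fk
        z = term if z is None else z + term
    z = _fuse_activation(z, activation)
    beta_map = {name: float(betas.data[0, k]) for k, (name, _) in enumerate(members)}
    return z.data[0], beta_map


def score_pair(z_l: np.ndarray, z_d: np.ndarray, clf_W, clf_b) -> float:
    """Positive-class probability for one (lncRNA, disease) embedding pair."""
    W = clf_W.data if isinstance(clf_W, Tensor) else np.asarray(clf_W, dtype=float)
    b = clf_b.data if isinstance(clf_b, Tensor) else np.asarray(clf_b, dtype=float)
    if W.shape[0] == 2 and W.shape[1] != 2:
        W = W.T  # accept the (2, 2d) layout as well
    x = np.concatenate([np.asarray(z_l, float), np.asarray(z_d, float)])
    logits = x @ W + b
    logits = logits - logits.max()
    e = np.exp(logits)
    return float(e[1] / e.sum())


def loss(scores, labels) -> float:
    """Two-class cross-entropy  -sum_i [y_i log s_i + (1-y_i) log(1-s_i)].

    Scores exactly 0 or 1 are clamped at 1e-12 with a warning.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    eps = 1e-12
    if ((s <= 0.0) | (s >= 1.0)).any():
        warnings.warn("scores at 0 or 1 clamped to (1e-12, 1-1e-12)")
        s = np.clip(s, eps, 1.0 - eps)
    return float(-(y * np.log(s) + (1.0 - y) * np.log(1.0 - s)).sum())


# --------------------------------------------------------------------------
# batched forward / training
# --------------------------------------------------------------------------

class _FeatureIndex:
    """Precomputed per-node typed-neighbor index arrays into the content table."""

    def __init__(self, content: ContentEmbeddingTable,
                 neighbors: dict[str, TypedNeighborSet], nodes: list[str]):
        self.nodes = list(nodes)
        self.node_pos = {n: i for i, n in enumerate(self.nodes)}
        self.self_idx = np.array([content.index(n) for n in self.nodes])
        self.type_idx: dict[str, np.ndarray] = {}
        self.type_mask: dict[str, np.ndarray] = {}
        for t in NODE_TYPES:
            ks = [len(neighbors[n].neighbors[t]) for n in self.nodes if n in neighbors]
            k = max([k for k in ks if k > 0], default=1)
            idx = np.zeros((len(self.nodes), k), dtype=np.int64)
            mask = np.zeros(len(self.nodes))
            for i, n in enumerate(self.nodes):
                ns = neighbors.get(n)
                ids = ns.ids(t) if ns is not None else []
                if ids:
                    idx[i] = [content.index(x) for x in ids]
                    mask[i] = 1.0
                else:
                    idx[i] = content.index(n)  # fallback rows feed f(v) itself
            self.type_idx[t] = idx
            self.type_mask[t] = mask[:, None]


def _forward_nodes(state: ModelState, content_t: Tensor, feat: _FeatureIndex) -> Tensor:
    """Fused embeddings z for feat.nodes; shape (n_nodes, d)."""
    cfg = state.cfg
    f_self = content_t.gather_rows(feat.self_idx)
    if cfg.variant == "noNeigh":
        return f_self
    f_types: dict[str, Tensor] = {}
    for t in NODE_TYPES:
        idx = feat.type_idx[t]
        xs = [content_t.gather_rows(idx[:, s]) for s in range(idx.shape[1])]
        agg_out = state.aggregators[t].forward(xs)
        mask = Tensor(feat.type_mask[t])
        # rows whose type was never sampled use the node's own content vector
        f_types[t] = mask * agg_out + (1.0 - mask) * f_self
    if cfg.variant == "noAttention":
        x = ad.concat([f_self] + [f_types[t] for t in NODE_TYPES], axis=1)
        return _fuse_activation(x @ state.dense_W + state.dense_b, cfg.fuse_activation)
    members = [f_self] + [f_types[t] for t in NODE_TYPES]
    logits = ad.concat([ad.concat([f_self, fk], axis=1) @ state.q for fk in members], axis=1)
    betas = ad.softmax(logits.relu(), axis=1)
    z = None
    for k, fk in enumerate(members):
        term = betas.narrow(1, k, 1) * fk
        z = term if z is None else z + term
    return _fuse_activation(z, cfg.fuse_activation)


def _pair_logits(state: ModelState, z: Tensor, l_pos: np.ndarray, d_pos: np.ndarray) -> Tensor:
    x = ad.concat([z.gather_rows(l_pos), z.gather_rows(d_pos)], axis=1)
    return x @ state.clf_W + state.clf_b


class _Adam:
    def __init__(self, params: list[Tensor], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m[:] = b1 * m + (1 - b1) * p.grad
            v[:] = b2 * v + (1 - b2) * p.grad**2
            mh = m / (1 - b1**self.t)
            vh = v / (1 - b2**self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _check_pairs(pairs, content: ContentEmbeddingTable,
                 neighbors: dict[str, TypedNeighborSet], variant: str) -> None:
    # nodes without a sampled neighbor set (isolated in the training graph)
    # are allowed: every type falls back to the node's own content vector
    for l, d, *_ in pairs:
        for node in (l, d):
            if node not in content:
                raise ValueError(f"pair endpoint {node!r} has no content embedding")


def train(
    state: ModelState,
    content: ContentEmbeddingTable,
    neighbors: dict[str, TypedNeighborSet],
    pairs: list[tuple[str, str, int]],
) -> ModelState:
    """Mini-batch Adam training on labeled (lncRNA, disease, y) pairs.

    Records the mean per-sample cross-entropy of each epoch in
    state.loss_trajectory. Deterministic given state.cfg.seed.
    """
    cfg = state.cfg
    _check_pairs(pairs, content, neighbors, cfg.variant)
    nodes = sorted({n for l, d, _ in pairs for n in (l, d)})
    feat = _FeatureIndex(content, neighbors, nodes)
    l_pos = np.array([feat.node_pos[l] for l, _, _ in pairs])
    d_pos = np.array([feat.node_pos[d] for _, d, _ in pairs])
    labels = np.array([y for _, _, y in pairs], dtype=np.int64)

    content_t = Tensor(content.vectors.copy(), requires_grad=cfg.fine_tune)
    params = state.parameters() + ([content_t] if cfg.fine_tune else [])
    opt = _Adam(params, cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    n = len(pairs)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for s in range(0, n, cfg.batch_size):
            bidx = order[s : s + cfg.batch_size]
            opt.zero_grad()
            z = _forward_nodes(state, content_t, feat)
            logits = _pair_logits(state, z, l_pos[bidx], d_pos[bidx])
            batch_loss = ad.softmax_cross_entropy(logits, labels[bidx])
            batch_loss.backward()
            opt.step()
            epoch_loss += float(batch_loss.data) * len(bidx)
        state.loss_trajectory.append(epoch_loss / n)
    if cfg.fine_tune:
        content.vectors[:] = content_t.data
    return state


def predict(
    state: ModelState,
    content: ContentEmbeddingTable,
    neighbors: dict[str, TypedNeighborSet],
    pairs: list[tuple[str, str]],
) -> np.ndarray:
    """Positive-class probability per pair, in input order.

    Each pair's score depends only on its own two nodes' embeddings and
    neighbor sets, so scores are invariant to batch composition and order.
    """
    _check_pairs(pairs, content, neighbors, state.cfg.variant)
    nodes = sorted({n for p in pairs for n in p[:2]})
    feat = _FeatureIndex(content, neighbors, nodes)
    content_t = Tensor(content.vectors)
    z = _forward_nodes(state, content_t, feat)
    l_pos = np.array([feat.node_pos[p[0]] for p in pairs])
    d_pos = np.array([feat.node_pos[p[1]] for p in pairs])
    logits = _pair_logits(state, z, l_pos, d_pos).data
    logits = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e[:, 1] / e.sum(axis=1)


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

def save_state(state: ModelState, path) -> None:
    """Single-file checkpoint: every tensor plus the JSON-encoded config."""
    arrays: dict[str, np.ndarray] = {}
    for t in NODE_TYPES:
        agg = state.aggregators[t]
        for name in ("W_f", "U_f", "b_f", "W_b", "U_b", "b_b"):
            arrays[f"agg.{t}.{name}"] = getattr(agg, name).data
    arrays["q"] = state.q.data
    arrays["clf_W"] = state.clf_W.data
    arrays["clf_b"] = state.clf_b.data
    if state.dense_W is not None:
        arrays["dense_W"] = state.dense_W.data
        arrays["dense_b"] = state.dense_b.data
    cfg_json = json.dumps(state.cfg.__dict__)
    np.savez(path, __config__=np.array(cfg_json), **arrays)


def load_state(path) -> ModelState:
    with np.load(path, allow_pickle=False) as data:
        cfg = ModelConfig(**json.loads(str(data["__config__"])))
        state = init_state(cfg)
        for t in NODE_TYPES:
            agg = state.aggregators[t]
            for name in ("W_f", "U_f", "b_f", "W_b", "U_b", "b_b"):
                getattr(agg, name).data[:] = data[f"agg.{t}.{name}"]
        state.q.data[:] = data["q"]
        state.clf_W.data[:] = data["clf_W"]
        state.clf_b.data[:] = data["clf_b"]
        if "dense_W" in data:
            state.dense_W.data[:] = data["dense_W"]
            state.dense_b.data[:] = data["dense_b"]
    return state
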