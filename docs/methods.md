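# Methods

`hetwalk` predicts lncRNA–disease associations from a heterogeneous
network of lncRNAs, diseases and miRNAs. This note describes the model,
its assumptions, the tunable parameters, the synthetic benchmark, the
numerical choices, and — importantly — a structural limitation of the
scoring architecture that determines what the benchmark results can and
cannot show.

## Model

### Similarity layers

Disease semantic similarity (DSS) uses the DAG contribution measure: a
disease contributes 1 to itself and `delta^k` to an ancestor `k` edges up
(taking the maximum over paths); the similarity of two diseases is the sum
of their shared ancestors' contributions divided by the sum of their total
semantic values. `delta` defaults to 0.5, the conventional value in the
disease-similarity literature; the measure's source data (an ontology such
as MeSH) is typically distributed separately, so a precomputed DSS matrix
may be supplied directly instead of a DAG.

lncRNA functional similarity (LFS) is the best-match average of DSS over
the two lncRNAs' associated-disease sets,

    S(l1, l2) = ( Σ_i max_j DSS(d1i, d2j) + Σ_j max_i DSS(d2j, d1i) ) / (m + n),

the "similar diseases ↔ functionally similar lncRNAs" assumption made
operational. A lncRNA with no known disease has similarity 0 to everything
(diagonal fixed at 1); both sets empty would divide by zero, so the pair
value is defined as 0 with a warning.

### Heterogeneous network

Nodes are lncRNAs, diseases and miRNAs; edges are lncRNA–disease and
lncRNA–miRNA associations (weight 1) plus lncRNA–lncRNA similarity edges.
The similarity matrix is dense, so it is sparsified to each lncRNA's
`lnc_topk` (default 10) most similar partners, weight = similarity; a
threshold mode exists as an alternative. Without sparsification the
similarity layer is a near-clique that dominates every walk. Edges are
stored once and walked in both directions. There are deliberately no
disease–disease or miRNA–miRNA edges.

### Neighbor sampling (restart random walk)

From every node a walk jumps back to its start with probability `p`
(default 0.5) or moves to a neighbor with probability proportional to edge
weight times a node2vec-style in-out bias: moves to nodes not adjacent to
the previous position are down-weighted by `1/q`. The default `q = 1`
gives the pure restart walk, whose visiting distribution solves
`π = p·e_start + (1−p)·π W`; the package includes a power-iteration solver
for that equation as an independent test oracle (damped iteration, so
periodic chains at `p = 0` also converge; tolerance 1e-10).

Visited nodes (excluding the start itself) are banked until
`collect_size` (default 100) visits have accumulated and every node type
has at least `min_per_type` (default 5), or `max_steps`
(default 10·collect_size) is reached, in which case the result is flagged
and padding applies downstream. Per type, the top `k_t` most frequently
visited nodes (defaults: 10 lncRNAs, 10 diseases, 6 miRNAs; ties broken by
identifier) form the node's typed neighbor set; fewer than `k_t` distinct
neighbors are padded by cycling the ranked list so the Bi-LSTM always sees
fixed-length input, and a type never visited stays empty — the model then
substitutes the node's own content embedding. Each node's walk consumes an
independent RNG stream derived from (seed, node position), which makes the
output reproducible and insensitive to relabeling that preserves order.

### Content embeddings

The walk sequences double as the skip-gram training corpus: one sentence
per start node, tokens = visited node identifiers. Embeddings are trained
with negative sampling (window 5, 5 negatives, 5 epochs, linearly decayed
learning rate 0.025, unigram^0.75 noise distribution, min token count 1),
implemented as vectorized mini-batch SGD in numpy with a single seeded
stream, so identical corpus + seed gives identical tables. Batches are
kept at 4096 pairs: summed duplicate-row updates grow with batch size and
destabilize training well before 10^4. Isolated nodes never enter the
corpus and receive seeded random vectors with a warning.

### Aggregation, fusion, scoring

One bidirectional LSTM per node type (standard gating, tanh candidate
cell, hidden size d/2 per direction) reads the type's neighbor content
vectors in frequency order; forward and backward hidden states are
concatenated per position and mean-pooled, giving a d-dimensional type
embedding f^t(v). Attention fuses the node's own content embedding f(v)
with its three type embeddings:

    β_k ∝ exp(ReLU(qᵀ [f(v) ‖ f^k(v)])),   z(v) = ReLU(Σ_k β_k f^k(v)),

with q a learned 2d-vector. A pair (l, d) is scored by softmax over a
2-logit linear layer on the concatenation [z(l) ‖ z(d)], trained with
two-class cross-entropy against known positives and uniformly sampled
unknown pairs (balanced 1:1). Content embeddings are frozen inputs by
default; a fine-tune flag propagates gradients into them.

Two printed-formula corrections are deliberate: the candidate cell uses
tanh (the sigmoid sometimes printed for it breaks the (−1,1) cell update
and is treated as a typo), and the loss is the full two-class
cross-entropy rather than only the positive-class term. Likewise the
ROC/PR bookkeeping uses the standard definitions
(TPR = TP/(TP+FN), FPR = FP/(FP+TN), Precision = TP/(TP+FP),
Recall = TPR); variants that divide by TP+TN cannot produce the curves
being integrated. AUC is the trapezoidal ROC area (equal to pairwise
concordance with half credit for ties — asserted against a brute-force
oracle in the tests); AUPR is the step-wise, non-interpolated precision
integral.

The default optimizer is Adam (lr 1e-3, batch 64, 50 epochs, d = 128); the
desk-scale benchmark configuration uses d = 64, 30 epochs, batch 256,
lr 5e-3, which reaches the same final fit in about a tenth of the time on
one CPU. Training and inference run entirely on a small float64
reverse-mode autodiff written for this package; every primitive and the
full frozen network are checked against central finite differences
(relative tolerance 1e-4).

### Ablation variants

`noNeigh` scores pairs from the raw content embeddings (z(v) = f(v); no
aggregation, no attention). `noAttention` replaces the attention weights
by a learned dense layer over the concatenated type embeddings. Variants
are re-initialized from the same seed so comparisons differ only in
architecture.

## Evaluation protocols

Balanced 5-fold cross-validation draws as many unknown pairs as there are
known positives (uniformly, without replacement, seeded) and splits the
combined set into five near-equal folds. In the default **strict** mode,
each round removes the test fold's positives from the association matrix
before anything is computed — similarity, graph, walks, embeddings and
classifier all see only training edges — and the absence of held-out edges
from the fold's graph is asserted, not assumed. A **paper** mode (one
shared build from all known associations) is also provided, since much of
this literature evaluates that way; it inflates results on real data
through degree leakage. Candidate ranking for a disease excludes its known
partners and sorts by score (ties by identifier); the novel-disease
protocol masks a disease's entire column, retrains from scratch and ranks
every lncRNA.

## Synthetic benchmark

The generator plants the structure the method presumes: nodes of all three
types are assigned to blocks; associations appear with probability `p_in`
within a block and `p_out` across; DSS is `dss_in` within disease blocks,
`dss_out` across, diagonal 1. The canonical configuration is 60 lncRNAs,
80 diseases, 50 miRNAs, 4 blocks, p_in = 0.30, p_out = 0.01,
dss_in = 0.8, dss_out = 0.1, seed 1 (≈ 400 expected positives). DSS is
emitted directly for speed; a DAG emitter (one root per block under a
global root) exercises the semantic-similarity computation end to end. An
optional hold-out fraction moves LD positives into a truth list for
masking experiments.

What the generator does **not** emulate: the heavy-tailed degree
distributions of curated association databases (a handful of intensely
studied lncRNAs carry a large share of all known associations), ontology
depth beyond two levels, and correlated noise between the LD and LM
layers. This matters for interpreting the results — see below.

## A structural limit of the scoring architecture

The pair score is softmax over a linear layer on the **concatenation**
[z(l) ‖ z(d)], so every attainable score is additive,
s(l, d) = u·z(l) + v·z(d) + c, where z is a per-node quantity. An additive
ranking cannot express the interaction "l and d belong to the same
block": for equal blocks, s(1,1) + s(2,2) = s(1,2) + s(2,1), so
within-block positives cannot systematically outrank cross-block
negatives. On the canonical benchmark even the finest additive family
(one free score per node, fit on the evaluation pairs themselves) reaches
AUC ≈ 0.74, while a same-block oracle reaches ≈ 0.89; under strict
cross-validation — where the balanced, uniformly-sampled negatives make
the node marginals uninformative — additive models of any capacity sit
near AUC 0.5, and that is exactly where the full model, both ablation
variants and every embedding size land (≈ 0.49–0.52 over seeds 1–3).

The consequence: on a node-exchangeable planted-block benchmark this
architecture cannot demonstrate link-prediction skill, and its benchmark
cross-validation numbers are noise-level *by construction*, not by
implementation defect. High reported performance of additive scorers on
real association data is consistent with this analysis: real datasets
carry strong node-degree signal (popular lncRNAs and well-studied diseases
account for most positives), which additive scores capture, and
per-disease top-k lists produced by such models overlap heavily across
diseases — a near-global lncRNA ranking. What the passing tests *do*
establish: every stage transmits the planted structure (embedding
block-separation rises with planted contrast), all probabilistic contracts
hold, gradients are exact, the protocols are leak-free and every stage is
reproducible bit-for-bit from one seed. Interaction-aware scoring (e.g. a
bilinear term or element-wise product features) would lift the ceiling,
but is deliberately out of scope: the concatenation scorer is the
method being reproduced.

## Numerical choices and degenerate inputs

- float64 throughout the model; sigmoid uses the sign-split stable form;
  softmax subtracts a detached row max; cross-entropy floors the picked
  probability at 1e-300; the standalone loss function clamps scores at
  1e-12 with a warning.
- Ties: neighbor frequency ties and ranking-score ties break by
  identifier; similarity top-k ties likewise.
- Degenerate inputs: isolated walk starts are rejected; isolated nodes are
  skipped in sampling, get fallback content vectors, and fall back to
  f(v) for all types in the model; a disease with nothing to mask is
  rejected by the novel-disease protocol; metric computation refuses
  single-class inputs.
- Determinism: one top-level seed fans out to walk/skip-gram/model stages
  (seed, seed+1, seed+2); all randomness flows through
  `numpy.random.Generator`; string hashes use CRC32, not Python's
  per-process `hash`.

## Problem sizes used in the shipped runs

The test suite and the acceptance script run the canonical benchmark
(190 nodes, ≈ 800 balanced pairs, d = 64) for three seeds across three
model variants plus a d = 8 sweep, reusing identical per-fold
graph/walk/embedding builds across variants; the complete set finishes in
roughly seven minutes on one CPU. The library defaults (d = 128, 50
epochs) are intended for real-data scale (hundreds of nodes per type).
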