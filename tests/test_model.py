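"""The association-prediction network: Bi-LSTM type aggregation, attention
fusion, pair scoring, the cross-entropy loss, training behaviour, ablation
variants and an end-to-end analytic-vs-finite-difference gradient check."""

import numpy as np
import pytest

from hetwalk import autodiff as ad
from hetwalk.autodiff import Tensor
from hetwalk.embedding import ContentEmbeddingTable
from hetwalk.hetgraph import DISEASE, LNCRNA, MIRNA, NODE_TYPES
from hetwalk.model import (
    ModelConfig,
    TypeAggregator,
    _FeatureIndex,
    _forward_nodes,
    _pair_logits,
    aggregate_type,
    attention_fuse,
    init_state,
    loss,
    make_variant,
    predict,
    score_pair,
    train,
)
from hetwalk.sampler import TypedNeighborSet


from conftest import mini_world


class TestTypeAggregator:
    def test_output_dimension_is_d(self):
        d = 8
        agg = TypeAggregator(DISEASE, d, np.random.default_rng(0))
        out = aggregate_type(np.random.default_rng(1).normal(size=(3, d)), agg)
        assert out.shape == (d,)

    def test_single_neighbor_mean_pool_is_identity(self):
        d = 6
        agg = TypeAggregator(DISEASE, d, np.random.default_rng(0))
        x = np.random.default_rng(1).normal(size=(1, d))
        out = aggregate_type(x, agg)
        hf = agg._run([Tensor(x)], agg.W_f, agg.U_f, agg.b_f)[0].data[0]
        hb = agg._run([Tensor(x)], agg.W_b, agg.U_b, agg.b_b)[0].data[0]
        np.testing.assert_allclose(out, np.concatenate([hf, hb]), atol=1e-12)

    def test_zero_parameters_give_zero_output(self):
        d = 4
        agg = TypeAggregator(DISEASE, d, np.random.default_rng(0))
        for p in agg.parameters():
            p.data[:] = 0.0
        out = aggregate_type(np.ones((3, d)), agg)
        np.testing.assert_allclose(out, np.zeros(d), atol=1e-15)

    def test_empty_list_falls_back_to_center_vector(self):
        agg = TypeAggregator(DISEASE, 4, np.random.default_rng(0))
        center = np.arange(4.0)
        np.testing.assert_array_equal(aggregate_type([], agg, center), center)
        with pytest.raises(ValueError, match="center"):
            aggregate_type([], agg)


class TestAttentionFuse:
    def test_betas_sum_to_one(self):
        rng = np.random.default_rng(0)
        d = 6
        f_self = rng.normal(size=d)
        f_types = {t: rng.normal(size=d) for t in NODE_TYPES}
        _, betas = attention_fuse(f_self, f_types, rng.normal(size=2 * d))
        assert sum(betas.values()) == pytest.approx(1.0, abs=1e-6)

    def test_identical_members_get_exactly_uniform_betas(self):
        d = 4
        f = np.full(d, 0.3)
        _, betas = attention_fuse(f, {t: f.copy() for t in NODE_TYPES},
                                  np.random.default_rng(1).normal(size=2 * d))
        assert all(b == 0.25 for b in betas.values())

    def test_self_only_logit_gives_uniform_betas_and_mean_fusion(self):
        # q touches only the (shared) self half of each concatenation, so all
        # four logits coincide and z is the ReLU of the plain average
        d = 2
        q = np.array([1.0, 0.0, 0.0, 0.0])
        f_self = np.array([2.0, 0.0])
        f_types = {
            LNCRNA: np.array([0.5, -1.0]),
            DISEASE: np.array([-0.25, 0.75]),
            MIRNA: np.array([0.1, 0.2]),
        }
        z, betas = attention_fuse(f_self, f_types, q)
        assert all(b == pytest.approx(0.25, abs=1e-12) for b in betas.values())
        mean = (f_self + sum(f_types.values())) / 4.0
        np.testing.assert_allclose(z, np.maximum(mean, 0.0), atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            attention_fuse(np.ones(4), {LNCRNA: np.ones(3)}, np.ones(8))


class TestScorePair:
    def test_zero_classifier_scores_half_exactly(self):
        assert score_pair(np.ones(3), np.ones(3), np.zeros((2, 6)), np.zeros(2)) == 0.5

    def test_large_negative_bias_saturates_to_zero(self):
        s = score_pair(np.ones(2), np.ones(2), np.zeros((2, 4)), np.array([50.0, -50.0]))
        assert s < 1e-20

    def test_hand_softmax_d1(self):
        # d=1, W=[[1,0],[0,1]], b=0, x=(2,0): class-0 prob e^2/(e^2+1)
        W = np.array([[1.0, 0.0], [0.0, 1.0]])
        s = score_pair(np.array([2.0]), np.array([0.0]), W, np.zeros(2))
        class0 = np.e**2 / (np.e**2 + 1)
        assert s == pytest.approx(1 - class0, abs=1e-12)

    def test_complementary_probabilities_sum_to_one(self):
        rng = np.random.default_rng(0)
        W, b = rng.normal(size=(2, 8)), rng.normal(size=2)
        z_l, z_d = rng.normal(size=4), rng.normal(size=4)
        s = score_pair(z_l, z_d, W, b)
        s_flip = score_pair(z_l, z_d, W[::-1], b[::-1])  # swap the two classes
        assert s + s_flip == pytest.approx(1.0, abs=1e-7)


class TestLoss:
    def test_perfect_scores_give_near_zero(self):
        eps = 1e-9
        val = loss([1 - eps, eps], [1, 0])
        assert 0 <= val < 1e-8

    def test_all_half_scores_closed_form(self):
        T = 7
        assert loss([0.5] * T, [1, 0, 1, 0, 1, 0, 1]) == pytest.approx(
            T * np.log(2), abs=1e-9
        )

    def test_hand_example(self):
        assert loss([0.9, 0.2], [1, 0]) == pytest.approx(
            -(np.log(0.9) + np.log(0.8)), abs=1e-12
        )

    def test_degenerate_scores_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            val = loss([1.0, 0.0], [1, 0])
        assert np.isfinite(val)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            loss([0.5], [1, 0])


class TestTraining:
    def test_loss_decreases_on_separable_toy(self):
        content, neighbors, pairs = mini_world(d=8, seed=1)
        cfg = ModelConfig(d=8, epochs=25, batch_size=8, lr=1e-2, seed=0)
        state = train(init_state(cfg), content, neighbors, pairs)
        assert state.loss_trajectory[-1] < state.loss_trajectory[0]

    def test_positive_pairs_outscore_negative_pairs_after_training(self):
        content, neighbors, pairs = mini_world(d=8, seed=2)
        cfg = ModelConfig(d=8, epochs=40, batch_size=8, lr=1e-2, seed=0)
        state = train(init_state(cfg), content, neighbors, pairs)
        scores = predict(state, content, neighbors, [(l, d) for l, d, _ in pairs])
        y = np.array([y for _, _, y in pairs], dtype=bool)
        assert scores[y].mean() > scores[~y].mean()

    def test_same_seed_reproduces_final_scores(self):
        content, neighbors, pairs = mini_world(d=8, seed=3)
        cfg = ModelConfig(d=8, epochs=5, batch_size=8, lr=1e-2, seed=9)
        s1 = train(init_state(cfg), content, neighbors, pairs)
        s2 = train(init_state(cfg), content, neighbors, pairs)
        p1 = predict(s1, content, neighbors, [(l, d) for l, d, _ in pairs])
        p2 = predict(s2, content, neighbors, [(l, d) for l, d, _ in pairs])
        np.testing.assert_array_equal(p1, p2)

    def test_linearly_separable_frozen_features_reach_full_accuracy(self):
        # noNeigh bypasses the aggregators: scoring is logistic regression on
        # frozen [f(l) || f(d)]; verify the oracle solvability first
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(4)
        lncs = [f"l{i}" for i in range(8)]
        diss = [f"d{i}" for i in range(8)]
        d = 4
        vecs = []
        labels_by_l = {}
        for i, l in enumerate(lncs):
            side = 1.0 if i < 4 else -1.0
            labels_by_l[l] = int(side > 0)
            vecs.append(side * np.ones(d) + 0.05 * rng.normal(size=d))
        for _ in diss:
            vecs.append(0.1 * rng.normal(size=d))
        content = ContentEmbeddingTable(lncs + diss, np.array(vecs))
        pairs = [(l, dd, labels_by_l[l]) for l in lncs for dd in diss[:2]]
        X = np.array([np.concatenate([content.lookup(l), content.lookup(dd)])
                      for l, dd, _ in pairs])
        y = np.array([t[2] for t in pairs])
        oracle = LogisticRegression(max_iter=1000).fit(X, y)
        assert oracle.score(X, y) == 1.0
        cfg = ModelConfig(d=d, epochs=150, batch_size=16, lr=5e-2, seed=0,
                          variant="noNeigh")
        state = train(init_state(cfg), content, {}, pairs)
        scores = predict(state, content, {}, [(l, dd) for l, dd, _ in pairs])
        assert ((scores > 0.5).astype(int) == y).all()

    def test_unknown_pair_endpoint_rejected(self):
        content, neighbors, pairs = mini_world()
        with pytest.raises(ValueError, match="content embedding"):
            train(init_state(ModelConfig(d=8, epochs=1)), content, neighbors,
                  pairs + [("ghost", "d0", 1)])


class TestPredict:
    def test_scores_bounded_and_duplicates_identical(self):
        content, neighbors, pairs = mini_world(seed=5)
        state = init_state(ModelConfig(d=8, seed=1))
        batch = [("l0", "d0"), ("l1", "d1"), ("l0", "d0")]
        scores = predict(state, content, neighbors, batch)
        assert ((scores >= 0) & (scores <= 1)).all()
        assert scores[0] == scores[2]

    def test_batch_order_invariance(self):
        content, neighbors, pairs = mini_world(seed=6)
        state = init_state(ModelConfig(d=8, seed=2))
        batch = [(l, d) for l, d, _ in pairs]
        fwd = predict(state, content, neighbors, batch)
        rev = predict(state, content, neighbors, batch[::-1])
        np.testing.assert_allclose(fwd, rev[::-1], atol=1e-12)


class TestVariants:
    def test_parameter_counts_differ_between_full_and_no_attention(self):
        full = init_state(ModelConfig(d=8, seed=0))
        no_att = make_variant(full, "noAttention")
        assert full.parameter_count() != no_att.parameter_count()

    def test_no_neigh_ignores_neighbor_sets(self):
        content, neighbors, pairs = mini_world(seed=7)
        state = init_state(ModelConfig(d=8, seed=0, variant="noNeigh"))
        batch = [(l, d) for l, d, _ in pairs]
        base = predict(state, content, neighbors, batch)
        shuffled = {
            n: TypedNeighborSet(n, {t: lst[::-1] for t, lst in ns.neighbors.items()})
            for n, ns in neighbors.items()
        }
        np.testing.assert_array_equal(base, predict(state, content, shuffled, batch))

    def test_full_model_does_react_to_neighbor_sets(self):
        content, neighbors, pairs = mini_world(seed=8)
        state = init_state(ModelConfig(d=8, seed=0))
        batch = [(l, d) for l, d, _ in pairs]
        base = predict(state, content, neighbors, batch)
        swapped = {
            n: TypedNeighborSet(
                n,
                {
                    LNCRNA: ns.neighbors[LNCRNA],
                    DISEASE: [("d0", 1)] * len(ns.neighbors[DISEASE]),
                    MIRNA: ns.neighbors[MIRNA],
                },
            )
            for n, ns in neighbors.items()
        }
        assert not np.allclose(base, predict(state, content, swapped, batch))

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            make_variant(init_state(ModelConfig(d=8)), "bogus")


@pytest.mark.parametrize("variant", ["full", "noAttention"])
def test_analytic_gradients_match_finite_differences(variant):
    """End-to-end gradient check of the frozen d=8 mini-model."""
    content, neighbors, pairs = mini_world(d=8, seed=11)
    cfg = ModelConfig(d=8, seed=0, variant=variant)
    state = init_state(cfg)
    nodes = sorted({n for l, d, _ in pairs for n in (l, d)})
    feat = _FeatureIndex(content, neighbors, nodes)
    l_pos = np.array([feat.node_pos[l] for l, _, _ in pairs])
    d_pos = np.array([feat.node_pos[d] for _, d, _ in pairs])
    labels = np.array([y for _, _, y in pairs])

    def compute_loss() -> float:
        content_t = Tensor(content.vectors)
        z = _forward_nodes(state, content_t, feat)
        logits = _pair_logits(state, z, l_pos, d_pos)
        return float(ad.softmax_cross_entropy(logits, labels).data)

    content_t = Tensor(content.vectors)
    z = _forward_nodes(state, content_t, feat)
    batch_loss = ad.softmax_cross_entropy(_pair_logits(state, z, l_pos, d_pos), labels)
    batch_loss.backward()

    eps = 1e-6
    rng = np.random.default_rng(0)
    for p in state.parameters():
        flat = p.data.reshape(-1)
        gflat = p.grad.reshape(-1)
        picks = rng.choice(flat.size, size=min(12, flat.size), replace=False)
        for i in picks:
            orig = flat[i]
            flat[i] = orig + eps
            fp = compute_loss()
            flat[i] = orig - eps
            fm = compute_loss()
            flat[i] = orig
            fd = (fp - fm) / (2 * eps)
            # the 1e-5 floor keeps FD truncation noise on near-zero gradients
            # from masquerading as relative error
            denom = max(abs(fd), abs(gflat[i]), 1e-5)
            assert abs(gflat[i] - fd) / denom < 1e-4
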