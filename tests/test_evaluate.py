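"""Evaluation machinery: negative sampling, fold construction, ROC/PR
metrics against a brute-force concordance oracle, leakage control and the
two case-study ranking protocols."""

import numpy as np
import pytest

from hetwalk.data_io import AssociationMatrix
from hetwalk.evaluate import (
    SampleSet,
    assert_no_leakage,
    compute_metrics,
    embedding_size_sweep,
    five_fold_cv,
    make_folds,
    negative_sample,
    novel_disease_rank,
    rank_for_disease,
)
from hetwalk.pipeline import build_stage, fit_pipeline, mask_pairs


def concordance_auc(scores, labels):
    """Independent oracle: pairwise concordance with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


class TestNegativeSample:
    def test_balanced_and_disjoint(self):
        rng = np.random.default_rng(0)
        ld = AssociationMatrix(
            [f"l{i}" for i in range(6)], [f"d{j}" for j in range(7)],
            (rng.random((6, 7)) < 0.3).astype(int),
        )
        ss = negative_sample(ld, ld.n_positives, seed=1)
        assert len(ss.negatives) == len(ss.positives)
        assert not set(ss.positives) & set(ss.negatives)

    def test_same_seed_same_negatives(self):
        ld = AssociationMatrix(["l1", "l2"], ["d1", "d2", "d3"],
                               np.array([[1, 0, 0], [0, 1, 0]]))
        s1 = negative_sample(ld, 3, seed=5)
        s2 = negative_sample(ld, 3, seed=5)
        assert s1.negatives == s2.negatives

    def test_exhaustive_when_n_equals_zero_cells(self):
        ld = AssociationMatrix(
            ["l1", "l2", "l3"], ["d1", "d2", "d3"],
            np.array([[1, 1, 0], [0, 1, 0], [1, 0, 0]]),
        )
        ss = negative_sample(ld, 5, seed=0)
        assert sorted(ss.negatives) == [
            ("l1", "d3"), ("l2", "d1"), ("l2", "d3"), ("l3", "d2"), ("l3", "d3"),
        ]

    def test_oversampling_rejected(self):
        ld = AssociationMatrix(["l1"], ["d1", "d2"], np.array([[1, 0]]))
        with pytest.raises(ValueError, match="zero cells"):
            negative_sample(ld, 2, seed=0)

    def test_overlapping_sample_set_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SampleSet(positives=[("l1", "d1")], negatives=[("l1", "d1")], seed=0)


def test_folds_are_disjoint_exhaustive_and_balanced():
    folds = make_folds(23, 5, seed=3)
    all_idx = np.concatenate(folds)
    assert sorted(all_idx.tolist()) == list(range(23))
    sizes = [len(f) for f in folds]
    assert max(sizes) - min(sizes) <= 1


class TestComputeMetrics:
    def test_perfect_separation(self):
        m = compute_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert m.auc == 1.0 and m.aupr == 1.0

    def test_hand_case_three_of_four_concordant(self):
        m = compute_metrics([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0])
        assert m.auc == pytest.approx(0.75, abs=1e-12)

    def test_ties_get_half_credit(self):
        m = compute_metrics([0.3, 0.3], [1, 0])
        assert m.auc == pytest.approx(0.5, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            compute_metrics([0.5, 0.6], [1, 1])

    def test_roc_curve_endpoints(self):
        m = compute_metrics([0.9, 0.4, 0.6, 0.1], [1, 0, 1, 0])
        fpr, tpr = m.roc
        assert fpr[0] == 0.0 and tpr[0] == 0.0
        assert fpr[-1] == 1.0 and tpr[-1] == 1.0

    def test_auc_equals_concordance_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(6, 30))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            m = compute_metrics(scores, labels)
            assert m.auc == pytest.approx(concordance_auc(scores, labels), abs=1e-12)

    def test_random_scores_near_half_auc(self):
        rng = np.random.default_rng(0)
        n = 300
        labels = np.repeat([0, 1], n // 2)
        aucs = [
            compute_metrics(rng.random(n), labels).auc for _ in range(30)
        ]
        se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < 3 * se + 0.01


class TestLeakageControl:
    def test_masked_pairs_removed_everywhere(self, micro_data, micro_pipeline_cfg):
        ld, lm, dss, _ = micro_data
        masked = ld.ones()[:5]
        ld_masked = mask_pairs(ld, masked)
        assert all(ld_masked.values[ld_masked.row_index(l), ld_masked.col_index(d)] == 0
                   for l, d in masked)
        graph, _, _ = build_stage(ld_masked, lm, dss, micro_pipeline_cfg.with_seed(0))
        assert_no_leakage(graph, masked)

    def test_leaked_edge_detected(self, micro_data, micro_pipeline_cfg):
        ld, lm, dss, _ = micro_data
        graph, _, _ = build_stage(ld, lm, dss, micro_pipeline_cfg.with_seed(0))
        with pytest.raises(AssertionError, match="leaked"):
            assert_no_leakage(graph, [ld.ones()[0]])


class TestFiveFoldCV:
    def test_strict_cv_runs_and_reports_five_folds(self, micro_data, micro_pipeline_cfg):
        ld, lm, dss, _ = micro_data
        rep = five_fold_cv(ld, lm, dss, micro_pipeline_cfg, seed=1)
        assert len(rep.folds) == 5
        assert 0.0 <= rep.mean_auc <= 1.0 and 0.0 <= rep.mean_aupr <= 1.0

    def test_same_seed_reproduces_report(self, micro_data, micro_pipeline_cfg):
        ld, lm, dss, _ = micro_data
        r1 = five_fold_cv(ld, lm, dss, micro_pipeline_cfg, seed=2)
        r2 = five_fold_cv(ld, lm, dss, micro_pipeline_cfg, seed=2)
        assert r1.summary() == r2.summary()

    def test_build_cache_does_not_change_results(self, micro_data, micro_pipeline_cfg):
        ld, lm, dss, _ = micro_data
        plain = five_fold_cv(ld, lm, dss, micro_pipeline_cfg, seed=3)
        cached = five_fold_cv(ld, lm, dss, micro_pipeline_cfg, seed=3, build_cache={})
        assert plain.summary() == cached.summary()

    def test_unknown_leakage_mode_rejected(self, micro_data, micro_pipeline_cfg):
        ld, lm, dss, _ = micro_data
        with pytest.raises(ValueError, match="leakage_mode"):
            five_fold_cv(ld, lm, dss, micro_pipeline_cfg, 1, leakage_mode="loose")


@pytest.fixture(scope="module")
def micro_fitted(micro_data, micro_pipeline_cfg):
    ld, lm, dss, _ = micro_data
    cfg = micro_pipeline_cfg.with_seed(1)
    samples = negative_sample(ld, ld.n_positives, 1)
    return fit_pipeline(ld, lm, dss, samples.labeled(), cfg)


class TestRankForDisease:
    def test_known_partners_excluded_and_length_correct(self, micro_data, micro_fitted):
        ld, _, _, _ = micro_data
        disease = ld.col_ids[0]
        known = set(ld.row_ids[i] for i in np.nonzero(ld.values[:, 0])[0])
        ranked = rank_for_disease(disease, micro_fitted, ld)
        names = [l for l, _ in ranked]
        assert not set(names) & known
        assert len(names) == len(ld.row_ids) - len(known)

    def test_scores_sorted_descending(self, micro_data, micro_fitted):
        ld, _, _, _ = micro_data
        ranked = rank_for_disease(ld.col_ids[1], micro_fitted, ld)
        scores = [s for _, s in ranked]
        assert scores == sorted(scores, reverse=True)

    def test_unknown_disease_rejected(self, micro_data, micro_fitted):
        ld, _, _, _ = micro_data
        with pytest.raises(ValueError, match="unknown disease"):
            rank_for_disease("nope", micro_fitted, ld)


class TestNovelDiseaseRank:
    def test_ranking_covers_every_lncRNA(self, micro_data, micro_pipeline_cfg):
        ld, lm, dss, _ = micro_data
        disease = max(ld.col_ids, key=lambda d: ld.values[:, ld.col_index(d)].sum())
        ranked = novel_disease_rank(disease, ld, lm, dss, micro_pipeline_cfg, seed=1)
        assert sorted(l for l, _ in ranked) == sorted(ld.row_ids)

    def test_disease_without_associations_rejected(self, micro_data, micro_pipeline_cfg):
        ld, lm, dss, _ = micro_data
        empty = AssociationMatrix(ld.row_ids, ld.col_ids + ["d_none"],
                                  np.hstack([ld.values, np.zeros((len(ld.row_ids), 1))]))
        with pytest.raises(ValueError, match="no association"):
            novel_disease_rank("d_none", empty, lm, dss, micro_pipeline_cfg, seed=1)


class TestEmbeddingSizeSweep:
    def test_one_row_per_size(self, micro_data, micro_pipeline_cfg):
        ld, lm, dss, _ = micro_data
        res = embedding_size_sweep([4, 8], ld, lm, dss, micro_pipeline_cfg, seeds=[1])
        assert sorted(res) == [4, 8]
        assert all(0.0 <= v <= 1.0 for v in res.values())

    def test_odd_size_rejected(self, micro_data, micro_pipeline_cfg):
        ld, lm, dss, _ = micro_data
        with pytest.raises(ValueError, match="even"):
            embedding_size_sweep([7], ld, lm, dss, micro_pipeline_cfg, seeds=[1])
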