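import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from birw import (
    AssociationRecord,
    BiRWParams,
    BlockModelSpec,
    auc_from_scores,
    build_adjacency,
    generate_block_association,
    kfold_cv,
    loocv,
    make_fold_plan,
    predict,
    rank_candidates,
    roc_curve,
)

scores = st.lists(st.floats(-10, 10, allow_nan=False), min_size=1, max_size=200)


def brute_force_auc(pos, neg):
    """Oracle: exhaustive pairwise win fraction, ties 1/2."""
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAucFromScores:
    def test_perfect_separation(self):
        assert auc_from_scores([2.0, 3.0], [0.0, 1.0]) == 1.0

    def test_all_tied(self):
        assert auc_from_scores([1.0, 1.0], [1.0, 1.0, 1.0]) == 0.5

    def test_interleaved(self):
        assert auc_from_scores([0.9, 0.7], [0.8, 0.6]) == 0.75

    def test_empty_error(self):
        with pytest.raises(ValueError):
            auc_from_scores([], [1.0])

    @settings(max_examples=60, deadline=None)
    @given(pos=scores, neg=scores)
    def test_matches_brute_force(self, pos, neg):
        assert auc_from_scores(pos, neg) == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)


class TestRocCurve:
    def test_perfect_separation(self):
        pts = roc_curve([1.0], [0.0])
        np.testing.assert_array_equal(pts, [[0, 0], [0, 1], [1, 1]])

    def test_all_tied(self):
        pts = roc_curve([1.0, 1.0], [1.0])
        np.testing.assert_array_equal(pts, [[0, 0], [1, 1]])
        assert np.trapezoid(pts[:, 1], pts[:, 0]) == pytest.approx(0.5)

    def test_single_positive_above_half(self):
        pts = roc_curve([0.5], [0.0, 0.0, 1.0, 1.0])
        # TPR jumps 0 -> 1 at FPR 0.5
        assert [0.5, 1.0] in pts.tolist()
        assert np.trapezoid(pts[:, 1], pts[:, 0]) == pytest.approx(0.5)

    @settings(max_examples=60, deadline=None)
    @given(pos=scores, neg=scores)
    def test_monotone_and_area_equals_auc(self, pos, neg):
        pts = roc_curve(pos, neg)
        assert tuple(pts[0]) == (0.0, 0.0)
        assert tuple(pts[-1]) == (1.0, 1.0)
        assert (np.diff(pts[:, 0]) >= 0).all()
        assert (np.diff(pts[:, 1]) >= 0).all()
        area = np.trapezoid(pts[:, 1], pts[:, 0])
        assert area == pytest.approx(auc_from_scores(pos, neg), abs=1e-12)


class TestFoldPlan:
    def test_balanced_and_complete(self):
        plan = make_fold_plan(23, k=5, repeats=4, seed=0)
        for rep in range(4):
            sizes = np.bincount(plan.assignments[rep], minlength=5)
            assert sizes.sum() == 23
            assert sizes.max() - sizes.min() <= 1

    def test_deterministic(self):
        a = make_fold_plan(50, k=5, repeats=3, seed=9)
        b = make_fold_plan(50, k=5, repeats=3, seed=9)
        np.testing.assert_array_equal(a.assignments, b.assignments)

    def test_k_exceeds_n_error(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_fold_plan(3, k=5, repeats=1, seed=0)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            make_fold_plan(10, k=1, repeats=1, seed=0)


class TestLoocv:
    def test_too_few_associations_error(self):
        with pytest.raises(ValueError, match="at least two"):
            loocv([AssociationRecord("d1", "m1")])

    def test_deterministic(self, block_records):
        r1 = loocv(block_records)
        r2 = loocv(block_records)
        assert r1.auc == r2.auc
        np.testing.assert_array_equal(r1.test_scores, r2.test_scores)

    def test_block_structure_recovered(self, block_records):
        result = loocv(block_records)
        assert result.auc > 0.5
        assert result.n_candidates > 0

    def test_roc_points_valid(self, block_records):
        pts = loocv(block_records).roc_points
        assert tuple(pts[0]) == (0.0, 0.0)
        assert tuple(pts[-1]) == (1.0, 1.0)
        assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()

    def test_fast_mode_runs(self, block_records):
        result = loocv(block_records, recompute_similarity=False)
        assert 0.0 <= result.auc <= 1.0


class TestKfoldCv:
    def test_deterministic_under_seed(self, block_records):
        r1 = kfold_cv(block_records, k=5, repeats=2, seed=3)
        r2 = kfold_cv(block_records, k=5, repeats=2, seed=3)
        assert r1.auc_mean == r2.auc_mean
        assert r1.auc_sd == r2.auc_sd
        assert r1.per_repeat_auc == r2.per_repeat_auc

    def test_seed_changes_partition(self, block_records):
        r1 = kfold_cv(block_records, k=5, repeats=1, seed=1)
        r2 = kfold_cv(block_records, k=5, repeats=1, seed=2)
        assert r1.per_repeat_auc != r2.per_repeat_auc

    def test_shapes_of_result(self, block_records):
        r = kfold_cv(block_records, k=4, repeats=3, seed=0)
        assert len(r.per_repeat_auc) == 3
        assert len(r.per_fold_auc) == 3 and all(len(f) == 4 for f in r.per_fold_auc)
        assert r.auc_mean == pytest.approx(np.mean(r.per_repeat_auc))
        assert r.auc_sd == pytest.approx(np.std(r.per_repeat_auc, ddof=1))

    def test_k_exceeds_associations_error(self, toy_records):
        with pytest.raises(ValueError, match="exceeds"):
            kfold_cv(toy_records, k=5, repeats=1, seed=0)

    def test_block_structure_recovered(self, block_records):
        r = kfold_cv(block_records, k=5, repeats=2, seed=0)
        assert r.auc_mean > 0.5


class TestRankCandidates:
    def _toy(self):
        # d1 is linked to m1, m2; m3 shares d2 with m1/m2's block; m4 isolated-ish
        records = [
            AssociationRecord("d1", "m1"),
            AssociationRecord("d1", "m2"),
            AssociationRecord("d2", "m1"),
            AssociationRecord("d2", "m2"),
            AssociationRecord("d2", "m3"),
            AssociationRecord("d3", "m4"),
        ]
        am = build_adjacency(records)
        md = predict(records)
        return am, md

    def test_most_similar_candidate_ranks_first(self):
        am, md = self._toy()
        ranked = rank_candidates(md, am, "d1", top_k=2)
        assert ranked[0][0] == "m3"  # shares disease d2 with d1's partners

    def test_all_known_gives_empty(self):
        records = [AssociationRecord("d1", "m1"), AssociationRecord("d2", "m1")]
        am = build_adjacency(records)
        md = predict(records)
        assert rank_candidates(md, am, "d1") == []

    def test_unknown_disease_error_lists_names(self):
        am, md = self._toy()
        with pytest.raises(ValueError, match="d1"):
            rank_candidates(md, am, "nope")

    def test_scores_descending_and_truncated(self):
        am, md = self._toy()
        ranked = rank_candidates(md, am, "d3", top_k=2)
        assert len(ranked) == 2
        assert ranked[0][1] >= ranked[1][1]

    def test_tie_break_by_index_order(self, toy_matrix):
        from birw import PredictionMatrix

        md = PredictionMatrix(np.zeros((2, 2)), toy_matrix.disease_index, toy_matrix.microbe_index)
        ranked = rank_candidates(md, toy_matrix, "d1")
        assert [name for name, _ in ranked] == ["m2"]  # m1 is known for d1


def test_planted_structure_beats_structureless_every_seed():
    strong, flat = [], []
    for seed in range(4):
        strong.append(
            loocv(generate_block_association(BlockModelSpec(10, 30, 3, 0.9, 0.02, seed=seed))).auc
        )
        flat.append(
            loocv(generate_block_association(BlockModelSpec(10, 30, 3, 0.15, 0.15, seed=seed))).auc
        )
    assert all(s > f for s, f in zip(strong, flat))
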