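"""Cross-validation and ranking evaluation for the prediction pipeline.

Leave-one-out CV hides one known association per round, recomputes both
similarity matrices from the reduced adjacency, reruns the walk and ranks
the hidden pair against every unverified pair (the global candidate set:
all pairs that are zero in the *full* adjacency).  Repeated k-fold CV does
the same per fold with a seeded random partition of the known associations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve
from scipy.stats import rankdata

from .associations import AssociationMatrix, AssociationRecord, build_adjacency
from .similarity import KernelParams, LogisticParams, disease_similarity, microbe_similarity
from .walk import BiRWParams, PredictionMatrix, bi_random_walk

__all__ = [
    "CVResult",
    "FoldPlan",
    "auc_from_scores",
    "roc_curve",
    "loocv",
    "kfold_cv",
    "make_fold_plan",
    "rank_candidates",
]


@dataclass(frozen=True)
class CVResult:
    """Outcome of one cross-validation experiment."""

    test_scores: np.ndarray
    roc_points: np.ndarray  # (n, 2) array of (FPR, TPR)
    auc: float
    auc_mean: float
    auc_sd: float
    per_fold_auc: list[list[float]] | None = None  # k-fold only: repeats x k
    per_repeat_auc: list[float] | None = None
    n_candidates: int = 0

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_mean": self.auc_mean,
            "auc_sd": self.auc_sd,
            "n_test": int(len(self.test_scores)),
            "n_candidates": self.n_candidates,
            "per_repeat_auc": self.per_repeat_auc,
            "per_fold_auc": self.per_fold_auc,
        }


@dataclass(frozen=True)
class FoldPlan:
    """Seeded fold assignment: one fold label per association per repeat."""

    k: int
    repeats: int
    seed: int
    assignments: np.ndarray  # shape (repeats, n_associations), values in [0, k)

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be positive")


def make_fold_plan(n_associations: int, k: int, repeats: int, seed: int) -> FoldPlan:
    """Balanced random fold labels; fold sizes within a repeat differ by <= 1."""
    if k > n_associations:
        raise ValueError(f"k={k} exceeds the number of associations ({n_associations})")
    rng = np.random.default_rng(seed)
    base = np.arange(n_associations) % k  # balanced label pool
    assignments = np.empty((repeats, n_associations), dtype=np.int64)
    for rep in range(repeats):
        assignments[rep] = rng.permutation(base)
    return FoldPlan(k=k, repeats=repeats, seed=seed, assignments=assignments)


def auc_from_scores(positive_scores: Sequence[float], negative_scores: Sequence[float]) -> float:
    """P(random positive outranks random negative), ties counted 1/2.

    Mann-Whitney statistic computed via mid-ranks; identical to the
    trapezoidal area under the threshold-swept ROC curve.
    """
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be nonempty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def roc_curve(
    positive_scores: Sequence[float], negative_scores: Sequence[float]
) -> np.ndarray:
    """(FPR, TPR) points from (0,0) to (1,1), one per distinct threshold."""
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be nonempty")
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    fpr, tpr, _ = _sk_roc_curve(labels, np.concatenate([pos, neg]), drop_intermediate=False)
    return np.column_stack([fpr, tpr])


def _rank_staircase_roc(above: np.ndarray, n_neg: int) -> np.ndarray:
    """ROC over per-round rank thresholds.

    ``above[i]`` is the number of that round's candidates strictly
    outranking test sample i.  TPR at FPR = a/n_neg is the fraction of test
    samples ranked within the top a candidates.
    """
    distinct, counts = np.unique(above, return_counts=True)
    tpr = np.cumsum(counts) / above.size
    fpr = distinct / n_neg
    pts = np.column_stack([fpr, tpr])
    if pts.size == 0 or pts[0, 0] > 0 or pts[0, 1] > 0:
        pts = np.vstack([[0.0, 0.0], pts])
    if pts[-1, 0] < 1.0 or pts[-1, 1] < 1.0:
        pts = np.vstack([pts, [1.0, 1.0]])
    return pts


def _similarities(am, kparams, lparams, kparams_d=None):
    SM = microbe_similarity(am, kparams)
    SD = disease_similarity(am, kparams_d or kparams, lparams)
    return SM, SD


def loocv(
    records: Sequence[AssociationRecord],
    kparams: KernelParams = KernelParams(),
    lparams: LogisticParams = LogisticParams(),
    bparams: BiRWParams = BiRWParams(),
    recompute_similarity: bool = True,
) -> CVResult:
    """Leave-one-out cross validation over all known associations.

    Per round the held-out pair's score is ranked against the scores of all
    unverified pairs from the same round; the reported AUC is the mean of
    the per-round win fractions (ties 1/2), i.e. the probability that a
    held-out association outranks a random unverified pair.

    ``recompute_similarity=False`` reuses the full-matrix similarities in
    every round (fast approximation, testing only).
    """
    am = build_adjacency(records)
    positives = np.argwhere(am.A == 1)
    if len(positives) < 2:
        raise ValueError("LOOCV requires at least two known associations")
    neg_mask = am.A == 0
    n_neg = int(neg_mask.sum())
    if n_neg == 0:
        raise ValueError("no unverified pairs to rank against")

    if not recompute_similarity:
        SM_full, SD_full = _similarities(am, kparams, lparams)

    test_scores = np.empty(len(positives))
    round_auc = np.empty(len(positives))
    above = np.empty(len(positives), dtype=np.int64)  # negatives strictly outranking
    A_work = am.A.copy()
    for idx, (i, j) in enumerate(positives):
        A_work[i, j] = 0
        reduced = am.with_matrix(A_work)
        if recompute_similarity:
            SM, SD = _similarities(reduced, kparams, lparams)
        else:
            SM, SD = SM_full, SD_full
        MD = bi_random_walk(reduced, SM, SD, bparams).MD
        A_work[i, j] = 1

        pos_score = MD[i, j]
        neg_scores = MD[neg_mask]
        test_scores[idx] = pos_score
        wins = np.count_nonzero(neg_scores < pos_score)
        ties = np.count_nonzero(neg_scores == pos_score)
        round_auc[idx] = (wins + 0.5 * ties) / n_neg
        above[idx] = n_neg - wins - ties

    auc = float(round_auc.mean())
    roc = _rank_staircase_roc(above, n_neg)
    return CVResult(
        test_scores=test_scores,
        roc_points=roc,
        auc=auc,
        auc_mean=auc,
        auc_sd=0.0,
        per_repeat_auc=None,
        per_fold_auc=None,
        n_candidates=n_neg,
    )


def kfold_cv(
    records: Sequence[AssociationRecord],
    kparams: KernelParams = KernelParams(),
    lparams: LogisticParams = LogisticParams(),
    bparams: BiRWParams = BiRWParams(),
    k: int = 5,
    repeats: int = 100,
    seed: int = 0,
) -> CVResult:
    """Repeated seeded k-fold cross validation.

    Per repeat the known associations are randomly split into k near-equal
    folds; each fold is hidden in turn, similarities are recomputed and the
    fold's held-out scores are ranked against all unverified pairs.  The
    per-repeat AUC pools the folds (held-out size weighted); mean and
    sample standard deviation are reported over repeats.
    """
    am = build_adjacency(records)
    positives = np.argwhere(am.A == 1)
    n_pos = len(positives)
    plan = make_fold_plan(n_pos, k=k, repeats=repeats, seed=seed)
    neg_mask = am.A == 0
    n_neg = int(neg_mask.sum())

    repeat_auc: list[float] = []
    per_fold: list[list[float]] = []
    all_test_scores: list[np.ndarray] = []
    first_repeat_neg: list[np.ndarray] = []
    for rep in range(repeats):
        fold_aucs: list[float] = []
        weighted = 0.0
        for fold in range(k):
            held = positives[plan.assignments[rep] == fold]
            A_work = am.A.copy()
            A_work[held[:, 0], held[:, 1]] = 0
            reduced = am.with_matrix(A_work)
            SM, SD = _similarities(reduced, kparams, lparams)
            MD = bi_random_walk(reduced, SM, SD, bparams).MD

            pos_scores = MD[held[:, 0], held[:, 1]]
            neg_scores = MD[neg_mask]
            fold_auc = auc_from_scores(pos_scores, neg_scores)
            fold_aucs.append(fold_auc)
            weighted += fold_auc * len(held)
            if rep == 0:
                all_test_scores.append(pos_scores)
                first_repeat_neg.append(neg_scores)
        per_fold.append(fold_aucs)
        repeat_auc.append(weighted / n_pos)

    repeat_auc_arr = np.asarray(repeat_auc)
    auc_mean = float(repeat_auc_arr.mean())
    auc_sd = float(repeat_auc_arr.std(ddof=1)) if repeats > 1 else 0.0
    roc = roc_curve(np.concatenate(all_test_scores), np.concatenate(first_repeat_neg))
    return CVResult(
        test_scores=np.concatenate(all_test_scores),
        roc_points=roc,
        auc=auc_mean,
        auc_mean=auc_mean,
        auc_sd=auc_sd,
        per_repeat_auc=repeat_auc,
        per_fold_auc=per_fold,
        n_candidates=n_neg,
    )


def rank_candidates(
    MD: PredictionMatrix,
    am: AssociationMatrix,
    disease: str,
    top_k: int = 10,
) -> list[tuple[str, float]]:
    """Top-k unverified microbes for a disease, by descending score.

    Ties are broken by microbe index order (stable sort).
    """
    if MD.disease_index != am.disease_index or MD.microbe_index != am.microbe_index:
        raise ValueError("prediction and adjacency indices do not match")
    if disease not in MD.disease_index:
        raise ValueError(
            f"unknown disease {disease!r}; valid names: {sorted(MD.disease_index)}"
        )
    i = MD.disease_index.index(disease)
    row = MD.MD[i]
    unknown = np.flatnonzero(am.A[am.disease_position(disease)] == 0)
    order = unknown[np.argsort(-row[unknown], kind="stable")]
    return [(MD.microbe_index[j], float(row[j])) for j in order[:top_k]]
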