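"""Bi-random walk on the heterogeneous disease-microbe network.

Two step-limited random walks run simultaneously: one propagates the score
matrix through the microbe similarity network (right multiplication), the
other through the disease similarity network (left multiplication).  At
each step the active walks are averaged; after max(l, r) steps the score
matrix is the prediction.

Two modes are supported.  The default ("normalized") Laplacian-normalizes
both similarity matrices and scales the seed to unit total mass, following
the canonical bi-random-walk formulation; the "raw" mode iterates the
update equations verbatim on the unnormalized inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .associations import AssociationMatrix, AssociationRecord, build_adjacency
from .similarity import (
    KernelParams,
    LogisticParams,
    SimilarityMatrix,
    disease_similarity,
    microbe_similarity,
)

__all__ = [
    "BiRWParams",
    "PredictionMatrix",
    "laplacian_normalize",
    "bi_random_walk",
    "predict",
]


@dataclass(frozen=True)
class BiRWParams:
    """Walk configuration.

    alpha
        Decay factor in (0, 1]: weight of propagated mass vs the seed.
    l, r
        Step limits of the microbe-side and disease-side walks.
    normalize_similarity
        Laplacian-normalize the similarity matrices before walking.
    normalize_seed
        Scale the seed matrix to unit total mass.
    """

    alpha: float = 0.4
    l: int = 2
    r: int = 2
    normalize_similarity: bool = True
    normalize_seed: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.l < 0 or self.r < 0:
            raise ValueError("step limits l and r must be nonnegative")
        if self.l + self.r < 1:
            raise ValueError("at least one walk step is required (l + r >= 1)")


@dataclass(frozen=True)
class PredictionMatrix:
    """Disease x microbe association scores, indices as in the adjacency."""

    MD: np.ndarray
    disease_index: tuple[str, ...]
    microbe_index: tuple[str, ...]

    def __post_init__(self) -> None:
        MD = np.asarray(self.MD, dtype=float)
        if MD.shape != (len(self.disease_index), len(self.microbe_index)):
            raise ValueError("prediction shape does not match index lengths")
        if not np.isfinite(MD).all():
            raise ValueError("prediction matrix contains non-finite entries")
        object.__setattr__(self, "MD", MD)

    def score(self, disease: str, microbe: str) -> float:
        return float(
            self.MD[self.disease_index.index(disease), self.microbe_index.index(microbe)]
        )


def _as_array(S: SimilarityMatrix | np.ndarray) -> np.ndarray:
    return S.S if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)


def laplacian_normalize(S: SimilarityMatrix | np.ndarray) -> SimilarityMatrix | np.ndarray:
    """Symmetric normalization D^{-1/2} S D^{-1/2}, D = diag of row sums."""
    arr = _as_array(S)
    d = arr.sum(axis=1)
    zero = np.flatnonzero(d == 0)
    if zero.size:
        names: Sequence = (
            [S.node_index[i] for i in zero] if isinstance(S, SimilarityMatrix) else zero.tolist()
        )
        raise ValueError(f"cannot normalize: all-zero row(s) for node(s) {list(names)}")
    inv_sqrt = 1.0 / np.sqrt(d)
    out = arr * inv_sqrt[:, None] * inv_sqrt[None, :]
    if isinstance(S, SimilarityMatrix):
        return SimilarityMatrix(out, S.node_index)
    return out


def bi_random_walk(
    am: AssociationMatrix,
    SM: SimilarityMatrix | np.ndarray,
    SD: SimilarityMatrix | np.ndarray,
    params: BiRWParams = BiRWParams(),
) -> PredictionMatrix:
    """Run the step-limited bi-random walk and return the prediction matrix.

    Iterates t = 1 .. max(l, r).  While t <= l the microbe-side walk
    computes ``alpha * MD @ SM + (1 - alpha) * seed``; while t <= r the
    disease-side walk computes ``alpha * SD @ MD + (1 - alpha) * seed``.
    The step result is the mean of the walks active at that step.
    """
    SM_arr = _as_array(SM)
    SD_arr = _as_array(SD)
    nd, nm = am.A.shape
    if SM_arr.shape != (nm, nm):
        raise ValueError(f"microbe similarity must be {nm}x{nm}, got {SM_arr.shape}")
    if SD_arr.shape != (nd, nd):
        raise ValueError(f"disease similarity must be {nd}x{nd}, got {SD_arr.shape}")
    if isinstance(SM, SimilarityMatrix) and SM.node_index != am.microbe_index:
        raise ValueError("microbe similarity index does not match adjacency")
    if isinstance(SD, SimilarityMatrix) and SD.node_index != am.disease_index:
        raise ValueError("disease similarity index does not match adjacency")

    if params.normalize_similarity:
        SM_arr = laplacian_normalize(SM_arr)
        SD_arr = laplacian_normalize(SD_arr)

    seed = am.A.astype(float)
    if params.normalize_seed:
        total = seed.sum()
        if total == 0:
            raise ValueError("cannot normalize the seed of an empty association matrix")
        seed = seed / total

    alpha = params.alpha
    MD = seed
    for t in range(1, max(params.l, params.r) + 1):
        walks = []
        if t <= params.l:
            walks.append(alpha * MD @ SM_arr + (1.0 - alpha) * seed)
        if t <= params.r:
            walks.append(alpha * SD_arr @ MD + (1.0 - alpha) * seed)
        MD = walks[0] if len(walks) == 1 else (walks[0] + walks[1]) / 2.0
    return PredictionMatrix(MD, am.disease_index, am.microbe_index)


def predict(
    records: Sequence[AssociationRecord],
    kparams: KernelParams = KernelParams(),
    lparams: LogisticParams = LogisticParams(),
    bparams: BiRWParams = BiRWParams(),
    kparams_d: KernelParams | None = None,
) -> PredictionMatrix:
    """Full pipeline: adjacency -> GIP similarities -> bi-random walk.

    ``kparams`` sets the microbe-side bandwidth; ``kparams_d`` (default:
    same as ``kparams``) the disease-side one.
    """
    am = build_adjacency(records)
    SM = microbe_similarity(am, kparams)
    SD = disease_similarity(am, kparams_d or kparams, lparams)
    return bi_random_walk(am, SM, SD, bparams)
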