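"""Gaussian interaction-profile (GIP) kernel similarities.

Node similarity is a Gaussian of the squared distance between binary
association profiles; the bandwidth is the raw bandwidth divided by the
mean squared profile norm.  Disease similarity is additionally squashed
through a logistic transform that suppresses weak kernel values and
saturates strong ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .associations import AssociationMatrix

__all__ = [
    "KernelParams",
    "LogisticParams",
    "SimilarityMatrix",
    "gip_bandwidth",
    "gip_kernel",
    "logistic_transform",
    "microbe_similarity",
    "disease_similarity",
    "similarity_histogram",
]

#: offset making the logistic transform hit exactly 1e-4 at kernel value 0
DEFAULT_LOGISTIC_OFFSET = math.log(9999.0)


@dataclass(frozen=True)
class KernelParams:
    """Unnormalized GIP bandwidth (one value per node set)."""

    gamma_prime: float = 1.0

    def __post_init__(self) -> None:
        if not self.gamma_prime > 0:
            raise ValueError(f"gamma_prime must be positive, got {self.gamma_prime}")


@dataclass(frozen=True)
class LogisticParams:
    """Slope ``c`` (negative) and offset ``d`` of the logistic regulation."""

    c: float = -15.0
    d: float = DEFAULT_LOGISTIC_OFFSET

    def __post_init__(self) -> None:
        if not self.c < 0:
            raise ValueError(f"logistic slope c must be negative, got {self.c}")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric positive similarity matrix over one node set."""

    S: np.ndarray
    node_index: tuple[str, ...]

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("similarity matrix must be square")
        if S.shape[0] != len(self.node_index):
            raise ValueError("similarity shape does not match node index")
        if not np.allclose(S, S.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        object.__setattr__(self, "S", S)

    @property
    def n(self) -> int:
        return self.S.shape[0]


def gip_bandwidth(profiles: np.ndarray, gamma_prime: float = 1.0) -> float:
    """Normalized kernel bandwidth: gamma' / mean squared profile norm.

    ``profiles`` holds one binary profile per row.
    """
    if not gamma_prime > 0:
        raise ValueError("gamma_prime must be positive")
    profiles = np.asarray(profiles, dtype=float)
    mean_sq_norm = float(np.mean(np.sum(profiles**2, axis=1)))
    if mean_sq_norm == 0.0:
        raise ValueError("all profiles are zero: GIP bandwidth is undefined")
    return gamma_prime / mean_sq_norm


def gip_kernel(
    profiles: np.ndarray,
    gamma_prime: float = 1.0,
    node_index: tuple[str, ...] | None = None,
) -> SimilarityMatrix:
    """Gaussian kernel over pairwise squared profile distances.

    S(i, j) = exp(-gamma * ||p_i - p_j||^2) with the normalized bandwidth
    from :func:`gip_bandwidth`; the diagonal is exactly 1.
    """
    profiles = np.asarray(profiles, dtype=float)
    gamma = gip_bandwidth(profiles, gamma_prime)
    sq = squareform(pdist(profiles, metric="sqeuclidean"))
    S = np.exp(-gamma * sq)
    np.fill_diagonal(S, 1.0)
    S = (S + S.T) / 2.0  # guard against rounding asymmetry
    if node_index is None:
        node_index = tuple(f"n{i}" for i in range(profiles.shape[0]))
    return SimilarityMatrix(S, node_index)


def logistic_transform(K: SimilarityMatrix, params: LogisticParams) -> SimilarityMatrix:
    """Elementwise 1 / (1 + exp(c*K + d)), applied to every entry incl. diagonal."""
    S = 1.0 / (1.0 + np.exp(params.c * K.S + params.d))
    return SimilarityMatrix(S, K.node_index)


def microbe_similarity(am: AssociationMatrix, params: KernelParams = KernelParams()) -> SimilarityMatrix:
    """GIP kernel over microbe profiles (columns of the adjacency)."""
    return gip_kernel(am.A.T, params.gamma_prime, am.microbe_index)


def disease_similarity(
    am: AssociationMatrix,
    kparams: KernelParams = KernelParams(),
    lparams: LogisticParams = LogisticParams(),
) -> SimilarityMatrix:
    """Logistic-regulated GIP kernel over disease profiles (rows of the adjacency)."""
    K = gip_kernel(am.A, kparams.gamma_prime, am.disease_index)
    return logistic_transform(K, lparams)


def similarity_histogram(S: SimilarityMatrix, n_bins: int = 10) -> np.ndarray:
    """Bin counts of off-diagonal similarity values over [0, 1]."""
    off = S.S[~np.eye(S.n, dtype=bool)]
    counts, _ = np.histogram(off, bins=n_bins, range=(0.0, 1.0))
    return counts
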