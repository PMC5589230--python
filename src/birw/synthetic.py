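"""Synthetic bipartite association networks with planted block structure.

A stochastic block model over a disease x microbe bipartite graph: nodes
are assigned to blocks round-robin (deterministic block sizes), and each
pair is associated with probability ``p_in`` when the blocks match and
``p_out`` otherwise.  With p_in >> p_out the similarity-driven ranking is
recoverable, which makes the generator the ground truth for end-to-end
pipeline tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .associations import AssociationRecord

__all__ = ["BlockModelSpec", "generate_block_association", "expected_density"]


@dataclass(frozen=True)
class BlockModelSpec:
    n_diseases: int
    n_microbes: int
    n_blocks: int
    p_in: float
    p_out: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_diseases < 1 or self.n_microbes < 1:
            raise ValueError("node counts must be positive")
        if not 1 <= self.n_blocks <= min(self.n_diseases, self.n_microbes):
            raise ValueError("n_blocks must be in [1, min(n_diseases, n_microbes)]")
        if not 0.0 <= self.p_out <= self.p_in <= 1.0:
            raise ValueError("require 0 <= p_out <= p_in <= 1")


def _block_labels(n: int, n_blocks: int) -> np.ndarray:
    return np.arange(n) % n_blocks


def generate_block_association(spec: BlockModelSpec) -> list[AssociationRecord]:
    """Draw one association table from the block model (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    d_blocks = _block_labels(spec.n_diseases, spec.n_blocks)
    m_blocks = _block_labels(spec.n_microbes, spec.n_blocks)
    match = d_blocks[:, None] == m_blocks[None, :]
    p = np.where(match, spec.p_in, spec.p_out)
    draws = rng.random((spec.n_diseases, spec.n_microbes)) < p
    rows, cols = np.nonzero(draws)
    return [
        AssociationRecord(f"D{i + 1}", f"M{j + 1}")
        for i, j in zip(rows.tolist(), cols.tolist())
    ]


def expected_density(spec: BlockModelSpec) -> float:
    """Closed-form expected fraction of 1-entries under the block partition."""
    d_blocks = _block_labels(spec.n_diseases, spec.n_blocks)
    m_blocks = _block_labels(spec.n_microbes, spec.n_blocks)
    d_sizes = np.bincount(d_blocks, minlength=spec.n_blocks)
    m_sizes = np.bincount(m_blocks, minlength=spec.n_blocks)
    matched = int(np.sum(d_sizes * m_sizes))
    total = spec.n_diseases * spec.n_microbes
    return (matched * spec.p_in + (total - matched) * spec.p_out) / total


def records_to_table(records: list[AssociationRecord], delimiter: str = "\t") -> str:
    """Serialize records in the same format the reader consumes (with header)."""
    lines = [f"disease{delimiter}microbe"]
    lines += [f"{r.disease}{delimiter}{r.microbe}" for r in records]
    return "\n".join(lines) + "\n"
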