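"""Reading, deduplicating and indexing disease-microbe association tables.

The association network is a bipartite graph between diseases and microbes,
stored as a dense binary adjacency matrix ``A`` with diseases on the rows
and microbes on the columns.  Row/column order follows first appearance in
the input unless sorting is requested, so rebuilding from the same table is
bit-for-bit reproducible.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np

__all__ = [
    "AssociationRecord",
    "AssociationMatrix",
    "DegreeStats",
    "read_association_table",
    "deduplicate",
    "build_adjacency",
    "degree_summary",
    "write_adjacency",
]

# header tokens used to auto-detect which column holds which entity
_DISEASE_KEYS = ("disease", "phenotype", "condition")
_MICROBE_KEYS = ("microbe", "organism", "taxon", "bacteri", "species", "genus")


@dataclass(frozen=True)
class AssociationRecord:
    """One (disease, microbe) association, names whitespace-trimmed."""

    disease: str
    microbe: str

    def __post_init__(self) -> None:
        if not self.disease.strip() or not self.microbe.strip():
            raise ValueError("association record requires non-empty disease and microbe names")
        object.__setattr__(self, "disease", self.disease.strip())
        object.__setattr__(self, "microbe", self.microbe.strip())


@dataclass(frozen=True, eq=False)
class AssociationMatrix:
    """Binary disease x microbe adjacency with name <-> index maps."""

    A: np.ndarray
    disease_index: tuple[str, ...]
    microbe_index: tuple[str, ...]
    _disease_pos: dict[str, int] = field(repr=False, compare=False, default_factory=dict)
    _microbe_pos: dict[str, int] = field(repr=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        A = np.asarray(self.A)
        if A.ndim != 2:
            raise ValueError("adjacency must be a 2-D matrix")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency entries must all be 0 or 1")
        if A.shape != (len(self.disease_index), len(self.microbe_index)):
            raise ValueError("adjacency shape does not match index lengths")
        if len(set(self.disease_index)) != len(self.disease_index):
            raise ValueError("duplicate disease names in index")
        if len(set(self.microbe_index)) != len(self.microbe_index):
            raise ValueError("duplicate microbe names in index")
        object.__setattr__(self, "A", A)
        self._disease_pos.update({d: i for i, d in enumerate(self.disease_index)})
        self._microbe_pos.update({m: j for j, m in enumerate(self.microbe_index)})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssociationMatrix):
            return NotImplemented
        return (
            self.disease_index == other.disease_index
            and self.microbe_index == other.microbe_index
            and np.array_equal(self.A, other.A)
        )

    @property
    def n_diseases(self) -> int:
        return self.A.shape[0]

    @property
    def n_microbes(self) -> int:
        return self.A.shape[1]

    @property
    def n_associations(self) -> int:
        return int(self.A.sum())

    def disease_position(self, name: str) -> int:
        return self._disease_pos[name]

    def microbe_position(self, name: str) -> int:
        return self._microbe_pos[name]

    def with_matrix(self, A: np.ndarray) -> "AssociationMatrix":
        """Same indices, different (same-shape) adjacency."""
        return AssociationMatrix(A, self.disease_index, self.microbe_index)

    def to_records(self) -> list[AssociationRecord]:
        rows, cols = np.nonzero(self.A)
        return [
            AssociationRecord(self.disease_index[i], self.microbe_index[j])
            for i, j in zip(rows.tolist(), cols.tolist())
        ]


@dataclass(frozen=True)
class DegreeStats:
    microbe_degrees: np.ndarray
    disease_degrees: np.ndarray
    mean_microbe_degree: float
    mean_disease_degree: float


def _detect_columns(header: Sequence[str]) -> tuple[int, int] | None:
    """Return (disease_col, microbe_col) from header keywords, or None."""
    d_col = m_col = None
    for idx, name in enumerate(header):
        low = name.strip().lower()
        if d_col is None and any(k in low for k in _DISEASE_KEYS):
            d_col = idx
        elif m_col is None and any(k in low for k in _MICROBE_KEYS):
            m_col = idx
    if d_col is not None and m_col is not None:
        return d_col, m_col
    return None


def read_association_table(
    source: str | Path | TextIO,
    delimiter: str = "\t",
    has_header: bool = True,
    disease_col: int | None = None,
    microbe_col: int | None = None,
) -> list[AssociationRecord]:
    """Parse a delimited two-column association table into records.

    With ``has_header`` the disease/microbe columns are detected from header
    keywords; otherwise (or if detection fails) positional columns are used,
    defaulting to column 0 = disease, column 1 = microbe.  Row order is
    preserved and no deduplication is applied.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8", newline="") as fh:
            return read_association_table(fh, delimiter, has_header, disease_col, microbe_col)

    reader = csv.reader(source, delimiter=delimiter)
    records: list[AssociationRecord] = []
    d_col = 0 if disease_col is None else disease_col
    m_col = 1 if microbe_col is None else microbe_col
    for lineno, row in enumerate(reader, start=1):
        if lineno == 1 and has_header:
            if disease_col is None and microbe_col is None:
                detected = _detect_columns(row)
                if detected is not None:
                    d_col, m_col = detected
            continue
        if not row or all(not f.strip() for f in row):
            continue  # blank line
        if len(row) <= max(d_col, m_col):
            raise ValueError(
                f"line {lineno}: expected at least {max(d_col, m_col) + 1} fields, got {len(row)}"
            )
        records.append(AssociationRecord(row[d_col], row[m_col]))
    return records


def deduplicate(
    records: Iterable[AssociationRecord], case_sensitive: bool = True
) -> list[AssociationRecord]:
    """Drop repeated (disease, microbe) pairs, keeping first occurrences in order."""
    seen: set[tuple[str, str]] = set()
    out: list[AssociationRecord] = []
    for rec in records:
        key = (rec.disease, rec.microbe)
        if not case_sensitive:
            key = (rec.disease.lower(), rec.microbe.lower())
        if key not in seen:
            seen.add(key)
            out.append(rec)
    return out


def build_adjacency(
    records: Sequence[AssociationRecord], sort_indices: bool = False
) -> AssociationMatrix:
    """Build the binary disease x microbe adjacency from deduplicated records.

    Index order is first appearance in ``records`` (or lexicographic with
    ``sort_indices``).
    """
    records = list(records)
    if not records:
        raise ValueError("cannot build an adjacency matrix from an empty record list")

    diseases: dict[str, int] = {}
    microbes: dict[str, int] = {}
    for rec in records:
        diseases.setdefault(rec.disease, len(diseases))
        microbes.setdefault(rec.microbe, len(microbes))
    d_names = sorted(diseases) if sort_indices else list(diseases)
    m_names = sorted(microbes) if sort_indices else list(microbes)
    d_pos = {d: i for i, d in enumerate(d_names)}
    m_pos = {m: j for j, m in enumerate(m_names)}

    A = np.zeros((len(d_names), len(m_names)), dtype=np.int8)
    for rec in records:
        A[d_pos[rec.disease], m_pos[rec.microbe]] = 1
    return AssociationMatrix(A, tuple(d_names), tuple(m_names))


def degree_summary(am: AssociationMatrix) -> DegreeStats:
    """Per-node association counts and their means (column sums = microbes)."""
    A = am.A
    if A.size == 0:
        raise ValueError("empty adjacency matrix")
    microbe_degrees = A.sum(axis=0).astype(np.int64)
    disease_degrees = A.sum(axis=1).astype(np.int64)
    total = float(A.sum())
    return DegreeStats(
        microbe_degrees=microbe_degrees,
        disease_degrees=disease_degrees,
        mean_microbe_degree=total / am.n_microbes,
        mean_disease_degree=total / am.n_diseases,
    )


def write_adjacency(am: AssociationMatrix, path: str | Path) -> None:
    """Write the adjacency as a labeled dense TSV plus a JSON index sidecar."""
    import pandas as pd

    path = Path(path)
    df = pd.DataFrame(am.A, index=list(am.disease_index), columns=list(am.microbe_index))
    df.to_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".index.json")
    with open(sidecar, "w", encoding="utf-8") as fh:
        json.dump(
            {"diseases": list(am.disease_index), "microbes": list(am.microbe_index)},
            fh,
            indent=2,
        )


def records_from_text(text: str, delimiter: str = "\t", has_header: bool = False) -> list[AssociationRecord]:
    """Convenience wrapper: parse an in-memory table (used by tests and CLI pipes)."""
    return read_association_table(io.StringIO(text), delimiter=delimiter, has_header=has_header)
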