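"""Locating and loading the curated association dataset.

The published HMDAD association export is not redistributed with this
package.  Place a delimited two-column (disease, microbe) export under
``data/`` in the repository root (or point ``BIRW_ASSOCIATIONS`` at it) to
enable the dataset-dependent evaluation paths.
"""

from __future__ import annotations

import os
from pathlib import Path

from .associations import AssociationRecord, read_association_table

__all__ = ["find_dataset", "load_dataset", "DATASET_HINT"]

_CANDIDATE_NAMES = (
    "associations.tsv",
    "associations.csv",
    "hmdad.tsv",
    "hmdad.csv",
    "hmdad_associations.tsv",
)

DATASET_HINT = (
    "curated association table not found: set BIRW_ASSOCIATIONS to a two-column "
    "(disease, microbe) delimited export, or place one under data/ as one of "
    + ", ".join(_CANDIDATE_NAMES)
)


def find_dataset(root: str | Path | None = None) -> Path | None:
    """Return the path of the curated association table, if available."""
    env = os.environ.get("BIRW_ASSOCIATIONS")
    if env:
        p = Path(env)
        if p.is_file():
            return p
    roots = [Path(root)] if root is not None else [Path.cwd(), Path(__file__).resolve().parents[2]]
    for base in roots:
        for name in _CANDIDATE_NAMES:
            p = base / "data" / name
            if p.is_file():
                return p
    return None


def load_dataset(path: str | Path | None = None) -> list[AssociationRecord]:
    """Parse the curated association table (delimiter inferred from suffix)."""
    if path is None:
        path = find_dataset()
    if path is None:
        raise FileNotFoundError(DATASET_HINT)
    path = Path(path)
    delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    records = read_association_table(path, delimiter=delimiter, has_header=True)
    if not records:
        # single try with the other delimiter before giving up
        delimiter = "\t" if delimiter == "," else ","
        records = read_association_table(path, delimiter=delimiter, has_header=True)
    return records
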