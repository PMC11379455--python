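"""Cell-type signature matrices over the three-symbol alphabet {+, -, A}.

A classification matrix encodes prior immunological knowledge: each row is a
cell lineage, each column a phenotypic marker, and each entry states whether
the lineage expresses the marker ('+'), lacks it ('-') or may do either
('A', any). The classifier matches binarized cells against these rows, so
two rows that can both match the same cell -- no marker where one says '+'
and the other '-' -- make annotation ambiguous; :func:`separability_report`
finds all such pairs up front.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MatrixParseError, ValidationError

ALPHABET = ("+", "-", "A")

# Unicode minus and en-dash occasionally appear in hand-edited tables.
_NORMALIZE = {"−": "-", "–": "-"}


@dataclass
class ClassificationMatrix:
    """Validated cell types x markers signature table.

    ``entries.loc[cell_type, marker]`` is '+', '-' or 'A'. Cell-type names
    are case-sensitive and whitespace-stripped; rows must be pairwise
    distinct and each row needs at least one informative (non-'A') entry.
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        entries = self.entries
        bad = set(np.unique(entries.to_numpy())) - set(ALPHABET)
        if bad:
            raise MatrixParseError(f"entries outside {{+,-,A}}: {sorted(bad)}")
        if entries.index.duplicated().any():
            dupes = entries.index[entries.index.duplicated()].tolist()
            raise ValidationError(f"duplicate cell-type names: {dupes}")
        if entries.columns.duplicated().any():
            dupes = entries.columns[entries.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate marker names: {dupes}")
        all_any = entries.index[(entries == "A").all(axis=1)].tolist()
        if all_any:
            raise ValidationError(
                f"rows with only 'A' entries would match every cell: {all_any}"
            )
        row_sigs = entries.apply(lambda r: tuple(r), axis=1)
        if row_sigs.duplicated().any():
            dupes = entries.index[row_sigs.duplicated()].tolist()
            raise ValidationError(f"identical signature rows: {dupes}")

    @property
    def cell_types(self) -> list[str]:
        return list(self.entries.index)

    @property
    def markers(self) -> list[str]:
        return list(self.entries.columns)

    def informative_markers(self) -> list[str]:
        """Markers with at least one non-'A' entry; only these need
        binarization."""
        mask = (self.entries != "A").any(axis=0)
        return list(self.entries.columns[mask])

    def specificity(self) -> pd.Series:
        """Number of informative entries per row; used for tie-breaking."""
        return (self.entries != "A").sum(axis=1)


def parse_classification_matrix(
    source: str | os.PathLike | io.TextIOBase,
    experiment_markers: list[str] | None = None,
) -> tuple[ClassificationMatrix, list[str]]:
    """Parse a delimited text table into a validated matrix.

    Layout: header row of marker names, first column of cell-type names.
    Returns ``(matrix, markers_missing_from_experiment)``; the second item
    is empty when ``experiment_markers`` is None or covers every column.
    Symbols outside the alphabet raise a parse error naming row and column.
    """
    if isinstance(source, (str, os.PathLike)) and os.path.exists(os.fspath(source)):
        sep = "\t" if os.fspath(source).endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(source, sep=sep, index_col=0, dtype=str)
    else:
        text = source.read() if hasattr(source, "read") else str(source)
        sep = "\t" if "\t" in text.splitlines()[0] else ","
        df = pd.read_csv(io.StringIO(text), sep=sep, index_col=0, dtype=str)

    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    cleaned = df.apply(lambda col: col.astype(str).str.strip())
    for uni, ascii_ in _NORMALIZE.items():
        cleaned = cleaned.replace(uni, ascii_)
    for cell_type, row in cleaned.iterrows():
        for marker, symbol in row.items():
            if symbol not in ALPHABET:
                raise MatrixParseError(
                    f"invalid symbol {symbol!r} at row {cell_type!r}, "
                    f"column {marker!r} (expected one of {ALPHABET})"
                )
    matrix = ClassificationMatrix(cleaned)
    missing: list[str] = []
    if experiment_markers is not None:
        missing = [m for m in matrix.markers if m not in set(experiment_markers)]
    return matrix, missing


def separability_report(matrix: ClassificationMatrix) -> list[tuple[str, str]]:
    """All row pairs that can co-match a cell.

    A pair is separable only if some marker carries '+' in one row and '-'
    in the other ('A' never excludes). An empty list means the signatures
    are mutually exclusive and every cell matches at most one lineage.
    The result is a set of unordered pairs, reported in row order, and is
    independent of row permutation.
    """
    entries = matrix.entries.to_numpy()
    names = matrix.cell_types
    pairs: list[tuple[str, str]] = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            conflict = (
                ((entries[i] == "+") & (entries[j] == "-"))
                | ((entries[i] == "-") & (entries[j] == "+"))
            ).any()
            if not conflict:
                pairs.append((names[i], names[j]))
    return pairs


def write_classification_matrix(
    matrix: ClassificationMatrix, path: str | os.PathLike
) -> None:
    matrix.entries.to_csv(path, index_label="cell_type")
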