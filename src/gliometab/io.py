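"""Readers and writers for the tabular and set-file formats.

Peak-area matrices travel as delimited text (CSV or TSV) with identifiers
in the first row/column and blanks (or ``NA``) for non-detects.  Metabolite
sets travel in the GMT dialect (one set per row: name, description,
members...) or the GMX dialect (one set per column), chosen by file
extension and overridable.  Ranked lists serialize to the two-column
RNK-style preranked format.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    ANNOTATION_COLUMNS,
    Layer,
    MetaboliteSet,
    PeakAreaMatrix,
    SampleAnnotation,
    ValidationError,
)

__all__ = [
    "read_peak_matrix",
    "write_peak_matrix",
    "read_annotation",
    "write_annotation",
    "read_set_file",
    "write_set_file",
    "write_rnk",
    "read_rnk",
]

#: strings interpreted as a missing value in matrix cells
_MISSING = {"", "NA", "NaN", "nan", "na"}

_NEWLINE = "\n"  # all writers emit LF regardless of platform


def _sep_for(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_peak_matrix(
    path: str | Path,
    orientation: str = "metabolites_in_rows",
    sep: str | None = None,
    batch_of: dict[str, str] | None = None,
) -> PeakAreaMatrix:
    """Parse a delimited peak-area table into a raw-layer matrix.

    Empty cells and ``NA`` are missing values.  Zero or negative values are
    rejected: normalized peak areas are strictly positive and a non-detect
    must be encoded as a blank, not a 0.  Non-numeric cells raise a parse
    error naming the offending row and column.
    """
    if orientation not in ("metabolites_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _sep_for(path, sep)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    if not rows or len(rows) < 2:
        raise ValidationError(f"{path}: matrix file needs a header and data rows")
    header = [c.strip() for c in rows[0][1:]]
    row_ids, data = [], []
    for r in rows[1:]:
        if not r or all(c.strip() == "" for c in r):
            continue
        row_ids.append(r[0].strip())
        vals = []
        for j, cell in enumerate(r[1:]):
            cell = cell.strip()
            if cell in _MISSING:
                vals.append(np.nan)
                continue
            try:
                vals.append(float(cell))
            except ValueError:
                raise ValidationError(
                    f"{path}: non-numeric value {cell!r} at row {r[0]!r}, "
                    f"column {header[j] if j < len(header) else j + 2!r}"
                ) from None
        if len(vals) < len(header):
            vals += [np.nan] * (len(header) - len(vals))
        data.append(vals[: len(header)])
    frame = pd.DataFrame(data, index=row_ids, columns=header, dtype=float)
    if orientation == "samples_in_rows":
        frame = frame.T
    return PeakAreaMatrix(values=frame, layer=Layer.RAW, batch_of=dict(batch_of or {}))


def write_peak_matrix(
    matrix: PeakAreaMatrix,
    path: str | Path,
    orientation: str = "metabolites_in_rows",
    sep: str | None = None,
) -> None:
    """Write a matrix with blanks for missing values (full float precision)."""
    sep = _sep_for(path, sep)
    frame = matrix.values if orientation == "metabolites_in_rows" else matrix.values.T
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep, lineterminator=_NEWLINE)
        w.writerow([frame.index.name or "id"] + list(frame.columns))
        for rid, row in frame.iterrows():
            w.writerow([rid] + ["" if np.isnan(v) else repr(float(v)) for v in row])


def read_annotation(path: str | Path) -> SampleAnnotation:
    """Read the sample annotation CSV (documented canonical columns)."""
    t = pd.read_csv(path, dtype={"sample_id": str, "case_id": str, "batch": str})
    required = {"sample_id", "case_id", "location"}
    missing = required - set(t.columns)
    if missing:
        raise ValidationError(f"{path}: annotation missing columns {sorted(missing)}")
    return SampleAnnotation(t.set_index("sample_id"))


def write_annotation(annotation: SampleAnnotation, path: str | Path) -> None:
    t = annotation.table.copy()
    t["perfusate_excluded"] = [";".join(sorted(v)) for v in t["perfusate_excluded"]]
    cols = [c for c in ANNOTATION_COLUMNS if c != "sample_id" and c in t.columns]
    t[cols].to_csv(path, index=True, index_label="sample_id", lineterminator=_NEWLINE)


# ---------------------------------------------------------------------------
# GMT / GMX metabolite-set files
# ---------------------------------------------------------------------------

def _dialect_for(path: str | Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("gmt", "gmx"):
            raise ValueError(f"unknown set-file dialect {dialect!r}")
        return dialect
    return "gmx" if str(path).lower().endswith(".gmx") else "gmt"


def read_set_file(path: str | Path, dialect: str | None = None) -> list[MetaboliteSet]:
    """Read metabolite sets from a GMT (row-wise) or GMX (column-wise) file.

    Member order is preserved; blank trailing fields are dropped.  Empty sets
    and duplicate set names are rejected.
    """
    dialect = _dialect_for(path, dialect)
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t")]
    rows = [r for r in rows if any(c.strip() != "" for c in r)]
    if not rows:
        raise ValidationError(f"{path}: empty set file")
    if dialect == "gmx":
        width = max(len(r) for r in rows)
        rows = [r + [""] * (width - len(r)) for r in rows]
        rows = [list(col) for col in zip(*rows)]  # transpose: sets become rows
    sets: list[MetaboliteSet] = []
    names: set[str] = set()
    for r in rows:
        fields = [c.strip() for c in r]
        while fields and fields[-1] == "":
            fields.pop()
        if not fields:
            continue
        name = fields[0]
        desc = fields[1] if len(fields) > 1 else ""
        members = [m for m in fields[2:] if m != ""]
        if name in names:
            raise ValidationError(f"{path}: duplicate set name {name!r}")
        names.add(name)
        if not members:
            raise ValidationError(f"{path}: set {name!r} has no members")
        sets.append(MetaboliteSet(name=name, members=tuple(members), description=desc))
    return sets


def write_set_file(
    sets: Sequence[MetaboliteSet], path: str | Path, dialect: str | None = None
) -> None:
    """Write sets as GMT or GMX.  Output is bit-stable for identical input:
    fields in (name, description, members...) order, tab-separated, LF
    newlines."""
    if not sets:
        raise ValidationError("cannot write an empty set list")
    dialect = _dialect_for(path, dialect)
    rows = [[s.name, s.description, *s.members] for s in sets]
    if dialect == "gmx":
        width = max(len(r) for r in rows)
        rows = [r + [""] * (width - len(r)) for r in rows]
        rows = [list(col) for col in zip(*rows)]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator=_NEWLINE)
        w.writerows(rows)


# ---------------------------------------------------------------------------
# RNK-style ranked lists
# ---------------------------------------------------------------------------

def write_rnk(entries: pd.DataFrame, path: str | Path) -> None:
    """Write (metabolite, rank_score) pairs in the two-column preranked
    format, in list order."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator=_NEWLINE)
        for _, row in entries.iterrows():
            w.writerow([row["metabolite"], repr(float(row["rank_score"]))])


def read_rnk(path: str | Path) -> pd.DataFrame:
    """Read a two-column preranked file into a (metabolite, rank_score)
    frame sorted by descending score (ties by metabolite name)."""
    t = pd.read_csv(path, sep="\t", header=None, names=["metabolite", "rank_score"])
    if t["metabolite"].duplicated().any():
        dups = sorted(t["metabolite"][t["metabolite"].duplicated()])
        raise ValidationError(f"{path}: duplicate metabolites in ranked list: {dups}")
    t = t.sort_values(
        ["rank_score", "metabolite"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    t["rank"] = np.arange(1, len(t) + 1)
    return t
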