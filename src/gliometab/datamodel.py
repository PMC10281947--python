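"""Core data containers for microdialysate metabolomics.

The pipeline operates on three kinds of objects: a peak-area matrix
(metabolites x samples, with explicit missingness), a per-sample annotation
table (patient/case, catheter location, IDH status, heme content for CSF),
and named metabolite sets.  Values are relative abundances from untargeted
LC-MS; they are strictly positive when present, and a non-detect is a
missing value, never a zero.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Layer",
    "Location",
    "IdhStatus",
    "PeakAreaMatrix",
    "SampleAnnotation",
    "MetaboliteSet",
    "ValidationError",
]

MEDIAN_TOL = 1e-9


class ValidationError(ValueError):
    """An input violates a structural invariant of the data model."""


class Layer(str, enum.Enum):
    RAW = "raw"
    NORMALIZED = "normalized"


class Location(str, enum.Enum):
    E = "E"      # enhancing tumour (contrast-enhancing, BBB-disrupted)
    NE = "NE"    # non-enhancing tumour (radiographically BBB-intact)
    B = "B"      # brain adjacent to tumour (internal control)
    CSF = "CSF"  # cerebrospinal fluid (contamination reference samples)


class IdhStatus(str, enum.Enum):
    MUTANT = "mutant"
    WILD_TYPE = "wild_type"
    UNKNOWN = "unknown"


@dataclass
class PeakAreaMatrix:
    """Metabolites x samples abundance table with an explicit missing mask.

    Parameters
    ----------
    values
        DataFrame indexed by metabolite id with sample ids as columns.
        Missing entries are NaN; present entries must be strictly positive.
    layer
        ``Layer.RAW`` or ``Layer.NORMALIZED`` (per-metabolite, per-batch
        median scaled to 1).
    batch_of
        Mapping sample id -> batch label.  Samples without an entry are
        assigned a single default batch.
    """

    values: pd.DataFrame
    layer: Layer = Layer.RAW
    batch_of: dict[str, str] = field(default_factory=dict)
    #: True once cells were masked after normalization (perfusate
    #: exclusions); the median==1 invariant then no longer holds cell-wise
    #: and is not re-checked.
    masked_after_normalization: bool = False

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.layer = Layer(self.layer)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise ValidationError(f"duplicate metabolite ids: {dups}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique())
            raise ValidationError(f"duplicate sample ids: {dups}")
        arr = self.values.to_numpy()
        bad = (arr <= 0) & ~np.isnan(arr)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                "peak areas must be strictly positive; found "
                f"{arr[i, j]!r} at metabolite {idx[i]!r}, sample {cols[j]!r} "
                "(use an empty cell for a non-detect, never 0)"
            )
        if self.layer is Layer.NORMALIZED and not self.masked_after_normalization:
            for batch, samples in self.samples_by_batch().items():
                med = self.values[samples].median(axis=1, skipna=True)
                off = (med - 1.0).abs() > MEDIAN_TOL
                if off.any():
                    raise ValidationError(
                        f"layer=normalized but batch {batch!r} has "
                        f"{int(off.sum())} metabolite(s) with median != 1 "
                        f"(first: {med[off].index[0]!r})"
                    )

    # -- convenience ------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def batch_labels(self) -> pd.Series:
        """Batch label per sample (default batch ``"1"`` when unspecified)."""
        return pd.Series(
            [self.batch_of.get(s, "1") for s in self.values.columns],
            index=self.values.columns,
            name="batch",
        )

    def samples_by_batch(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, b in self.batch_labels().items():
            out.setdefault(b, []).append(s)
        return out

    def copy_with(
        self,
        values: pd.DataFrame,
        layer: Layer | None = None,
        masked_after_normalization: bool | None = None,
    ) -> "PeakAreaMatrix":
        return PeakAreaMatrix(
            values=values,
            layer=self.layer if layer is None else layer,
            batch_of=dict(self.batch_of),
            masked_after_normalization=(
                self.masked_after_normalization
                if masked_after_normalization is None
                else masked_after_normalization
            ),
        )


#: canonical annotation columns, in serialization order
ANNOTATION_COLUMNS = [
    "sample_id",
    "case_id",
    "catheter",
    "location",
    "idh_status",
    "recurrent",
    "batch",
    "heme",
    "perfusate_excluded",
]


@dataclass
class SampleAnnotation:
    """Per-sample metadata table.

    ``table`` is indexed by sample_id with columns case_id, catheter,
    location, idh_status, recurrent, batch, heme, perfusate_excluded.
    ``perfusate_excluded`` holds a frozenset of metabolite ids whose values
    are unreliable for that sample because the perfusate itself contained
    the analyte (e.g. lactate in a lactate-containing perfusion fluid).
    ``heme`` is a blood-contamination surrogate, present only for CSF
    samples; its units are arbitrary — only rank order is used.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.name != "sample_id":
            if "sample_id" in t.columns:
                t = t.set_index("sample_id")
            else:
                t = t.rename_axis("sample_id")
        if t.index.has_duplicates:
            dups = sorted(t.index[t.index.duplicated()].unique())
            raise ValidationError(f"duplicate sample annotations: {dups}")
        t = t.copy()
        if "perfusate_excluded" not in t.columns:
            t["perfusate_excluded"] = [frozenset()] * len(t)
        else:
            t["perfusate_excluded"] = [
                v if isinstance(v, frozenset) else frozenset(v) if isinstance(v, (set, list, tuple)) else _parse_excl(v)
                for v in t["perfusate_excluded"]
            ]
        if "heme" not in t.columns:
            t["heme"] = np.nan
        t["heme"] = t["heme"].astype(float)
        if "recurrent" not in t.columns:
            t["recurrent"] = False
        t["location"] = [Location(x).value for x in t["location"]]
        if "idh_status" not in t.columns:
            t["idh_status"] = IdhStatus.UNKNOWN.value
        t["idh_status"] = [IdhStatus(x).value for x in t["idh_status"]]
        non_csf = t["location"] != Location.CSF.value
        if t.loc[non_csf, "heme"].notna().any():
            bad = t.index[non_csf & t["heme"].notna()][0]
            raise ValidationError(
                f"heme content is defined only for CSF samples (sample {bad!r})"
            )
        self.table = t

    def for_matrix(self, matrix: PeakAreaMatrix) -> "SampleAnnotation":
        """Check every matrix sample is annotated; return the aligned subset."""
        missing = [s for s in matrix.sample_ids if s not in self.table.index]
        if missing:
            raise ValidationError(f"samples without annotation: {missing}")
        return SampleAnnotation(self.table.loc[matrix.sample_ids])

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def samples_at(self, location: Location | str) -> list[str]:
        loc = Location(location).value
        return list(self.table.index[self.table["location"] == loc])

    def case_of(self, sample_id: str) -> str:
        return str(self.table.loc[sample_id, "case_id"])

    def sample_for(self, case_id: str, location: Location | str) -> str | None:
        """The unique sample of a case at a location, or None."""
        loc = Location(location).value
        hits = self.table.index[
            (self.table["case_id"] == case_id) & (self.table["location"] == loc)
        ]
        if len(hits) == 0:
            return None
        if len(hits) > 1:
            raise ValidationError(
                f"case {case_id!r} has {len(hits)} catheters at {loc}; expected one"
            )
        return str(hits[0])

    def cases(self) -> list[str]:
        seen: list[str] = []
        for c in self.table["case_id"]:
            if c not in seen:
                seen.append(str(c))
        return seen


def _parse_excl(v: object) -> frozenset:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return frozenset()
    return frozenset(str(v).split(";"))


@dataclass(frozen=True)
class MetaboliteSet:
    """A named, ordered collection of metabolite ids."""

    name: str
    members: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValidationError(f"metabolite set {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            seen: set[str] = set()
            dups = []
            for m in self.members:
                if m in seen:
                    dups.append(m)
                seen.add(m)
            raise ValidationError(f"set {self.name!r} has duplicate members: {dups}")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, item: object) -> bool:
        return item in self.members

    @classmethod
    def from_ids(cls, name: str, members: Iterable[str], description: str = "") -> "MetaboliteSet":
        return cls(name=name, members=tuple(members), description=description)
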