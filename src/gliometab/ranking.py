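"""Paired fold-change ranked metabolite lists.

Each case contributes catheter pairs (enhancing tumour E, non-enhancing
tumour NE, brain B); for a contrast such as E-vs-B every analyzable
metabolite gets a fold change value(E)/value(B) and the list is ordered
from the most tumour-associated (rank 1) to the most brain-associated
(rank N).  The signed rank score is log2(fold change), which orders the
list identically to the raw ratio but gives the enrichment weighting a
scale symmetric about zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import PeakAreaMatrix, SampleAnnotation, ValidationError

__all__ = ["Contrast", "RankedList", "make_ranked_list", "group_fold_change",
           "ranked_list_from_fc", "average_rank_table"]


@dataclass(frozen=True)
class Contrast:
    """A numerator/denominator sample pair (or group pair) within one case."""

    numerator: tuple[str, ...]
    denominator: tuple[str, ...]
    label: str = "custom"

    def __post_init__(self) -> None:
        num, den = set(self.numerator), set(self.denominator)
        if not num or not den:
            raise ValidationError("contrast needs non-empty numerator and denominator")
        if num & den:
            raise ValidationError(f"numerator and denominator overlap: {sorted(num & den)}")

    @classmethod
    def paired(cls, numerator_sample: str, denominator_sample: str, label: str) -> "Contrast":
        return cls((numerator_sample,), (denominator_sample,), label)


@dataclass
class RankedList:
    """A strict ordering of metabolites by signed fold-change score.

    ``entries`` columns: metabolite, fold_change, rank_score, rank.
    Rank 1 is the most numerator-associated (tumour end); rank N the most
    denominator-associated (brain end).  ``provenance`` records omitted
    (masked/missing) metabolites and how the score was computed.
    """

    name: str
    entries: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        e = self.entries
        n = len(e)
        if n == 0:
            raise ValidationError(f"ranked list {self.name!r} is empty")
        if sorted(e["rank"]) != list(range(1, n + 1)):
            raise ValidationError(f"ranked list {self.name!r}: ranks are not 1..{n}")
        scores = e["rank_score"].to_numpy()
        if np.any(np.diff(scores) > 1e-12):
            raise ValidationError(f"ranked list {self.name!r}: not sorted by descending score")
        if (e["fold_change"] <= 0).any():
            raise ValidationError(f"ranked list {self.name!r}: non-positive fold change")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def metabolites(self) -> list[str]:
        return list(self.entries["metabolite"])

    def rank_of(self, metabolite: str) -> int:
        hit = self.entries.index[self.entries["metabolite"] == metabolite]
        if len(hit) != 1:
            raise KeyError(metabolite)
        return int(self.entries.loc[hit[0], "rank"])

    def scores(self) -> pd.Series:
        return pd.Series(
            self.entries["rank_score"].to_numpy(),
            index=self.entries["metabolite"].to_numpy(),
        )


def _order_entries(fc: pd.Series) -> pd.DataFrame:
    """Descending log2 fold change; ties broken by ascending metabolite name."""
    t = pd.DataFrame({"metabolite": fc.index, "fold_change": fc.to_numpy()})
    t["rank_score"] = np.log2(t["fold_change"])
    t = t.sort_values(
        ["rank_score", "metabolite"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    t["rank"] = np.arange(1, len(t) + 1)
    return t


def make_ranked_list(
    matrix: PeakAreaMatrix,
    contrast: Contrast,
    annotation: SampleAnnotation | None = None,
    name: str | None = None,
    allow_cross_case: bool = False,
) -> RankedList:
    """Rank metabolites by the paired fold change numerator/denominator.

    Metabolites with a missing (or masked) value in either sample are
    omitted from the list and recorded in ``provenance['omitted']``.  A
    contrast whose samples span different cases is rejected unless
    ``allow_cross_case`` is set (the design is paired within a surgery).
    """
    if len(contrast.numerator) != 1 or len(contrast.denominator) != 1:
        raise ValidationError("make_ranked_list takes single-sample contrasts; "
                              "use group_fold_change for group contrasts")
    num, den = contrast.numerator[0], contrast.denominator[0]
    for s in (num, den):
        if s not in matrix.values.columns:
            raise ValidationError(f"sample {s!r} not in matrix")
    if annotation is not None and not allow_cross_case:
        if annotation.case_of(num) != annotation.case_of(den):
            raise ValidationError(
                f"contrast {num!r}/{den!r} crosses cases "
                f"({annotation.case_of(num)!r} vs {annotation.case_of(den)!r}); "
                "pass allow_cross_case=True to override"
            )
    a = matrix.values[num]
    b = matrix.values[den]
    ok = a.notna() & b.notna()
    omitted = list(matrix.values.index[~ok])
    fc = a[ok] / b[ok]
    if fc.empty:
        raise ValidationError(f"no metabolite observed in both {num!r} and {den!r}")
    entries = _order_entries(fc)
    return RankedList(
        name=name or f"{contrast.label}:{num}/{den}",
        entries=entries,
        provenance={
            "contrast": contrast.label,
            "numerator": num,
            "denominator": den,
            "score": "log2(fold_change)",
            "omitted": omitted,
        },
    )


def group_fold_change(
    matrix: PeakAreaMatrix,
    group_a: list[str],
    group_b: list[str],
) -> pd.Series:
    """Per-metabolite ratio of group means, mean(A)/mean(B), over
    non-missing values.  Metabolites unobserved in an entire group are NaN."""
    a_set, b_set = set(group_a), set(group_b)
    if not a_set or not b_set:
        raise ValidationError("groups must be non-empty")
    if a_set & b_set:
        raise ValidationError(f"groups overlap: {sorted(a_set & b_set)}")
    mean_a = matrix.values[list(group_a)].mean(axis=1, skipna=True)
    mean_b = matrix.values[list(group_b)].mean(axis=1, skipna=True)
    return mean_a / mean_b


def ranked_list_from_fc(fc: pd.Series, name: str, provenance: dict | None = None) -> RankedList:
    """Build a RankedList from an arbitrary fold-change vector (NaN dropped)."""
    fc = fc.dropna()
    if fc.empty:
        raise ValidationError(f"ranked list {name!r}: no usable fold changes")
    return RankedList(name=name, entries=_order_entries(fc),
                      provenance=dict(provenance or {}, score="log2(fold_change)"))


def average_rank_table(lists: list[RankedList]) -> pd.DataFrame:
    """Per-metabolite ranks across lists plus their mean, sorted by
    ascending mean rank (ties by metabolite name).

    Lists sharing the same universe line up exactly; otherwise the
    intersection is used and a note is attached via the returned frame's
    ``attrs['universe_note']``.
    """
    if not lists:
        raise ValidationError("average_rank_table needs at least one list")
    universes = [set(rl.metabolites) for rl in lists]
    shared = set.intersection(*universes)
    note = ""
    if any(u != shared for u in universes):
        note = (f"lists do not share a universe; using the {len(shared)}-metabolite "
                "intersection")
    if not shared:
        raise ValidationError("ranked lists have no metabolites in common")
    cols = {}
    for rl in lists:
        r = rl.entries.set_index("metabolite")["rank"]
        cols[rl.name] = r.loc[sorted(shared)]
    table = pd.DataFrame(cols)
    table["mean_rank"] = table.mean(axis=1)
    # stable sort: by name first, then mean rank, so ties fall to the name
    table = table.sort_index(kind="mergesort").sort_values("mean_rank", kind="mergesort")
    table.index.name = "metabolite"
    table.attrs["universe_note"] = note
    return table
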