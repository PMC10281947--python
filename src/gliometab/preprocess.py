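"""Normalization, presence filtering, and perfusate-contamination masking.

These three steps define the analyzable metabolite universe: peak areas are
scaled so each metabolite's within-batch median is 1, metabolites observed
in too few catheters are dropped, and (metabolite, case) pairs whose
perfusion fluid contained the analyte are masked out of downstream paired
statistics.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .datamodel import Layer, PeakAreaMatrix, SampleAnnotation, ValidationError

__all__ = [
    "median_normalize",
    "normalizable_subset",
    "presence_threshold",
    "presence_filter",
    "apply_perfusate_exclusions",
]


def normalizable_subset(matrix: PeakAreaMatrix) -> tuple[PeakAreaMatrix, list[str]]:
    """Drop metabolites with an all-missing (metabolite, batch) group.

    Per-batch median scaling is undefined for a metabolite never observed
    in a batch; such metabolites (non-detects of the platform run) are
    removed before normalization and returned for the provenance log.  Any
    metabolite kept here but thinly observed still faces the presence
    filter downstream.
    """
    keep = pd.Series(True, index=matrix.values.index)
    for _batch, samples in matrix.samples_by_batch().items():
        keep &= matrix.values[samples].notna().any(axis=1)
    dropped = list(matrix.values.index[~keep])
    return matrix.copy_with(matrix.values.loc[keep]), dropped


def median_normalize(matrix: PeakAreaMatrix) -> PeakAreaMatrix:
    """Scale each metabolite so its median over non-missing values equals 1
    within each batch.

    The median of an even count is the midpoint mean.  Missingness is
    untouched.  Idempotent: normalizing a normalized matrix is the identity.
    """
    vals = matrix.values.copy()
    offenders = []
    for batch, samples in matrix.samples_by_batch().items():
        block = vals[samples]
        med = block.median(axis=1, skipna=True)
        empty = med.isna()
        if empty.any():
            offenders += [(m, batch) for m in med.index[empty]]
            continue
        vals[samples] = block.div(med, axis=0)
    if offenders:
        raise ValidationError(
            f"all-missing (metabolite, batch) groups: {offenders[:10]}"
            + ("..." if len(offenders) > 10 else "")
        )
    return matrix.copy_with(vals, layer=Layer.NORMALIZED)


def presence_threshold(n_samples: int, min_fraction: float) -> int:
    """Minimum number of observations required: ceil(min_fraction * n).

    With 44 catheters and min_fraction 0.90 this is 40, i.e. the
    "present in >= 40/44 catheters" rule.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    return math.ceil(min_fraction * n_samples)


def presence_filter(
    matrix: PeakAreaMatrix, min_fraction: float = 0.90
) -> tuple[PeakAreaMatrix, int]:
    """Keep metabolites observed in at least ceil(min_fraction * n_samples)
    samples.  Surviving metabolites keep their original order.  Returns the
    filtered matrix and the number kept."""
    need = presence_threshold(matrix.n_samples, min_fraction)
    counts = matrix.values.notna().sum(axis=1)
    keep = counts >= need
    out = matrix.copy_with(matrix.values.loc[keep])
    return out, int(keep.sum())


def apply_perfusate_exclusions(
    matrix: PeakAreaMatrix, annotation: SampleAnnotation
) -> tuple[PeakAreaMatrix, pd.DataFrame]:
    """Mask values whose perfusate contained the analyte.

    Exclusions come from the annotation's per-sample ``perfusate_excluded``
    sets and are applied per (metabolite, case): every catheter of the
    affected case is masked for that metabolite, so paired contrasts (e.g.
    a lactate E/B test) run on the remaining cases.  Masking sets the cell
    missing; rows are never deleted, so the metabolite universe for ranked
    lists is preserved.

    Returns the masked matrix and a log frame (metabolite, case, sample).
    """
    ann = annotation.for_matrix(matrix)
    vals = matrix.values.copy()
    known = set(matrix.metabolite_ids)
    log_rows = []
    case_mets: set[tuple[str, str]] = set()
    for sample_id, row in ann.table.iterrows():
        for met in row["perfusate_excluded"]:
            if met not in known:
                raise ValidationError(
                    f"perfusate exclusion for unknown metabolite {met!r} "
                    f"(sample {sample_id!r})"
                )
            case_mets.add((met, str(row["case_id"])))
    for met, case in sorted(case_mets):
        samples = [
            s for s in matrix.sample_ids
            if str(ann.table.loc[s, "case_id"]) == case
        ]
        for s in samples:
            if not np.isnan(vals.at[met, s]):
                vals.at[met, s] = np.nan
            log_rows.append({"metabolite": met, "case_id": case, "sample_id": s})
    log = pd.DataFrame(log_rows, columns=["metabolite", "case_id", "sample_id"])
    masked = matrix.masked_after_normalization or bool(
        log_rows and matrix.layer is Layer.NORMALIZED
    )
    return matrix.copy_with(vals, masked_after_normalization=masked), log
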