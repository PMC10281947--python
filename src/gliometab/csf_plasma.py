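"""Blood-contamination ("bloodiness") reference lists from CSF and
plasma-contamination enrichment in microdialysate contrasts.

A contrast-enhancing tumour region has, by definition, a disrupted
blood-brain barrier, so its extracellular fluid should be enriched for
plasma-derived metabolites.  To test this without plasma samples, CSF
serves as the reference: a bloody-vs-clean CSF fold-change ranked list
defines which metabolites track blood content.  Two constructions are
supported — a paired list from one subject's simultaneously drawn bloody
and clean samples, and a pooled list contrasting the top and bottom heme
quartiles across many CSF samples.  The top-k (bloody) and bottom-k
(clean) members of either list become metabolite sets queried against each
case's tumour-contrast ranked list.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .datamodel import MetaboliteSet, PeakAreaMatrix, ValidationError
from .enrichment import (
    EnrichmentResult,
    build_sets_from_list,
    fdr_across_sets,
    permutation_null,
)
from .ranking import RankedList, ranked_list_from_fc

__all__ = [
    "paired_bloodiness_list",
    "pooled_bloodiness_list",
    "plasma_enrichment",
]


def paired_bloodiness_list(
    csf_matrix: PeakAreaMatrix,
    bloody_sample: str,
    clean_sample: str,
    microdialysate_universe: list[str],
    name: str = "bloody_vs_clean_paired",
) -> RankedList:
    """Ranked bloodiness list from one bloody/clean CSF pair.

    Universe: metabolites observed in both CSF samples, intersected with
    the microdialysate presence-filtered set.  FC = bloody/clean, ordered
    from most blood-associated (rank 1) downwards.  A degenerate list
    (identical samples, all FC = 1) is flagged in provenance.
    """
    for s in (bloody_sample, clean_sample):
        if s not in csf_matrix.values.columns:
            raise ValidationError(f"CSF sample {s!r} not in matrix")
    bl = csf_matrix.values[bloody_sample]
    cl = csf_matrix.values[clean_sample]
    in_both = bl.notna() & cl.notna()
    universe = [m for m in csf_matrix.metabolite_ids
                if in_both.get(m, False) and m in set(microdialysate_universe)]
    if not universe:
        raise ValidationError(
            "no metabolite is present in both CSF samples and the "
            "microdialysate universe"
        )
    fc = (bl / cl).loc[universe]
    rl = ranked_list_from_fc(
        fc, name,
        provenance={"bloody": bloody_sample, "clean": clean_sample,
                    "n_universe": len(universe)},
    )
    if np.allclose(fc.to_numpy(), 1.0):
        rl.provenance["degenerate"] = True
        warnings.warn("bloody and clean CSF samples are identical; "
                      "bloodiness list is degenerate", stacklevel=2)
    return rl


def quartile_pools(
    heme: pd.Series, exclude: list[str] | None = None
) -> tuple[list[str], list[str]]:
    """Top (bloody) and bottom (clean) heme quartiles, ceil(n/4) each.

    Samples are sorted by heme descending; ties are broken by sample id
    (ascending) with a warning when a tie straddles a pool boundary.
    """
    heme = heme.dropna()
    if exclude:
        heme = heme.drop(index=[s for s in exclude if s in heme.index])
    n = len(heme)
    if n < 8:
        raise ValidationError(f"need >= 8 CSF samples with heme values, got {n}")
    k = math.ceil(n / 4)
    # stable sort on id first, then value, gives deterministic tie order
    order = heme.loc[sorted(heme.index)].sort_values(
        ascending=False, kind="mergesort"
    )
    ids = list(order.index)
    vals = order.to_numpy()
    for boundary in (k, n - k):
        if 0 < boundary < n and vals[boundary - 1] == vals[boundary]:
            warnings.warn(
                f"heme tie at value {vals[boundary]!r} straddles a quartile "
                "boundary; resolved by sample id", stacklevel=2,
            )
    return ids[:k], ids[n - k:]


def pooled_bloodiness_list(
    csf_matrix: PeakAreaMatrix,
    heme: pd.Series,
    microdialysate_universe: list[str],
    exclude: list[str] | None = None,
    csf_min_fraction: float = 0.85,
    name: str = "bloody_vs_clean_pooled",
) -> RankedList:
    """Ranked bloodiness list from pooled heme quartiles.

    CSF samples (minus exclusions) are ranked by heme content; the top and
    bottom ceil(n/4) form the bloody and clean pools.  Universe: the
    microdialysate presence-filtered set intersected with metabolites
    observed in more than ``csf_min_fraction`` of the CSF samples.
    FC = mean(bloody pool) / mean(clean pool), arithmetic means.
    """
    bloody, clean = quartile_pools(heme, exclude=exclude)
    pool_samples = [s for s in heme.dropna().index
                    if not exclude or s not in set(exclude)]
    sub = csf_matrix.values[pool_samples]
    frac = sub.notna().mean(axis=1)
    csf_ok = set(frac.index[frac > csf_min_fraction])
    universe = [m for m in csf_matrix.metabolite_ids
                if m in csf_ok and m in set(microdialysate_universe)]
    if not universe:
        raise ValidationError("empty universe after CSF/microdialysate filtering")
    mean_bl = csf_matrix.values.loc[universe, bloody].mean(axis=1, skipna=True)
    mean_cl = csf_matrix.values.loc[universe, clean].mean(axis=1, skipna=True)
    fc = mean_bl / mean_cl
    return ranked_list_from_fc(
        fc, name,
        provenance={"bloody_pool": bloody, "clean_pool": clean,
                    "pool_size": len(bloody), "n_universe": len(universe)},
    )


def plasma_enrichment(
    case_lists: list[RankedList],
    bloodiness: RankedList,
    k: int = 35,
    weighting_exponent: float = 1.0,
    n_permutations: int = 1000,
    seed: int = 0,
    fdr_threshold: float = 0.05,
) -> tuple[pd.DataFrame, list[EnrichmentResult], dict]:
    """Test each case's tumour contrast for plasma contamination.

    The bloodiness list's top-k set (blood-associated) and bottom-k set
    (clean-CSF-associated) are queried against every case's ranked list;
    all results share a null family for the FDR.  A case is "positive for
    bloody" when the bloody set is positively enriched at FDR <= threshold
    (plasma metabolites sit at the tumour end of the list), and "positive
    for clean" when the clean set is enriched at the denominator end
    (NES < 0 with FDR <= threshold).

    Returns (per-case table, results, summary counts).  The summary is
    omitted for a single-case input.
    """
    top, bottom = build_sets_from_list(bloodiness, k=k)
    root = np.random.SeedSequence(seed)
    streams = iter(root.spawn(2 * len(case_lists)))
    results: list[EnrichmentResult] = []
    for rl in case_lists:
        for ms in (top, bottom):
            rng = np.random.default_rng(next(streams))
            results.append(
                permutation_null(rl, ms, weighting_exponent=weighting_exponent,
                                 n_permutations=n_permutations, seed=seed, rng=rng)
            )
    fdr_across_sets(results)
    rows = []
    for i, rl in enumerate(case_lists):
        r_top, r_bot = results[2 * i], results[2 * i + 1]
        sig_bloody = r_top.nes > 0 and r_top.q_raw <= fdr_threshold
        sig_clean = r_bot.nes < 0 and r_bot.q_raw <= fdr_threshold
        rows.append({
            "list": rl.name,
            "nes_bloody_set": r_top.nes,
            "fdr_bloody_set": r_top.fdr_q,
            "star_bloody": "*" if sig_bloody else "",
            "nes_clean_set": r_bot.nes,
            "fdr_clean_set": r_bot.fdr_q,
            "star_clean": "*" if sig_clean else "",
            "significant_any": sig_bloody or sig_clean,
            "significant_both": sig_bloody and sig_clean,
        })
    table = pd.DataFrame(rows)
    summary: dict = {}
    if len(case_lists) > 1:
        summary = {
            "n_cases": len(case_lists),
            "n_significant_bloody": int(sum(r["star_bloody"] == "*" for r in rows)),
            "n_significant_clean": int(sum(r["star_clean"] == "*" for r in rows)),
            "n_significant_any": int(table["significant_any"].sum()),
            "n_significant_both": int(table["significant_both"].sum()),
        }
    return table, results, summary
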