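"""Metabolite-set enrichment against ranked fold-change lists.

The statistic is the weighted Kolmogorov–Smirnov-style running sum used by
preranked gene-set enrichment analysis, applied to metabolites: walking a
ranked list from the tumour end to the brain end, encountering a set member
("hit") at position i increments the sum by |score_i|^p / N_R (N_R = the sum
of |score|^p over all hits) and a non-member decrements it by 1/(N - N_H).
The enrichment score ES is the signed maximum deviation of this sum from
zero.  Because a ranked list comes from a single catheter pair, there are
no sample labels to permute; the null is formed by redrawing the set's
member positions uniformly from the list (metabolite permutation).  NES
normalizes ES by the mean |null ES| of the same sign, the nominal p is the
same-sign tail fraction, and FDR q follows the ratio-of-tails convention
over all (list, set) pairs sharing a null family.

A permutation estimate of exactly zero is reported at the display floor
1e-5 ("< 1e-05"); raw estimates are retained on the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MetaboliteSet, ValidationError
from .ranking import RankedList

__all__ = [
    "EnrichmentResult",
    "REPORT_FLOOR",
    "build_sets_from_list",
    "enrichment_score",
    "permutation_null",
    "fdr_across_sets",
    "cross_case_enrichment_matrix",
]

#: presentation floor for permutation p and FDR q estimates of exactly 0
REPORT_FLOOR = 1e-5


@dataclass
class EnrichmentResult:
    """One (ranked list, metabolite set) enrichment outcome."""

    list_name: str
    set_name: str
    es: float
    nes: float = np.nan
    p_nominal: float = np.nan
    fdr_q: float = np.nan
    n_set_in_list: int = 0
    n_set_total: int = 0
    weighting_exponent: float = 1.0
    n_permutations: int = 0
    seed: int | None = None
    #: raw (unfloored) permutation estimates, for provenance
    p_raw: float = np.nan
    q_raw: float = np.nan
    null_es: np.ndarray | None = field(default=None, repr=False)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.es <= 1.0 + 1e-12:
            raise ValidationError(f"ES out of [-1, 1]: {self.es}")
        if np.isfinite(self.nes) and self.es * self.nes < 0:
            raise ValidationError("NES sign must match ES sign")

    def display_p(self) -> str:
        return "<1e-05" if self.p_raw == 0 else f"{self.p_nominal:.4g}"

    def display_q(self) -> str:
        return "<1e-05" if self.q_raw == 0 else f"{self.fdr_q:.4g}"


def build_sets_from_list(
    ranked: RankedList, k: int = 35
) -> tuple[MetaboliteSet, MetaboliteSet]:
    """Extract the top-k (tumour-end) and bottom-k (brain-end) members of a
    ranked list as two disjoint metabolite sets."""
    n = len(ranked)
    if 2 * k > n:
        raise ValidationError(f"2k={2 * k} exceeds list length {n}")
    mets = ranked.metabolites
    top = MetaboliteSet.from_ids(
        f"{ranked.name}__top{k}", mets[:k],
        description=f"ranks 1..{k} of {ranked.name}",
    )
    bottom = MetaboliteSet.from_ids(
        f"{ranked.name}__bottom{k}", mets[n - k:],
        description=f"ranks {n - k + 1}..{n} of {ranked.name}",
    )
    return top, bottom


def _es_from_hits(
    abs_scores_p: np.ndarray, hit_mask: np.ndarray
) -> tuple[float, np.ndarray]:
    """Running-sum ES for one hit configuration.

    ``abs_scores_p``: |score|^p along the list; ``hit_mask``: boolean hits.
    Returns (es, running_sum profile).  Assumes N_R > 0.
    """
    n = hit_mask.size
    n_h = int(hit_mask.sum())
    n_r = float(abs_scores_p[hit_mask].sum())
    steps = np.where(hit_mask, abs_scores_p / n_r, -1.0 / (n - n_h))
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))  # first index attaining the max |dev|
    return float(running[i]), running


def enrichment_score(
    ranked: RankedList,
    met_set: MetaboliteSet,
    weighting_exponent: float = 1.0,
) -> tuple[float, np.ndarray, np.ndarray, dict]:
    """Weighted running-sum enrichment score of a set against a ranked list.

    Returns (es, running_sum, hit_positions (0-based), info).  Set members
    absent from the list are ignored; their count is in
    ``info['n_missing']``.  If every hit has score 0 under p > 0 the
    weighting falls back to p = 0 for this set (``info['fallback_p0']``).
    """
    if weighting_exponent < 0:
        raise ValidationError("weighting exponent must be >= 0")
    mets = ranked.entries["metabolite"].to_numpy()
    scores = ranked.entries["rank_score"].to_numpy(dtype=float)
    members = set(met_set.members)
    hit_mask = np.fromiter((m in members for m in mets), dtype=bool, count=mets.size)
    n_h = int(hit_mask.sum())
    if n_h == 0:
        raise ValidationError(
            f"set {met_set.name!r} has no members in list {ranked.name!r}"
        )
    if n_h == mets.size:
        raise ValidationError(
            f"set {met_set.name!r} covers the entire list {ranked.name!r}; "
            "misses are undefined"
        )
    info = {
        "n_hits": n_h,
        "n_missing": len(met_set) - n_h,
        "weighting_exponent": weighting_exponent,
        "fallback_p0": False,
    }
    abs_p = np.abs(scores) ** weighting_exponent
    if abs_p[hit_mask].sum() == 0.0:
        if weighting_exponent > 0:
            abs_p = np.ones_like(scores)
            info["fallback_p0"] = True
            info["weighting_exponent"] = 0.0
        else:  # p == 0 gives all-ones weights; cannot be zero
            raise AssertionError("unreachable: p=0 weights are 1")
    es, running = _es_from_hits(abs_p, hit_mask)
    return es, running, np.flatnonzero(hit_mask), info


def _null_es_sample(
    abs_scores_p: np.ndarray, n_h: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """ES under the metabolite-permutation null: redraw n_h hit positions
    uniformly without replacement, n_perm times.  Vectorized over
    permutations."""
    n = abs_scores_p.size
    # row-wise random subsets via argpartition of uniform keys
    keys = rng.random((n_perm, n))
    hit_idx = np.argpartition(keys, n_h - 1, axis=1)[:, :n_h]
    hit_mask = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(hit_mask, hit_idx, True, axis=1)
    weights = np.broadcast_to(abs_scores_p, (n_perm, n))
    n_r = np.where(hit_mask, weights, 0.0).sum(axis=1)
    # degenerate draws (all-zero hit weights) fall back to unweighted steps
    degen = n_r == 0.0
    if degen.any():
        w = weights.copy()
        w[degen] = 1.0
        n_r = np.where(degen, float(n_h), n_r)
    else:
        w = weights
    steps = np.where(hit_mask, w / n_r[:, None], -1.0 / (n - n_h))
    running = np.cumsum(steps, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), idx]


def permutation_null(
    ranked: RankedList,
    met_set: MetaboliteSet,
    weighting_exponent: float = 1.0,
    n_permutations: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> EnrichmentResult:
    """ES, NES and nominal p for one (list, set) pair.

    NES = es / mean(|null es| over null values sharing es's sign); the
    nominal p is the fraction of same-sign null ES at least as extreme,
    floored at 1e-5 when the estimate is exactly 0.  If no same-sign null
    value exists, the pooled |null| mean is used and the result is flagged.
    Identical seed and inputs give bit-identical results.
    """
    if rng is None:
        if seed is None:
            raise ValidationError("permutation_null requires a seed (or an rng)")
        rng = np.random.default_rng(seed)
    es, _, hits, info = enrichment_score(ranked, met_set, weighting_exponent)
    scores = ranked.entries["rank_score"].to_numpy(dtype=float)
    abs_p = (
        np.ones_like(scores)
        if info["fallback_p0"]
        else np.abs(scores) ** weighting_exponent
    )
    null = _null_es_sample(abs_p, info["n_hits"], n_permutations, rng)
    flags = ["fallback_p0"] if info["fallback_p0"] else []

    if es == 0.0:
        nes, p_raw = 0.0, 1.0
    else:
        same = null * np.sign(es) > 0
        if same.any():
            denom = float(np.abs(null[same]).mean())
            p_raw = float((np.abs(null[same]) >= abs(es)).sum() / same.sum())
        else:
            denom = float(np.abs(null).mean())
            p_raw = 0.0
            flags.append("no_same_sign_null")
        nes = es / denom if denom > 0 else 0.0
    p_nominal = max(p_raw, REPORT_FLOOR) if p_raw == 0.0 else p_raw
    return EnrichmentResult(
        list_name=ranked.name,
        set_name=met_set.name,
        es=es,
        nes=nes,
        p_nominal=p_nominal,
        p_raw=p_raw,
        n_set_in_list=info["n_hits"],
        n_set_total=len(met_set),
        weighting_exponent=info["weighting_exponent"],
        n_permutations=n_permutations,
        seed=seed,
        null_es=null,
        flags=flags,
    )


def fdr_across_sets(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """FDR q per result, ratio-of-tails style over a shared null family.

    Each result's null ES sample is normalized into null NES (same-sign
    mean, like the observed NES); the pooled same-sign null NES tail
    fraction at |nes*| is divided by the observed same-sign tail fraction,
    clipped to [0, 1], then monotonized so q never decreases as |nes|
    decreases within a sign family.  A single result falls back to its
    nominal p, flagged.  Results are modified in place and returned.
    """
    if not results:
        return results
    if len(results) == 1:
        r = results[0]
        r.q_raw = r.p_raw
        r.fdr_q = r.p_nominal
        r.flags.append("fdr_single_result")
        return results
    for r in results:
        if r.null_es is None:
            raise ValidationError(
                f"result ({r.list_name!r}, {r.set_name!r}) has no stored null sample"
            )

    # normalize each result's null sample into null NES values
    pooled: list[np.ndarray] = []
    for r in results:
        null = r.null_es
        pos = null[null > 0]
        neg = null[null < 0]
        mean_pos = float(pos.mean()) if pos.size else np.nan
        mean_neg = float(np.abs(neg).mean()) if neg.size else np.nan
        null_nes = np.zeros_like(null)
        if pos.size:
            null_nes[null > 0] = null[null > 0] / mean_pos
        if neg.size:
            null_nes[null < 0] = null[null < 0] / mean_neg
        pooled.append(null_nes)
    pooled_nes = np.concatenate(pooled)

    obs = np.array([r.nes for r in results], dtype=float)
    for r in results:
        if r.nes == 0.0:
            r.q_raw = 1.0
            continue
        sign = np.sign(r.nes)
        null_same = pooled_nes[pooled_nes * sign > 0]
        obs_same = obs[obs * sign > 0]
        if null_same.size == 0:
            frac_null = 0.0
        else:
            frac_null = float((np.abs(null_same) >= abs(r.nes)).sum() / null_same.size)
        frac_obs = float((np.abs(obs_same) >= abs(r.nes)).sum() / obs_same.size)
        r.q_raw = min(1.0, frac_null / frac_obs) if frac_obs > 0 else 1.0

    # monotonize within each sign family: larger |NES| never has larger q
    for sign in (1.0, -1.0):
        fam = [r for r in results if np.sign(r.nes) == sign]
        fam.sort(key=lambda r: -abs(r.nes))
        running = 0.0
        for r in fam:
            running = max(running, r.q_raw)
            r.q_raw = running
    for r in results:
        r.fdr_q = max(r.q_raw, REPORT_FLOOR) if r.q_raw == 0.0 else r.q_raw
    return results


def cross_case_enrichment_matrix(
    lists: list[RankedList],
    sets: list[MetaboliteSet],
    weighting_exponent: float = 1.0,
    n_permutations: int = 1000,
    seed: int = 0,
    include_self: bool = False,
    self_of: dict[str, str] | None = None,
    fdr_threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, list[EnrichmentResult]]:
    """Query every set against every other case's ranked list.

    ``self_of`` maps set name -> list name of the case the set was built
    from; those diagonal cells are skipped unless ``include_self``.  All
    results share one null family for the FDR.  Returns (NES table,
    significance-star table at FDR <= threshold, results).
    """
    self_of = self_of or {}
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(lists) * len(sets))
    results: list[EnrichmentResult] = []
    k = 0
    for rl in lists:
        for ms in sets:
            rng = np.random.default_rng(streams[k])
            k += 1
            if not include_self and self_of.get(ms.name) == rl.name:
                continue
            results.append(
                permutation_null(
                    rl, ms, weighting_exponent=weighting_exponent,
                    n_permutations=n_permutations, seed=seed, rng=rng,
                )
            )
    fdr_across_sets(results)
    nes = pd.DataFrame(index=[rl.name for rl in lists],
                       columns=[ms.name for ms in sets], dtype=float)
    stars = pd.DataFrame("", index=nes.index, columns=nes.columns)
    for r in results:
        nes.loc[r.list_name, r.set_name] = r.nes
        stars.loc[r.list_name, r.set_name] = "*" if r.q_raw <= fdr_threshold else ""
    nes.index.name = "ranked_list"
    stars.index.name = "ranked_list"
    return nes, stars, results


def results_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Flat TSV-ready table of enrichment results."""
    return pd.DataFrame(
        {
            "list": [r.list_name for r in results],
            "set": [r.set_name for r in results],
            "size": [r.n_set_in_list for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p_nominal": [r.p_nominal for r in results],
            "fdr_q": [r.fdr_q for r in results],
            "p_display": [r.display_p() for r in results],
            "fdr_display": [r.display_q() for r in results],
            "seed": [r.seed for r in results],
            "n_perm": [r.n_permutations for r in results],
            "weighting": [r.weighting_exponent for r in results],
        }
    )
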