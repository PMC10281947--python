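"""Sample-level Spearman correlation maps and Ward hierarchical clustering.

Correlations are computed per sample pair over the metabolites observed in
both (pairwise-complete), so missing values never enter a rank.  For
clustering, remaining missing values are filled with half the metabolite's
minimum observed value (a conventional detection-floor surrogate),
metabolites are optionally autoscaled (mean 0, sd 1), and samples are
agglomerated by Ward linkage on Euclidean distances.  Clipping of
autoscaled values at +/-6 affects the display matrix only, never the
distances.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .datamodel import PeakAreaMatrix, ValidationError

__all__ = ["spearman_matrix", "hierarchical_cluster", "ClusterResult"]

MIN_SHARED = 3
DISPLAY_CLIP = 6.0


def spearman_matrix(
    matrix: PeakAreaMatrix, samples: list[str] | None = None
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Spearman rho per sample pair over shared non-missing metabolites.

    Returns (symmetric table with unit diagonal, list of undefined pairs
    that shared fewer than 3 metabolites — their cells are NaN).
    """
    samples = samples or matrix.sample_ids
    vals = matrix.values[samples]
    n = len(samples)
    rho = pd.DataFrame(np.eye(n), index=samples, columns=samples)
    undefined: list[tuple[str, str]] = []
    arr = vals.to_numpy()
    present = ~np.isnan(arr)
    for i in range(n):
        for j in range(i + 1, n):
            shared = present[:, i] & present[:, j]
            if shared.sum() < MIN_SHARED:
                rho.iat[i, j] = rho.iat[j, i] = np.nan
                undefined.append((samples[i], samples[j]))
                continue
            r = stats.spearmanr(arr[shared, i], arr[shared, j]).statistic
            rho.iat[i, j] = rho.iat[j, i] = float(r)
    rho.index.name = "sample"
    return rho, undefined


class ClusterResult:
    """Ward clustering output: linkage matrix, leaf order, display matrix."""

    def __init__(
        self,
        linkage: np.ndarray,
        leaves: list[str],
        data: pd.DataFrame,
        display: pd.DataFrame,
        dropped: list[str],
    ):
        self.linkage = linkage
        self.leaves = leaves          # sample ids in dendrogram order
        self.data = data              # the matrix distances were computed on
        self.display = display       # autoscale-clipped copy for heat maps
        self.dropped = dropped        # zero-variance metabolites removed

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with merge heights as branch
        lengths."""
        tree = hierarchy.to_tree(self.linkage)
        labels = list(self.data.columns)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{labels[node.id]}:{length:.10g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        return walk(tree, tree.dist) + ";"


def hierarchical_cluster(
    matrix: PeakAreaMatrix, scaling: str = "autoscale"
) -> ClusterResult:
    """Ward-linkage clustering of samples on (optionally autoscaled)
    metabolite profiles.

    Missing values are filled with half the metabolite's minimum observed
    value before scaling.  Under autoscale, zero-variance metabolites are
    dropped with a warning.  Samples enter the linkage in lexicographic
    order so the dendrogram is invariant to input column order (ties in the
    agglomeration then resolve deterministically by that order).
    """
    if scaling not in ("autoscale", "none"):
        raise ValidationError(f"unknown scaling {scaling!r}")
    vals = matrix.values[sorted(matrix.sample_ids)].copy()
    # detection-floor fill: half the row minimum
    row_min = vals.min(axis=1, skipna=True)
    if row_min.isna().any():
        bad = list(row_min.index[row_min.isna()])
        raise ValidationError(f"metabolites with no observed value: {bad[:5]}")
    fill = 0.5 * row_min
    vals = vals.apply(lambda row: row.fillna(fill[row.name]), axis=1)

    dropped: list[str] = []
    if scaling == "autoscale":
        mu = vals.mean(axis=1)
        sd = vals.std(axis=1, ddof=1)
        zero = sd == 0
        if zero.any():
            dropped = list(vals.index[zero])
            warnings.warn(
                f"dropping {len(dropped)} zero-variance metabolite(s) under autoscale",
                stacklevel=2,
            )
            vals, mu, sd = vals.loc[~zero], mu[~zero], sd[~zero]
        vals = vals.sub(mu, axis=0).div(sd, axis=0)
    if vals.shape[1] < 2:
        raise ValidationError("need at least 2 samples to cluster")

    display = vals.clip(-DISPLAY_CLIP, DISPLAY_CLIP)
    linkage = hierarchy.linkage(vals.to_numpy().T, method="ward", metric="euclidean")
    order = hierarchy.leaves_list(linkage)
    leaves = [vals.columns[i] for i in order]
    return ClusterResult(linkage=linkage, leaves=leaves, data=vals,
                         display=display, dropped=dropped)
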