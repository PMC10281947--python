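import numpy as np
import pandas as pd
import pytest

from gliometab import (
    MetaboliteSet,
    PeakAreaMatrix,
    RankedList,
    median_normalize,
    presence_filter,
)
from gliometab.preprocess import normalizable_subset
from gliometab.synthetic import fixture_small


@pytest.fixture(scope="session")
def cohort():
    """The deterministic miniature cohort: (raw matrix, annotation, truth)."""
    return fixture_small()


@pytest.fixture(scope="session")
def micro_filtered(cohort):
    """Normalized, presence-filtered microdialysate matrix (no CSF)."""
    matrix, annotation, _truth = cohort
    micro_ids = [s for s in matrix.sample_ids
                 if annotation.table.loc[s, "location"] != "CSF"]
    sub, _ = normalizable_subset(matrix.copy_with(matrix.values[micro_ids]))
    filtered, _n = presence_filter(median_normalize(sub), 0.90)
    return filtered


@pytest.fixture(scope="session")
def csf_normalized(cohort):
    """Normalized CSF block of the miniature cohort."""
    matrix, annotation, _truth = cohort
    csf_ids = [s for s in matrix.sample_ids
               if annotation.table.loc[s, "location"] == "CSF"]
    sub, _ = normalizable_subset(matrix.copy_with(matrix.values[csf_ids]))
    return median_normalize(sub)


def make_ranked(scores: dict[str, float], name: str = "toy") -> RankedList:
    """RankedList from metabolite -> log2 score (descending, name ties)."""
    t = pd.DataFrame({"metabolite": list(scores), "rank_score": list(scores.values())})
    t["fold_change"] = 2.0 ** t["rank_score"]
    t = t.sort_values(["rank_score", "metabolite"], ascending=[False, True],
                      kind="mergesort").reset_index(drop=True)
    t["rank"] = np.arange(1, len(t) + 1)
    return RankedList(name=name, entries=t)


def matrix_from(values, metabolites=None, samples=None, **kw) -> PeakAreaMatrix:
    arr = np.asarray(values, dtype=float)
    metabolites = metabolites or [f"m{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return PeakAreaMatrix(
        values=pd.DataFrame(arr, index=metabolites, columns=samples), **kw
    )
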