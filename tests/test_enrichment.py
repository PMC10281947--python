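"""Weighted running-sum enrichment: ES oracle equivalence, permutation
NES/p, FDR behaviour."""

import numpy as np
import pytest

from gliometab import (
    MetaboliteSet,
    ValidationError,
    build_sets_from_list,
    enrichment_score,
    fdr_across_sets,
    permutation_null,
)
from gliometab.enrichment import cross_case_enrichment_matrix
from conftest import make_ranked


def bruteforce_es(scores, hit_mask, p):
    """Independent O(N) re-enumeration of the running sum."""
    n = len(scores)
    n_h = sum(hit_mask)
    n_r = sum(abs(s) ** p for s, h in zip(scores, hit_mask) if h)
    total, best = 0.0, 0.0
    for s, h in zip(scores, hit_mask):
        total += (abs(s) ** p) / n_r if h else -1.0 / (n - n_h)
        if abs(total) > abs(best):
            best = total
    return best


def random_list(rng, n):
    mets = [f"m{i:03d}" for i in range(n)]
    scores = np.sort(rng.normal(scale=2.0, size=n))[::-1]
    return make_ranked(dict(zip(mets, scores)))


class TestEnrichmentScore:
    def test_top_block_scores_plus_one(self):
        rl = make_ranked({f"m{i}": 10.0 - i for i in range(10)})
        top = MetaboliteSet.from_ids("top", rl.metabolites[:4])
        es, _, _, _ = enrichment_score(rl, top, 1.0)
        assert es == pytest.approx(1.0)

    def test_bottom_block_scores_minus_one(self):
        rl = make_ranked({f"m{i}": 10.0 - i for i in range(10)})
        bottom = MetaboliteSet.from_ids("bot", rl.metabolites[-4:])
        es, _, _, _ = enrichment_score(rl, bottom, 1.0)
        assert es == pytest.approx(-1.0)

    def test_worked_example_three_hits(self):
        # scores 10..1, hits at positions 1, 5, 10: N_R = 17, the running
        # sum peaks at 10/17 right after the first hit
        rl = make_ranked({f"m{i:02d}": float(10 - i) for i in range(10)})
        ms = MetaboliteSet.from_ids("s", ["m00", "m04", "m09"])
        es, running, hits, _ = enrichment_score(rl, ms, 1.0)
        assert es == pytest.approx(10.0 / 17.0, abs=1e-12)
        assert list(hits) == [0, 4, 9]
        assert running[0] == pytest.approx(10.0 / 17.0)

    @pytest.mark.parametrize("p", [0.0, 1.0, 2.0])
    def test_matches_bruteforce_oracle(self, p):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(5, 200))
            rl = random_list(rng, n)
            k = int(rng.integers(1, max(2, n // 2)))
            members = list(rng.choice(rl.metabolites, size=k, replace=False))
            ms = MetaboliteSet.from_ids("s", members)
            es, _, _, _ = enrichment_score(rl, ms, p)
            scores = rl.entries["rank_score"].to_numpy()
            hit = [m in set(members) for m in rl.metabolites]
            assert es == pytest.approx(bruteforce_es(scores, hit, p), abs=1e-12)
            assert -1.0 <= es <= 1.0

    def test_unweighted_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(8)
        rl = random_list(rng, 50)
        members = list(rng.choice(rl.metabolites, size=10, replace=False))
        ms = MetaboliteSet.from_ids("s", members)
        es0, _, _, _ = enrichment_score(rl, ms, 0.0)
        # cube the scores: order preserved, magnitudes distorted
        warped = make_ranked({
            m: float(np.sign(s) * abs(s) ** 3)
            for m, s in rl.scores().items()
        })
        es0w, _, _, _ = enrichment_score(warped, ms, 0.0)
        assert es0 == pytest.approx(es0w, abs=1e-12)

    def test_reversal_negates_es(self):
        rng = np.random.default_rng(9)
        rl = random_list(rng, 40)
        members = list(rng.choice(rl.metabolites, size=8, replace=False))
        ms = MetaboliteSet.from_ids("s", members)
        es, _, _, _ = enrichment_score(rl, ms, 1.0)
        flipped = make_ranked({m: -s for m, s in rl.scores().items()})
        es_r, _, _, _ = enrichment_score(flipped, ms, 1.0)
        assert es_r == pytest.approx(-es, abs=1e-12)

    def test_absent_set_rejected(self):
        rl = make_ranked({"a": 1.0, "b": 0.5})
        with pytest.raises(ValidationError, match="no members"):
            enrichment_score(rl, MetaboliteSet.from_ids("s", ["zzz"]), 1.0)

    def test_all_zero_hit_scores_fall_back_to_unweighted(self):
        rl = make_ranked({"a": 1.0, "b": 0.0, "c": 0.0, "d": -1.0})
        ms = MetaboliteSet.from_ids("s", ["b", "c"])
        _, _, _, info = enrichment_score(rl, ms, 1.0)
        assert info["fallback_p0"] is True


class TestBuildSets:
    def test_study_scale_universe(self):
        rl = make_ranked({f"m{i:03d}": 200.0 - i for i in range(162)})
        top, bottom = build_sets_from_list(rl, 35)
        assert len(top) == len(bottom) == 35
        assert not set(top.members) & set(bottom.members)
        assert top.members == tuple(rl.metabolites[:35])
        assert bottom.members == tuple(rl.metabolites[-35:])

    def test_singleton_boundary(self):
        rl = make_ranked({"a": 2.0, "b": 1.0, "c": 0.0})
        top, bottom = build_sets_from_list(rl, 1)
        assert top.members == ("a",) and bottom.members == ("c",)

    def test_overlapping_k_rejected(self):
        rl = make_ranked({"a": 2.0, "b": 1.0, "c": 0.0})
        with pytest.raises(ValidationError):
            build_sets_from_list(rl, 2)

    def test_matches_slice_after_independent_sort(self):
        rng = np.random.default_rng(10)
        scores = dict(zip([f"m{i:02d}" for i in range(40)], rng.normal(size=40)))
        rl = make_ranked(scores)
        top, bottom = build_sets_from_list(rl, 7)
        order = sorted(scores, key=lambda m: (-scores[m], m))
        assert list(top.members) == order[:7]
        assert list(bottom.members) == order[-7:]


class TestPermutationNull:
    def test_deterministic_for_identical_seed(self):
        rng = np.random.default_rng(11)
        rl = random_list(rng, 80)
        ms = MetaboliteSet.from_ids("s", rl.metabolites[:10])
        r1 = permutation_null(rl, ms, 1.0, 500, seed=123)
        r2 = permutation_null(rl, ms, 1.0, 500, seed=123)
        assert (r1.es, r1.nes, r1.p_nominal) == (r2.es, r2.nes, r2.p_nominal)
        assert np.array_equal(r1.null_es, r2.null_es)

    def test_top_set_strongly_significant(self):
        rng = np.random.default_rng(12)
        rl = random_list(rng, 100)
        ms = MetaboliteSet.from_ids("s", rl.metabolites[:15])
        r = permutation_null(rl, ms, 1.0, 1000, seed=5)
        assert r.nes > 0
        assert r.p_nominal < 0.05

    def test_seed_required(self):
        rl = make_ranked({"a": 1.0, "b": -1.0, "c": 0.5})
        ms = MetaboliteSet.from_ids("s", ["a"])
        with pytest.raises(ValidationError, match="seed"):
            permutation_null(rl, ms)

    def test_doubling_permutations_within_binomial_error(self):
        rng = np.random.default_rng(13)
        rl = random_list(rng, 60)
        members = list(rng.choice(rl.metabolites, size=12, replace=False))
        ms = MetaboliteSet.from_ids("s", members)
        r1 = permutation_null(rl, ms, 1.0, 1000, seed=1)
        r2 = permutation_null(rl, ms, 1.0, 2000, seed=2)
        p = max(r1.p_raw, 1e-3)
        ci = 4.0 * np.sqrt(p * (1 - p) / 1000)
        assert abs(r1.p_raw - r2.p_raw) <= max(ci, 0.02)

    def test_zero_floor_reported_below_1e5(self):
        rng = np.random.default_rng(14)
        rl = random_list(rng, 120)
        ms = MetaboliteSet.from_ids("s", rl.metabolites[:20])
        r = permutation_null(rl, ms, 1.0, 2000, seed=3)
        if r.p_raw == 0.0:
            assert r.p_nominal == 1e-5
            assert r.display_p() == "<1e-05"


class TestFdr:
    def _family(self, seed=15, n_sets=8, strong_first=True):
        rng = np.random.default_rng(seed)
        rl = random_list(rng, 100)
        sets = []
        if strong_first:
            sets.append(MetaboliteSet.from_ids("strong", rl.metabolites[:12]))
        for k in range(n_sets):
            members = list(rng.choice(rl.metabolites, size=12, replace=False))
            sets.append(MetaboliteSet.from_ids(f"rand{k}", members))
        streams = np.random.SeedSequence(seed).spawn(len(sets))
        return [
            permutation_null(rl, ms, 1.0, 1000, seed=seed,
                             rng=np.random.default_rng(st))
            for ms, st in zip(sets, streams)
        ]

    def test_overwhelming_set_hits_the_floor(self):
        results = fdr_across_sets(self._family())
        strong = next(r for r in results if r.set_name == "strong")
        assert strong.q_raw == 0.0
        assert strong.fdr_q == 1e-5
        assert strong.display_q() == "<1e-05"

    def test_null_family_q_values_stochastically_large(self):
        medians = []
        for seed in (20, 21, 22):
            results = fdr_across_sets(self._family(seed=seed, strong_first=False))
            medians.append(np.median([r.q_raw for r in results]))
        assert np.median(medians) >= 0.2

    def test_duplicated_results_share_q(self):
        results = self._family(seed=23, n_sets=3)
        twin = self._family(seed=23, n_sets=3)
        merged = fdr_across_sets(results + twin)
        qs = {}
        for r in merged:
            qs.setdefault(r.set_name, []).append(r.q_raw)
        for name, vals in qs.items():
            assert vals[0] == vals[1], name

    def test_q_monotone_in_abs_nes_within_sign(self):
        results = fdr_across_sets(self._family(seed=24, n_sets=10))
        for sign in (1, -1):
            fam = sorted((r for r in results if np.sign(r.nes) == sign),
                         key=lambda r: -abs(r.nes))
            qs = [r.q_raw for r in fam]
            assert qs == sorted(qs)

    def test_single_result_falls_back_to_p(self):
        (r,) = fdr_across_sets(self._family(seed=25, n_sets=0))
        assert r.fdr_q == r.p_nominal
        assert "fdr_single_result" in r.flags


class TestCrossCaseMatrix:
    def test_single_case_has_empty_offdiagonal(self):
        rng = np.random.default_rng(16)
        rl = random_list(rng, 50)
        top, bottom = build_sets_from_list(rl, 5)
        nes, stars, results = cross_case_enrichment_matrix(
            [rl], [top, bottom], seed=1,
            self_of={top.name: rl.name, bottom.name: rl.name},
        )
        assert results == []
        assert nes.isna().all().all()

    def test_include_self_recovers_diagonal(self):
        rng = np.random.default_rng(17)
        rl = random_list(rng, 50)
        top, _ = build_sets_from_list(rl, 5)
        nes, _, results = cross_case_enrichment_matrix(
            [rl], [top], seed=1, include_self=True,
            self_of={top.name: rl.name},
        )
        assert len(results) == 1
        assert nes.loc[rl.name, top.name] > 0
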