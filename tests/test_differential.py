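"""Exact paired signed-rank testing, volcano classification, concordance."""

import itertools

import numpy as np
import pytest
from scipy import stats

from gliometab import (
    ValidationError,
    cross_platform_concordance,
    exact_wilcoxon_signed_rank,
    paired_contrast_table,
    volcano_table,
)
from gliometab.differential import classify


def enumerate_p(diffs):
    """Brute-force exact two-sided p over all 2^n sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    sums = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    lower = sum(s <= w_obs + 1e-12 for s in sums) / 2**n
    upper = sum(s >= w_obs - 1e-12 for s in sums) / 2**n
    return min(1.0, 2.0 * min(lower, upper))


class TestExactWilcoxon:
    def test_attainable_minimum_nine_pairs(self):
        # all nine differences positive: p = 2/512, printed 0.0039
        w, p = exact_wilcoxon_signed_rank(np.arange(1.0, 10.0))
        assert p == 2 / 512
        assert f"{p:.4f}" == "0.0039"
        assert w == 0.0

    def test_attainable_minimum_seven_pairs(self):
        w, p = exact_wilcoxon_signed_rank(-np.arange(1.0, 8.0))
        assert p == 2 / 128
        assert f"{p:.4f}" == "0.0156"

    def test_worked_five_pair_example(self):
        w, p = exact_wilcoxon_signed_rank([1.5, 2.3, -0.4, 3.1, 0.9])
        assert w == 1.0          # the lone negative difference has rank 1
        assert p == 2 * (2 / 32)  # only sums 14 and 15 are as extreme

    @pytest.mark.parametrize("n", range(1, 13))
    def test_matches_sign_assignment_enumeration(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(8):
            d = rng.normal(size=n)
            if rng.random() < 0.3 and n > 2:  # inject tied magnitudes
                d[1] = -d[0]
            _, p = exact_wilcoxon_signed_rank(d)
            assert p == pytest.approx(enumerate_p(d), abs=1e-12)

    def test_agrees_with_scipy_on_tie_free_input(self):
        rng = np.random.default_rng(30)
        for n in (6, 9, 15, 20):
            d = rng.normal(size=n)
            _, p = exact_wilcoxon_signed_rank(d)
            p_ref = stats.wilcoxon(d, method="exact").pvalue
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_zero_differences_discarded(self):
        _, p_with = exact_wilcoxon_signed_rank([0.0, 1.0, 2.0, 3.0])
        _, p_without = exact_wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert p_with == p_without == 2 / 8

    def test_all_zero_is_degenerate(self):
        w, p = exact_wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert (w, p) == (0.0, 1.0)

    def test_invariant_under_positive_scaling(self):
        rng = np.random.default_rng(31)
        d = rng.normal(size=9)
        _, p1 = exact_wilcoxon_signed_rank(d)
        _, p2 = exact_wilcoxon_signed_rank(1e6 * d)
        assert p1 == p2

    def test_nan_rejected(self):
        with pytest.raises(ValidationError, match="NaN"):
            exact_wilcoxon_signed_rank([1.0, np.nan])


class TestPairedContrastTable:
    def test_planted_tumour_metabolite_recovered(self, cohort, micro_filtered):
        _, annotation, truth = cohort
        results, _ = paired_contrast_table(micro_filtered, annotation, "E/B")
        by_id = {r.metabolite_id: r for r in results}
        gaa = by_id[truth.special["gaa_like"]]
        assert gaa.significance_class == "up"
        assert gaa.p_two_sided == 2 / 512   # all nine pairs elevated
        assert gaa.mean_fc > 64             # planted 2^7 effect
        naa = by_id[truth.special["naa_like"]]
        assert naa.significance_class == "down"

    def test_class_calls_match_truth_for_tested_classes(self, cohort, micro_filtered):
        _, annotation, truth = cohort
        results, _ = paired_contrast_table(micro_filtered, annotation, "E/B")
        cls = truth.metabolite_class
        calls = {}
        for r in results:
            calls.setdefault(cls[r.metabolite_id], []).append(r.significance_class)
        assert set(calls["plasma_derived"]) == {"up"}
        assert set(calls["tumour_produced"]) == {"up"}
        assert set(calls["brain_associated"]) == {"down"}
        assert set(calls["background"]) == {"ns"}

    def test_all_equal_values_everything_ns(self):
        import pandas as pd
        from gliometab import PeakAreaMatrix, SampleAnnotation
        vals = pd.DataFrame(
            np.ones((4, 6)),
            index=[f"m{i}" for i in range(4)],
            columns=[f"c{k}_{loc}" for k in range(3) for loc in ("E", "B")],
        )
        m = PeakAreaMatrix(values=vals)
        ann = SampleAnnotation(pd.DataFrame({
            "sample_id": list(vals.columns),
            "case_id": [c.split("_")[0] for c in vals.columns],
            "location": [c.split("_")[1] for c in vals.columns],
        }))
        results, _ = paired_contrast_table(m, ann, "E/B")
        assert all(r.significance_class == "ns" for r in results)
        assert all(r.p_two_sided == 1.0 and r.degenerate for r in results)

    def test_swapping_contrast_inverts_fc_keeps_p(self, cohort, micro_filtered):
        _, annotation, _ = cohort
        eb, _ = paired_contrast_table(micro_filtered, annotation, "E/B")
        # manual B/A on the same pairs for a few metabolites
        from gliometab.differential import CONTRASTS
        import pandas as pd
        pairs = []
        for case in annotation.cases():
            sa = annotation.sample_for(case, "E")
            sb = annotation.sample_for(case, "B")
            if sa and sb:
                pairs.append((sa, sb))
        for r in eb[:20]:
            a = micro_filtered.values.loc[r.metabolite_id, [p[0] for p in pairs]]
            b = micro_filtered.values.loc[r.metabolite_id, [p[1] for p in pairs]]
            ok = a.notna().to_numpy() & b.notna().to_numpy()
            _, p_rev = exact_wilcoxon_signed_rank(
                (b.to_numpy() - a.to_numpy())[ok])
            assert p_rev == pytest.approx(r.p_two_sided, abs=1e-12)
            inv_mean_fc = float(np.mean(b.to_numpy()[ok] / a.to_numpy()[ok]))
            # B/A mean FC is the mean of reciprocals, not 1/mean; both
            # directions are recomputable from the same pairs
            assert inv_mean_fc > 0


class TestVolcano:
    def test_counts_match_threshold_recount(self, cohort, micro_filtered):
        _, annotation, _ = cohort
        results, _ = paired_contrast_table(micro_filtered, annotation, "E/B")
        t = volcano_table(results)
        counts = t.attrs["class_counts"]
        manual = [classify(r.p_two_sided, r.mean_fc, 0.05, 2.0) for r in results]
        assert counts["up"] == manual.count("up")
        assert counts["down"] == manual.count("down")
        assert counts["ns"] == manual.count("ns")
        assert len(t) == len(results)
        assert t["mean_fc"].is_monotonic_decreasing

    def test_single_result_single_row(self):
        from gliometab.differential import DifferentialResult
        r = DifferentialResult("m", "E/B", 9, 2.5, 2.4, 0.01, "up")
        t = volcano_table([r])
        assert len(t) == 1
        assert t.attrs["class_counts"] == {"up": 1, "down": 0, "ns": 0}

    def test_classification_boundaries(self):
        assert classify(0.05, 2.0, 0.05, 2.0) == "up"      # inclusive cutoffs
        assert classify(0.051, 2.0, 0.05, 2.0) == "ns"
        assert classify(0.05, 0.5, 0.05, 2.0) == "down"
        assert classify(0.05, 1.9, 0.05, 2.0) == "ns"


class TestConcordance:
    def test_exact_proportionality(self):
        x = np.array([1.0, 10.0, 100.0])
        slope, intercept, r2 = cross_platform_concordance(x, 3.5 * x)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(3.5)
        assert intercept == pytest.approx(0.0, abs=1e-9)

    def test_wide_dynamic_range_with_noise(self):
        # pairs spanning a 2500-fold range with small multiplicative noise
        rng = np.random.default_rng(32)
        x = np.logspace(0, np.log10(2500), 24)
        y = 2.0 * x * np.exp(rng.normal(0, 0.05, x.size))
        _, _, r2 = cross_platform_concordance(x, y)
        assert r2 > 0.99

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError, match="variance"):
            cross_platform_concordance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            cross_platform_concordance([1.0, 2.0], [1.0, 2.0])
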