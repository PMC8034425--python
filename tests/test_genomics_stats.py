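"""Alteration, co-occurrence, rank-sum and survival statistics."""

import math
from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from scipy.stats import kstest

from screenkit.genomics_stats import (
    AlterationMatrix,
    SurvivalRecord,
    alteration_frequency,
    bh_fdr,
    cooccurrence_enrichment,
    fisher_exact,
    km_curve,
    log2_pct_ratio,
    logrank_test,
    median_split,
    wilcoxon_ranksum,
)
from screenkit.synthetic_data import gen_alteration_matrix, gen_survival


def toy_matrix(calls: dict, types=None):
    df = pd.DataFrame(calls)
    types = pd.Series(
        types if types is not None else ["T"] * len(df), index=df.index
    )
    return AlterationMatrix(calls=df, cancer_types=types)


class TestAlterationFrequency:
    def test_headline_rounding(self):
        calls = {"EGFR": [1] * 821 + [0] * (10967 - 821)}
        m = toy_matrix(calls)
        out = alteration_frequency(m, "EGFR")
        assert out["pct"] == 7
        assert out["altered"] == 821

    def test_all_zero_column(self):
        m = toy_matrix({"G": [0, 0, 0]})
        assert alteration_frequency(m, "G")["pct"] == 0

    def test_recovers_planted_rate(self):
        matrix, truth = gen_alteration_matrix(
            n_samples=5000, index_rate=0.12, seed=1
        )
        out = alteration_frequency(matrix, "EGFR")
        assert abs(out["pct"] - 12) <= 1

    def test_per_cancer_type_breakdown(self):
        m = toy_matrix(
            {"G": [1, 0, 1, 0]}, types=["GBM", "GBM", "LUAD", "LUAD"]
        )
        out = alteration_frequency(m, "G", by_cancer_type=True)
        assert out["by_cancer_type"] == {"GBM": 50.0, "LUAD": 50.0}

    def test_unknown_gene(self):
        with pytest.raises(KeyError):
            alteration_frequency(toy_matrix({"G": [0]}), "NOPE")


class TestLogRatio:
    @pytest.mark.parametrize(
        "alt, unalt, expected",
        [
            (8.85, 1.69, 2.39),    # published RICTOR row
            (7.91, 1.34, 2.56),    # published UGGT1 row
            (4.69, 7.51, -0.68),   # published KRAS row
            (5.0, 5.0, 0.0),
        ],
    )
    def test_published_percentage_ratios(self, alt, unalt, expected):
        assert log2_pct_ratio(alt, unalt) == expected

    def test_zero_groups_give_infinite_sentinel(self):
        assert log2_pct_ratio(5.0, 0.0) == math.inf
        assert log2_pct_ratio(0.0, 5.0) == -math.inf
        assert log2_pct_ratio(0.0, 0.0) == 0.0


class TestFisherExact:
    def test_perfect_separation_closed_form(self):
        # table (0 10 / 10 0): only 2 of the C(20,10) equi-probable
        # margin-preserving tables are as extreme
        expected = 2 / comb(20, 10, exact=True)
        assert fisher_exact(0, 10, 10, 0) == pytest.approx(expected, rel=1e-6)

    def test_balanced_table_p_one(self):
        assert fisher_exact(5, 5, 5, 5) == 1.0

    def test_all_zero_convention(self):
        assert fisher_exact(0, 0, 0, 0) == 1.0

    def test_agrees_with_enumeration_small_margins(self):
        """Two-sided p equals direct hypergeometric enumeration."""
        from scipy.stats import hypergeom

        for a, b, c, d in product(range(5), repeat=4):
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            n = a + b + c + d
            row1, col1 = a + b, a + c
            rv = hypergeom(n, row1, col1)
            support = range(max(0, row1 + col1 - n), min(row1, col1) + 1)
            p_obs = rv.pmf(a)
            expected = sum(
                rv.pmf(k) for k in support if rv.pmf(k) <= p_obs * (1 + 1e-7)
            )
            assert fisher_exact(a, b, c, d) == pytest.approx(
                min(1.0, expected), rel=1e-6
            ), (a, b, c, d)


class TestBHFDR:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_stepup_example(self):
        # q_i = min over j>=i of p_j * m / j = 0.04 for all four
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        assert (bh_fdr([1.0, 1.0, 1.0]) == 1.0).all()

    def test_monotone_in_sorted_p_and_dominates_p(self):
        rng = np.random.default_rng(0)
        p = np.sort(rng.uniform(size=50))
        q = bh_fdr(p)
        assert (np.diff(q) >= -1e-12).all()
        assert (q >= p - 1e-12).all()
        assert (q <= 1.0).all()


class TestCooccurrenceEnrichment:
    def test_planted_odds_ratio_detected(self):
        matrix, truth = gen_alteration_matrix(
            n_samples=10_000,
            index_rate=0.07,
            planted_odds_ratios={"G000": 8.0},
            seed=2,
        )
        rows = cooccurrence_enrichment(matrix, "EGFR")
        planted = rows[rows.gene == "G000"].iloc[0]
        assert planted.log_ratio > 1.5
        assert planted.q < 0.01
        assert planted.enriched_in == "altered"

    def test_null_genes_have_small_log_ratios(self):
        # group sizes and base rates chosen so the null log2-ratio sampling
        # sd stays below ~0.11, putting 0.3 beyond 2.7 sigma per gene
        rates = {f"G{i:03d}": 0.08 + 0.006 * i for i in range(20)}
        matrix, _ = gen_alteration_matrix(
            n_samples=30_000,
            gene_base_rates=rates,
            planted_odds_ratios={},
            seed=3,
        )
        rows = cooccurrence_enrichment(matrix, "EGFR")
        frac_small = (rows.log_ratio.abs() < 0.3).mean()
        assert frac_small >= 0.95

    def test_label_shuffle_gives_uniformish_p(self):
        """Permuting the index column should yield near-uniform p-values."""
        rng = np.random.default_rng(4)
        n = 2000
        calls = {"IDX": (rng.uniform(size=n) < 0.2).astype(int)}
        for i in range(200):
            calls[f"G{i:03d}"] = (rng.uniform(size=n) < 0.15).astype(int)
        m = toy_matrix(calls)
        rows = cooccurrence_enrichment(m, "IDX")
        # discrete p-values are stochastically >= uniform, so only reject
        # if they look anti-conservative
        stat = kstest(rows.p, "uniform", alternative="greater")
        assert stat.pvalue > 0.01

    def test_identical_frequency_gene(self):
        m = toy_matrix(
            {
                "IDX": [1, 1, 0, 0],
                "G": [1, 0, 1, 0],
            }
        )
        row = cooccurrence_enrichment(m, "IDX").iloc[0]
        assert row.log_ratio == 0.0
        assert row.p == 1.0

    def test_empty_group_rejected(self):
        m = toy_matrix({"IDX": [1, 1], "G": [0, 1]})
        with pytest.raises(ValueError, match="non-empty"):
            cooccurrence_enrichment(m, "IDX")


class TestWilcoxon:
    def test_identical_groups(self):
        _, p = wilcoxon_ranksum([1, 2, 3], [1, 2, 3])
        assert p > 0.9

    def test_exact_small_sample_separation(self):
        """Fully separated 3v3: two-sided exact p = 2/C(6,3) = 0.1."""
        _, p = wilcoxon_ranksum([1, 2, 3], [10, 11, 12])
        assert p == pytest.approx(2 / 20)

    def test_power_under_shift_alternative(self):
        rng = np.random.default_rng(5)
        rejected = 0
        n_sims = 200
        for _ in range(n_sims):
            a = rng.normal(0, 1, 50)
            b = rng.normal(2, 1, 50)
            _, p = wilcoxon_ranksum(a, b)
            rejected += p < 0.001
        assert rejected / n_sims >= 0.95

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_ranksum([], [1.0])


class TestMedianSplit:
    def test_even_split(self):
        s = pd.Series(range(1, 11))
        high, low = median_split(s)
        assert len(high) == len(low) == 5

    def test_all_equal_degenerate(self):
        high, low = median_split(pd.Series([2.0, 2.0, 2.0]))
        assert len(high) == 0 and len(low) == 3

    def test_median_ties_go_low(self):
        s = pd.Series({"a": 1.0, "b": 2.0, "c": 2.0, "d": 3.0})
        high, low = median_split(s)
        assert list(high) == ["d"]
        assert set(low) == {"a", "b", "c"}


class TestKaplanMeier:
    def test_hand_product_limit(self):
        records = [SurvivalRecord(t, 1) for t in (1.0, 2.0, 3.0)]
        curve = km_curve(records)
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_flat_at_one(self):
        records = [SurvivalRecord(t, 0) for t in (1.0, 2.0)]
        curve = km_curve(records)
        assert curve.survival_at(5.0) == 1.0

    def test_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(6)
        times = rng.exponential(10, 200)
        records = [SurvivalRecord(float(t), 1) for t in times]
        curve = km_curve(records)
        for t in np.quantile(times, [0.1, 0.5, 0.9]):
            empirical = (times > t).mean()
            assert curve.survival_at(t) == pytest.approx(empirical, abs=1e-12)

    def test_median_recovery_from_exponential(self):
        records, truth = gen_survival(
            n_per_group=500, baseline_rate=0.05, hazard_ratio=1.0,
            censor_rate=0.0, seed=8,
        )
        curve = km_curve([r for r in records if r.group == "low"])
        assert curve.median_survival() == pytest.approx(
            truth["median_low"], rel=0.10
        )

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        records, _ = gen_survival(n_per_group=150, censor_rate=0.02, seed=9)
        sub = [r for r in records if r.group == "high"]
        curve = km_curve(sub)
        kmf = lifelines.KaplanMeierFitter().fit(
            [r.time for r in sub], [r.event for r in sub]
        )
        for t in curve.times[:: max(1, len(curve.times) // 20)]:
            theirs = float(
                kmf.survival_function_at_times(t).iloc[0]
            )
            assert curve.survival_at(t) == pytest.approx(theirs, abs=1e-9)


class TestLogrank:
    def test_identical_groups_null(self):
        records, _ = gen_survival(n_per_group=100, hazard_ratio=1.0, seed=10)
        group = [r for r in records if r.group == "low"]
        result = logrank_test(group, list(group))
        assert result.chi2 == pytest.approx(0.0, abs=1e-9)
        assert result.hr == pytest.approx(1.0, abs=1e-9)

    def test_recovers_planted_hazard_ratio(self):
        records, _ = gen_survival(
            n_per_group=300, baseline_rate=0.03, hazard_ratio=2.0,
            censor_rate=0.0075, seed=7,
        )
        high = [r for r in records if r.group == "high"]
        low = [r for r in records if r.group == "low"]
        result = logrank_test(high, low)
        assert 1.6 <= result.hr <= 2.5
        assert result.hr_ci[0] < result.hr < result.hr_ci[1]
        assert result.p < 1e-6

    def test_no_events_rejected(self):
        a = [SurvivalRecord(1.0, 0)]
        with pytest.raises(ValueError, match="no events"):
            logrank_test(a, a)

    def test_chi2_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        from lifelines.statistics import logrank_test as ll_logrank

        records, _ = gen_survival(n_per_group=120, censor_rate=0.01, seed=12)
        high = [r for r in records if r.group == "high"]
        low = [r for r in records if r.group == "low"]
        ours = logrank_test(high, low)
        theirs = ll_logrank(
            [r.time for r in high], [r.time for r in low],
            [r.event for r in high], [r.event for r in low],
        )
        assert ours.chi2 == pytest.approx(theirs.test_statistic, rel=1e-6)
        assert ours.p == pytest.approx(theirs.p_value, rel=1e-6)
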