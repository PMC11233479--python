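"""Cohort statistics against first-principles rank arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ktmese.cohort import CohortSpec, generate_cohort
from ktmese.stats import (
    bland_altman_agreement,
    grade_trend_summary,
    kruskal_dunn,
    shapiro_wilk_gate,
    spearman,
)


class TestShapiroGate:
    def test_gaussian_quantiles_pass(self):
        q = sps.norm.ppf(np.linspace(0.01, 0.99, 50))
        w, p, is_normal = shapiro_wilk_gate(q)
        assert w > 0.99
        assert is_normal

    def test_bimodal_sample_fails_gate(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([np.zeros(50), np.full(50, 10.0)])
        vals += rng.normal(0, 0.01, 100)
        _, p, is_normal = shapiro_wilk_gate(vals)
        assert p < 0.05
        assert not is_normal

    def test_sample_size_bounds(self):
        with pytest.raises(ValueError):
            shapiro_wilk_gate([1.0, 2.0])


class TestKruskalDunn:
    def test_twelve_value_hand_oracle(self):
        """H and Dunn z from first-principles rank formulas (no ties)."""
        groups = {
            "a": np.array([1.0, 2, 3, 4]),
            "b": np.array([5.0, 6, 7, 8]),
            "c": np.array([9.0, 10, 11, 12]),
        }
        res = kruskal_dunn(groups)
        # ranks are the values themselves; mean ranks 2.5 / 6.5 / 10.5
        n, N = 4, 12
        h_oracle = 12.0 / (N * (N + 1)) * n * ((2.5 - 6.5) ** 2
                                               + 0.0 + (10.5 - 6.5) ** 2)
        assert res.h_statistic == pytest.approx(h_oracle, abs=1e-12)
        se = np.sqrt((N * (N + 1) / 12.0) * (1 / 4 + 1 / 4))
        assert res.pair("a", "b").z == pytest.approx((2.5 - 6.5) / se,
                                                     abs=1e-12)
        assert res.pair("a", "c").z == pytest.approx((2.5 - 10.5) / se,
                                                     abs=1e-12)
        p_ab = 2 * sps.norm.sf(abs((2.5 - 6.5) / se))
        assert res.pair("a", "b").p_adjusted == pytest.approx(
            min(1.0, 3 * p_ab), abs=1e-12
        )

    def test_identical_groups_are_null(self):
        g = np.arange(1.0, 11.0)
        res = kruskal_dunn({"a": g, "b": g.copy(), "c": g.copy()})
        assert res.h_statistic == pytest.approx(0.0, abs=1e-9)
        assert all(c.p_adjusted == 1.0 for c in res.pairwise)

    def test_two_groups_match_mann_whitney_asymptotic(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.8, 1, 9)
        x[3] = y[2]  # introduce a tie across groups
        res = kruskal_dunn({"x": x, "y": y})
        mw = sps.mannwhitneyu(x, y, alternative="two-sided",
                              method="asymptotic", use_continuity=False)
        assert res.p_omnibus == pytest.approx(mw.pvalue, abs=1e-9)

    def test_permutation_invariance(self, rng):
        x = rng.normal(0, 1, 8)
        y = rng.normal(1, 1, 6)
        a = kruskal_dunn({"x": x, "y": y})
        b = kruskal_dunn({"y": rng.permutation(y), "x": rng.permutation(x)})
        assert a.h_statistic == pytest.approx(b.h_statistic, abs=1e-12)
        assert a.pair("x", "y").p_adjusted == pytest.approx(
            b.pair("x", "y").p_adjusted, abs=1e-12
        )

    def test_adjusted_never_below_unadjusted_and_capped(self, rng):
        groups = {k: rng.normal(i, 1, 5) for i, k in enumerate("abcd")}
        res = kruskal_dunn(groups)
        for c in res.pairwise:
            assert c.p_adjusted >= c.p_unadjusted - 1e-15
            assert c.p_adjusted <= 1.0

    def test_small_cohort_power_prcc_vs_ro(self):
        """Two-group contrast at the emulated study's scale: lesion medians
        drawn at 51 vs 141 ms with study-scale spreads, n = (3, 7)."""
        hits = 0
        n_rep = 500
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            prcc = np.exp(rng.normal(np.log(51.0), 0.15, 3))
            ro = np.exp(rng.normal(np.log(141.0), 0.33, 7))
            res = kruskal_dunn({"pRCC": prcc, "RO": ro})
            if res.pair("pRCC", "RO").p_adjusted < 0.05:
                hits += 1
        assert hits / n_rep >= 0.80

    def test_empty_or_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_dunn({"a": np.array([1.0, 2.0]), "b": np.array([3.0])})


class TestAgreement:
    def test_identity_pairs(self):
        a = np.array([1.0, 2, 3, 4, 5])
        res = bland_altman_agreement(a, a)
        assert res.bias == 0.0
        assert res.loa_low == 0.0 and res.loa_high == 0.0
        assert res.spearman_r == 1.0

    def test_constant_offset(self):
        a = np.array([1.0, 2, 3, 4, 5])
        res = bland_altman_agreement(a, a - 5.0)
        assert res.bias == pytest.approx(5.0)
        assert res.spearman_r == 1.0

    def test_loa_bracket_bias(self, rng):
        a = rng.normal(100, 10, 30)
        b = a + rng.normal(2, 3, 30)
        res = bland_altman_agreement(a, b)
        assert res.loa_low <= res.bias <= res.loa_high

    def test_spearman_rank_arithmetic_example(self):
        """ρ by hand: b-ranks (2,1,4,3,5) → Σd² = 4 → 1 − 24/120 = 0.8."""
        rho, p = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8, abs=1e-12)

    def test_spearman_exact_permutation_small_n(self):
        rho, p = spearman([1, 2, 3, 4, 5], [1, 2, 3, 5, 4])
        # exact two-sided permutation p: count of |rho| >= 0.9 among 120
        count = 0
        from itertools import permutations

        a = np.arange(1.0, 6.0)
        for perm in permutations(a):
            r = sps.spearmanr(a, perm).statistic
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        assert p == pytest.approx(count / 120.0, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman_agreement([1.0, 2, 3], [1.0, 2])


class TestGradeTrend:
    def _records(self, grade_values):
        rows = []
        for proto in ("high_res", "bh"):
            for g, vals in grade_values.items():
                for i, v in enumerate(vals):
                    rows.append({
                        "subject_id": f"S{g}{i}", "lesion_id": f"L{g}{i}",
                        "subtype": "ccRCC", "who_isup_grade": g,
                        "protocol": proto, "median_t2_ms": v,
                        "kurtosis": 4.0, "skewness": 0.5,
                        "diameter_mm": 50.0, "n_pixels": 500,
                    })
        return pd.DataFrame(rows)

    def test_constant_grade_values_reported_exactly(self):
        df = self._records({2: [209.0] * 3, 3: [151.0] * 3, 4: [106.0] * 3})
        table, comps = grade_trend_summary(df)
        hr = table[table.protocol == "high_res"].sort_values("who_isup_grade")
        assert list(hr["median"]) == [209.0, 151.0, 106.0]
        assert list(hr["who_isup_grade"]) == [2, 3, 4]
        assert np.all(np.diff(hr["median"]) < 0)

    def test_single_grade_rejected(self):
        df = self._records({3: [150.0] * 4})
        with pytest.raises(ValueError):
            grade_trend_summary(df)

    def test_missing_metric_rejected(self):
        df = self._records({2: [209.0] * 2, 3: [151.0] * 2})
        with pytest.raises(KeyError):
            grade_trend_summary(df, metric="entropy")

    def test_generator_grade_medians_monotone_in_most_replicates(self):
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            df = generate_cohort(CohortSpec(seed=seed))
            hr = df[(df.protocol == "high_res") & df.who_isup_grade.notna()]
            gm = hr.groupby("who_isup_grade")["median_t2_ms"].median()
            if gm[2] > gm[3] > gm[4]:
                hits += 1
        assert hits / n_rep >= 0.95
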