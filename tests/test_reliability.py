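"""ICC / SEm / Sdiff / RCI, Bland-Altman, and paired comparisons.

The three-pair hand example used throughout was worked by explicit one-way
ANOVA: pairs (1,1), (2,2), (3,4) give SS_between = 6.3333 (df 2), SS_within =
0.5 (df 3), so ICC = (3.1667 - 0.1667)/3.1667 = 0.9474.
"""

import numpy as np
import pytest

from mealscope.datamodel import AOILabel, MealscopeError, RaterRow, RaterTable
from mealscope.reliability import (
    bland_altman,
    icc_oneway,
    paired_compare,
    pearson_r,
    rci_analysis,
    sd_between_sample,
)

from conftest import random_rater_table


def table_from_pairs(pairs):
    """Build a small table from raw (x1, x2) pairs, bypassing the %-sum rule
    by scaling into a single pseudo-video that sums to 100."""
    labels = list(AOILabel)
    rows = []
    s1 = sum(p[0] for p in pairs)
    s2 = sum(p[1] for p in pairs)
    for i, (a, b) in enumerate(pairs):
        rows.append(
            RaterRow(labels[i % len(labels)], "V", 100 * a / s1, 100 * b / s2)
        )
    return RaterTable(rows=rows)


def raw_table(pairs):
    """Table with raw values; skips constructor checks via __new__."""
    labels = list(AOILabel)
    t = RaterTable.__new__(RaterTable)
    t.rows = [
        RaterRow(labels[i % len(labels)], "V", float(a), float(b))
        for i, (a, b) in enumerate(pairs)
    ]
    return t


class TestICC:
    def test_identical_columns_give_icc_one(self):
        t = raw_table([(1, 1), (2, 2), (3, 3)])
        assert icc_oneway(t).icc == pytest.approx(1.0)

    def test_hand_anova_three_pairs(self):
        t = raw_table([(1, 1), (2, 2), (3, 4)])
        fit = icc_oneway(t)
        assert fit.ss_b == pytest.approx(6.33333, abs=1e-4)
        assert fit.ss_w == pytest.approx(0.5)
        assert (fit.df_b, fit.df_w) == (2, 3)
        assert fit.icc == pytest.approx((3.16667 - 0.16667) / 3.16667, abs=1e-4)

    def test_fixture_icc_near_printed_value(self, rater_fixture):
        assert icc_oneway(rater_fixture).icc == pytest.approx(0.9649, abs=5e-4)

    def test_matches_pingouin_icc1k(self, rater_fixture):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        records = []
        for i, row in enumerate(rater_fixture.rows):
            records.append({"target": i, "rater": "r1", "score": row.r1_pct})
            records.append({"target": i, "rater": "r2", "score": row.r2_pct})
        res = pg.intraclass_corr(
            pd.DataFrame(records), targets="target", raters="rater", ratings="score"
        )
        mask = res["Type"].isin(["ICC1k", "ICC(1,k)"])
        icc1k = float(res.loc[mask, "ICC"].iloc[0])
        assert icc_oneway(rater_fixture).icc == pytest.approx(icc1k, abs=1e-10)

    def test_negative_icc_reported_with_warning(self):
        t = raw_table([(1, 9), (10, 2), (3, 8), (7, 3)])
        with pytest.warns(UserWarning, match="ICC"):
            fit = icc_oneway(t)
        assert fit.icc < 0

    def test_constant_shift_invariance(self):
        rng = np.random.default_rng(0)
        t = random_rater_table(rng)
        base = icc_oneway(t).icc
        shifted = raw_table([(r.r1_pct + 7.0, r.r2_pct + 7.0) for r in t.rows])
        assert icc_oneway(shifted).icc == pytest.approx(base, abs=1e-10)

    def test_noise_on_one_rater_lowers_expected_icc(self):
        rng = np.random.default_rng(1)
        drops = 0
        n = 40
        for _ in range(n):
            t = random_rater_table(rng)
            base = icc_oneway(t).icc
            noisy = raw_table(
                [(r.r1_pct, max(r.r2_pct + rng.normal(0, 5.0), 0.01)) for r in t.rows]
            )
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if icc_oneway(noisy).icc < base:
                    drops += 1
        assert drops > 0.8 * n  # decreases in expectation


class TestSdBetween:
    def test_fixture_value(self, rater_fixture):
        assert sd_between_sample(rater_fixture) == pytest.approx(11.52, abs=0.01)

    def test_three_pair_example(self):
        t = raw_table([(1, 1), (2, 2), (3, 4)])
        assert sd_between_sample(t) == pytest.approx(np.sqrt(3.16667), abs=1e-4)

    def test_no_between_variance_is_error(self):
        t = raw_table([(5, 5), (5, 5), (5, 5)])
        with pytest.raises(MealscopeError):
            sd_between_sample(t)


class TestPearson:
    def test_identical_columns(self):
        t = raw_table([(1, 1), (2, 2), (3, 3)])
        assert pearson_r(t) == pytest.approx(1.0)

    def test_anti_ordered(self):
        t = raw_table([(1, 3), (2, 2), (3, 1)])
        assert pearson_r(t) == pytest.approx(-1.0)

    def test_fixture_against_textbook_formula(self, rater_fixture):
        x, y = rater_fixture.rater_columns()
        x, y = np.array(x), np.array(y)
        n = len(x)
        oracle = (n * np.sum(x * y) - x.sum() * y.sum()) / np.sqrt(
            (n * np.sum(x**2) - x.sum() ** 2) * (n * np.sum(y**2) - y.sum() ** 2)
        )
        assert pearson_r(rater_fixture) == pytest.approx(float(oracle), abs=1e-12)
        # rounded 1-decimal inputs land near, not at, the unrounded-data value
        assert 0.90 <= pearson_r(rater_fixture) <= 0.96

    def test_zero_variance_is_error(self):
        t = raw_table([(2, 1), (2, 2), (2, 3)])
        with pytest.raises(MealscopeError):
            pearson_r(t)


class TestRCI:
    def test_fixture_reproduces_printed_column(self, rater_fixture):
        res = rci_analysis(rater_fixture)
        assert round(res.sem, 2) == 2.16
        assert round(res.sdiff, 2) == 3.06
        by_group = {p.group: p for p in res.pairs}
        meat = by_group["meatballs:A"]
        assert meat.rci == pytest.approx(2.193, abs=5e-4)
        assert meat.significant
        rice = by_group["rice:A"]
        assert rice.rci == pytest.approx(1.113, abs=5e-4)
        assert not rice.significant
        veg_b = by_group["vegetables:B"]
        assert veg_b.rci == pytest.approx(1.473, abs=5e-4)

    def test_equal_ratings_give_zero_rci(self, rater_fixture):
        fit = icc_oneway(rater_fixture)
        res = rci_analysis(rater_fixture, sd_ref=fit.sd_b, icc=fit.icc)
        t = raw_table([(10, 10), (20, 21), (30, 29)])
        res2 = rci_analysis(t)
        assert res2.pairs[0].rci == 0.0
        assert res.sdiff > 0

    def test_swapping_raters_negates_rci(self, rater_fixture):
        res = rci_analysis(rater_fixture)
        swapped = raw_table([(r.r2_pct, r.r1_pct) for r in rater_fixture.rows])
        res_sw = rci_analysis(swapped)
        for p, q in zip(res.pairs, res_sw.pairs):
            assert q.rci == pytest.approx(-p.rci, abs=1e-10)

    def test_sem_equals_sd_within_identity(self):
        """SEm = SD_w algebraically when SD_ref = SD_b and ICC is the one-way
        SS-method value; checked numerically on random tables."""
        rng = np.random.default_rng(2)
        for _ in range(200):
            t = random_rater_table(rng, k=int(rng.integers(3, 9)))
            fit = icc_oneway(t)
            if fit.icc < 0:
                continue
            res = rci_analysis(t)
            assert res.sem == pytest.approx(fit.sd_w, rel=1e-9)

    def test_icc_above_one_is_error(self, rater_fixture):
        with pytest.raises(MealscopeError):
            rci_analysis(rater_fixture, sd_ref=1.0, icc=1.5)


class TestBlandAltman:
    def test_zero_differences(self):
        x = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(x, x)
        assert ba.mean_diff == 0 and ba.loa_lo == 0 and ba.loa_hi == 0

    def test_loa_cover_95pct_of_normal_differences(self):
        rng = np.random.default_rng(12)
        d = rng.standard_normal(10_000)
        ba = bland_altman(d, np.zeros_like(d))
        inside = np.mean((d >= ba.loa_lo) & (d <= ba.loa_hi))
        assert inside == pytest.approx(0.95, abs=0.01)

    def test_non_normal_differences_flag_loa_not_applicable(self):
        rng = np.random.default_rng(3)
        d = rng.exponential(1.0, 200) ** 3
        ba = bland_altman(d, np.zeros_like(d))
        assert not ba.loa_applicable

    def test_loa_ordering_invariant(self):
        rng = np.random.default_rng(4)
        x = rng.normal(10, 2, 30)
        y = rng.normal(10, 2, 30)
        ba = bland_altman(x, y)
        assert ba.loa_lo <= ba.mean_diff <= ba.loa_hi

    def test_too_few_pairs_is_error(self):
        with pytest.raises(MealscopeError):
            bland_altman([1.0, 2.0], [1.0, 2.0])


class TestPairedCompare:
    def test_equal_inputs_degenerate_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_compare(x, x)
        assert res.p_value == 1.0
        assert res.test == "degenerate"

    def test_normal_shift_detected_with_t(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 30)
        y = x + 1.0 + rng.normal(0, 0.01, 30)
        res = paired_compare(y, x)
        assert res.test == "t"
        assert res.p_value < 1e-6

    def test_skewed_differences_use_wilcoxon(self):
        rng = np.random.default_rng(6)
        x = rng.exponential(1.0, 50) ** 2
        y = np.zeros(50)
        res = paired_compare(x, y)
        assert res.test == "wilcoxon"

    def test_power_against_unit_shift(self):
        """Paired t at n=30, delta=1, sigma=1 has power > 0.99; seeded
        replicates should essentially always reject at alpha = 0.05."""
        rng = np.random.default_rng(7)
        rejections = 0
        trials = 40
        for _ in range(trials):
            x = rng.normal(0, 1, 30)
            y = x + 1.0 + rng.normal(0, 1, 30)
            res = paired_compare(y, x)
            rejections += res.p_value < 0.05
        assert rejections >= trials - 1
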