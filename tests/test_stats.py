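"""Statistics layer against independently computed reference values.

Reference W/p/r/t values were computed with R 4.3.3 (shapiro.test,
cor.test, t.test) and are frozen here.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from vasomet.stats import compare, correlate, normality_gate, summarise


def tidy(rows):
    return pd.DataFrame(rows)


def make_table(values_by_group_window, variable="v"):
    rows = []
    for (grp, win), vals in values_by_group_window.items():
        for i, v in enumerate(vals):
            rows.append({"subject": f"{grp}{i}", "group": grp, "window": win, variable: v})
    return tidy(rows)


class TestNormalityGate:
    def test_matches_reference_shapiro(self):
        df = tidy(
            [{"subject": str(i), "group": "g", "window": "baseline", "v": x}
             for i, x in enumerate([2.1, 2.2, 2.0, 2.3, 2.15])]
        )
        res = normality_gate(df)[0]
        assert res.W == pytest.approx(0.9992933591, abs=1e-6)
        assert res.p == pytest.approx(0.9998029362, abs=1e-6)
        assert not res.non_normal

    def test_bimodal_flagged(self):
        vals = [0.0] * 10 + [10.0] * 10
        df = tidy(
            [{"subject": str(i), "group": "g", "window": "baseline", "v": x}
             for i, x in enumerate(vals)]
        )
        res = normality_gate(df)[0]
        assert res.W == pytest.approx(0.6411192275, abs=1e-6)
        assert res.p < 0.05 and res.non_normal

    def test_constant_vector_untestable(self):
        df = tidy(
            [{"subject": str(i), "group": "g", "window": "baseline", "v": 3.0}
             for i in range(6)]
        )
        assert normality_gate(df)[0].untestable


class TestCompare:
    def test_paired_matches_reference(self):
        a = [5.1, 4.9, 6.2, 5.8, 5.5]
        b = [4.8, 5.0, 5.9, 5.2, 5.1]
        rows = []
        for i, (x, y) in enumerate(zip(a, b)):
            rows.append({"subject": f"s{i}", "group": "g", "window": "baseline", "v": x})
            rows.append({"subject": f"s{i}", "group": "g", "window": "pe", "v": y})
        res = compare(tidy(rows), "v", "within", group="g")
        assert res.t == pytest.approx(2.631174057921, abs=1e-6)
        assert res.p == pytest.approx(0.058114697934, abs=1e-6)
        assert not res.significant

    def test_unpaired_matches_reference(self):
        df = make_table({
            ("A", "baseline"): [1.2, 1.5, 1.1, 1.9, 1.4],
            ("B", "baseline"): [2.0, 2.4, 1.8, 2.6, 2.1, 2.3],
        })
        res = compare(df, "v", "between", window="baseline")
        assert res.t == pytest.approx(-4.299069457431, abs=1e-6)
        assert res.p == pytest.approx(0.001993370541, abs=1e-6)
        assert res.significant

    def test_symmetric_paired_differences_not_significant(self):
        base = [3.0, 1.0, 3.0, 1.0]
        pe = [2.0, 2.0, 2.0, 2.0]
        rows = []
        for i, (x, y) in enumerate(zip(base, pe)):
            rows.append({"subject": f"s{i}", "group": "g", "window": "baseline", "v": x})
            rows.append({"subject": f"s{i}", "group": "g", "window": "pe", "v": y})
        res = compare(tidy(rows), "v", "within", group="g")
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-9)

    def test_identical_groups_give_t_zero(self):
        df = make_table({
            ("A", "baseline"): [1.0, 2.0, 3.0],
            ("B", "baseline"): [1.0, 2.0, 3.0],
        })
        res = compare(df, "v", "between", window="baseline")
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-9)

    def test_paired_self_comparison_degenerate_not_significant(self):
        rows = []
        for i, x in enumerate([1.4, 2.0, 0.9, 3.1]):
            rows.append({"subject": f"s{i}", "group": "g", "window": "baseline", "v": x})
            rows.append({"subject": f"s{i}", "group": "g", "window": "pe", "v": x})
        res = compare(tidy(rows), "v", "within", group="g")
        assert res.t == 0.0 and not res.significant

    def test_mismatched_pairing_rejected(self):
        rows = [
            {"subject": "s0", "group": "g", "window": "baseline", "v": 1.0},
            {"subject": "s1", "group": "g", "window": "baseline", "v": 2.0},
            {"subject": "s0", "group": "g", "window": "pe", "v": 1.5},
        ]
        with pytest.raises(ValueError, match="matched"):
            compare(tidy(rows), "v", "within", group="g")

    def test_welch_option_differs_under_unequal_variance(self):
        df = make_table({
            ("A", "baseline"): [1.0, 1.1, 0.9, 1.05, 0.95],
            ("B", "baseline"): [2.0, 5.0, -1.0, 4.0, 0.5, 3.5],
        })
        student = compare(df, "v", "between", window="baseline", equal_var=True)
        welch = compare(df, "v", "between", window="baseline", equal_var=False)
        assert student.p != pytest.approx(welch.p, rel=1e-3)


class TestCorrelate:
    @staticmethod
    def df_from_xy(x, y):
        rows = []
        for i, (a, b) in enumerate(zip(x, y)):
            rows.append({"subject": f"s{i}", "group": "g", "window": "baseline",
                         "x": a, "y": b})
        return tidy(rows)

    def test_hand_fixture_matches_direct_formula(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 6])
        res = correlate(self.df_from_xy(x, y), "x", "y", subgroup="baseline")
        r_hand = np.sum((x - x.mean()) * (y - y.mean())) / (
            np.sqrt(np.sum((x - x.mean()) ** 2)) * np.sqrt(np.sum((y - y.mean()) ** 2))
        )
        assert res.r == pytest.approx(r_hand, abs=1e-9)
        assert res.r == pytest.approx(0.821994936527, abs=1e-9)  # R cor.test
        assert res.p == pytest.approx(0.087706647008, abs=1e-6)
        assert not res.relevant  # |r| > 0.5 but p > 0.05

    def test_exact_line_gives_unit_correlation(self):
        x = np.arange(1.0, 8.0)
        res = correlate(self.df_from_xy(x, 2 * x + 1), "x", "y", subgroup="baseline")
        assert res.r == pytest.approx(1.0)
        assert res.relevant

    def test_negative_slope_gives_minus_one(self):
        x = np.arange(1.0, 8.0)
        res = correlate(self.df_from_xy(x, -x), "x", "y", subgroup="baseline")
        assert res.r == pytest.approx(-1.0)
        assert res.relevant

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=12)
        y = 0.5 * x + rng.normal(size=12)
        df = self.df_from_xy(x, y)
        r_xy = correlate(df, "x", "y", subgroup="baseline").r
        r_yx = correlate(df, "y", "x", subgroup="baseline").r
        assert r_xy == pytest.approx(r_yx, abs=1e-12)
        df2 = self.df_from_xy(3.0 * x + 2.0, y)
        assert correlate(df2, "x", "y", subgroup="baseline").r == pytest.approx(r_xy, abs=1e-12)
        df3 = self.df_from_xy(-3.0 * x, y)
        assert correlate(df3, "x", "y", subgroup="baseline").r == pytest.approx(-r_xy, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            correlate(self.df_from_xy(np.ones(5), np.arange(5.0)), "x", "y",
                      subgroup="baseline")

    def test_pooled_concatenates_windows(self):
        rows = []
        for i in range(4):
            rows.append({"subject": f"s{i}", "group": "g", "window": "baseline",
                         "x": float(i), "y": float(i)})
            rows.append({"subject": f"s{i}", "group": "g", "window": "pe",
                         "x": float(i) + 0.5, "y": float(i) + 0.5})
        res = correlate(tidy(rows), "x", "y", subgroup="pooled")
        assert res.n == 8


class TestSummarise:
    def test_two_identical_subjects_sd_zero(self):
        df = make_table({("A", "baseline"): [2.0, 2.0]})
        out = summarise(df)
        assert out.loc["v", ("A", "baseline", "mean")] == 2.0
        assert out.loc["v", ("A", "baseline", "sd")] == 0.0

    def test_single_subject_sd_missing(self):
        df = make_table({("A", "baseline"): [2.0]})
        out = summarise(df)
        assert np.isnan(out.loc["v", ("A", "baseline", "sd")])


class TestPower:
    def test_unpaired_test_detects_1p5_sd_difference_in_majority_of_studies(self):
        # direct-draw power check: effect 1.5 pooled SD, n = 5 vs 6
        rng = np.random.default_rng(2024)
        hits = 0
        n_studies = 50
        for _ in range(n_studies):
            a = rng.normal(0.0, 1.0, 5)
            b = rng.normal(1.5, 1.0, 6)
            _, p = sps.ttest_ind(a, b, equal_var=True)
            hits += p < 0.05
        assert hits > n_studies / 2
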