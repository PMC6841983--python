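import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from retimorph import anova_oneway, anova_twoway, compact_letter_display, region_ttest
from retimorph.errors import DesignError


def records(region_values=None, group_values=None, metric="db"):
    rows = []
    if region_values:
        for region, vals in region_values.items():
            for v in vals:
                rows.append({"region": region, "group": "H", metric: v})
    if group_values:
        for group, vals in group_values.items():
            for v in vals:
                rows.append({"region": "whole", "group": group, metric: v})
    return pd.DataFrame(rows)


class TestRegionTtest:
    def test_identical_samples_give_t0_p1(self):
        df = records(region_values={"macula": [1.0, 1.0, 1.0], "optic_disc": [1.0, 1.0, 1.0]})
        res = region_ttest(df, "db")
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_pooled_variance_closed_form(self):
        df = records(region_values={"macula": [1, 2, 3], "optic_disc": [4, 5, 6]})
        res = region_ttest(df, "db")
        # pooled s^2 = 1, se = sqrt(2/3), t = -3/se, df = 4
        t_expected = -3.0 / np.sqrt(2.0 / 3.0)
        p_expected = 2 * sps.t.sf(abs(t_expected), 4)
        assert res.statistic == pytest.approx(t_expected, abs=1e-3)  # -3.674
        assert res.p_value == pytest.approx(p_expected, abs=1e-4)  # ~0.0214
        assert res.means["macula"] == 2.0 and res.ns["optic_disc"] == 3

    def test_welch_option_differs_under_heteroscedasticity(self):
        df = records(
            region_values={"macula": [1.0, 1.1, 0.9, 1.0], "optic_disc": [2.0, 8.0, -3.0, 5.0]}
        )
        student = region_ttest(df, "db", equal_var=True)
        welch = region_ttest(df, "db", equal_var=False)
        assert student.p_value != welch.p_value

    def test_single_level_rejected(self):
        df = records(region_values={"macula": [1, 2, 3]})
        with pytest.raises(DesignError):
            region_ttest(df, "db")


class TestAnovaOneway:
    def test_identical_constant_groups(self):
        df = records(group_values={g: [2.0] * 4 for g in ("H", "G", "DR")})
        res = anova_oneway(df, "db")
        assert res.statistic == 0.0 and res.p_value == 1.0
        assert len(set(res.letters.values())) == 1

    def test_separated_constant_group_gets_distinct_letter(self):
        df = records(group_values={"H": [0, 0, 0, 0], "G": [0, 0, 0, 0], "DR": [10, 10, 10, 10]})
        res = anova_oneway(df, "db")
        assert np.isinf(res.statistic) and res.p_value == 0.0
        assert res.letters["DR"] not in (res.letters["H"], res.letters["G"])
        assert res.letters["H"] == res.letters["G"]

    def test_f_matches_textbook_decomposition(self):
        groups = {"H": [1, 2, 3], "G": [2, 3, 4], "DR": [6, 7, 8]}
        df = records(group_values=groups)
        res = anova_oneway(df, "db")
        all_vals = np.concatenate(list(groups.values()))
        ss_between = sum(
            len(v) * (np.mean(v) - all_vals.mean()) ** 2 for v in groups.values()
        )
        ss_within = sum(np.sum((np.array(v) - np.mean(v)) ** 2) for v in groups.values())
        f_expected = (ss_between / 2) / (ss_within / 6)
        assert res.statistic == pytest.approx(f_expected)
        assert res.p_value == pytest.approx(sps.f.sf(f_expected, 2, 6))

    def test_tukey_adjusted_p_not_below_raw_p(self, rng):
        for _ in range(5):
            df = records(
                group_values={g: rng.normal(i * 0.3, 1, 8) for i, g in enumerate(("H", "G", "DR"))}
            )
            res = anova_oneway(df, "db")
            for pair in res.posthoc:
                a = df[(df["group"] == pair.a)]["db"]
                b = df[(df["group"] == pair.b)]["db"]
                _, raw_p = sps.ttest_ind(a, b)
                assert pair.p_adj >= raw_p - 1e-9


class TestAnovaTwoway:
    @staticmethod
    def layout(cell_means, n=4, sigma=1.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for (region, group), mu in cell_means.items():
            for _ in range(n):
                rows.append(
                    {"region": region, "group": group, "db": mu + sigma * rng.normal()}
                )
        return pd.DataFrame(rows)

    def test_identical_cells_share_one_letter(self):
        cells = {(r, g): 0.0 for r in ("macula", "optic_disc") for g in ("H", "G", "DR")}
        df = self.layout(cells, sigma=0.0)
        res = anova_twoway(df, "db")
        assert all(f == 0.0 and p == 1.0 for f, p in res.effects.values())
        assert len(set(res.letters.values())) == 1

    def test_single_shifted_cell_gets_distinct_letter(self):
        cells = {(r, g): 0.0 for r in ("macula", "optic_disc") for g in ("H", "G", "DR")}
        cells[("macula", "DR")] = 10.0  # 10 SDs with sigma=1
        df = self.layout(cells, n=5, sigma=1.0, seed=3)
        res = anova_twoway(df, "db")
        shifted = res.letters["macula:DR"]
        others = {v for k, v in res.letters.items() if k != "macula:DR"}
        assert all(shifted != o for o in others)
        # oracle: all-pairs Welch tests confirm only the shifted cell separates
        cell = df["region"] + ":" + df["group"]
        for level in res.letters:
            a = df.loc[cell == "macula:DR", "db"]
            b = df.loc[cell == level, "db"]
            if level != "macula:DR":
                assert sps.ttest_ind(a, b, equal_var=False).pvalue < 0.01

    def test_f_matches_balanced_decomposition(self):
        cells = {
            ("macula", "H"): 1.0,
            ("macula", "DR"): 2.0,
            ("optic_disc", "H"): 3.0,
            ("optic_disc", "DR"): 5.0,
        }
        df = self.layout(cells, n=6, sigma=1.0, seed=11)
        res = anova_twoway(df, "db")
        y = df["db"].to_numpy()
        grand = y.mean()
        regions, groups = sorted(df["region"].unique()), sorted(df["group"].unique())
        n = 6
        ss_region = sum(
            n * len(groups) * (df[df["region"] == r]["db"].mean() - grand) ** 2 for r in regions
        )
        ss_group = sum(
            n * len(regions) * (df[df["group"] == g]["db"].mean() - grand) ** 2 for g in groups
        )
        cell_means = df.groupby(["region", "group"])["db"].mean()
        ss_cells = sum(n * (m - grand) ** 2 for m in cell_means)
        ss_inter = ss_cells - ss_region - ss_group
        ss_err = sum(
            ((df[(df["region"] == r) & (df["group"] == g)]["db"] - cell_means[(r, g)]) ** 2).sum()
            for r in regions
            for g in groups
        )
        df_err = len(y) - len(regions) * len(groups)
        f_inter = (ss_inter / 1) / (ss_err / df_err)
        assert res.effects["interaction"][0] == pytest.approx(f_inter)
        f_region = (ss_region / 1) / (ss_err / df_err)
        assert res.effects["region"][0] == pytest.approx(f_region)

    def test_missing_cell_rejected(self):
        cells = {("macula", "H"): 0.0, ("optic_disc", "H"): 0.0, ("macula", "DR"): 0.0}
        df = self.layout(cells)
        with pytest.raises(DesignError):
            anova_twoway(df, "db")


class TestCompactLetterDisplay:
    def test_deterministic_function_of_matrix(self):
        levels = ["a1", "a2", "a3", "a4"]
        means = {"a1": 4.0, "a2": 3.0, "a3": 2.0, "a4": 1.0}
        sig = {frozenset(("a1", "a4")), frozenset(("a1", "a3"))}
        first = compact_letter_display(levels, means, sig)
        second = compact_letter_display(list(reversed(levels)), dict(means), set(sig))
        assert first == second

    def test_shared_letter_iff_not_significant(self):
        levels = ["hi", "mid", "lo"]
        means = {"hi": 3.0, "mid": 2.0, "lo": 1.0}
        sig = {frozenset(("hi", "lo"))}
        letters = compact_letter_display(levels, means, sig)
        assert set(letters["hi"]) & set(letters["mid"])
        assert set(letters["mid"]) & set(letters["lo"])
        assert not set(letters["hi"]) & set(letters["lo"])

    def test_all_distinct(self):
        levels = ["x", "y", "z"]
        means = {"x": 3.0, "y": 2.0, "z": 1.0}
        sig = {frozenset(p) for p in (("x", "y"), ("y", "z"), ("x", "z"))}
        letters = compact_letter_display(levels, means, sig)
        assert len({letters[lv] for lv in levels}) == 3
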