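import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from cardioresp.stats import (
    choose_omnibus,
    frequency_analysis,
    frequency_table,
    friedman_with_wilcoxon_posthoc,
    is_normal,
    kruskal_with_ranksum_posthoc,
    normality_and_sphericity,
    rm_anova_gg,
    two_way_anova_trials,
)

from .oracles import friedman_bruteforce


def wide_df(arr, cols=None):
    arr = np.asarray(arr, dtype=float)
    cols = cols or [f"c{i}" for i in range(arr.shape[1])]
    df = pd.DataFrame(arr, columns=cols)
    df.index.name = "subject"
    return df


class TestNormalityAndSphericity:
    def test_shapiro_type_i_calibrated(self):
        rng = np.random.default_rng(0)
        rej = sum(sst.shapiro(rng.normal(size=36)).pvalue < 0.05 for _ in range(1000))
        assert 0.03 <= rej / 1000 <= 0.07

    def test_shapiro_rejects_lognormal(self):
        rng = np.random.default_rng(1)
        rej = sum(sst.shapiro(rng.lognormal(0, 1, 36)).pvalue < 0.05 for _ in range(200))
        assert rej / 200 > 0.5

    def test_spherical_data_epsilon_near_one(self):
        rng = np.random.default_rng(2)
        res = normality_and_sphericity(wide_df(rng.normal(size=(300, 3))))
        mauchly = [r for r in res if r.name == "mauchly"][0]
        assert mauchly.p_value > 0.01  # no evidence against sphericity

    def test_constant_column_flagged(self):
        res = normality_and_sphericity(wide_df(np.ones((10, 1))))
        assert "constant" in res[0].notes

    def test_branching_helper(self):
        rng = np.random.default_rng(3)
        assert is_normal(wide_df(rng.normal(size=(36, 3))))
        heavy = wide_df(rng.lognormal(0, 1.5, size=(36, 3)))
        assert not is_normal(heavy)
        assert choose_omnibus(heavy).name == "friedman"


class TestFriedman:
    def test_identical_columns_null_result(self):
        x = np.tile(np.arange(10.0)[:, None], (1, 3))
        res = friedman_with_wilcoxon_posthoc(wide_df(x))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_bruteforce_ranking(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            m = rng.normal(size=(8, 3))
            res = friedman_with_wilcoxon_posthoc(wide_df(m))
            assert res.statistic == pytest.approx(friedman_bruteforce(m), rel=1e-9)

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(5)
        rej = 0
        for _ in range(1000):
            m = rng.normal(size=(36, 3))
            stat, p = sst.friedmanchisquare(m[:, 0], m[:, 1], m[:, 2])
            rej += p < 0.05
        assert 0.03 <= rej / 1000 <= 0.07

    def test_posthoc_family_and_bonferroni(self):
        rng = np.random.default_rng(6)
        m = rng.normal(size=(30, 4))
        m[:, 3] += 2.0  # strong effect so the omnibus fires
        res = friedman_with_wilcoxon_posthoc(wide_df(m))
        assert len(res.posthoc) == 6  # k(k-1)/2
        for ph in res.posthoc:
            assert 0.0 <= ph["p_bonf"] <= 1.0
            assert ph["p_bonf"] == pytest.approx(min(1.0, 6 * ph["p_raw"]))

    def test_two_conditions_fall_back_to_wilcoxon(self):
        rng = np.random.default_rng(7)
        res = friedman_with_wilcoxon_posthoc(wide_df(rng.normal(size=(20, 2))))
        assert res.name == "wilcoxon"


class TestRmAnova:
    def test_identical_columns_f_zero(self):
        x = np.tile(np.arange(12.0)[:, None], (1, 3))
        res = rm_anova_gg(wide_df(x))
        assert res.statistic == 0.0

    def test_two_condition_f_equals_squared_paired_t(self):
        rng = np.random.default_rng(8)
        m = rng.normal(size=(25, 2))
        m[:, 1] += 0.5
        res = rm_anova_gg(wide_df(m))
        t, _ = sst.ttest_rel(m[:, 0], m[:, 1])
        assert res.statistic == pytest.approx(t**2, rel=1e-6)

    def test_null_type_i_with_gg_within_bounds(self):
        rng = np.random.default_rng(9)
        rej = 0
        n_rep = 400
        for _ in range(n_rep):
            res = rm_anova_gg(wide_df(rng.normal(size=(20, 4))))
            rej += res.p_value < 0.05
        assert rej / n_rep <= 0.075

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(10)
        m = rng.normal(size=(20, 3))
        res1 = rm_anova_gg(wide_df(m))
        res2 = rm_anova_gg(wide_df(m[rng.permutation(20)]))
        assert res1.statistic == pytest.approx(res2.statistic)
        assert res1.p_value == pytest.approx(res2.p_value)


class TestTwoWayAnova:
    @staticmethod
    def design(values_by_cell):
        z, a, b = [], [], []
        for (fa, fb), vals in values_by_cell.items():
            for v in vals:
                z.append(v)
                a.append(fa)
                b.append(fb)
        return pd.Series(z, dtype=float), pd.Series(a), pd.Series(b)

    def test_constant_response_gives_zero_f(self):
        z, a, b = self.design({(x, y): [1.0, 1.0] for x in "01" for y in "01"})
        ra, rb = two_way_anova_trials(z, a, b)
        assert ra.statistic == 0.0 and rb.statistic == 0.0

    def test_balanced_shift_matches_closed_form(self):
        # cells of size 2 with residuals +-1; shift d on factor A
        d = 3.0
        cells = {("lo", "x"): [-1.0, 1.0], ("lo", "y"): [-1.0, 1.0],
                 ("hi", "x"): [d - 1.0, d + 1.0], ("hi", "y"): [d - 1.0, d + 1.0]}
        z, a, b = self.design(cells)
        ra, rb = two_way_anova_trials(z, a, b)
        # SSA = N d^2/4 = 2 d^2, MSE = 8/4 = 2  =>  F_A = d^2
        assert ra.statistic == pytest.approx(d**2, rel=1e-9)
        assert rb.statistic == pytest.approx(0.0, abs=1e-9)

    def test_null_type_i_per_factor(self):
        rng = np.random.default_rng(11)
        rej_a = rej_b = 0
        n_rep = 300
        for _ in range(n_rep):
            z = pd.Series(rng.normal(size=40))
            a = pd.Series(np.repeat(["0", "1"], 20))
            b = pd.Series(np.tile(np.repeat(["0", "1"], 10), 2))
            ra, rb = two_way_anova_trials(z, a, b)
            rej_a += ra.p_value < 0.05
            rej_b += rb.p_value < 0.05
        assert 0.02 <= rej_a / n_rep <= 0.09
        assert 0.02 <= rej_b / n_rep <= 0.09

    def test_empty_cell_refused(self):
        z, a, b = self.design({("0", "0"): [1.0], ("0", "1"): [2.0], ("1", "0"): [3.0]})
        with pytest.raises(ValueError):
            two_way_anova_trials(z, a, b)

    def test_pooled_sd_posthoc_count(self):
        rng = np.random.default_rng(12)
        z, a, b = self.design({(x, y): rng.normal(size=10).tolist()
                               for x in "01" for y in "01"})
        ra, _ = two_way_anova_trials(z, a, b)
        assert len(ra.posthoc) == 6


class TestKruskal:
    def test_posthoc_on_clear_separation(self):
        rng = np.random.default_rng(13)
        vals = np.concatenate([rng.normal(0, 1, 20), rng.normal(4, 1, 20)])
        groups = np.repeat(["a", "b"], 20)
        res = kruskal_with_ranksum_posthoc(pd.Series(vals), pd.Series(groups))
        assert res.p_value < 0.001
        assert res.posthoc and res.posthoc[0]["p_bonf"] <= 1.0


class TestFrequency:
    def make_trials(self):
        # 1 subject, hand-countable layout
        rows = []
        layout = [
            ("IEt", "none", "1st", "high_pos"),
            ("IEt", "none", "1st", "low_pos"),
            ("IEt", "none", "2nd", "high_pos"),
            ("EIt", "1st", "none", "low_neg"),
            ("EIt", "2nd", "none", "high_neg"),
            ("EIt", "2nd", "none", "high_pos"),
        ]
        for i, (cond, eih, ieh, b) in enumerate(layout):
            rows.append(dict(subject=1, block=1, trial=i, condition=cond,
                             eit_half=eih, iet_half=ieh, delta_rri_bin=b,
                             correct=True, rt_robust_z=0.0, rt_s=1.0))
        return pd.DataFrame(rows)

    def test_hand_counted_rates(self):
        by_half, by_bin = frequency_table(self.make_trials())
        rates = by_half.set_index("condition")["rate"]
        assert rates["IEt-1st"] == pytest.approx(0.5)   # 1 of 2 high_pos
        assert rates["IEt-2nd"] == pytest.approx(1.0)
        assert rates["EIt-1st"] == pytest.approx(0.0)
        assert rates["EIt-2nd"] == pytest.approx(0.5)
        bin_rates = by_bin.set_index("condition")["rate"]
        assert bin_rates["high_neg"] == pytest.approx(1.0)  # the one high_neg is EIt-2nd
        assert bin_rates["high_pos"] == pytest.approx(1.0 / 3.0)

    def test_all_high_pos_rates_one(self):
        t = self.make_trials()
        t["delta_rri_bin"] = "high_pos"
        by_half, _ = frequency_table(t)
        assert (by_half["rate"] == 1.0).all()

    def test_denominators_recorded(self):
        by_half, by_bin = frequency_table(self.make_trials())
        assert by_half["n"].sum() == 6
        assert by_bin["n"].sum() == 6

    def test_cohort_analysis_runs(self, cohort_trials):
        out = frequency_analysis(cohort_trials)
        assert set(out) >= {"by_half", "by_bin", "test_by_half", "test_by_bin"}
        assert ((out["by_half"]["rate"] >= 0) & (out["by_half"]["rate"] <= 1)).all()
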