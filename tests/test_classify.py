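import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cardioresp.classify import (
    bin_delta_rri,
    build_trial_table,
    classify_trial,
    compute_delta_rri,
    compute_delta_rri_b,
    condition_means,
    half_condition,
    robust_z_rt,
)
from cardioresp.signals import PhaseSeries, RRISeries

from .oracles import (
    bin_bruteforce,
    classify_bruteforce,
    delta_rri_b_bruteforce,
    delta_rri_bruteforce,
    robust_z_bruteforce,
)


def random_phases(rng, n_cycles=40, start=0.0):
    periods = rng.uniform(2.0, 6.0, n_cycles)
    ei = start + np.concatenate([[0.0], np.cumsum(periods)])
    ie = ei[:-1] + rng.uniform(0.25, 0.7, n_cycles) * periods
    return PhaseSeries(ei, ie)


class TestClassifyTrial:
    def test_wholly_within_exhalation(self):
        ph = PhaseSeries([0.0, 4.0], [1.6])
        cond, eih, ieh = classify_trial(2.0, 3.0, ph)
        assert (cond, eih, ieh) == ("EXH", "none", "none")

    def test_ei_in_second_half(self):
        ph = PhaseSeries([0.0, 10.7], [1.6])
        cond, eih, ieh = classify_trial(10.0, 11.0, ph)
        assert cond == "EIt" and eih == "2nd" and ieh == "none"

    def test_midpoint_transition_counts_as_second(self):
        ph = PhaseSeries([0.0, 10.5], [1.6])
        cond, eih, _ = classify_trial(10.0, 11.0, ph)
        assert cond == "EIt" and eih == "2nd"

    def test_transition_at_cue_or_press_excluded(self):
        ph = PhaseSeries([0.0, 10.0], [1.6, 11.0])
        cond, _, _ = classify_trial(10.0, 11.0, ph)  # EI at cue, IE at press
        assert cond == "INH"  # open interval contains neither

    def test_uncovered_trial_raises(self):
        ph = PhaseSeries([10.0, 14.0], [11.6])
        with pytest.raises(ValueError):
            classify_trial(9.0, 10.5, ph)  # cue before first transition

    def test_press_after_last_transition_allowed(self):
        ph = PhaseSeries([0.0, 4.0], [1.6])
        cond, _, _ = classify_trial(4.5, 5.5, ph)  # trailing inhalation continues
        assert cond == "INH"

    def test_agrees_with_bruteforce_on_random_trials(self):
        rng = np.random.default_rng(42)
        n_checked = 0
        for _ in range(40):
            ph = random_phases(rng)
            lo, hi = ph.span()
            for _ in range(50):
                cue = rng.uniform(lo, hi - 5.0)
                press = cue + rng.uniform(0.2, 4.0)
                got = classify_trial(cue, press, ph)
                want = classify_bruteforce(cue, press, ph.ei_times.tolist(),
                                           ph.ie_times.tolist())
                assert got == want
                n_checked += 1
        assert n_checked == 2000


class TestDeltaRri:
    def test_same_interval_is_zero(self):
        s = RRISeries(np.array([0.0, 0.85, 1.7]))
        assert compute_delta_rri(0.9, 1.2, s) == 0.0

    def test_direct_subtraction(self):
        s = RRISeries(np.array([0.0, 0.80, 1.80]))  # RRIs 0.8 then 1.0
        assert compute_delta_rri(0.5, 1.2, s) == pytest.approx(0.20)

    def test_uncovered_event_is_missing(self):
        s = RRISeries(np.array([0.0, 0.85, 1.7]))
        assert np.isnan(compute_delta_rri(0.5, 2.5, s))

    @given(st.integers(0, 10_000))
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        r = np.cumsum(rng.uniform(0.5, 1.3, 30))
        s = RRISeries(r)
        a, b = sorted(rng.uniform(r[0] + 1e-6, r[-1], 2))
        assert compute_delta_rri(a, b, s) == pytest.approx(
            -compute_delta_rri(b, a, s), nan_ok=True
        )

    def test_matches_generator_truth_elementwise(self, one_subject):
        rri = RRISeries(one_subject.r_times)
        truth = pd.DataFrame(one_subject.truth["trials"])
        ev = one_subject.events
        got = [compute_delta_rri(c, p, rri)
               for c, p in zip(ev["cue_time_s"], ev["press_time_s"])]
        np.testing.assert_allclose(got, truth["delta_rri"], atol=1e-12)

    def test_matches_bruteforce(self, one_subject):
        rri = RRISeries(one_subject.r_times)
        r_list = one_subject.r_times.tolist()
        rng = np.random.default_rng(9)
        for _ in range(500):
            cue = rng.uniform(r_list[0] + 0.1, r_list[-1] - 5.0)
            press = cue + rng.uniform(0.2, 4.0)
            got = compute_delta_rri(cue, press, rri)
            want = delta_rri_bruteforce(cue, press, r_list)
            assert got == pytest.approx(want, nan_ok=True)


class TestDeltaRriB:
    def test_stationary_rris_give_zero(self):
        s = RRISeries(np.arange(0.0, 10.0, 0.85))
        assert compute_delta_rri_b(3.0, 3.5, s) == pytest.approx(0.0)

    def test_direct_subtraction(self):
        s = RRISeries(np.array([0.0, 0.80, 1.75, 2.75]))  # RRIs .8, .95, 1.0
        # cue at 1.0: last complete interval before it is (0, 0.8] -> 0.8
        # press at 2.0: owning interval (1.75, 2.75] -> 1.0
        assert compute_delta_rri_b(1.0, 2.0, s) == pytest.approx(0.20)

    def test_no_prior_interval_is_missing(self):
        s = RRISeries(np.array([0.0, 0.85, 1.7]))
        assert np.isnan(compute_delta_rri_b(0.5, 1.0, s))

    def test_matches_bruteforce(self, one_subject):
        rri = RRISeries(one_subject.r_times)
        r_list = one_subject.r_times.tolist()
        rng = np.random.default_rng(10)
        for _ in range(500):
            cue = rng.uniform(r_list[0] + 2.0, r_list[-1] - 5.0)
            press = cue + rng.uniform(0.2, 4.0)
            assert compute_delta_rri_b(cue, press, rri) == pytest.approx(
                delta_rri_b_bruteforce(cue, press, r_list), nan_ok=True
            )


class TestBinDeltaRri:
    def test_worked_example(self):
        bins = bin_delta_rri(pd.Series([0.2, 0.08, -0.1]))
        assert list(bins) == ["high_pos", "low_pos", "high_neg"]

    def test_single_positive_is_its_own_maximum(self):
        assert list(bin_delta_rri(pd.Series([0.05]))) == ["high_pos"]

    def test_boundary_ratio_goes_high(self):
        bins = bin_delta_rri(pd.Series([0.2, 0.1]))  # ratio exactly 0.5
        assert list(bins) == ["high_pos", "high_pos"]

    def test_zero_goes_low_pos(self):
        assert list(bin_delta_rri(pd.Series([0.0, -0.1]))) == ["low_pos", "high_neg"]

    @given(st.integers(0, 10_000), st.floats(0.1, 100.0))
    def test_scale_invariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        d = pd.Series(rng.normal(0, 0.1, 30))
        assert list(bin_delta_rri(d)) == list(bin_delta_rri(d * scale))

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            d = rng.normal(0, 0.1, 90)
            d[rng.random(90) < 0.05] = np.nan
            got = [x if pd.notna(x) else None for x in bin_delta_rri(pd.Series(d))]
            assert got == bin_bruteforce(d.tolist())


class TestRobustZ:
    def test_hand_computed_example(self):
        z, scale = robust_z_rt(pd.Series([1.0, 2.0, 3.0, 4.0, 5.0]),
                               pd.Series([True] * 5))
        np.testing.assert_allclose(z, [-1.0, -0.5, 0.0, 0.5, 1.0])
        assert scale.median_s == 3.0 and scale.iqr_s == 2.0

    def test_median_zero_iqr_one_exactly(self, one_subject):
        ev = one_subject.events
        z, _ = robust_z_rt(ev["rt_s"], ev["correct"])
        zc = z[ev["correct"]].to_numpy()
        assert np.median(zc) == pytest.approx(0.0, abs=1e-12)
        assert np.percentile(zc, 75) - np.percentile(zc, 25) == pytest.approx(1.0)

    @given(st.integers(0, 10_000), st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    def test_affine_invariance(self, seed, a, b):
        rng = np.random.default_rng(seed)
        rt = pd.Series(rng.lognormal(0, 0.3, 20))
        ok = pd.Series([True] * 20)
        z1, _ = robust_z_rt(rt, ok)
        z2, _ = robust_z_rt(a * rt + b, ok)
        np.testing.assert_allclose(z1, z2, atol=1e-9)

    def test_matches_sort_based_bruteforce(self):
        rng = np.random.default_rng(12)
        rt = pd.Series(rng.lognormal(0, 0.4, 51))
        z, _ = robust_z_rt(rt, pd.Series([True] * 51))
        np.testing.assert_allclose(z, robust_z_bruteforce(rt.tolist()), atol=1e-9)

    def test_degenerate_iqr_flagged(self):
        z, scale = robust_z_rt(pd.Series([1.0] * 6), pd.Series([True] * 6))
        assert scale is None and z.isna().all()

    def test_incorrect_trials_get_no_z(self):
        rt = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 9.9])
        ok = pd.Series([True, True, True, True, True, False])
        z, _ = robust_z_rt(rt, ok)
        assert np.isnan(z.iloc[-1])


class TestConditionMeans:
    def test_constant_z_gives_that_mean(self, cohort_trials):
        t = cohort_trials[cohort_trials["subject"] == 1].copy()
        t["rt_robust_z"] = np.where(t["correct"], 2.5, np.nan)
        m = condition_means(t, "phase")
        assert np.allclose(m["mean_z"].dropna(), 2.5)

    def test_not_pools_inh_and_exh(self, cohort_trials):
        m = condition_means(cohort_trials, "phase")
        assert set(m["condition"]) <= {"NOt", "IEt", "EIt"}
        n_not = cohort_trials["not_flag"].sum()
        assert m[m["condition"] == "NOt"]["n_trials"].sum() == n_not

    def test_double_cells_partition_double_trials(self, cohort_trials):
        m = condition_means(cohort_trials, "double")
        n_double = (cohort_trials["condition"] == "DOUBLE").sum()
        assert m["n_trials"].sum() == n_double

    def test_half_labels_cover_single_transition_trials(self, cohort_trials):
        lab = half_condition(cohort_trials)
        single = cohort_trials["condition"].isin(["IEt", "EIt"])
        assert lab[single].notna().all()
        assert lab[~single].isna().all()

    def test_unknown_grouping_rejected(self, cohort_trials):
        with pytest.raises(ValueError):
            condition_means(cohort_trials, "nope")


class TestTrialTable:
    def test_invariants(self, cohort_trials):
        t = cohort_trials
        assert (t["rt_s"] > 0).all()
        is_double = t["condition"] == "DOUBLE"
        both = (t["eit_half"] != "none") & (t["iet_half"] != "none")
        assert (is_double == both).all()
        signs = t.loc[t["delta_rri"].notna() & (t["delta_rri"] != 0)]
        pos = signs["delta_rri"] > 0
        assert signs.loc[pos, "delta_rri_bin"].isin(["low_pos", "high_pos"]).all()
        assert signs.loc[~pos, "delta_rri_bin"].isin(["low_neg", "high_neg"]).all()

    def test_uncoverable_trials_excluded_and_logged(self, one_subject):
        # drop the first 60 cycles so early trials fall before phase coverage
        ph = PhaseSeries(one_subject.phases.ei_times[60:], one_subject.phases.ie_times[60:])
        rri = RRISeries(one_subject.r_times)
        tdf, qc = build_trial_table(1, one_subject.events, ph, rri)
        assert len(tdf) + len(qc["excluded_trials"]) == len(one_subject.events)
        assert len(qc["excluded_trials"]) > 0
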