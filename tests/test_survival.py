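import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from tamtil import synthetic as syn
from tamtil.survival import (
    GROUP_LABELS,
    chi_square_test,
    combine_tam_til_groups,
    cox_ph,
    filter_survival_cohort,
    kaplan_meier,
    logrank_test,
    median_split,
    two_group_compare,
    z_transform,
)


def records(times, events, index=None):
    idx = index or [f"S{i}" for i in range(len(times))]
    return pd.DataFrame(
        {"followup_months": times, "event": events}, index=idx
    )


class TestCohortFilter:
    def make_clinical(self):
        return pd.DataFrame(
            {
                "followup_months": [40.0, 12.0, 80.0, 70.0, 90.0],
                "event": [0, 1, 0, 0, 1],
                "simpson": [1, 2, 4, 3, 1],
                "status": ["newly_diagnosed"] * 4 + ["recurrent"],
            },
            index=list("abcde"),
        )

    def test_short_followup_censored_record_excluded(self):
        out = filter_survival_cohort(self.make_clinical(), min_followup_months=60)
        assert "a" not in out.index  # censored at 40 < 60

    def test_early_event_retained(self):
        out = filter_survival_cohort(self.make_clinical(), min_followup_months=60)
        assert "b" in out.index  # event at 12 months is informative

    def test_gtr_and_status_filters(self):
        out = filter_survival_cohort(self.make_clinical(), min_followup_months=60)
        assert "c" not in out.index  # Simpson 4 is not GTR
        assert "e" not in out.index  # recurrent
        assert list(out.index) == ["b", "d"]

    def test_gtr_flag_column_supported(self):
        clin = self.make_clinical().drop(columns="simpson")
        clin["gtr"] = [True, True, False, True, True]
        out = filter_survival_cohort(clin, min_followup_months=36)
        assert "c" not in out.index

    def test_empty_result_warns(self):
        clin = self.make_clinical()
        out = filter_survival_cohort(clin, min_followup_months=1000)
        assert list(out.index) == ["b"]  # only the eligible early event survives
        with pytest.warns(UserWarning, match="every record"):
            out2 = filter_survival_cohort(
                clin[clin["event"] == 0], min_followup_months=1000
            )
        assert len(out2) == 0


class TestMedianSplit:
    def test_even_n_splits_half_half(self):
        levels, thr = median_split(pd.Series([1, 2, 3, 4], index=list("abcd")))
        assert thr == 2.5
        assert levels.tolist() == ["low", "low", "high", "high"]

    def test_ties_at_median_go_low(self):
        levels, thr = median_split(pd.Series([1, 2, 2, 9], index=list("abcd")))
        assert thr == 2.0
        assert levels.tolist() == ["low", "low", "low", "high"]

    def test_odd_n_strict_inequality_count(self):
        rng = np.random.default_rng(0)
        v = pd.Series(rng.permutation(101).astype(float))
        levels, _ = median_split(v)
        assert (levels == "high").sum() == 50

    def test_degenerate_split_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            median_split(pd.Series([3.0, 3.0, 3.0]))


class TestCombineGroups:
    def test_mapping_and_partition(self):
        tam = pd.Series(["low", "low", "high", "high"], index=list("abcd"))
        til = pd.Series(["high", "low", "high", "low"], index=list("abcd"))
        combined = combine_tam_til_groups(tam, til)
        assert combined.tolist() == list(GROUP_LABELS)
        assert combined.value_counts().sum() == 4

    def test_mismatched_samples_rejected(self):
        tam = pd.Series(["low"], index=["a"])
        til = pd.Series(["low"], index=["b"])
        with pytest.raises(ValueError, match="different samples"):
            combine_tam_til_groups(tam, til)


class TestKaplanMeier:
    def test_no_events_survival_stays_one_median_unreached(self):
        km = kaplan_meier(records([5.0, 8.0, 12.0], [0, 0, 0]))["all"]
        assert (km.survival == 1.0).all()
        assert np.isinf(km.median)

    def test_three_subject_all_event_product_limit(self):
        km = kaplan_meier(records([1.0, 2.0, 3.0], [1, 1, 1]))["all"]
        np.testing.assert_allclose(km.survival[km.times > 0], [2 / 3, 1 / 3, 0.0])
        assert km.median == 2.0

    def test_event_counted_before_censoring_at_tied_time(self):
        # at t=2: one event, one censoring; S(2) = 1 - 1/3 with 3 at risk
        km = kaplan_meier(records([2.0, 2.0, 5.0], [1, 0, 0]))["all"]
        s_at_2 = km.survival[km.times == 2.0][0]
        assert s_at_2 == pytest.approx(2 / 3)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(10, 40).round(2)
        km = kaplan_meier(records(times, np.ones(40, dtype=int)))["all"]
        for t, s in zip(km.times, km.survival):
            assert s == pytest.approx((times > t).mean(), abs=1e-12)


def hand_logrank_two_groups(times, events, groups):
    """Observed-minus-expected tabulation over distinct event times."""
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        rec = records([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], [1, 1, 0, 1, 1, 0])
        grp = pd.Series(["A"] * 3 + ["B"] * 3, index=rec.index)
        chi2, dof, p = logrank_test(rec, grp)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert dof == 1

    def test_six_subject_fixture_matches_hand_tabulation(self):
        times = np.array([1.0, 3.0, 5.0, 2.0, 4.0, 6.0])
        events = np.array([1, 1, 0, 1, 1, 1])
        grp_num = np.array([1, 1, 1, 0, 0, 0])
        rec = records(times, events)
        grp = pd.Series(np.where(grp_num == 1, "A", "B"), index=rec.index)
        chi2, dof, _ = logrank_test(rec, grp)
        assert chi2 == pytest.approx(hand_logrank_two_groups(times, events, grp_num),
                                     rel=1e-10)

    def test_four_groups_have_three_degrees_of_freedom(self):
        rec = records(np.arange(1.0, 9.0), [1] * 8)
        grp = pd.Series(list("AABBCCDD"), index=rec.index)
        _, dof, _ = logrank_test(rec, grp)
        assert dof == 3

    def test_single_group_rejected(self):
        rec = records([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError, match="2 groups"):
            logrank_test(rec, pd.Series(["A", "A"], index=rec.index))

    def test_invariant_under_monotone_time_transform(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(10, 30)
        events = rng.integers(0, 2, 30)
        events[0] = 1
        grp = pd.Series(rng.choice(["A", "B"], 30))
        rec = records(times, events, index=list(grp.index.astype(str)))
        grp.index = rec.index
        chi2_a, _, _ = logrank_test(rec, grp)
        rec2 = rec.assign(followup_months=np.exp(rec["followup_months"] / 20))
        chi2_b, _, _ = logrank_test(rec2, grp)
        assert chi2_a == pytest.approx(chi2_b, rel=1e-9)


def hand_cox_partial_likelihood(times, events, x):
    """Brute-force 1D maximization of the Cox partial log-likelihood (no ties)."""

    def neg_pll(b):
        ll = 0.0
        for i in np.flatnonzero(events == 1):
            risk = times >= times[i]
            ll += b * x[i] - np.log(np.sum(np.exp(b * x[risk])))
        return -ll

    res = minimize_scalar(neg_pll, bounds=(-10, 10), method="bounded",
                          options={"xatol": 1e-10})
    return res.x


class TestCox:
    def test_constant_covariate_rejected(self):
        rec = records([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 0])
        cov = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0]}, index=rec.index)
        with pytest.raises(ValueError, match="constant"):
            cox_ph(rec, cov)

    def test_four_subject_binary_covariate_matches_brute_force(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0])
        rec = records(times, events)
        cov = pd.DataFrame({"x": x}, index=rec.index)
        fit = cox_ph(rec, cov)
        b_ref = hand_cox_partial_likelihood(times, events, x)
        assert fit.loc["x", "coef"] == pytest.approx(b_ref, abs=1e-4)
        assert fit.loc["x", "hr"] == pytest.approx(np.exp(b_ref), abs=1e-4)
        assert fit.loc["x", "ci_lower"] < fit.loc["x", "hr"] < fit.loc["x", "ci_upper"]

    def test_recovers_true_hazard_ratio_with_nominal_ci_coverage(self):
        # HR = 2 for a binary covariate; 200 replicates at n = 300
        rng = np.random.default_rng(12)
        true_b = np.log(2.0)
        hits, estimates = 0, []
        for _ in range(200):
            x = rng.integers(0, 2, 300).astype(float)
            t = rng.exponential(1.0 / (0.01 * np.exp(true_b * x)))
            cens = rng.exponential(300.0, 300)
            rec = records(np.minimum(t, cens), (t <= cens).astype(int))
            fit = cox_ph(rec, pd.DataFrame({"x": x}, index=rec.index))
            estimates.append(fit.loc["x", "hr"])
            if fit.loc["x", "ci_lower"] <= 2.0 <= fit.loc["x", "ci_upper"]:
                hits += 1
        coverage = hits / 200
        assert 0.90 <= coverage <= 0.99
        assert 1.7 <= np.median(estimates) <= 2.35

    def test_cox_on_simulated_cohort_recovers_tam_effect(self):
        truth = pd.DataFrame(
            {
                "tam_frac": np.random.default_rng(4).lognormal(-3.6, 1.0, 1000),
                "til_frac": 0.006,
                "who_grade": 2,
            },
            index=[f"S{i}" for i in range(1000)],
        )
        cfg = syn.SurvivalConfig(log_hr_tam=np.log(2), log_hr_til=0.0,
                                 log_hr_grade=0.0, seed=6)
        surv = syn.simulate_survival(truth, cfg)
        z_tam = z_transform(np.log(truth["tam_frac"]))
        fit = cox_ph(surv, pd.DataFrame({"z_tam": z_tam}))
        assert 1.7 <= fit.loc["z_tam", "hr"] <= 2.35


class TestZTransform:
    def test_hand_standardization(self):
        np.testing.assert_allclose(z_transform(np.array([1.0, 2.0, 3.0])),
                                   [-1.0, 0.0, 1.0])

    def test_output_mean_is_zero(self):
        rng = np.random.default_rng(5)
        z = z_transform(rng.random(57))
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0)

    @given(st.floats(-10, 10), st.floats(0.1, 10))
    def test_affine_invariance(self, a, b):
        x = np.array([0.5, 1.5, 2.0, 4.0, 9.0])
        np.testing.assert_allclose(z_transform(a + b * x), z_transform(x), atol=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            z_transform(np.array([2.0, 2.0]))


class TestChiSquare:
    def test_independence_gives_zero(self):
        margins_r = np.array([0.3, 0.7])
        margins_c = np.array([0.2, 0.5, 0.3])
        table = 1000 * np.outer(margins_r, margins_c)
        stat, dof, p = chi_square_test(table)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_two_by_two_closed_form(self):
        stat, dof, _ = chi_square_test([[10, 20], [20, 10]])
        assert stat == pytest.approx(20 / 3, rel=1e-12)
        assert dof == 1

    def test_three_by_four_df_contract(self):
        rng = np.random.default_rng(6)
        _, dof, _ = chi_square_test(rng.integers(5, 30, (3, 4)))
        assert dof == 6

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_test([[0, 0], [5, 3]])


class TestTwoGroupCompare:
    def test_fully_separated_groups_have_extreme_u(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        name, u, _ = two_group_compare(values, labels)
        assert name.startswith("mann_whitney_u")
        assert u == 0.0  # first group entirely below the second

    def test_group_order_swap_reflects_u(self):
        rng = np.random.default_rng(7)
        values = rng.permutation(12).astype(float)
        labels = np.array(["a"] * 5 + ["b"] * 7)
        _, u_ab, p_ab = two_group_compare(values, labels)
        # present the groups in the opposite order: U flips to n1*n2 - U
        _, u_ba, p_ba = two_group_compare(values[::-1], labels[::-1])
        assert u_ab + u_ba == 5 * 7
        assert p_ab == pytest.approx(p_ba)

    def test_large_samples_use_asymptotic_method(self):
        rng = np.random.default_rng(8)
        values = rng.random(40)
        labels = np.array(["a"] * 20 + ["b"] * 20)
        name, _, _ = two_group_compare(values, labels)
        assert name.endswith("asymptotic")

    def test_paired_wilcoxon_and_degenerate_case(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        name, _, _ = two_group_compare(x, paired_with=x + [0.5, -0.2, 0.1, 0.3, -0.4])
        assert name == "wilcoxon_signed_rank"
        with pytest.raises(ValueError, match="zero"):
            two_group_compare(x, paired_with=x.copy())


class TestFourGroupExperiment:
    def test_group_median_ordering_reproduced_across_cohorts(self):
        """High TAM should be the dominant adverse factor, TIL protective:
        lowTAM_highTIL best and highTAM_lowTIL worst in >= 90% of cohorts."""
        wins = 0
        n_cohorts = 100
        for seed in range(n_cohorts):
            rng = np.random.default_rng(1000 + seed)
            n = 400
            truth = pd.DataFrame(
                {
                    "tam_frac": rng.lognormal(-3.6, 1.0, n),
                    "til_frac": rng.lognormal(-5.0, 1.4, n),
                    "who_grade": rng.choice([1, 2, 3], n, p=[0.3, 0.5, 0.2]),
                },
                index=[f"S{i}" for i in range(n)],
            )
            cfg = syn.SurvivalConfig(
                log_hr_tam=0.9, log_hr_til=-0.5, log_hr_grade=0.0,
                admin_censor_months=np.inf, random_censor_rate=0.0,
                seed=2000 + seed,
            )
            surv = syn.simulate_survival(truth, cfg)
            tam_lvl, _ = median_split(truth["tam_frac"])
            til_lvl, _ = median_split(truth["til_frac"])
            grp = combine_tam_til_groups(tam_lvl, til_lvl)
            med = surv.groupby(grp)["followup_months"].median()
            ranked = med.sort_values(ascending=False).index
            if ranked[0] == "lowTAM_highTIL" and ranked[-1] == "highTAM_lowTIL":
                wins += 1
        assert wins / n_cohorts >= 0.9
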