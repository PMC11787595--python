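"""Statistical battery: ANOVA/ANCOVA against brute-force oracles,
paired tests, split-plot time course, and the power computation."""

import numpy as np
import pytest

from somnocal import (
    PowerSpec,
    adjusted_group_comparison,
    five_group_anova,
    paired_phase_test,
    rm_power,
    rm_power_total_n,
    timecourse_ancova,
)


def anova_oracle(groups):
    """Textbook between/within mean-square ratio from explicit sums of squares."""
    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    ss_between = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
    ss_within = sum(np.sum((np.asarray(v) - np.mean(v)) ** 2) for v in groups.values())
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


def ols_oracle(X, y):
    """Normal-equations least squares."""
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestFiveGroupAnova:
    def test_identical_values_f_zero(self):
        res = five_group_anova({k: [5.0, 5.0, 5.0] for k in "abcde"})
        assert res.statistic == pytest.approx(0.0)

    def test_separated_groups_tiny_p(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(10, 1, 10)
        res = five_group_anova({"a": a, "b": b})
        assert res.p_value < 1e-3

    def test_matches_sums_of_squares_oracle(self, rng):
        groups = {k: rng.normal(i, 1.5, 4) for i, k in enumerate("abc")}
        res = five_group_anova(groups)
        assert res.statistic == pytest.approx(anova_oracle(groups), rel=1e-10)
        assert res.df == (2, 9)

    def test_posthoc_pairs_present(self, rng):
        groups = {k: rng.normal(0, 1, 5) for k in "abc"}
        res = five_group_anova(groups, posthoc=True)
        assert len(res.details["posthoc"]) == 3

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            five_group_anova({"a": [1.0], "b": [1.0, 2.0]})

    def test_type_i_error_calibrated(self, rng):
        """Null simulation: rejection rate at alpha=0.05 in [3.5%, 6.5%]."""
        rejections = 0
        for _ in range(1000):
            groups = {k: rng.normal(0, 1, 9) for k in "abcde"}
            if five_group_anova(groups).p_value < 0.05:
                rejections += 1
        assert 35 <= rejections <= 65


class TestPairedPhaseTest:
    def test_identical_pairs(self):
        res = paired_phase_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_hand_computed_t(self):
        """Differences [1,2,3,4]: t = 2.5 / (1.2910/2) = 3.873."""
        f = np.array([10.0, 10.0, 10.0, 10.0])
        res = paired_phase_test(f, f + np.array([1.0, 2.0, 3.0, 4.0]))
        assert res.statistic == pytest.approx(3.872983, abs=1e-5)
        assert res.df == (3,)

    def test_constant_nonzero_differences_flagged(self):
        res = paired_phase_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert not res.details["defined"]

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            paired_phase_test([1.0, 2.0], [1.0])


class TestAdjustedGroupComparison:
    def test_constant_covariates_reduce_to_anova(self, rng):
        """Covariates with no variation drop out: group F and p equal the
        plain one-way ANOVA exactly."""
        values = np.concatenate([rng.normal(0, 1, 8), rng.normal(1, 1, 8)])
        group = np.repeat(["a", "b"], 8)
        res = adjusted_group_comparison(values, group, np.full(16, 50.0),
                                        np.full(16, 10.0))
        plain = five_group_anova({"a": values[:8], "b": values[8:]})
        assert res.statistic == pytest.approx(plain.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(plain.p_value, rel=1e-10)
        assert res.covariate_slopes == {"ffm": 0.0, "fm": 0.0}

    def test_group_signal_vanishes_after_adjustment(self):
        """Values built purely from FFM: adjusting for FFM removes the
        apparent group effect in >= 90% of replicates."""
        rng = np.random.default_rng(7)
        nonsig = 0
        n_rep = 200
        for _ in range(n_rep):
            ffm = np.concatenate([rng.normal(55, 3, 10), rng.normal(40, 3, 10)])
            fm = rng.normal(10, 2, 20)
            values = 77 * ffm + rng.normal(0, 40, 20)
            group = np.repeat(["male", "female"], 10)
            res = adjusted_group_comparison(values, group, ffm, fm)
            if res.p_value > 0.05:
                nonsig += 1
        assert nonsig >= 0.9 * n_rep

    def test_coefficients_match_normal_equations(self, rng):
        values = rng.normal(100, 10, 12)
        group = np.tile(["a", "b", "c"], 4)
        ffm = rng.normal(50, 5, 12)
        fm = rng.normal(12, 3, 12)
        res = adjusted_group_comparison(values, group, ffm, fm)
        X = np.column_stack([np.ones(12), group == "b", group == "c", ffm, fm])
        beta = ols_oracle(X, values)
        assert res.covariate_slopes["ffm"] == pytest.approx(beta[3], rel=1e-10)
        assert res.covariate_slopes["fm"] == pytest.approx(beta[4], rel=1e-10)

    def test_adjusted_means_at_covariate_grand_mean(self, rng):
        values = rng.normal(100, 10, 12)
        group = np.tile(["a", "b"], 6)
        ffm = rng.normal(50, 5, 12)
        fm = rng.normal(12, 3, 12)
        res = adjusted_group_comparison(values, group, ffm, fm)
        X = np.column_stack([np.ones(12), group == "b", ffm, fm])
        beta = ols_oracle(X, values)
        expect_a = beta[0] + beta[2] * ffm.mean() + beta[3] * fm.mean()
        assert res.adjusted_means["a"] == pytest.approx(expect_a, rel=1e-10)

    def test_collinear_covariates_flagged(self, rng):
        values = rng.normal(0, 1, 12)
        group = np.tile(["a", "b"], 6)
        ffm = rng.normal(50, 5, 12)
        res = adjusted_group_comparison(values, group, ffm, 2 * ffm + 1e-9)
        assert res.details["conditioning_warning"]


class TestTimecourseAncova:
    def test_flat_shared_profile_interaction_zero(self):
        y = np.tile(np.full(16, 5.0), (10, 1))
        group = np.repeat(["a", "b"], 5)
        res = timecourse_ancova(y, group)
        assert res["interaction"].statistic == pytest.approx(0.0, abs=1e-20)

    def test_crossing_profiles_strong_interaction(self, rng):
        """Time courses that cross mid-night give interaction p < 0.001."""
        t = np.linspace(0, 1, 16)
        y_a = 5 + 1.0 * t + 0.01 * rng.standard_normal((8, 16))
        y_b = 6 - 1.0 * t + 0.01 * rng.standard_normal((8, 16))
        y = np.vstack([y_a, y_b])
        group = np.repeat(["a", "b"], 8)
        res = timecourse_ancova(y, group)
        assert res["interaction"].p_value < 1e-3

    def test_level_shift_gives_group_not_interaction(self):
        """A pure level shift shows a group main effect but no interaction
        in >= 90% of seeded replicates."""
        rng = np.random.default_rng(11)
        profile = 5 + np.sin(np.linspace(0, np.pi, 16))
        good = 0
        n_rep = 200
        for _ in range(n_rep):
            y_a = profile + 0.2 * rng.standard_normal((8, 16))
            y_b = profile + 1.0 + 0.2 * rng.standard_normal((8, 16))
            res = timecourse_ancova(np.vstack([y_a, y_b]), np.repeat(["a", "b"], 8))
            if res["interaction"].p_value > 0.05 and res["group"].p_value < 0.05:
                good += 1
        assert good >= 0.9 * n_rep

    def test_within_f_matches_sums_of_squares_oracle(self, rng):
        y = rng.normal(5, 1, (9, 4))
        group = np.array(["a"] * 4 + ["b"] * 5)
        res = timecourse_ancova(y, group)
        # independent split-plot decomposition
        dev = y - y.mean(axis=1, keepdims=True)
        tmean = dev.mean(axis=0)
        ss_time = len(y) * np.sum(tmean**2)
        ss_int, ss_err = 0.0, 0.0
        for g in ("a", "b"):
            cell = dev[group == g]
            cm = cell.mean(axis=0)
            ss_int += len(cell) * np.sum((cm - tmean) ** 2)
            ss_err += np.sum((cell - cm) ** 2)
        f_int = (ss_int / 3) / (ss_err / 21)
        f_time = (ss_time / 3) / (ss_err / 21)
        assert res["interaction"].statistic == pytest.approx(f_int, rel=1e-10)
        assert res["time"].statistic == pytest.approx(f_time, rel=1e-10)

    def test_missing_bins_drop_subject(self, rng):
        y = rng.normal(5, 1, (10, 16))
        y[3, 7] = np.nan
        res = timecourse_ancova(y, np.repeat(["a", "b"], 5))
        assert res["dropped_subjects"] == 1


class TestRmPower:
    def test_study_settings_reproduce_total_n_8(self):
        """f=0.4, alpha=0.05, power=0.95, rho=0.5, eps=1, 2 groups, 16
        measures: smallest adequate total N is 8 (4 per group)."""
        res = rm_power_total_n(PowerSpec())
        assert res["total_n"] == 8
        assert res["per_group"] == 4
        assert res["power"] >= 0.95
        assert rm_power(6, PowerSpec()) < 0.95  # minimality

    def test_huge_effect_needs_minimum_n(self):
        res = rm_power_total_n(PowerSpec(f=10.0))
        assert res["total_n"] == 4  # smallest equal-group N with df2 >= 1

    def test_rho_never_increases_required_n(self):
        previous = np.inf
        for rho in np.linspace(0.0, 0.5, 6):
            n = rm_power_total_n(PowerSpec(f=0.25, rho=float(rho)))["total_n"]
            assert n <= previous
            previous = n

    def test_power_monotone_in_n_f_alpha(self):
        spec = PowerSpec()
        assert rm_power(10, spec) >= rm_power(8, spec)
        assert rm_power(8, PowerSpec(f=0.5)) >= rm_power(8, PowerSpec(f=0.4))
        assert rm_power(8, PowerSpec(alpha=0.10)) >= rm_power(8, PowerSpec(alpha=0.05))

    def test_returned_n_is_minimal(self):
        spec = PowerSpec(f=0.25)
        res = rm_power_total_n(spec)
        assert rm_power(res["total_n"], spec) >= spec.power_target
        assert rm_power(res["total_n"] - spec.g, spec) < spec.power_target

    def test_unreachable_target_raises(self):
        with pytest.raises(ValueError, match="unreachable"):
            rm_power_total_n(PowerSpec(f=1e-6), n_cap=100)

    @pytest.mark.parametrize("kw", [
        {"alpha": 0.0}, {"power_target": 1.0}, {"g": 1}, {"m": 1},
        {"rho": 1.0}, {"epsilon": 0.0}, {"f": 0.0},
    ])
    def test_invalid_spec_rejected(self, kw):
        with pytest.raises(ValueError):
            PowerSpec(**kw)
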