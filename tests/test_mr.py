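"""MR estimators against independent oracles, plus diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from crossmr.mr import (
    MRError, PowerSpec, wald_ratio, ivw, egger, raps, cochran_q,
    f_statistic, single_snp_table, leave_one_out, power_binary, plot_data,
)

from conftest import random_instruments


class TestWaldRatio:
    def test_direct_arithmetic(self):
        est, se = wald_ratio((0.1, 0.0, 0.02, 0.05))
        assert est == pytest.approx(0.2)
        assert se == pytest.approx(0.5)

    def test_zero_outcome_effect(self):
        est, _ = wald_ratio((0.1, 0.0, 0.0, 0.05))
        assert est == 0.0

    def test_null_instrument_rejected(self):
        with pytest.raises(MRError, match="null instrument"):
            wald_ratio((0.0, 0.0, 0.02, 0.05))

    def test_second_order_se_matches_finite_difference_oracle(self, rng):
        # delta method: Var(f) ~ grad^T Sigma grad for f = by/bx with
        # independent errors; gradient by central differences
        bx, sx, by, sy = 0.12, 0.015, 0.03, 0.04
        f = lambda x, y: y / x
        h = 1e-7
        dfdx = (f(bx + h, by) - f(bx - h, by)) / (2 * h)
        dfdy = (f(bx, by + h) - f(bx, by - h)) / (2 * h)
        se_oracle = math.sqrt(dfdx**2 * sx**2 + dfdy**2 * sy**2)
        _, se = wald_ratio((bx, sx, by, sy), second_order=True)
        assert se == pytest.approx(se_oracle, rel=1e-6)


class TestIVW:
    def test_single_instrument_equals_wald_ratio(self):
        df = pd.DataFrame({"beta_exp": [0.1], "se_exp": [0.01],
                           "beta_out": [0.02], "se_out": [0.05]})
        res = ivw(df)
        assert res.estimate == pytest.approx(0.2)
        assert "fell back to fixed" in res.notes[0]

    def test_all_null_outcome_gives_zero(self):
        df = pd.DataFrame({"beta_exp": [0.1, 0.2], "se_exp": [0.01, 0.01],
                           "beta_out": [0.0, 0.0], "se_out": [0.05, 0.05]})
        assert ivw(df).estimate == 0.0

    def test_matches_wls_through_origin_oracle(self, hand_instruments):
        res = ivw(hand_instruments, model="fixed")
        w = 1.0 / hand_instruments["se_out"] ** 2
        fit = sm.WLS(hand_instruments["beta_out"],
                     hand_instruments[["beta_exp"]], weights=w).fit()
        assert res.estimate == pytest.approx(fit.params.iloc[0], rel=1e-10)

    def test_three_formulations_agree(self, rng):
        # weighted mean of Wald ratios == WLS through origin ==
        # fixed-effect meta-analysis of ratios, to 10 significant digits
        for _ in range(10):
            insts = random_instruments(rng, 12)
            res = ivw(insts, model="fixed")
            theta = insts["beta_out"] / insts["beta_exp"]
            w = insts["beta_exp"] ** 2 / insts["se_out"] ** 2
            meta = np.sum(w * theta) / np.sum(w)  # FE meta-analysis
            fit = sm.WLS(insts["beta_out"], insts[["beta_exp"]],
                         weights=1 / insts["se_out"] ** 2).fit()
            assert res.estimate == pytest.approx(meta, rel=1e-10)
            assert res.estimate == pytest.approx(fit.params.iloc[0],
                                                 rel=1e-10)
            assert res.se == pytest.approx(np.sum(w) ** -0.5, rel=1e-10)

    def test_mre_inflates_se_only_under_heterogeneity(self, rng):
        insts = random_instruments(rng, 20, pleio_sd=0.05)
        fixed = ivw(insts, model="fixed")
        mre = ivw(insts, model="mre")
        assert mre.se >= fixed.se
        assert mre.se == pytest.approx(
            fixed.se * max(1, math.sqrt(mre.q_stat / (mre.n_snps - 1))))

    def test_orientation_invariance(self, rng):
        insts = random_instruments(rng, 15)
        flipped = insts.copy()
        flipped.loc[::2, ["beta_exp", "beta_out"]] *= -1
        a, b = ivw(insts), ivw(flipped)
        assert a.estimate == pytest.approx(b.estimate, rel=1e-12)
        assert a.q_stat == pytest.approx(b.q_stat, rel=1e-12)


class TestEgger:
    def test_noiseless_linear_data_recovered_exactly(self):
        bx = np.array([0.05, 0.08, 0.11, 0.14, 0.2])
        df = pd.DataFrame({"beta_exp": bx, "se_exp": 0.01,
                           "beta_out": 0.01 + 0.3 * bx, "se_out": 0.05})
        res = egger(df)
        assert res.estimate == pytest.approx(0.3, abs=1e-12)
        assert res.intercept == pytest.approx(0.01, abs=1e-12)

    def test_matches_weighted_regression_oracle(self, rng):
        for _ in range(10):
            insts = random_instruments(rng, 6, pleio_sd=0.03)
            insts["beta_exp"] = np.abs(insts["beta_exp"])
            res = egger(insts)
            w = 1.0 / insts["se_out"] ** 2
            X = sm.add_constant(insts["beta_exp"])
            fit = sm.WLS(insts["beta_out"], X, weights=w).fit()
            assert res.intercept == pytest.approx(fit.params.iloc[0],
                                                  rel=1e-9)
            assert res.estimate == pytest.approx(fit.params.iloc[1],
                                                 rel=1e-9)

    def test_requires_three_instruments(self):
        df = pd.DataFrame({"beta_exp": [0.1, 0.2], "se_exp": [0.01, 0.01],
                           "beta_out": [0.02, 0.04], "se_out": [0.05, 0.05]})
        with pytest.raises(MRError, match=">= 3"):
            egger(df)

    def test_orientation_invariance_via_internal_orientation(self, rng):
        insts = random_instruments(rng, 12, pleio_sd=0.02)
        flipped = insts.copy()
        flipped.loc[1::2, ["beta_exp", "beta_out"]] *= -1
        a, b = egger(insts), egger(flipped)
        assert a.estimate == pytest.approx(b.estimate, rel=1e-12)
        assert a.intercept == pytest.approx(b.intercept, rel=1e-12)

    def test_balanced_pleiotropy_intercept_near_zero(self, rng):
        # zero-mean pleiotropy under InSIDE: intercept consistent for 0
        n = 4000
        bx = rng.normal(0.1, 0.03, n)
        alpha = rng.normal(0.0, 0.02, n)
        sy = np.full(n, 0.02)
        by = 0.2 * bx + alpha + rng.normal(0, 1, n) * sy
        df = pd.DataFrame({"beta_exp": bx, "se_exp": 0.001,
                           "beta_out": by, "se_out": sy})
        res = egger(df)
        assert abs(res.intercept) < 3 * res.intercept_se


from conftest import raps_profile_root_by_grid


class TestRAPS:
    def test_reduces_to_ivw_when_no_exposure_error(self, rng):
        insts = random_instruments(rng, 30)
        insts["se_exp"] = 0.0
        res = raps(insts)
        fixed = ivw(insts, model="fixed")
        assert res.estimate == pytest.approx(fixed.estimate, rel=1e-8)

    def test_null_simulation_centers_on_zero(self, rng):
        ests = []
        for _ in range(50):
            insts = random_instruments(rng, 50, true_beta=0.0)
            ests.append(raps(insts).estimate)
        mean = np.mean(ests)
        mc_se = np.std(ests, ddof=1) / math.sqrt(len(ests))
        assert abs(mean) < 4 * mc_se + 1e-3

    def test_root_matches_grid_search_oracle(self, rng):
        for _ in range(5):
            insts = random_instruments(rng, 5, true_beta=0.3)
            res = raps(insts)
            oracle = raps_profile_root_by_grid(insts, step=1e-5)
            assert res.estimate == pytest.approx(oracle, abs=2e-5)

    def test_overdispersed_estimates_positive_tau2_under_pleiotropy(self, rng):
        insts = random_instruments(rng, 100, pleio_sd=0.05)
        res = raps(insts, overdispersed=True)
        assert res.converged
        assert res.tau2 > 0

    def test_huber_loss_downweights_one_gross_outlier(self, rng):
        insts = random_instruments(rng, 40, true_beta=0.1)
        insts.loc[0, "beta_out"] = 5.0  # wild pleiotropic outlier
        l2 = raps(insts, loss="l2")
        hb = raps(insts, loss="huber")
        clean = raps(insts.iloc[1:], loss="l2")
        assert abs(hb.estimate - clean.estimate) < abs(l2.estimate
                                                       - clean.estimate)

    def test_requires_three_instruments(self):
        df = pd.DataFrame({"beta_exp": [0.1, 0.2], "se_exp": [0.01, 0.01],
                           "beta_out": [0.02, 0.04], "se_out": [0.05, 0.05]})
        with pytest.raises(MRError):
            raps(df)


class TestCochranQ:
    def test_identical_ratios_give_zero(self):
        df = pd.DataFrame({"beta_exp": [0.1, 0.2, 0.4],
                           "se_exp": [0.01] * 3,
                           "beta_out": [0.02, 0.04, 0.08],
                           "se_out": [0.05] * 3})
        q, df_, p = cochran_q(df, 0.2)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert df_ == 2

    def test_two_instruments_hand_computation(self):
        # theta = (0.3, 0.1); w = bx^2/sy^2 = (4, 1); est = 0.26
        insts = pd.DataFrame({"beta_exp": [0.2, 0.1], "se_exp": [0.01, 0.01],
                              "beta_out": [0.06, 0.01],
                              "se_out": [0.1, 0.1]})
        w = np.array([0.2**2 / 0.1**2, 0.1**2 / 0.1**2])
        theta = np.array([0.3, 0.1])
        est = np.sum(w * theta) / w.sum()
        q_hand = float(np.sum(w * (theta - est) ** 2))
        q, df_, p = cochran_q(insts, est)
        assert q == pytest.approx(q_hand, rel=1e-12)
        assert p == pytest.approx(stats.chi2.sf(q_hand, 1), rel=1e-12)

    def test_single_instrument_rejected(self):
        df = pd.DataFrame({"beta_exp": [0.1], "se_exp": [0.01],
                           "beta_out": [0.02], "se_out": [0.05]})
        with pytest.raises(MRError):
            cochran_q(df, 0.2)


class TestFStatistic:
    def test_mean_per_snp_square(self):
        df = pd.DataFrame({"beta_exp": [0.1], "se_exp": [0.01],
                           "beta_out": [0.0], "se_out": [1.0]})
        assert f_statistic(df) == pytest.approx(100.0)

    def test_overall_r2_null(self):
        assert f_statistic(mode="overall-r2", n_exposure=1000, r2=1e-12,
                           n_snps=10) == pytest.approx(0.0, abs=1e-9)

    def test_overall_r2_study_scale_arithmetic(self):
        # direct evaluation of (n-k-1)/k * r2/(1-r2)
        n, k, r2 = 694_649, 319, 0.039
        expected = (n - k - 1) / k * r2 / (1 - r2)
        assert f_statistic(mode="overall-r2", n_exposure=n, r2=r2,
                           n_snps=k) == pytest.approx(expected, rel=1e-12)

    def test_missing_inputs_rejected(self):
        with pytest.raises(ValueError):
            f_statistic(mode="overall-r2", n_exposure=1000)


class TestSingleSnpAndLOO:
    def test_rows_match_wald_ratio(self, hand_instruments):
        table = single_snp_table(hand_instruments)
        assert len(table) == 5
        for j, row in table.iterrows():
            est, se = wald_ratio(tuple(
                hand_instruments.loc[j, ["beta_exp", "se_exp",
                                         "beta_out", "se_out"]]))
            assert row["estimate"] == pytest.approx(est)
            assert row["funnel_x"] == pytest.approx(est)
            assert row["funnel_y"] == pytest.approx(1 / se)

    def test_null_calibration_of_significance_flag(self, rng):
        insts = random_instruments(rng, 4000, true_beta=0.0)
        insts["se_exp"] = 1e-9  # exact exposure effects: Wald z is N(0,1)
        frac = single_snp_table(insts)["significant"].mean()
        assert frac == pytest.approx(0.05, abs=0.015)

    def test_loo_two_instruments_forced(self):
        df = pd.DataFrame({"beta_exp": [0.1, 0.2], "se_exp": [0.01, 0.01],
                           "beta_out": [0.03, 0.02], "se_out": [0.05, 0.05]})
        table = leave_one_out(df)
        assert table.loc[0, "estimate"] == pytest.approx(0.1)  # keeps rs2
        assert table.loc[1, "estimate"] == pytest.approx(0.3)

    def test_loo_rows_match_recomputation(self, rng):
        insts = random_instruments(rng, 10)
        table = leave_one_out(insts)
        for j in range(10):
            manual = ivw(insts.drop(index=j))
            assert table.loc[j, "estimate"] == pytest.approx(
                manual.estimate, rel=1e-12)

    def test_duplicated_instruments_give_identical_rows(self):
        df = pd.DataFrame({"beta_exp": [0.1] * 4, "se_exp": [0.01] * 4,
                           "beta_out": [0.02] * 4, "se_out": [0.05] * 4})
        table = leave_one_out(df)
        assert table["estimate"].nunique() == 1

    def test_plot_data_tables(self, hand_instruments):
        tables = plot_data(hand_instruments)
        assert set(tables) == {"scatter", "forest", "funnel"}
        assert len(tables["scatter"]) == 5
        assert len(tables["forest"]) == 7  # 5 SNPs + IVW + Egger rows


class TestPowerBinary:
    def spec(self, or_detect, alpha=0.05):
        return PowerSpec(n_total=105_318, case_fraction=40_675 / 105_318,
                         r2_exposure=0.039, or_detect=or_detect, alpha=alpha)

    def test_null_or_gives_size(self):
        assert power_binary(self.spec(1.0)) == pytest.approx(0.05, abs=1e-12)

    def test_monotone_in_n_r2_and_effect(self):
        base = power_binary(self.spec(1.05))
        assert power_binary(self.spec(1.08)) > base
        bigger_n = PowerSpec(n_total=300_000, case_fraction=0.386,
                             r2_exposure=0.039, or_detect=1.05)
        assert power_binary(bigger_n) > base
        more_r2 = PowerSpec(n_total=105_318, case_fraction=0.386,
                            r2_exposure=0.08, or_detect=1.05)
        assert power_binary(more_r2) > base
        # symmetric in |ln OR|: a protective OR of equal magnitude
        assert power_binary(self.spec(1 / 1.05)) == pytest.approx(
            power_binary(self.spec(1.05)), rel=1e-9)

    def test_out_of_range_spec_rejected(self):
        with pytest.raises(ValueError):
            power_binary(PowerSpec(n_total=100, case_fraction=1.2,
                                   r2_exposure=0.039, or_detect=1.1))

    def test_matches_ivw_ztest_simulation(self, rng):
        # Monte-Carlo oracle: simulate the IVW z-test under the
        # generative model at a moderate-power setting
        spec = PowerSpec(n_total=20_000, case_fraction=0.4,
                         r2_exposure=0.02, or_detect=1.15)
        analytic = power_binary(spec)
        b = math.log(spec.or_detect)
        se_ivw = 1 / math.sqrt(spec.n_total * spec.r2_exposure
                               * spec.case_fraction
                               * (1 - spec.case_fraction))
        reps = 40_000
        est = b + rng.normal(0, 1, reps) * se_ivw
        rej = np.mean(np.abs(est / se_ivw) > stats.norm.ppf(0.975))
        mc_se = math.sqrt(analytic * (1 - analytic) / reps)
        assert rej == pytest.approx(analytic, abs=4 * mc_se)
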