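"""Estimator suite: Wald ratios, IVW, Cochran Q, Egger, weighted median,
leave-one-out, odds-ratio transforms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mrmediate.mr import (
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    cochran_q,
    egger,
    ivw,
    leave_one_out,
    tau2_reml,
    to_odds_ratio,
    wald_ratios,
    weighted_median,
)
from .conftest import make_harmonized, random_harmonized


class TestWaldRatios:
    def test_basic_arithmetic(self):
        r = wald_ratios(make_harmonized([0.1], [0.05], se_out=[0.01]))
        assert r.loc[0, "ratio"] == pytest.approx(0.5)
        assert r.loc[0, "se_ratio"] == pytest.approx(0.1)

    def test_negative_exposure_effect(self):
        r = wald_ratios(make_harmonized([-0.1], [0.05], se_out=[0.01]))
        assert r.loc[0, "ratio"] == pytest.approx(-0.5)
        assert r.loc[0, "se_ratio"] == pytest.approx(0.1)

    def test_matches_elementwise_division_oracle(self, rng):
        h = random_harmonized(rng, k=30)
        r = wald_ratios(h)
        np.testing.assert_allclose(r["ratio"], h.rows["beta_out"] / h.rows["beta_exp"])
        np.testing.assert_allclose(
            r["se_ratio"], h.rows["se_out"] / h.rows["beta_exp"].abs()
        )

    def test_zero_exposure_beta_raises(self):
        with pytest.raises(DegenerateInstrumentError, match="rs1"):
            wald_ratios(make_harmonized([0.0, 0.1], [0.05, 0.05]))


class TestIVW:
    def test_single_instrument_is_wald_fit(self):
        f = ivw(make_harmonized([0.1], [0.05], se_out=[0.01]))
        assert f.method == "wald_single"
        assert f.beta == pytest.approx(0.5)
        assert f.se == pytest.approx(0.1)

    def test_two_ratio_closed_form(self):
        # ratios 0.1 and 0.3, each with se 0.1
        f = ivw(make_harmonized([1.0, 1.0], [0.1, 0.3], se_out=[0.1, 0.1]), model="fixed")
        assert f.beta == pytest.approx(0.2)
        assert f.se == pytest.approx(np.sqrt(1 / 200))
        assert f.q == pytest.approx(2.0)
        assert f.q_df == 1
        assert f.i2 == pytest.approx(50.0)

    def test_homogeneous_ratios_choose_fixed(self):
        f = ivw(make_harmonized([0.1, 0.2, 0.4], [0.05, 0.10, 0.20]))
        assert f.method == "ivw_fixed"
        assert f.beta == pytest.approx(0.5)
        assert f.q == pytest.approx(0.0, abs=1e-20)

    def test_fixed_effect_matches_weighted_mean_oracle(self, rng):
        for _ in range(200):
            h = random_harmonized(rng)
            f = ivw(h, model="fixed")
            r = h.rows["beta_out"] / h.rows["beta_exp"]
            w = (h.rows["beta_exp"].abs() / h.rows["se_out"]) ** 2
            assert f.beta == pytest.approx(float((w * r).sum() / w.sum()), abs=1e-12)
            assert f.se == pytest.approx(float(np.sqrt(1 / w.sum())), abs=1e-12)

    def test_invariant_to_joint_row_negation(self, rng):
        h = random_harmonized(rng, k=8)
        f1 = ivw(h, model="fixed")
        h.rows.loc[3, ["beta_exp", "beta_out"]] *= -1
        f2 = ivw(h, model="fixed")
        assert f1.beta == pytest.approx(f2.beta, abs=1e-14)

    def test_random_effects_se_not_below_fixed(self, rng):
        for _ in range(25):
            h = random_harmonized(rng)
            assert ivw(h, model="random").se >= ivw(h, model="fixed").se - 1e-12

    def test_empty_set_raises(self):
        h = make_harmonized([0.1], [0.05]).subset([])
        with pytest.raises(InsufficientInstrumentsError):
            ivw(h)

    def test_auto_switches_to_random_under_heterogeneity(self):
        # wildly heterogeneous ratios
        f = ivw(make_harmonized([0.1, 0.1, 0.1], [0.01, 0.05, 0.09], se_out=[0.001] * 3))
        assert f.method == "ivw_random"
        assert f.tau2 > 0


class TestCochranQ:
    def test_hand_computed_value(self):
        r = wald_ratios(make_harmonized([1.0, 1.0], [0.1, 0.3], se_out=[0.1, 0.1]))
        q, df, q_pval, i2 = cochran_q(r, 0.2)
        assert q == pytest.approx(2.0)
        assert df == 1
        assert q_pval == pytest.approx(stats.chi2.sf(2.0, 1))
        assert i2 == pytest.approx(50.0)

    def test_homogeneous_gives_zero(self):
        r = wald_ratios(make_harmonized([0.1, 0.2], [0.05, 0.10]))
        q, _, _, i2 = cochran_q(r, 0.5)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert i2 == 0.0

    def test_i2_clamped_at_zero_when_q_below_df(self):
        r = wald_ratios(make_harmonized([1.0, 1.0], [0.199, 0.201], se_out=[0.1, 0.1]))
        q, df, _, i2 = cochran_q(r, 0.2)
        assert q < df
        assert i2 == 0.0

    def test_requires_two_instruments(self):
        r = wald_ratios(make_harmonized([0.1], [0.05]))
        with pytest.raises(ValueError):
            cochran_q(r, 0.0)


class TestEgger:
    def test_exact_line_recovered(self):
        beta_exp = np.array([0.1, 0.2, 0.3])
        beta_out = 0.05 + 0.5 * beta_exp
        f = egger(make_harmonized(beta_exp, beta_out, se_out=[0.01] * 3))
        assert f.beta == pytest.approx(0.5, abs=1e-10)
        assert f.egger_intercept == pytest.approx(0.05, abs=1e-10)

    def test_no_pleiotropy_zero_intercept(self):
        beta_exp = np.array([0.1, 0.2, 0.3, 0.4])
        f = egger(make_harmonized(beta_exp, 0.5 * beta_exp))
        assert f.egger_intercept == pytest.approx(0.0, abs=1e-12)
        assert f.beta == pytest.approx(0.5, abs=1e-12)

    def test_matches_statsmodels_wls_oracle(self, rng):
        import statsmodels.api as sm

        for _ in range(200):
            h = random_harmonized(rng, k=int(rng.integers(5, 20)))
            f = egger(h)
            sign = np.where(h.rows["beta_exp"] < 0, -1.0, 1.0)
            x = (h.rows["beta_exp"] * sign).to_numpy()
            y = (h.rows["beta_out"] * sign).to_numpy()
            w = 1.0 / h.rows["se_out"].to_numpy() ** 2
            res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
            assert f.beta == pytest.approx(res.params[1], abs=1e-10)
            assert f.egger_intercept == pytest.approx(res.params[0], abs=1e-10)
            # se comparable when the residual inflation is not floored
            if res.mse_resid >= 1.0:
                assert f.se == pytest.approx(res.bse[1], rel=1e-8)

    def test_orientation_invariance(self, rng):
        h = random_harmonized(rng, k=10)
        f1 = egger(h)
        h.rows.loc[2, ["beta_exp", "beta_out"]] *= -1
        f2 = egger(h)
        assert f1.beta == pytest.approx(f2.beta, abs=1e-12)
        assert f1.egger_intercept == pytest.approx(f2.egger_intercept, abs=1e-12)

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_harmonized([0.1, 0.2], [0.05, 0.1]))


def _wm_oracle(ratio, weight):
    order = np.argsort(ratio)
    r, w = np.asarray(ratio, float)[order], np.asarray(weight, float)[order]
    s = (np.cumsum(w) - w / 2) / w.sum()
    return float(np.interp(0.5, s, r))


class TestWeightedMedian:
    def test_equal_weights_take_middle_ratio(self):
        f = weighted_median(make_harmonized([1, 1, 1], [0.1, 0.2, 0.3], se_out=[0.1] * 3),
                            n_boot=100, seed=1)
        assert f.beta == pytest.approx(0.2)

    def test_all_equal_ratios_return_that_value(self):
        f = weighted_median(make_harmonized([0.1, 0.2, 0.4], [0.05, 0.1, 0.2]),
                            n_boot=100, seed=1)
        assert f.beta == pytest.approx(0.5)

    def test_resists_minority_outliers(self):
        # 4 concordant ratios with dominant weight, 3 shifted outliers
        beta_exp = np.array([1, 1, 1, 1, 1, 1, 1], float)
        beta_out = np.array([0.20, 0.21, 0.19, 0.20, 2.0, 2.1, 1.9])
        se_out = np.array([0.01, 0.01, 0.01, 0.01, 0.2, 0.2, 0.2])
        f = weighted_median(make_harmonized(beta_exp, beta_out, se_out=se_out),
                            n_boot=100, seed=1)
        assert 0.18 < f.beta < 0.22

    def test_majority_weight_instrument_wins(self):
        beta_exp = np.array([1.0, 1.0, 1.0])
        beta_out = np.array([0.5, 0.1, 0.9])
        se_out = np.array([0.001, 1.0, 1.0])  # first carries >50% of weight
        f = weighted_median(make_harmonized(beta_exp, beta_out, se_out=se_out),
                            n_boot=100, seed=1)
        assert f.beta == pytest.approx(0.5, abs=1e-6)

    def test_matches_interpolation_oracle(self, rng):
        for _ in range(200):
            h = random_harmonized(rng)
            f = weighted_median(h, n_boot=10, seed=3)
            r = (h.rows["beta_out"] / h.rows["beta_exp"]).to_numpy()
            w = ((h.rows["beta_exp"].abs() / h.rows["se_out"]) ** 2).to_numpy()
            assert f.beta == pytest.approx(_wm_oracle(r, w), abs=1e-12)

    def test_bootstrap_reproducible_for_fixed_seed(self, rng):
        h = random_harmonized(rng, k=6)
        f1 = weighted_median(h, n_boot=200, seed=7)
        f2 = weighted_median(h, n_boot=200, seed=7)
        assert f1.se == f2.se


class TestLeaveOneOut:
    def test_two_instruments_give_single_wald_fits(self):
        fits = leave_one_out(make_harmonized([0.1, 0.2], [0.05, 0.1]))
        assert len(fits) == 2
        assert all(f.method == "wald_single" for _, f in fits)

    def test_homogeneous_data_gives_identical_fits(self):
        h = make_harmonized([0.1, 0.2, 0.4, 0.8], [0.05, 0.1, 0.2, 0.4])
        full = ivw(h)
        for _, f in leave_one_out(h):
            assert f.beta == pytest.approx(full.beta, abs=1e-12)

    def test_outlier_exclusion_moves_estimate_most(self, rng):
        h = random_harmonized(rng, k=10)
        h.rows.loc[4, "beta_out"] += 0.5  # gross outlier
        full = ivw(h, model="fixed")
        deltas = {vid: abs(f.beta - full.beta) for vid, f in leave_one_out(h, model="fixed")}
        assert max(deltas, key=deltas.get) == "rs5"

    def test_matches_independent_recomputation(self, rng):
        h = random_harmonized(rng, k=7)
        for vid, f in leave_one_out(h, model="fixed"):
            sub = h.drop([vid])
            r = sub.rows["beta_out"] / sub.rows["beta_exp"]
            w = (sub.rows["beta_exp"].abs() / sub.rows["se_out"]) ** 2
            assert f.beta == pytest.approx(float((w * r).sum() / w.sum()), abs=1e-12)


class TestOddsRatio:
    @pytest.mark.parametrize(
        "beta,expected",
        [(0.0, 1.000), (-0.193, 0.824), (0.072, 1.075), (-0.211, 0.810), (-0.153, 0.858)],
    )
    def test_published_spot_checks(self, beta, expected):
        or_, _, _ = to_odds_ratio(beta, 0.05)
        assert round(or_, 3) == expected

    def test_log_identity(self, rng):
        for or_true in rng.uniform(0.2, 5.0, 20):
            or_, _, _ = to_odds_ratio(np.log(or_true), 0.1)
            assert or_ == pytest.approx(or_true, rel=1e-12)

    def test_ci_uses_exact_normal_quantile(self):
        or_, lo, hi = to_odds_ratio(0.0, 1.0)
        z = stats.norm.ppf(0.975)
        assert hi == pytest.approx(np.exp(z))
        assert lo == pytest.approx(np.exp(-z))


class TestTau2:
    def test_zero_for_homogeneous_effects(self):
        y = np.full(6, 0.3)
        v = np.full(6, 0.01)
        assert tau2_reml(y, v) == 0.0

    def test_satisfies_reml_fixed_point(self, rng):
        y = rng.normal(0.2, 0.3, 12)
        v = rng.uniform(0.005, 0.02, 12)
        tau2 = tau2_reml(y, v)
        w = 1 / (v + tau2)
        mu = np.sum(w * y) / np.sum(w)
        rhs = np.sum(w**2 * ((y - mu) ** 2 - v)) / np.sum(w**2) + 1 / np.sum(w)
        assert tau2 == pytest.approx(max(0.0, rhs), abs=1e-8)

    def test_close_to_statsmodels_dl_under_moderate_heterogeneity(self, rng):
        from statsmodels.stats.meta_analysis import effectsize_smd  # noqa: F401  (env check)
        from statsmodels.stats.meta_analysis import combine_effects

        y = rng.normal(0.2, 0.15, 20)
        v = rng.uniform(0.004, 0.01, 20)
        res = combine_effects(y, v, method_re="dl")
        # REML and DL agree on order of magnitude on well-behaved data
        assert tau2_reml(y, v) == pytest.approx(res.tau2, rel=0.5, abs=0.01)
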