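"""Turgor balance, decline calibration LMM, and rate contrasts."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

import budhydro as bh
from budhydro.simulate import simulate_decline_table
from budhydro.water import DeclineCalibration, RateTrendModel, pearson, turgor


class TestTurgor:
    def test_severe_drought_differential(self):
        assert turgor(-2.09, -5.63) == pytest.approx(3.54, abs=1e-12)

    def test_minimum_differential(self):
        assert turgor(-0.5, -1.42) == pytest.approx(0.92, abs=1e-12)

    def test_equal_potentials_zero(self):
        assert turgor(-1.3, -1.3) == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(
        st.floats(-10, -1e-6, allow_nan=False),
        st.floats(-10, -1e-6, allow_nan=False),
    )
    def test_antisymmetry(self, a, b):
        assert turgor(a, b) == pytest.approx(-turgor(b, a))

    def test_positive_potential_rejected(self):
        with pytest.raises(ValueError, match="<= 0"):
            turgor(0.5, -1.0)
        with pytest.raises(ValueError, match="finite"):
            turgor(np.nan, -1.0)


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        r, p = pearson(x, 2 * x)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_perfect_negative(self):
        x = np.arange(10.0)
        r, _ = pearson(x, -x + 3)
        assert r == pytest.approx(-1.0)

    def test_independent_null(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(10_000), rng.standard_normal(10_000)
        r, _ = pearson(x, y)
        assert abs(r) < 0.05

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson(np.ones(5), np.arange(5.0))


class TestDeclineCalibration:
    def test_zero_day_variance_matches_ols(self):
        rng = np.random.default_rng(1)
        tab = simulate_decline_table(rng, sigma_day=0.0, sigma=0.4)
        fit = bh.fit_decline_lmm(tab)
        ols = sm.OLS(
            tab["psi_x"], sm.add_constant(tab["mean_stem_decline"])
        ).fit()
        assert fit.slope_ == pytest.approx(ols.params.iloc[1], abs=0.01)
        assert fit.r2_marginal_ == pytest.approx(fit.r2_conditional_, abs=0.03)

    def test_conditional_r2_never_below_marginal(self):
        for seed in range(5):
            tab = simulate_decline_table(seed)
            fit = bh.fit_decline_lmm(tab, ci_method="wald")
            assert fit.r2_conditional_ >= fit.r2_marginal_ - 1e-12
            assert fit.var_day_ >= 0 and fit.var_resid_ > 0

    def test_profile_ci_brackets_estimate(self):
        fit = bh.fit_decline_lmm(simulate_decline_table(2))
        lo, hi = fit.slope_ci_
        assert lo < fit.slope_ < hi

    def test_wald_flag(self):
        tab = simulate_decline_table(3)
        w = bh.fit_decline_lmm(tab, ci_method="wald")
        p = bh.fit_decline_lmm(tab, ci_method="profile")
        assert w.slope_ci_[0] < w.slope_ < w.slope_ci_[1]
        # both intervals agree to first order on a well-behaved dataset
        assert w.slope_ci_[0] == pytest.approx(p.slope_ci_[0], abs=0.05)

    def test_constant_decline_rejected(self):
        tab = simulate_decline_table(4, day_declines={27: 5.0, 34: 5.0, 41: 5.0})
        with pytest.raises(ValueError, match="constant"):
            bh.fit_decline_lmm(tab)

    def test_summary_dataclass_roundtrip(self):
        s = bh.fit_decline_lmm(simulate_decline_table(5)).summary()
        assert s.drop_per_percent == abs(s.slope)
        assert s.n_obs == 60


def _rate_table(rng, slopes, intercepts, days=(20, 27, 34, 41, 48, 50), n=15, sigma=0.25):
    rows = []
    for (measure, treatment), b in slopes.items():
        a = intercepts[(measure, treatment)]
        for day in days:
            vals = a + b * (day - 27.0) + rng.normal(0, sigma, size=n)
            for i, v in enumerate(vals):
                rows.append((f"P{treatment}{day}-{i}", float(day), treatment, measure, v, 1))
    return pd.DataFrame(
        rows, columns=["plant_id", "day", "treatment", "measure", "value", "pool_size"]
    )


class TestRateTrendModel:
    def test_intercept_is_day27_prediction(self):
        rng = np.random.default_rng(6)
        tab = _rate_table(
            rng,
            {("psi_x", "D"): -0.05, ("pi_bud", "D"): -0.11},
            {("psi_x", "D"): -0.9, ("pi_bud", "D"): -2.6},
        )
        model = bh.fit_rate_models(tab, center_day=27.0)
        for _, row in model.group_fits_.iterrows():
            grp = tab[(tab["measure"] == row["measure"]) & (tab["treatment"] == row["treatment"])]
            ols = sm.OLS(grp["value"], sm.add_constant(grp["day"] - 27.0)).fit()
            assert row["intercept"] == pytest.approx(ols.params.iloc[0])
            assert row["slope"] == pytest.approx(ols.params.iloc[1])

    def test_equal_slopes_not_flagged(self):
        rng = np.random.default_rng(7)
        tab = _rate_table(
            rng,
            {("psi_x", "W"): -0.01, ("pi_leaf", "W"): -0.01},
            {("psi_x", "W"): -0.6, ("pi_leaf", "W"): -1.0},
        )
        model = bh.fit_rate_models(tab)
        assert (model.slope_contrasts_["p_adj"] > 0.05).all()

    def test_widening_gap_flags_bud_vs_xylem_slopes(self):
        # the gap widens only while drought progresses, so the power check
        # runs on the pre-rehydration sampling days
        cfg = bh.ScenarioConfig(rng_seed=8)
        water, _ = bh.simulate_water_status(cfg)
        model = bh.fit_rate_models(water, day_range=(20, 48))
        row = model.slope_contrasts_.set_index("contrast").loc["pi_bud:D - psi_x:D"]
        assert row["significant"]
        # and the day-27 baselines differ too
        irow = model.intercept_contrasts_.set_index("contrast").loc["pi_bud:D - psi_x:D"]
        assert irow["significant"]

    def test_too_few_days_rejected(self):
        rng = np.random.default_rng(9)
        tab = _rate_table(
            rng,
            {("psi_x", "D"): -0.05, ("pi_bud", "D"): -0.1},
            {("psi_x", "D"): -0.9, ("pi_bud", "D"): -2.6},
            days=(27, 34),
        )
        with pytest.raises(ValueError, match="fewer than three"):
            bh.fit_rate_models(tab)

    def test_random_intercept_flag(self):
        rng = np.random.default_rng(10)
        tab = _rate_table(
            rng,
            {("psi_x", "D"): -0.05, ("pi_bud", "D"): -0.1},
            {("psi_x", "D"): -0.9, ("pi_bud", "D"): -2.6},
        )
        model = RateTrendModel(random_intercept=True).fit(tab)
        assert len(model.group_fits_) == 2

    def test_pipeline_scenario_turgor_floor(self):
        # day-level mean turgor of the droughted cohort never falls below
        # the configured differential by more than sampling noise allows
        cfg = bh.ScenarioConfig(rng_seed=11)
        water, truth = bh.simulate_water_status(cfg)
        means = (
            water[water["treatment"] == "D"]
            .groupby(["day", "measure"])["value"]
            .mean()
            .unstack()
        )
        pt = means["psi_x"] - means["pi_bud"]
        offsets = (
            truth.water_status_means.query("treatment == 'D'")
            .pivot(index="day", columns="measure", values="mean")
            .pipe(lambda w: w["psi_x"] - w["pi_bud"])
        )
        n_pools = 3
        se = np.sqrt(
            cfg.psi_noise_sd**2 / cfg.n_peripheral_per_timepoint
            + cfg.bud_noise_sd**2 / (cfg.bud_pool_size * n_pools)
        )
        assert ((pt - offsets) >= -3 * se).all()
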