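"""Hierarchical sigmoid lag model: identities, bookkeeping, inference."""

import numpy as np
import pandas as pd
import pytest

import budhydro as bh
from budhydro.lag import THETA_NAMES, build_model, sigmoid

from conftest import sigmoid_windows


class TestSigmoidIdentities:
    def test_midpoint_value(self):
        A, B, C, D = 120.0, 0.15, 4.0, -30.0
        assert sigmoid(C, A, B, C, D) == pytest.approx(A / 2 + D)

    def test_asymptotic_limits(self):
        A, B, C, D = 120.0, 0.15, 4.0, -30.0
        assert sigmoid(-1e6, A, B, C, D) == pytest.approx(A + D)
        assert sigmoid(1e6, A, B, C, D) == pytest.approx(D)

    def test_sign_reflection_family(self):
        # (A, B, C, D) and (-A, -B, C, D+A) trace the same curve
        t = np.linspace(-60, 60, 25)
        np.testing.assert_allclose(
            sigmoid(t, 120.0, 0.15, 4.0, -30.0),
            sigmoid(t, -120.0, -0.15, 4.0, -30.0 + 120.0),
        )

    def test_monotone_between_levels(self):
        t = np.linspace(-60, 60, 200)
        f = sigmoid(t, 120.0, 0.15, 0.0, -30.0)
        assert (np.diff(f) < 0).all()  # B>0, A>0: day transition drops


class TestBuildModel:
    def test_group_bookkeeping(self, windows_lag0):
        blocks = build_model(windows_lag0)
        assert set(blocks) == {"dawn", "dusk"}
        for data in blocks.values():
            for tissue in ("bud", "stem"):
                plants, days = data.labels[tissue]
                assert len(plants) == 5 and len(days) == 7
                assert data.Y[tissue].shape == (5, 7, 25)

    def test_single_tissue_rejected(self, windows_lag0):
        with pytest.raises(ValueError, match="both tissues"):
            build_model(windows_lag0[windows_lag0["tissue"] == "stem"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no transition windows"):
            build_model(pd.DataFrame(columns=["transition_type", "tissue", "t", "y"]))


class TestLikelihoodSymmetries:
    @pytest.fixture(scope="class")
    def small_windows(self):
        return sigmoid_windows(np.random.default_rng(5), n_plants=2, n_days=3, C_bud=6.0)

    def test_translation_equivariance(self, small_windows):
        model = bh.SigmoidLagModel()
        delta = 7.0
        shifted = small_windows.assign(t=small_windows["t"] + delta)
        d0 = build_model(small_windows)["dawn"]
        d1 = build_model(shifted)["dawn"]
        theta = np.array([0.15, 6.0, 0.0, np.log(5.0), np.log(4.0), np.log(2.0)])
        theta_shift = theta.copy()
        theta_shift[1] += delta
        theta_shift[2] += delta
        assert model._log_likelihood(theta, d0) == pytest.approx(
            model._log_likelihood(theta_shift, d1), rel=1e-12
        )

    def test_tissue_swap_negates_lag(self, small_windows):
        model = bh.SigmoidLagModel()
        swapped = small_windows.assign(
            tissue=small_windows["tissue"].map({"bud": "stem", "stem": "bud"})
        )
        d0 = build_model(small_windows)["dawn"]
        d1 = build_model(swapped)["dawn"]
        theta = np.array([0.15, 6.0, -2.0, np.log(5.0), np.log(4.0), np.log(2.0)])
        theta_swapped = theta.copy()
        theta_swapped[1], theta_swapped[2] = theta[2], theta[1]
        assert model._log_likelihood(theta, d0) == pytest.approx(
            model._log_likelihood(theta_swapped, d1), rel=1e-12
        )


class TestInference:
    def test_noiseless_parameter_recovery(self):
        truth = dict(A=120.0, B=0.15, C_bud=8.0, C_stem=8.0, D=-30.0)
        win = sigmoid_windows(
            np.random.default_rng(8),
            sigma=0.5,
            tau_A=0.1,
            tau_D=0.1,
            **truth,
        )
        model = bh.SigmoidLagModel(chains=2, iterations=1000, warmup=400, seed=4)
        model.fit(win)
        draws = model.theta_draws("dawn")
        assert draws["B"].mean() == pytest.approx(truth["B"], rel=0.02)
        assert draws["C_bud"].mean() == pytest.approx(truth["C_bud"], rel=0.02)
        assert draws["C_stem"].mean() == pytest.approx(truth["C_stem"], rel=0.02)
        betas = model.conditional_linear_draws("dawn", n_draws=100, seed=1)
        per_group = betas.groupby(["plant_id", "tissue"])[["A", "D"]].mean()
        # fixed A/D per plant-tissue were jittered around the population mean
        # with sd 5 and 3; posterior means must land near the truth
        assert per_group["A"].mean() == pytest.approx(truth["A"], rel=0.05)
        assert per_group["D"].mean() == pytest.approx(truth["D"], rel=0.05)

    def test_flat_data_leaves_midpoint_at_prior(self):
        win = sigmoid_windows(
            np.random.default_rng(9), n_plants=2, n_days=3, A=0.0, sigma=5.0
        )
        model = bh.SigmoidLagModel(chains=2, iterations=800, warmup=300, seed=5)
        model.fit(win)
        est = model.lag_["dawn"]
        # amplitude zero: C is non-identified, so the interval stays an
        # order of magnitude wider than an identified fit (~1-2 min)
        assert est.ci_high - est.ci_low > 20.0

    def test_single_day_degenerate_still_proper(self):
        win = sigmoid_windows(np.random.default_rng(10), n_plants=2, n_days=1)
        model = bh.SigmoidLagModel(chains=2, iterations=600, warmup=250, seed=6)
        model.fit(win)
        assert np.isfinite(model.lag_["dawn"].mean)
        draws = model.theta_draws("dawn")
        # day-level variances pinned near zero by the half-normal prior
        assert np.exp(draws["log_tau_A"]).median() < 15.0

    def test_lag_zero_when_midpoints_identical(self):
        # degenerate posterior: identical C draws per tissue imply lag 0
        model = bh.SigmoidLagModel()
        samples = np.zeros((2, 50, len(THETA_NAMES)))
        samples[:, :, 1] = 3.0
        samples[:, :, 2] = 3.0
        model.samples_ = {"dawn": samples}
        flat = samples.reshape(-1, len(THETA_NAMES))
        draws = flat[:, 1] - flat[:, 2]
        assert draws.mean() == 0.0 and np.percentile(draws, [2.5, 97.5]).tolist() == [0.0, 0.0]


class TestPosteriorPredictive:
    @pytest.fixture(scope="class")
    def fitted(self):
        win = sigmoid_windows(np.random.default_rng(11), n_plants=3, n_days=4, sigma=5.0)
        model = bh.SigmoidLagModel(chains=2, iterations=800, warmup=300, seed=7)
        return model.fit(win), win

    def test_self_consistency_coverage(self, fitted):
        model, _ = fitted
        out = model.posterior_predictive_check("dawn", n_draws=200, seed=2)
        assert not out["degenerate"]
        assert 0.90 <= out["coverage95"] <= 0.99
        assert 0.05 < out["p_sd"] < 0.95

    def test_outliers_degrade_coverage(self, fitted):
        model, win = fitted
        corrupted = win.copy()
        rng = np.random.default_rng(3)
        idx = rng.choice(len(corrupted), size=len(corrupted) // 10, replace=False)
        corrupted.loc[corrupted.index[idx], "y"] += rng.choice([-80, 80], size=idx.size)
        m2 = bh.SigmoidLagModel(chains=2, iterations=800, warmup=300, seed=8)
        m2.fit(corrupted)
        out = m2.posterior_predictive_check("dawn", n_draws=200, seed=2)
        base = model.posterior_predictive_check("dawn", n_draws=200, seed=2)
        assert out["coverage95"] < base["coverage95"]

    def test_zero_variance_data_flagged(self):
        t = np.arange(-60.0, 61.0, 5.0)
        rows = []
        for tissue in ("bud", "stem"):
            for day in (17, 18):
                rows.append(
                    pd.DataFrame(
                        {
                            "plant_id": "D1",
                            "tissue": tissue,
                            "transition_type": "dawn",
                            "day": day,
                            "t": t,
                            "y": 50.0,
                        }
                    )
                )
        win = pd.concat(rows, ignore_index=True)
        model = bh.SigmoidLagModel(chains=2, iterations=400, warmup=150, seed=9)
        model.fit(win)
        out = model.posterior_predictive_check("dawn", n_draws=50, seed=0)
        assert out["degenerate"]
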