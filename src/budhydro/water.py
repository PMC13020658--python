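"""Water relations: turgor balance, decline-to-potential calibration, and
osmotic-adjustment rate contrasts.

Tissue turgor follows the pressure balance ``P_t = Psi_x - Pi`` (MPa): a
cell's hydrostatic pressure is the difference between the xylem water
potential it equilibrates with and its own osmotic potential. The
calibration model regresses peripheral-plant predawn Psi_x on the sentinel
stems' mean daily area decline (a positive percentage below the
pre-rehydration maximum) with a random intercept per measurement day, and
reports the fixed-effect slope as "MPa drop per 1% decline" together with
marginal/conditional R-squared by the standard variance-partition
decomposition. Daily rates of change of Psi_x, Pi_L and Pi_B are compared
across tissues and treatments with Tukey-adjusted pairwise slope and
day-27 intercept contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "turgor",
    "pearson",
    "DeclineCalibration",
    "fit_decline_lmm",
    "RateTrendModel",
    "fit_rate_models",
]

_CHI2_95_1DF = stats.chi2.ppf(0.95, 1)


def turgor(psi_x: float, pi_b: float) -> float:
    """Turgor pressure P_t = Psi_x - Pi (MPa).

    Both arguments are water/osmotic potentials and must be non-positive;
    a negative result is a valid, reportable turgor-loss state.
    """
    psi_x = float(psi_x)
    pi_b = float(pi_b)
    if not (np.isfinite(psi_x) and np.isfinite(pi_b)):
        raise ValueError("potentials must be finite")
    if psi_x > 0 or pi_b > 0:
        raise ValueError("potentials are tensions and must be <= 0 MPa")
    return psi_x - pi_b


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided p-value (t transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least three observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has undefined correlation")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class LmmFit:
    """Summary of the decline-to-Psi_x mixed-model calibration."""

    slope: float  # signed: MPa per +1% decline (negative)
    drop_per_percent: float  # |slope|, "MPa drop per 1% decline"
    slope_ci: tuple
    intercept: float
    var_day: float
    var_resid: float
    r2_marginal: float
    r2_conditional: float
    pearson_r: float
    pearson_p: float
    singular: bool
    n_obs: int


class DeclineCalibration(BaseEstimator):
    """Linear mixed model Psi_x ~ stem decline with a day random intercept.

    ``fit(X, y, groups)`` takes the positive percentage decline (day-level
    covariate), the peripheral-plant Psi_x values (MPa) and the measurement
    day of each observation. REML estimation for the point estimates and
    variance components.

    The default slope CI (``ci_method="between-day"``) exploits the fact
    that a day-level covariate makes slope inference a regression of day
    means on day declines: the exact t interval on m-2 df is calibrated
    even at a handful of measurement days, where likelihood-based
    intervals undercover badly whenever the day-variance estimate hits the
    zero boundary. ``"profile"`` (profile ML deviance with a
    Satterthwaite-df cutoff) and ``"wald"`` (Satterthwaite-df t Wald) are
    available by flag.
    """

    def __init__(self, ci_method: str = "between-day", reml: bool = True):
        self.ci_method = ci_method
        self.reml = reml

    def fit(self, X, y, groups=None):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if groups is None:
            raise ValueError("day grouping labels are required")
        groups = np.asarray(groups)
        if not (x.size == y.size == groups.size):
            raise ValueError("X, y and groups must align")
        if np.unique(groups).size < 2:
            raise ValueError("need at least two measurement days")
        for g in np.unique(groups):
            if (groups == g).sum() < 2:
                raise ValueError("need at least two observations per day")
        if np.ptp(x) == 0:
            raise ValueError("decline is constant; slope is not identifiable")
        exog = sm.add_constant(x)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model = MixedLM(y, exog, groups=groups)
            res = model.fit(reml=self.reml)
        self.singular_ = any(
            "singular" in str(w.message).lower() or "boundary" in str(w.message).lower()
            for w in caught
        ) or float(np.asarray(res.cov_re)[0, 0]) < 1e-8
        self.result_ = res
        self.intercept_ = float(res.fe_params[0])
        self.slope_ = float(res.fe_params[1])
        self.var_day_ = float(np.asarray(res.cov_re)[0, 0])
        self.var_resid_ = float(res.scale)
        var_fixed = float(np.var(exog @ res.fe_params))
        total = var_fixed + self.var_day_ + self.var_resid_
        self.r2_marginal_ = var_fixed / total
        self.r2_conditional_ = (var_fixed + self.var_day_) / total
        self.pearson_r_, self.pearson_p_ = pearson(x, y)
        # Satterthwaite effective df for the day-level slope: with the
        # covariate constant within days, the slope variance mixes the
        # day-intercept variance (df = m-2) with the averaged residual
        # variance (df = N-m-1); a normal/chi-square quantile would
        # undercover badly at a handful of days.
        m = int(np.unique(groups).size)
        n_bar = x.size / m
        a = self.var_day_
        b = self.var_resid_ / n_bar
        df_day = max(m - 2, 1)
        df_res = max(x.size - m - 1, 1)
        if a + b <= 0:
            self.df_satterthwaite_ = float(df_res)
        else:
            self.df_satterthwaite_ = float(
                (a + b) ** 2 / (a**2 / df_day + b**2 / df_res)
            )
        if self.ci_method == "wald":
            se = float(np.asarray(res.bse)[1])
            tq = stats.t.ppf(0.975, self.df_satterthwaite_)
            self.slope_ci_ = (self.slope_ - tq * se, self.slope_ + tq * se)
        elif self.ci_method == "profile":
            self.slope_ci_ = self._profile_ci(x, y, groups)
        elif self.ci_method == "between-day":
            self.slope_ci_ = self._between_day_ci(x, y, groups)
        else:
            raise ValueError(f"unknown ci_method: {self.ci_method}")
        self._x, self._y, self._groups = x, y, groups
        self.n_obs_ = int(x.size)
        return self

    def _between_day_ci(self, x, y, groups) -> tuple:
        """Exact t interval from the regression of day means on day declines.

        Day means carry iid errors u_j + mean(eps)_j under the model, so
        OLS on the m aggregated points gives an exact t(m-2) interval for
        the slope. Falls back to the Satterthwaite Wald interval when fewer
        than three days leave no residual df.
        """
        days = np.unique(groups)
        if days.size < 3:
            se = float(np.asarray(self.result_.bse)[1])
            tq = stats.t.ppf(0.975, self.df_satterthwaite_)
            return (self.slope_ - tq * se, self.slope_ + tq * se)
        xm = np.array([x[groups == d].mean() for d in days])
        ym = np.array([y[groups == d].mean() for d in days])
        m = days.size
        X = np.column_stack([np.ones(m), xm])
        beta, *_ = np.linalg.lstsq(X, ym, rcond=None)
        resid = ym - X @ beta
        s2 = float(resid @ resid) / (m - 2)
        sxx = float(((xm - xm.mean()) ** 2).sum())
        se = np.sqrt(s2 / sxx)
        tq = stats.t.ppf(0.975, m - 2)
        return (float(beta[1] - tq * se), float(beta[1] + tq * se))

    def _profile_deviance(self, b1: float, x, y, groups) -> float:
        """-2 log ML with the slope fixed at b1 (offset refit)."""
        endog = y - b1 * x
        ones = np.ones((y.size, 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            llf = np.nan
            for method in (None, "lbfgs", "cg"):
                try:
                    kw = {} if method is None else {"method": method}
                    res = MixedLM(endog, ones, groups=groups).fit(reml=False, **kw)
                    llf = float(res.llf)
                except Exception:
                    continue
                if np.isfinite(llf):
                    break
        if not np.isfinite(llf):
            # optimiser failure far from the optimum: treat as beyond the CI
            return 1e10
        return -2.0 * llf

    def _profile_ci(self, x, y, groups) -> tuple:
        dev = lambda b: self._profile_deviance(b, x, y, groups)
        se = max(float(np.asarray(self.result_.bse)[1]), 1e-6)
        opt = optimize.minimize_scalar(
            dev, bounds=(self.slope_ - 4 * se, self.slope_ + 4 * se), method="bounded"
        )
        b_ml, dev_min = float(opt.x), float(opt.fun)
        # small-sample cutoff: squared t quantile at the Satterthwaite df
        # (reduces to the chi-square 3.84 as df -> infinity)
        cutoff = float(stats.t.ppf(0.975, self.df_satterthwaite_) ** 2)
        target = dev_min + cutoff

        def edge(direction: float) -> float:
            step = se
            b = b_ml
            for _ in range(60):
                b = b + direction * step
                if dev(b) > target:
                    return float(
                        optimize.brentq(
                            lambda v: dev(v) - target, min(b_ml, b), max(b_ml, b), xtol=1e-5
                        )
                    )
                step *= 1.6
            raise RuntimeError("profile CI bound not found")

        return (edge(-1.0), edge(+1.0))

    def predict(self, X):
        check_is_fitted(self, "slope_")
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.slope_ * x

    def summary(self) -> LmmFit:
        check_is_fitted(self, "slope_")
        return LmmFit(
            slope=self.slope_,
            drop_per_percent=abs(self.slope_),
            slope_ci=self.slope_ci_,
            intercept=self.intercept_,
            var_day=self.var_day_,
            var_resid=self.var_resid_,
            r2_marginal=self.r2_marginal_,
            r2_conditional=self.r2_conditional_,
            pearson_r=self.pearson_r_,
            pearson_p=self.pearson_p_,
            singular=self.singular_,
            n_obs=self.n_obs_,
        )


def fit_decline_lmm(table: pd.DataFrame, ci_method: str = "profile") -> DeclineCalibration:
    """Fit the calibration from a tidy decline table.

    ``table`` needs columns ``day``, ``mean_stem_decline`` (positive %),
    ``psi_x`` (MPa).
    """
    return DeclineCalibration(ci_method=ci_method).fit(
        table["mean_stem_decline"], table["psi_x"], groups=table["day"]
    )


class RateTrendModel(BaseEstimator):
    """Daily rates of change of water-status measures with Tukey contrasts.

    One linear model of value (MPa) versus day per (measure, treatment)
    group, reparameterised so the intercept is the predicted mean at
    ``center_day``. Peripheral plants are new at every timepoint, so the
    default is an ordinary regression per group;
    ``random_intercept=True`` adds a per-plant/pool random intercept
    (requires a ``plant_id`` column). All pairwise slope differences and
    center-day intercept differences are reported with Tukey-style
    (studentized-range) adjusted p-values over the family of groups.
    """

    def __init__(
        self,
        center_day: float = 27.0,
        alpha: float = 0.05,
        random_intercept: bool = False,
        day_range: tuple | None = None,
    ):
        self.center_day = center_day
        self.alpha = alpha
        self.random_intercept = random_intercept
        self.day_range = day_range

    def fit(self, X: pd.DataFrame, y=None):
        df = X
        required = {"day", "treatment", "measure", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"table must have columns {sorted(required)}")
        if self.day_range is not None:
            lo, hi = self.day_range
            df = df[(df["day"] >= lo) & (df["day"] <= hi)]
            if df.empty:
                raise ValueError("day_range excludes every observation")
        fits = []
        for (measure, treatment), grp in df.groupby(["measure", "treatment"], sort=True):
            if grp["day"].nunique() < 3:
                raise ValueError(
                    f"group {measure}/{treatment} has fewer than three sampling days"
                )
            day_c = grp["day"].to_numpy(dtype=float) - self.center_day
            exog = sm.add_constant(day_c)
            vals = grp["value"].to_numpy(dtype=float)
            if self.random_intercept:
                if "plant_id" not in grp.columns:
                    raise ValueError("random_intercept=True requires a plant_id column")
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = MixedLM(vals, exog, groups=grp["plant_id"]).fit(reml=True)
                df_resid = res.nobs - 2
            else:
                res = sm.OLS(vals, exog).fit()
                df_resid = res.df_resid
            se = res.bse
            fits.append(
                {
                    "measure": measure,
                    "treatment": treatment,
                    "group": f"{measure}:{treatment}",
                    "intercept": float(res.params[0]),
                    "intercept_se": float(se[0]),
                    "slope": float(res.params[1]),
                    "slope_se": float(se[1]),
                    "df_resid": float(df_resid),
                    "n_obs": int(len(grp)),
                }
            )
        if len(fits) < 2:
            raise ValueError("need at least two groups to contrast")
        self.group_fits_ = pd.DataFrame(fits)
        self.slope_contrasts_ = self._contrast("slope")
        self.intercept_contrasts_ = self._contrast("intercept")
        return self

    def _contrast(self, what: str) -> pd.DataFrame:
        g = self.group_fits_
        k = len(g)
        rows = []
        for i in range(k):
            for j in range(i + 1, k):
                est = g[what].iloc[i] - g[what].iloc[j]
                se_i, se_j = g[f"{what}_se"].iloc[i], g[f"{what}_se"].iloc[j]
                se = np.hypot(se_i, se_j)
                tval = est / se
                df_w = (se_i**2 + se_j**2) ** 2 / (
                    se_i**4 / g["df_resid"].iloc[i] + se_j**4 / g["df_resid"].iloc[j]
                )
                p_adj = float(
                    stats.studentized_range.sf(np.sqrt(2.0) * abs(tval), k, df_w)
                )
                rows.append(
                    {
                        "contrast": f"{g['group'].iloc[i]} - {g['group'].iloc[j]}",
                        "estimate": float(est),
                        "se": float(se),
                        "t": float(tval),
                        "df": float(df_w),
                        "p_adj": min(p_adj, 1.0),
                        "significant": p_adj < self.alpha,
                    }
                )
        return pd.DataFrame(rows)


def fit_rate_models(table: pd.DataFrame, center_day: float = 27.0, **kw) -> RateTrendModel:
    """Fit per-group day trends and Tukey-adjusted pairwise contrasts."""
    return RateTrendModel(center_day=center_day, **kw).fit(table)
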