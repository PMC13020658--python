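"""Growth-trend removal and dawn/dusk window extraction.

A rank-3 thin-plate regression spline of time is fit by ordinary least
squares to each relative-area series; with only three basis functions the
fit can follow the slow growth trend but not the 24-h turgor oscillation,
which therefore survives in the residuals. Residuals within +/-1 h of the
dawn and dusk light transitions are then cut into per-day windows and
rescaled to a percentage of the window-set maximum per plant-tissue.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .config import parse_clock

__all__ = ["SplineTrend", "fit_trend", "residuals", "extract_windows", "residual_frame"]


class SplineTrend(RegressorMixin, BaseEstimator):
    """Low-rank thin-plate smoothing spline of time, fit unpenalized.

    The basis is the span of the polynomial null space {1, t} plus the
    leading eigenvectors of the radial kernel ``|t - k|^3`` evaluated at
    ``n_knots`` quantile knots — the standard low-rank thin-plate
    regression-spline construction. With ``n_basis=3`` (default) the single
    nonlinear basis function allows one slow bend, so the fit isolates the
    growth trend and leaves diurnal oscillation in the residual.

    Parameters
    ----------
    n_basis : int
        Total number of basis functions (>= 2); the first two span the
        affine null space.
    n_knots : int
        Number of knots for the low-rank eigenbasis.

    Attributes
    ----------
    coef_ : (n_basis,) fitted coefficients.
    edof_ : effective degrees of freedom (= rank of the design).
    fitted_values_ : fit at the training timestamps.
    """

    def __init__(self, n_basis: int = 3, n_knots: int = 50):
        self.n_basis = n_basis
        self.n_knots = n_knots

    def _basis(self, t: np.ndarray) -> np.ndarray:
        tt = (t - self.t_center_) / self.t_scale_
        cols = [np.ones_like(tt), tt]
        if self.n_basis > 2:
            E = np.abs(tt[:, None] - self.knots_[None, :]) ** 3
            cols.append(E @ self.eig_basis_)
        X = np.column_stack(cols) if self.n_basis > 2 else np.column_stack(cols)
        return X[:, : self.n_basis]

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if t.shape != y.shape:
            raise ValueError("time and value arrays must align")
        if self.n_basis < 2:
            raise ValueError("need at least the affine null space (n_basis >= 2)")
        if t.size < self.n_basis:
            raise ValueError("fewer observations than basis functions")
        self.t_center_ = float(t.mean())
        self.t_scale_ = float(t.std() or 1.0)
        tt = (t - self.t_center_) / self.t_scale_
        uniq = np.unique(tt)
        n_knots = min(self.n_knots, uniq.size)
        self.knots_ = np.quantile(uniq, np.linspace(0.0, 1.0, n_knots))
        if self.n_basis > 2:
            E = np.abs(self.knots_[:, None] - self.knots_[None, :]) ** 3
            w, v = np.linalg.eigh(E)
            order = np.argsort(np.abs(w))[::-1]
            self.eig_basis_ = v[:, order[: self.n_basis - 2]]
        else:
            self.eig_basis_ = np.empty((n_knots, 0))
        B = self._basis(t)
        # column scaling keeps the lstsq well conditioned
        self._col_norms_ = np.linalg.norm(B, axis=0)
        self._col_norms_[self._col_norms_ == 0] = 1.0
        coef, _, rank, _ = np.linalg.lstsq(B / self._col_norms_, y, rcond=None)
        self.coef_ = coef / self._col_norms_
        self.edof_ = int(rank)
        self.fitted_values_ = B @ self.coef_
        self.train_time_ = t
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        t = np.asarray(X, dtype=float).reshape(-1)
        return self._basis(t) @ self.coef_


def fit_trend(t, y, n_basis: int = 3) -> SplineTrend:
    """Fit the growth trend of one series; thin wrapper over SplineTrend."""
    return SplineTrend(n_basis=n_basis).fit(t, y)


def residuals(t, y, trend: SplineTrend) -> np.ndarray:
    """Observed minus fitted at every timestamp."""
    t = np.asarray(t, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if t.shape != y.shape:
        raise ValueError("time and value arrays must align")
    return y - trend.predict(t)


def residual_frame(
    df: pd.DataFrame,
    value_col: str = "relative_area",
    time_col: str = "age_days",
    n_basis: int = 3,
    day_range: tuple | None = None,
) -> pd.DataFrame:
    """Detrend every plant-tissue series of a tidy frame.

    Fits one spline per (plant_id, tissue) on ``day_range`` (inclusive of
    the start day, exclusive of end_day+1) and appends a ``residual``
    column.
    """
    out = []
    for (plant, tissue), grp in df.groupby(["plant_id", "tissue"], sort=True):
        grp = grp.sort_values(time_col)
        if day_range is not None:
            lo, hi = day_range
            grp = grp[(grp[time_col] >= lo) & (grp[time_col] < hi + 1)]
        if grp.empty:
            continue
        trend = fit_trend(grp[time_col].to_numpy(), grp[value_col].to_numpy(), n_basis)
        grp = grp.copy()
        grp["residual"] = grp[value_col].to_numpy() - trend.fitted_values_
        out.append(grp)
    if not out:
        raise ValueError("no series to detrend in the requested day range")
    return pd.concat(out, ignore_index=True)


def extract_windows(
    df: pd.DataFrame,
    lights_on: str = "08:30",
    lights_off: str = "20:30",
    span: float = 60.0,
    day_range: tuple = (17, 23),
    time_col: str = "age_days",
    value_col: str = "residual",
) -> pd.DataFrame:
    """Cut detrended residuals into per-day dawn/dusk transition windows.

    Returns a tidy frame (plant_id, tissue, transition_type, day, t, y)
    where ``t`` is minutes relative to the light transition (|t| <= span)
    and ``y`` is the residual as a percentage of the maximum residual over
    the full analysed window set of that plant-tissue (one shared scale for
    dawn and dusk, so max(y) = 100 per plant-tissue).
    """
    on_h, off_h = parse_clock(lights_on), parse_clock(lights_off)
    days = range(int(day_range[0]), int(day_range[1]) + 1)
    rows = []
    for (plant, tissue), grp in df.groupby(["plant_id", "tissue"], sort=True):
        t = grp[time_col].to_numpy(dtype=float)
        y = grp[value_col].to_numpy(dtype=float)
        pieces = []
        for day in days:
            for transition, clock_h in (("dawn", on_h), ("dusk", off_h)):
                center = day + clock_h / 24.0
                rel_min = (t - center) * 24.0 * 60.0
                # tolerance of a millminute absorbs float accumulation in
                # the time grid without ever admitting an extra 5-min sample
                sel = np.abs(rel_min) <= span + 1e-3
                if not sel.any():
                    raise ValueError(
                        f"empty {transition} window on day {day} for {plant}/{tissue}"
                    )
                pieces.append(
                    pd.DataFrame(
                        {
                            "plant_id": plant,
                            "tissue": tissue,
                            "transition_type": transition,
                            "day": day,
                            "t": np.round(rel_min[sel], 3),
                            "y": y[sel],
                        }
                    )
                )
        win = pd.concat(pieces, ignore_index=True)
        peak = win["y"].max()
        if peak <= 0:
            raise ValueError(
                f"non-positive residual maximum for {plant}/{tissue}; cannot rescale"
            )
        win["y"] = win["y"] / peak * 100.0
        rows.append(win)
    if not rows:
        raise ValueError("no plant-tissue series in input")
    return pd.concat(rows, ignore_index=True)
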