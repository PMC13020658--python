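"""Synthetic study generator.

Emulates the dual-cohort glasshouse design the analysis pipeline was built
for: sentinel plants carry continuous dendrometry area signals
(growth trend x diurnal turgor oscillation x shared thermal drift x noise,
with a configurable bud-minus-stem transition lag), while peripheral plants
supply predawn water-status tables (xylem water potential, leaf and pooled
bud osmotic potentials). Every stochastic draw is reproducible from
``ScenarioConfig.rng_seed``, and the ground truth needed for
parameter-recovery tests is returned alongside the data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import ScenarioConfig, interp_day_map, parse_clock

__all__ = [
    "ScenarioTruth",
    "simulate_area_series",
    "simulate_water_status",
    "simulate_decline_table",
    "stem_decline_table",
    "oscillation_profile",
    "growth_value",
]

SOW_DATE = pd.Timestamp("2024-01-01")  # plant age 0; arbitrary anchor

#: logistic scale such that the 10-90% transition spans ``transition_duration``
_LOGISTIC_1090 = math.log(81.0)


@dataclass
class ScenarioTruth:
    """Ground-truth parameters behind one simulated scenario."""

    true_lag_dawn: float
    true_lag_dusk: float
    true_decline_slope: float
    water_status_means: pd.DataFrame  # day, treatment, measure, mean (MPa)
    plant_growth: dict = field(default_factory=dict)
    rng_seed: int = 0
    config_hash: str = ""

    def to_json(self, path) -> None:
        payload = {
            "true_lag_dawn": self.true_lag_dawn,
            "true_lag_dusk": self.true_lag_dusk,
            "true_decline_slope": self.true_decline_slope,
            "rng_seed": self.rng_seed,
            "config_hash": self.config_hash,
            "water_status_means": self.water_status_means.to_dict(orient="list"),
            "plant_growth": {str(k): v for k, v in self.plant_growth.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def growth_value(params: dict, t_days: np.ndarray, rehydration_day: float) -> np.ndarray:
    """Evaluate a growth-trend curve (multiple of the day-15 baseline).

    ``kind="logistic"`` is a saturating rise ``1 + gain*expit(rate*(t-mid))``;
    ``kind="peak_decline"`` caps the rise at ``peak_day``, declines linearly
    to ``(1-decline_frac)`` of the peak just before rehydration, then
    recovers to the peak over ``recovery_days``.
    """
    t = np.asarray(t_days, dtype=float)
    rise = 1.0 + params["gain"] * expit(params["rate"] * (t - params["midpoint"]))
    if params.get("kind", "logistic") == "logistic":
        return rise
    peak_day = params["peak_day"]
    g_peak = 1.0 + params["gain"] * expit(params["rate"] * (peak_day - params["midpoint"]))
    out = np.where(t <= peak_day, np.minimum(rise, g_peak), g_peak)
    decline_span = max(rehydration_day - peak_day, 1e-9)
    frac = np.clip((t - peak_day) / decline_span, 0.0, 1.0)
    out = out * (1.0 - params["decline_frac"] * frac)
    rec = np.clip((t - rehydration_day) / max(params.get("recovery_days", 1.0), 1e-9), 0.0, 1.0)
    target = g_peak * (1.0 - params["decline_frac"])
    out = np.where(t > rehydration_day, target + (g_peak - target) * rec, out)
    return out


def oscillation_profile(
    hour_of_day: np.ndarray,
    lights_on_h: float,
    lights_off_h: float,
    transition_duration: float,
    lag_dawn: float = 0.0,
    lag_dusk: float = 0.0,
) -> np.ndarray:
    """Smooth 0-1 'lights-on' indicator built from two logistic ramps.

    Tissue area contracts while the indicator is 1 (daytime transpiration)
    and re-expands at night. Lags shift the dawn/dusk midpoints of this
    tissue's response in minutes.
    """
    tau_h = transition_duration / _LOGISTIC_1090 / 60.0  # logistic scale, hours
    h = np.asarray(hour_of_day, dtype=float)
    c_dawn = lights_on_h + lag_dawn / 60.0
    c_dusk = lights_off_h + lag_dusk / 60.0
    return expit((h - c_dawn) / tau_h) * expit((c_dusk - h) / tau_h)


def _amplitude(config: ScenarioConfig, tissue: str, treatment: str, t: np.ndarray) -> np.ndarray:
    amp = config.oscillation_amplitude.get(tissue, 0.0)
    base = np.full_like(np.asarray(t, dtype=float), amp)
    if treatment == "D" and tissue == "stem" and config.drought_amplitude_gain > 0:
        dd = np.clip(
            np.minimum(t, config.rehydration_day) - config.drought_onset_day, 0.0, None
        )
        base = base * (1.0 + config.drought_amplitude_gain * dd)
    return base


def simulate_area_series(config: ScenarioConfig) -> tuple[pd.DataFrame, ScenarioTruth]:
    """Generate sentinel dendrometry series for both treatments.

    Returns a tidy frame with columns ``plant_id, treatment, tissue,
    timestamp, age_days, area_px`` (tissues ``bud``, ``stem`` and the
    drift-only ``reference``), and the scenario ground truth.
    """
    rng = np.random.default_rng(config.rng_seed)
    step_days = config.sampling_interval / (24.0 * 60.0)
    t = np.arange(config.start_day, config.end_day, step_days)
    hour = (t % 1.0) * 24.0
    on_h, off_h = parse_clock(config.lights_on), parse_clock(config.lights_off)

    frames = []
    plant_growth: dict = {}
    for treatment in config.treatments:
        for i in range(config.n_sentinel_per_treatment):
            plant = f"{treatment}{i + 1}"
            # shared thermal drift: one slow daily harmonic per camera
            phase = rng.uniform(0.0, 2.0 * np.pi)
            drift = config.thermal_drift_amplitude * np.sin(2.0 * np.pi * t + phase)
            gain_jitter = rng.lognormal(0.0, 0.10, size=2)  # bud, stem
            plant_growth[plant] = {}
            for j, tissue in enumerate(("bud", "stem")):
                params = dict(config.growth_trend[(tissue, treatment)])
                params["gain"] = params["gain"] * gain_jitter[j]
                plant_growth[plant][tissue] = params
                trend = growth_value(params, t, config.rehydration_day)
                lag_dawn = config.true_lag_dawn if tissue == "bud" else 0.0
                lag_dusk = config.true_lag_dusk if tissue == "bud" else 0.0
                osc = -_amplitude(config, tissue, treatment, t) * oscillation_profile(
                    hour, on_h, off_h, config.transition_duration, lag_dawn, lag_dusk
                )
                noise = rng.normal(0.0, config.noise_sd, size=t.size)
                rel = trend * (1.0 + osc + drift + noise)
                if np.any(rel <= 0):
                    raise ValueError(
                        "oscillation/drift amplitude drives area non-positive"
                    )
                area = config.baseline_area_px[tissue] * rel
                frames.append(
                    pd.DataFrame(
                        {
                            "plant_id": plant,
                            "treatment": treatment,
                            "tissue": tissue,
                            "age_days": t,
                            "area_px": area,
                        }
                    )
                )
            ref_noise = rng.normal(0.0, config.noise_sd, size=t.size)
            ref = config.baseline_area_px["reference"] * (1.0 + drift + ref_noise)
            frames.append(
                pd.DataFrame(
                    {
                        "plant_id": plant,
                        "treatment": treatment,
                        "tissue": "reference",
                        "age_days": t,
                        "area_px": ref,
                    }
                )
            )
    df = pd.concat(frames, ignore_index=True)
    df["timestamp"] = SOW_DATE + pd.to_timedelta(df["age_days"], unit="D")
    df["timestamp"] = df["timestamp"].dt.round("s")
    df = df[["plant_id", "treatment", "tissue", "timestamp", "age_days", "area_px"]]
    truth = ScenarioTruth(
        true_lag_dawn=config.true_lag_dawn,
        true_lag_dusk=config.true_lag_dusk,
        true_decline_slope=config.true_decline_slope,
        water_status_means=scenario_water_means(config),
        plant_growth=plant_growth,
        rng_seed=config.rng_seed,
        config_hash=config.config_hash(),
    )
    return df, truth


def _pt_offset_value(config: ScenarioConfig, treatment: str, day: float) -> float:
    off = config.pt_offset
    if isinstance(off, (int, float)):
        return float(off)
    per_trt = off[treatment]
    if isinstance(per_trt, (int, float)):
        return float(per_trt)
    return float(interp_day_map(per_trt, np.array([day]))[0])


def scenario_water_means(config: ScenarioConfig) -> pd.DataFrame:
    """Per day x treatment population means of Psi_x, Pi_L and Pi_B (MPa)."""
    rows = []
    for treatment in config.treatments:
        days = np.asarray(config.sampling_days, dtype=float)
        psi = interp_day_map(config.psi_trajectory[treatment], days)
        for day, p in zip(days, psi):
            off = _pt_offset_value(config, treatment, day)
            rows.append((day, treatment, "psi_x", p))
            rows.append((day, treatment, "pi_leaf", p - config.leaf_offset))
            rows.append((day, treatment, "pi_bud", p - off))
    return pd.DataFrame(rows, columns=["day", "treatment", "measure", "mean"])


def simulate_water_status(config: ScenarioConfig) -> tuple[pd.DataFrame, ScenarioTruth]:
    """Draw the predawn water-status table for the peripheral cohorts.

    Per sampling day and treatment: ``n_peripheral_per_timepoint`` individual
    Psi_x and Pi_L draws, and ``ceil(n/pool)`` bud-pool Pi_B values, each
    pool being the mean of ``bud_pool_size`` independent bud draws taken
    before measurement noise enters (mirroring physical pooling of tissue).
    """
    if config.bud_pool_size <= 0:
        raise ValueError("bud pool size must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 7]))
    means = scenario_water_means(config)
    n = config.n_peripheral_per_timepoint
    n_pools = math.ceil(n / config.bud_pool_size)
    rows = []
    for (day, treatment), grp in means.groupby(["day", "treatment"], sort=True):
        mu = grp.set_index("measure")["mean"]
        psi = mu["psi_x"] + rng.normal(0.0, config.psi_noise_sd, size=n)
        leaf = mu["pi_leaf"] + rng.normal(0.0, config.leaf_noise_sd, size=n)
        for k in range(n):
            rows.append((f"P{treatment}{int(day)}-{k + 1}", day, treatment, "psi_x", min(psi[k], -1e-3), 1))
            rows.append((f"P{treatment}{int(day)}-{k + 1}", day, treatment, "pi_leaf", min(leaf[k], -1e-3), 1))
        for k in range(n_pools):
            buds = mu["pi_bud"] + rng.normal(0.0, config.bud_noise_sd, size=config.bud_pool_size)
            rows.append(
                (
                    f"P{treatment}{int(day)}-pool{k + 1}",
                    day,
                    treatment,
                    "pi_bud",
                    min(float(np.mean(buds)), -1e-3),
                    config.bud_pool_size,
                )
            )
    table = pd.DataFrame(
        rows, columns=["plant_id", "day", "treatment", "measure", "value", "pool_size"]
    )
    truth = ScenarioTruth(
        true_lag_dawn=config.true_lag_dawn,
        true_lag_dusk=config.true_lag_dusk,
        true_decline_slope=config.true_decline_slope,
        water_status_means=means,
        rng_seed=config.rng_seed,
        config_hash=config.config_hash(),
    )
    return table, truth


def simulate_decline_table(
    rng: np.random.Generator | int,
    beta0: float = -1.0,
    beta1: float = 0.102,
    day_declines: dict | None = None,
    sigma_day: float = 0.37,
    sigma: float = 0.83,
    n_per_day: int = 15,
) -> pd.DataFrame:
    """Synthetic calibration dataset linking stem area decline to Psi_x.

    ``Psi_x_ij = beta0 - beta1*decline_j + u_j + eps_ij`` with day-level
    random intercepts ``u_j ~ N(0, sigma_day^2)``. ``decline`` is a positive
    percentage below the pre-rehydration maximum, shared by every
    observation of a day (it comes from the sentinel daily means), so the
    slope is a "MPa drop per 1% decline". Default variance components
    reproduce the marginal/conditional variance split of the glasshouse
    calibration at its four measurement days.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if day_declines is None:
        day_declines = {27: 0.5, 34: 3.0, 41: 10.0, 50: 18.0}
    rows = []
    for day, decline in sorted(day_declines.items()):
        if decline < 0:
            raise ValueError("decline must be a non-negative percentage")
        u = rng.normal(0.0, sigma_day)
        eps = rng.normal(0.0, sigma, size=n_per_day)
        psi = beta0 - beta1 * decline + u + eps
        for v in psi:
            rows.append((day, decline, v))
    return pd.DataFrame(rows, columns=["day", "mean_stem_decline", "psi_x"])


def stem_decline_table(
    area_df: pd.DataFrame,
    water_df: pd.DataFrame,
    days: tuple = (27, 34, 41, 50),
    rehydration_day: float = 50.0,
) -> pd.DataFrame:
    """Build the calibration table from simulated/extracted series.

    Daily mean stem area of droughted sentinels, expressed as a positive %
    decline from the pre-rehydration maximum of the across-plant daily mean,
    joined with the peripheral Psi_x draws of the droughted cohort.
    """
    stems = area_df[(area_df["treatment"] == "D") & (area_df["tissue"] == "stem")].copy()
    if stems.empty:
        raise ValueError("no droughted stem series in input")
    stems["day"] = np.floor(stems["age_days"]).astype(int)
    daily = stems.groupby("day")["area_px"].mean()
    pre = daily[daily.index <= rehydration_day]
    peak = pre.max()
    decline = (1.0 - daily / peak) * 100.0
    decline = decline.clip(lower=0.0)
    psi = water_df[
        (water_df["treatment"] == "D")
        & (water_df["measure"] == "psi_x")
        & (water_df["day"].isin(days))
    ]
    out = psi[["day", "value"]].rename(columns={"value": "psi_x"}).copy()
    out["mean_stem_decline"] = out["day"].map(decline)
    if out["mean_stem_decline"].isna().any():
        raise ValueError("declines unavailable for some requested days")
    return out[["day", "mean_stem_decline", "psi_x"]].reset_index(drop=True)
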