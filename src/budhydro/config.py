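"""Scenario, geometry and sampler configuration.

The default :class:`ScenarioConfig` encodes the glasshouse design the
analysis assumes: two treatments (well-watered ``W`` and droughted ``D``),
five continuously imaged sentinel plants per treatment sampled every 5 min
under a 12-h photoperiod (lights 08:30-20:30), fifteen destructively sampled
peripheral plants per treatment at each predawn timepoint (days 20, 27, 34,
41, 48, 50), drought imposed from day 20 with rehydration on day 50, and
node-2 bud osmotic potential measured on pools of five buds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "ScenarioConfig",
    "GeometrySpec",
    "McmcConfig",
    "parse_clock",
    "interp_day_map",
]


def parse_clock(value: str | float) -> float:
    """Convert a clock time (``"HH:MM"`` or fractional hours) to hours."""
    if isinstance(value, str):
        hh, mm = value.split(":")
        return int(hh) + int(mm) / 60.0
    return float(value)


def interp_day_map(day_map: Mapping[float, float], days: np.ndarray) -> np.ndarray:
    """Piecewise-linear interpolation of a {day: value} anchor map."""
    if not day_map:
        raise ValueError("empty day map")
    items = sorted(day_map.items())
    xs = np.array([k for k, _ in items], dtype=float)
    ys = np.array([v for _, v in items], dtype=float)
    return np.interp(np.asarray(days, dtype=float), xs, ys)


def _default_psi_trajectory() -> dict:
    # Anchors bracket the printed extremes: well-watered plants stay between
    # -0.47 and -0.87 MPa; droughted plants decline from about -0.5 MPa at
    # drought onset to -2.09 MPa on day 48, partially recovering after
    # rehydration on day 50.
    return {
        "W": {15: -0.47, 20: -0.47, 27: -0.60, 34: -0.87, 41: -0.70, 48: -0.60, 52: -0.55},
        "D": {15: -0.50, 20: -0.50, 27: -0.80, 34: -1.20, 41: -1.60, 48: -2.09, 49: -2.09, 50: -1.30, 52: -1.25},
    }


def _default_pt_offset() -> dict:
    # Pressure differential Psi_x - Pi_B. Pre-drought bud osmotic potential
    # of -2.27 MPa against Psi_x of -0.5 MPa gives 1.77 MPa; the droughted
    # differential widens to 3.54 MPa by day 48 (Pi_B = -5.63 MPa).
    return {
        "W": {15: 1.77, 52: 1.77},
        "D": {15: 1.77, 20: 1.77, 27: 2.00, 34: 2.40, 41: 3.00, 48: 3.54, 50: 2.60, 52: 2.40},
    }


def _default_growth() -> dict:
    """Per (tissue, treatment) growth-trend parameters.

    Saturating logistic rise from the day-15 baseline; droughted stems add a
    post-peak linear decline (peak day 32, declining to ``decline_frac``
    below the peak just before rehydration) and a rapid rehydration
    recovery.
    """
    return {
        ("stem", "W"): dict(kind="logistic", gain=0.60, midpoint=28.0, rate=0.18),
        ("bud", "W"): dict(kind="logistic", gain=2.00, midpoint=30.0, rate=0.25),
        ("stem", "D"): dict(
            kind="peak_decline", gain=0.25, midpoint=24.0, rate=0.25,
            peak_day=32.0, decline_frac=0.18, recovery_days=1.0,
        ),
        ("bud", "D"): dict(kind="logistic", gain=0.30, midpoint=34.0, rate=0.20),
    }


@dataclass
class ScenarioConfig:
    """Design constants and generative parameters for one synthetic study."""

    treatments: tuple = ("W", "D")
    n_sentinel_per_treatment: int = 5
    n_peripheral_per_timepoint: int = 15
    start_day: int = 15
    end_day: int = 52
    sampling_interval: float = 5.0  # minutes
    lights_on: str = "08:30"
    lights_off: str = "20:30"
    sampling_days: tuple = (20, 27, 34, 41, 48, 50)
    drought_onset_day: float = 20.0
    rehydration_day: float = 50.0

    # Bud-minus-stem transition lags in minutes (the quantity the lag model
    # estimates; the study found both indistinguishable from zero).
    true_lag_dawn: float = 0.0
    true_lag_dusk: float = 0.0
    transition_duration: float = 30.0  # minutes for the ~10-90% area change

    # Diurnal oscillation amplitude as a fraction of baseline area per
    # tissue; droughted stems gain amplitude linearly with days of drought.
    oscillation_amplitude: dict = field(
        default_factory=lambda: {"stem": 0.02, "bud": 0.02}
    )
    drought_amplitude_gain: float = 0.03  # fractional gain per drought day (stems)

    growth_trend: dict = field(default_factory=_default_growth)
    thermal_drift_amplitude: float = 0.005  # shared fractional daily drift
    noise_sd: float = 0.002  # fractional area noise

    psi_trajectory: dict = field(default_factory=_default_psi_trajectory)
    pt_offset: dict = field(default_factory=_default_pt_offset)
    leaf_offset: float = 0.45  # Psi_x - Pi_L in MPa (leaves track xylem closely)
    psi_noise_sd: float = 0.15  # MPa, per-plant predawn Psi_x
    leaf_noise_sd: float = 0.25  # MPa, per leaf disc
    bud_noise_sd: float = 0.30  # MPa, per bud before pooling
    bud_pool_size: int = 5

    true_decline_slope: float = 0.102  # MPa drop per 1% stem area decline

    baseline_area_px: dict = field(
        default_factory=lambda: {"stem": 4000.0, "bud": 600.0, "reference": 2000.0}
    )

    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if parse_clock(self.lights_on) >= parse_clock(self.lights_off):
            raise ValueError("lights_on must precede lights_off")
        if self.bud_pool_size <= 0:
            raise ValueError("bud pool size must be positive")
        if not self.treatments or not set(self.treatments) <= {"W", "D"}:
            raise ValueError("treatments must be a non-empty subset of {'W', 'D'}")
        if self.n_sentinel_per_treatment <= 0 or self.n_peripheral_per_timepoint <= 0:
            raise ValueError("cohort sizes must be positive")
        for day in self.sampling_days:
            if not (self.start_day <= day <= self.end_day):
                raise ValueError(f"sampling day {day} outside scenario range")
        days = np.arange(self.start_day, self.end_day + 1, dtype=float)
        for trt in self.treatments:
            off = self.pt_offset
            if not isinstance(off, (int, float)):
                off = off[trt]
            offs = (
                np.full(days.shape, float(off))
                if isinstance(off, (int, float))
                else interp_day_map(off, days)
            )
            if np.any(offs <= 0):
                raise ValueError("pt_offset must stay positive on every day")
        # droughted Psi_x must be non-increasing until rehydration
        if "D" in self.treatments:
            dd = days[(days >= self.drought_onset_day) & (days < self.rehydration_day)]
            psi_d = interp_day_map(self.psi_trajectory["D"], dd)
            if np.any(np.diff(psi_d) > 1e-9):
                raise ValueError(
                    "droughted psi_trajectory must be non-increasing before rehydration"
                )

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["growth_trend"] = {f"{k[0]}:{k[1]}": v for k, v in self.growth_trend.items()}
        # normalise anchor-day keys so hashes agree across (de)serialisation
        for key in ("psi_trajectory", "pt_offset"):
            if isinstance(d[key], dict):
                d[key] = {
                    trt: (
                        {float(day): float(v) for day, v in m.items()}
                        if isinstance(m, dict)
                        else float(m)
                    )
                    for trt, m in d[key].items()
                }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        d = dict(d)
        if "growth_trend" in d and d["growth_trend"] and all(
            isinstance(k, str) for k in d["growth_trend"]
        ):
            d["growth_trend"] = {
                tuple(k.split(":")): v for k, v in d["growth_trend"].items()
            }
        for key in ("psi_trajectory", "pt_offset"):
            if key in d and isinstance(d[key], dict):
                d[key] = {
                    trt: (
                        {float(day): float(v) for day, v in m.items()}
                        if isinstance(m, dict)
                        else float(m)
                    )
                    for trt, m in d[key].items()
                }
        for key in ("sampling_days", "treatments"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class GeometrySpec:
    """Pixel geometry of a rendered dendrometer frame.

    The stem silhouette is a vertical trapezoid, the bud an adjacent
    ellipse, and the thermal reference a fixed rectangle; all must fit in
    the frame without overlap so rectangular ROIs can separate them.
    """

    frame_height: int = 200
    frame_width: int = 280
    stem_x_center: float = 70.0
    stem_top: float = 20.0
    stem_bottom: float = 180.0
    stem_width_top: float = 22.0
    stem_width_bottom: float = 28.0
    bud_center: tuple = (70.0, 150.0)  # (row, col)
    bud_semi_axes: tuple = (14.0, 24.0)  # (row, col) semi-axes at unit scale
    ref_rect: tuple = (30, 220, 170, 250)  # r0, c0, r1, c1 half-open
    foreground_gray: int = 30
    background_gray: int = 220
    pixel_noise_sd: float = 0.0

    def validate(self) -> None:
        if not (0 <= self.foreground_gray < self.background_gray <= 255):
            raise ValueError("foreground gray must be darker than background")
        r0, c0, r1, c1 = self.ref_rect
        if not (0 <= r0 < r1 <= self.frame_height and 0 <= c0 < c1 <= self.frame_width):
            raise ValueError("reference rectangle outside frame")
        if self.stem_bottom <= self.stem_top:
            raise ValueError("degenerate stem silhouette")

    @property
    def stem_area0(self) -> float:
        return 0.5 * (self.stem_width_top + self.stem_width_bottom) * (
            self.stem_bottom - self.stem_top
        )

    @property
    def bud_area0(self) -> float:
        a, b = self.bud_semi_axes
        return float(np.pi * a * b)

    @property
    def ref_area(self) -> float:
        r0, c0, r1, c1 = self.ref_rect
        return float((r1 - r0) * (c1 - c0))


@dataclass
class McmcConfig:
    """Ensemble-sampler settings for the Bayesian lag model."""

    chains: int = 4
    iterations: int = 8000
    warmup: int = 2000
    walkers: int = 16
    seed: int = 0
    rhat_threshold: float = 1.01

    def __post_init__(self) -> None:
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be smaller than iterations")
        if self.chains < 2:
            raise ValueError("at least two chains are required for R-hat")
        if self.walkers < 14:
            raise ValueError("ensemble needs at least 2x(n_params)+2 walkers")
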