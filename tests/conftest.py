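"""Shared fixtures: synthetic scenarios and their transition windows."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import budhydro as bh


def make_lag_scenario(seed: int, lag_dawn: float = 0.0, lag_dusk: float = 0.0, **kw) -> bh.ScenarioConfig:
    """Droughted-cohort scenario covering the days-17-23 lag analysis."""
    defaults = dict(
        treatments=("D",),
        end_day=26,
        sampling_days=(20,),
        noise_sd=0.0015,
        rng_seed=seed,
        true_lag_dawn=lag_dawn,
        true_lag_dusk=lag_dusk,
    )
    defaults.update(kw)
    return bh.ScenarioConfig(**defaults)


def scenario_windows(config: bh.ScenarioConfig, day_range=(17, 23)) -> pd.DataFrame:
    """Full extraction path: simulate -> correct/normalise -> detrend -> windows."""
    area, _ = bh.simulate_area_series(config)
    rel = bh.relative_series(area[area["treatment"] == "D"], day_range=day_range)
    resid = bh.residual_frame(rel, day_range=day_range)
    return bh.extract_windows(
        resid,
        lights_on=config.lights_on,
        lights_off=config.lights_off,
        day_range=day_range,
    )


@pytest.fixture(scope="session")
def windows_lag0() -> pd.DataFrame:
    return scenario_windows(make_lag_scenario(seed=101))


@pytest.fixture(scope="session")
def windows_lag10() -> pd.DataFrame:
    return scenario_windows(make_lag_scenario(seed=202, lag_dawn=10.0, lag_dusk=10.0))


@pytest.fixture(scope="session")
def reduced_mcmc() -> bh.McmcConfig:
    """Shrunken sampler settings for test-suite-scale fits."""
    return bh.McmcConfig(chains=2, iterations=1000, warmup=400, walkers=16, seed=7)


def sigmoid_windows(
    rng: np.random.Generator,
    n_plants: int = 5,
    n_days: int = 7,
    A: float = 120.0,
    B: float = 0.15,
    C_bud: float = 0.0,
    C_stem: float = 0.0,
    D: float = -30.0,
    sigma: float = 5.0,
    tau_A: float = 5.0,
    tau_D: float = 3.0,
    transition: str = "dawn",
) -> pd.DataFrame:
    """Windows drawn directly from the hierarchical sigmoid model."""
    t = np.arange(-60.0, 60.0 + 1e-9, 5.0)
    rows = []
    for p in range(n_plants):
        for tissue, C in (("bud", C_bud), ("stem", C_stem)):
            A_g = A + rng.normal(0.0, 5.0)
            D_g = D + rng.normal(0.0, 3.0)
            for d in range(n_days):
                a_d = rng.normal(0.0, tau_A)
                d_d = rng.normal(0.0, tau_D)
                mu = bh.sigmoid(t, A_g + a_d, B, C, D_g + d_d)
                y = mu + rng.normal(0.0, sigma, size=t.size)
                rows.append(
                    pd.DataFrame(
                        {
                            "plant_id": f"D{p + 1}",
                            "tissue": tissue,
                            "transition_type": transition,
                            "day": 17 + d,
                            "t": t,
                            "y": y,
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)
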