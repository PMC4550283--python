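"""Seeded synthetic study conditions.

Generates weather, wading schedules and behavior-observation streams that
emulate the validation study's conditions: clear late-September days with
air temperatures spanning roughly 0.5-27.6 C, pond water near 15-20 C,
night-time roosting in shin-deep water, and instantaneous behavior
sampling at 30-second intervals with a small out-of-sight rate.  The same
seed always reproduces the same records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .energetics import DEFAULT_BEHAVIOR_COSTS
from .microclimate import DailyWeather, HourlyEnvironment, Site, hourly_from_daily

#: Behaviors emitted by the synthetic observer, with typical daytime rates.
_BEHAVIOR_DIRICHLET = {
    "comfort": 20.0,
    "forage": 12.0,
    "walk": 30.0,
    "rest_alert": 35.0,
    "rest_sleep": 2.0,
    "social": 1.0,
}


@dataclass(frozen=True)
class SyntheticScenario:
    """Study-condition envelope for the generator."""

    n_days: int = 4
    air_range: tuple[float, float] = (0.5, 27.6)
    water_range: tuple[float, float] = (15.0, 20.0)
    wind_range: tuple[float, float] = (0.1, 2.0)
    rh_range: tuple[float, float] = (40.0, 90.0)
    cloud_percent: float = 0.0
    first_julian_day: int = 268        # late September
    night_wading_depth: float = 0.094  # m; water half-way up the shin
    out_of_sight_rate: float = 0.058
    samples_per_day: int = 1800        # 30-s sampling over the active period
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.air_range, self.water_range, self.wind_range, self.rh_range):
            if lo > hi:
                raise ValueError("scenario range inverted")
        if self.n_days < 1:
            raise ValueError("need at least one day")


@dataclass(frozen=True)
class SyntheticData:
    """Bundle of generated study records."""

    daily_weather: tuple[DailyWeather, ...]
    hourly_envs: tuple[HourlyEnvironment, ...]   # wading fields filled in
    wading_schedule: pd.DataFrame
    behavior_observations: pd.DataFrame
    true_proportions: tuple[dict, ...]           # per day


def generate(scenario: SyntheticScenario, site: Site | None = None) -> SyntheticData:
    """Generate the full record bundle for one scenario (deterministic in
    the seed)."""
    rng = np.random.default_rng(scenario.seed)
    site = site or Site()
    t_lo, t_hi = scenario.air_range

    days: list[DailyWeather] = []
    for d in range(scenario.n_days):
        if d == 0:
            # First day pins the stated envelope exactly.
            tmin, tmax = t_lo, t_hi
        else:
            tmin = t_lo + rng.uniform(0.0, 0.25 * (t_hi - t_lo))
            tmax = t_hi - rng.uniform(0.0, 0.25 * (t_hi - t_lo))
        wmin = scenario.wind_range[0]
        wmax = rng.uniform(*scenario.wind_range)
        days.append(
            DailyWeather(
                julian_day=scenario.first_julian_day + d,
                air_min=round(tmin, 2), air_max=round(tmax, 2),
                wind_min=round(wmin, 2), wind_max=round(max(wmax, wmin), 2),
                rh_min=round(scenario.rh_range[0], 1),
                rh_max=round(scenario.rh_range[1], 1),
                cloud_percent=scenario.cloud_percent,
            )
        )

    # Pond water: slow sinusoid inside the configured range.
    w_lo, w_hi = scenario.water_range
    wading_rows = []
    envs: list[HourlyEnvironment] = []
    for d, day in enumerate(days):
        water = [
            w_lo + (w_hi - w_lo) * 0.5 * (1.0 - np.cos(2.0 * np.pi * (h - 4) / 24.0))
            for h in range(24)
        ]
        base = hourly_from_daily(day, site, water_temp=water)
        for h, env in enumerate(base):
            night = env.hour >= 20 or env.hour < 6
            if night:
                depth, frac = scenario.night_wading_depth, 1.0
            else:
                frac = float(np.round(rng.uniform(0.0, 0.5), 3))
                depth = scenario.night_wading_depth * float(rng.uniform(0.3, 1.0))
                depth = float(np.round(depth, 4))
            envs.append(replace(env, water_depth=depth, wading_fraction=frac))
            if d == 0:
                wading_rows.append({
                    "hour": h, "depth_m": depth, "fraction": frac,
                    "water_T_C": round(water[h], 3), "water_velocity_m_s": 0.0,
                })

    # Behavior streams: daily true proportions drawn around typical rates,
    # then instantaneous 30-s sampling with an out-of-sight rate.
    behaviors = list(_BEHAVIOR_DIRICHLET)
    alpha = np.array([_BEHAVIOR_DIRICHLET[b] for b in behaviors])
    obs_rows = []
    truths = []
    for d in range(scenario.n_days):
        p = rng.dirichlet(alpha)
        truths.append(dict(zip(behaviors, p)))
        draws = rng.choice(len(behaviors), size=scenario.samples_per_day, p=p)
        seen = rng.random(scenario.samples_per_day) >= scenario.out_of_sight_rate
        for i, (b_ix, ok) in enumerate(zip(draws, seen)):
            obs_rows.append({
                "day": d,
                "time_s": 6 * 3600 + 30 * i,
                "behavior": behaviors[b_ix] if ok else "out_of_sight",
                "water_depth_class": "none",
            })

    return SyntheticData(
        daily_weather=tuple(days),
        hourly_envs=tuple(envs),
        wading_schedule=pd.DataFrame(wading_rows),
        behavior_observations=pd.DataFrame(obs_rows),
        true_proportions=tuple(truths),
    )
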