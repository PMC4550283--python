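"""Experiment drivers.

Metabolic-chamber sweeps (with or without counter-current exchange and
wading), extraction of the lower/upper critical temperatures and minimal
thermal conductance from the resulting curves, one-at-a-time sensitivity
analysis with the cascade frozen, and the outdoor validation simulation
that couples hourly weather, activity targets, wading schedules and the
night roosting posture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .appendages import CounterCurrentParams
from .geometry import BodyPlan, consolidate_night_posture
from .heat_balance import whole_body_required_mr
from .microclimate import HourlyEnvironment, chamber_environment
from .thermoregulation import CascadeState, HourSolution, solve_hour

WadingOption = str  # "none" | "half" | "full"


class TransitionNotFound(RuntimeError):
    """The requested critical temperature is not inside the sweep range."""


@dataclass(frozen=True)
class ChamberPoint:
    air_temp: float
    achieved_mr: float
    achieved_heat: float
    cascade: CascadeState


@dataclass(frozen=True)
class ChamberCurve:
    """Metabolic rate vs air temperature under chamber conditions."""

    points: tuple[ChamberPoint, ...]
    wading: WadingOption = "none"
    counter_current: bool = True

    def __post_init__(self) -> None:
        temps = [p.air_temp for p in self.points]
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise ValueError("chamber temperatures must be strictly increasing")

    def mr(self) -> np.ndarray:
        return np.array([p.achieved_mr for p in self.points])

    def temps(self) -> np.ndarray:
        return np.array([p.air_temp for p in self.points])


def _leg_length(plan: BodyPlan) -> float:
    for part in plan.parts:
        if part.counter_current and part.shape.kind == "elliptical_cylinder":
            return part.shape.length
    raise ValueError("plan has no counter-current leg")


def chamber_sweep(
    plan: BodyPlan,
    cc_params: Optional[CounterCurrentParams] = None,
    wading: WadingOption = "none",
    counter_current: bool = True,
    t_min: float = -50.0,
    t_max: float = 50.0,
    step: float = 1.0,
) -> ChamberCurve:
    """Sweep chamber air temperature with the target rate at basal.

    Chamber conditions: wind 0.01 m/s, RH 5%, no solar, every radiant
    surface at air temperature.  Wading options submerge the legs fully
    or to half their length in water at air temperature, floored at
    0.1 C (ice water) for air at or below freezing.
    """
    if cc_params is None:
        cc_params = CounterCurrentParams(ceiling=plan.physiology.core_temp)
    depth = 0.0
    if wading == "full":
        depth = _leg_length(plan)
    elif wading == "half":
        depth = 0.5 * _leg_length(plan)
    elif wading != "none":
        raise ValueError(f"unknown wading option {wading!r}")

    points = []
    n = int(round((t_max - t_min) / step))
    for i in range(n + 1):
        ta = t_min + i * step
        env = chamber_environment(ta)
        if depth > 0:
            env = replace(env, water_depth=depth, wading_fraction=1.0,
                          water_temp=max(ta, 0.1))
        sol = solve_hour(plan, env, plan.physiology.bmr_w,
                         cc_params=cc_params, counter_current=counter_current)
        points.append(ChamberPoint(ta, sol.achieved_mr, sol.achieved_heat, sol.cascade))
    return ChamberCurve(points=tuple(points), wading=wading,
                        counter_current=counter_current)


def find_lct(curve: ChamberCurve, bmr_w: float) -> float:
    """Lower critical temperature: lowest air temperature whose achieved
    metabolic rate is within the +5% band above basal."""
    for p in curve.points:
        if p.achieved_mr <= 1.05 * bmr_w:
            return p.air_temp
    raise TransitionNotFound("no entry into the basal band inside the sweep")


def find_uct(curve: ChamberCurve, bmr_w: float) -> float:
    """Upper critical temperature: lowest air temperature at which the
    heat-stress flag is set (basal rate unsustainable without panting /
    core-temperature rise)."""
    for p in curve.points:
        if p.cascade.heat_stressed:
            return p.air_temp
    raise TransitionNotFound("no heat stress inside the sweep")


def minimal_conductance(
    curve: ChamberCurve,
    core_temp: float,
    t_range: tuple[float, float] = (-25.0, 0.0),
) -> float:
    """Mean minimal thermal conductance, W/C, below the thermoneutral zone.

    Metabolic heat loss divided by (deep body temperature - air
    temperature), averaged over the given sub-thermoneutral range.
    """
    lo, hi = t_range
    values = [
        p.achieved_heat / (core_temp - p.air_temp)
        for p in curve.points
        if lo <= p.air_temp <= hi
    ]
    if not values:
        raise ValueError("no chamber points inside the conductance range")
    return float(np.mean(values))


def scholander_fit(curve: ChamberCurve, t_range: tuple[float, float] = (-25.0, 0.0)
                   ) -> tuple[float, float, float]:
    """(slope W/C, intercept W, R^2) of metabolic rate vs air temperature
    below the thermoneutral zone (the Scholander-Irving line)."""
    lo, hi = t_range
    pts = [(p.air_temp, p.achieved_mr) for p in curve.points if lo <= p.air_temp <= hi]
    x = np.array([t for t, _ in pts])
    y = np.array([m for _, m in pts])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2


# ---------------------------------------------------------------------------
# Sensitivity analysis
# ---------------------------------------------------------------------------

def _scale_feathers(plan: BodyPlan, **scales: float) -> BodyPlan:
    parts = []
    for p in plan.parts:
        if p.feather is None:
            parts.append(p)
            continue
        f = p.feather
        f = replace(
            f,
            element_diameter_um=f.element_diameter_um * scales.get("diameter", 1.0),
            element_density_per_cm2=f.element_density_per_cm2 * scales.get("density", 1.0),
            length_dorsal_mm=f.length_dorsal_mm * scales.get("length", 1.0),
            length_ventral_mm=f.length_ventral_mm * scales.get("length", 1.0),
            depth_dorsal_mm=min(f.depth_dorsal_mm * scales.get("depth", 1.0),
                                f.length_dorsal_mm * scales.get("length", 1.0)),
            depth_ventral_mm=min(f.depth_ventral_mm * scales.get("depth", 1.0),
                                 f.length_ventral_mm * scales.get("length", 1.0)),
        )
        parts.append(replace(p, feather=f))
    return replace(plan, parts=tuple(parts))


def _scale_reflectivity(plan: BodyPlan, factor: float, legs_only: bool = False,
                        absolute: float | None = None) -> BodyPlan:
    parts = []
    for p in plan.parts:
        bare = p.feather is None
        if legs_only and not (p.counter_current and bare):
            parts.append(p)
            continue
        if bare:
            new_r = absolute if absolute is not None else p.reflectivity * factor
            parts.append(replace(p, reflectivity=min(new_r, 1.0)))
        elif not legs_only:
            f = p.feather
            new_r = absolute if absolute is not None else f.reflectivity * factor
            parts.append(replace(p, feather=replace(f, reflectivity=min(new_r, 1.0))))
        else:
            parts.append(p)
    return replace(plan, parts=tuple(parts))


#: Registered perturbable inputs for the sensitivity driver.  Each entry
#: maps (plan, cc, env_kwargs) under a fractional perturbation ``delta``.
def _perturb(plan: BodyPlan, cc: CounterCurrentParams, parameter: str, delta: float):
    env_kwargs: dict = {}
    if parameter == "morphometry":
        parts = tuple(replace(p, shape=p.shape.scaled(1.0 + delta)) for p in plan.parts)
        plan = replace(plan, parts=parts)
    elif parameter == "feather_diameter":
        plan = _scale_feathers(plan, diameter=1.0 + delta)
    elif parameter == "feather_density":
        plan = _scale_feathers(plan, density=1.0 + delta)
    elif parameter == "feather_length":
        plan = _scale_feathers(plan, length=1.0 + delta)
    elif parameter == "feather_depth":
        plan = _scale_feathers(plan, depth=1.0 + delta)
    elif parameter == "fat_fraction":
        plan = replace(plan, fat_fraction=plan.fat_fraction * (1.0 + delta))
    elif parameter == "reflectivity":
        plan = _scale_reflectivity(plan, 1.0 + delta)
    elif parameter == "leg_reflectivity":
        plan = _scale_reflectivity(plan, 1.0 + delta, legs_only=True)
    elif parameter == "core_temp":
        p = plan.physiology
        new_core = p.core_temp * (1.0 + delta)
        new_core = min(max(new_core, p.core_temp_min), p.core_temp_max)
        plan = replace(plan, physiology=replace(p, core_temp=new_core))
        cc = replace(cc, ceiling=new_core)
    elif parameter == "leg_dt_min":
        cc = replace(cc, dt_min=cc.dt_min * (1.0 + delta))
    elif parameter == "wind":
        env_kwargs["wind_factor"] = 1.0 + delta
    elif parameter == "solar":
        env_kwargs["solar_factor"] = 1.0 + delta
    else:
        raise KeyError(f"unknown sensitivity parameter {parameter!r}")
    return plan, cc, env_kwargs


def sensitivity_run(
    plan: BodyPlan,
    parameter: str,
    delta: float,
    cc_params: Optional[CounterCurrentParams] = None,
    t_range: tuple[float, float] = (-25.0, 35.0),
    step: float = 1.0,
    solar: float = 0.0,
    wading: WadingOption = "none",
) -> float:
    """Mean change in metabolic rate (W) under a one-at-a-time perturbation.

    The cascade is frozen (no ptiloerection, vasomotion, panting); only
    the counter-current appendage offset remains active so appendage
    temperatures stay realistic.  Points where either run's metabolic
    rate is zero or below are excluded from the mean.
    """
    if cc_params is None:
        cc_params = CounterCurrentParams(ceiling=plan.physiology.core_temp)
    pplan, pcc, env_kwargs = _perturb(plan, cc_params, parameter, delta)

    def frozen_mr(the_plan: BodyPlan, the_cc: CounterCurrentParams,
                  wind_factor: float = 1.0, solar_factor: float = 1.0) -> list[float]:
        p = the_plan.physiology
        state = CascadeState(
            ptiloerection=0.0, flesh_conductivity=p.flesh_conductivity,
            leg_elevation=0.0, core_temp=p.core_temp,
            o2_extraction=p.o2_extraction_max,
        )
        out = []
        depth = 0.0
        if wading == "full":
            depth = _leg_length(the_plan)
        elif wading == "half":
            depth = 0.5 * _leg_length(the_plan)
        n = int(round((t_range[1] - t_range[0]) / step))
        for i in range(n + 1):
            ta = t_range[0] + i * step
            env = chamber_environment(ta)
            env = replace(env, wind=env.wind * wind_factor,
                          solar=solar * solar_factor)
            if depth > 0:
                env = replace(env, water_depth=depth, wading_fraction=1.0,
                              water_temp=max(ta, 0.1))
            mr, _, _ = whole_body_required_mr(the_plan, env, state,
                                              cc_params=the_cc)
            out.append(mr)
        return out

    base = frozen_mr(plan, cc_params)
    pert = frozen_mr(pplan, pcc, **env_kwargs)
    diffs = [b - a for a, b in zip(base, pert) if a > 0 and b > 0]
    if not diffs:
        raise ValueError("no usable points in the sensitivity range")
    return float(np.mean(diffs))


# ---------------------------------------------------------------------------
# Validation simulation
# ---------------------------------------------------------------------------

NIGHT_HOURS = frozenset(list(range(20, 24)) + list(range(0, 6)))


@dataclass(frozen=True)
class ValidationResult:
    """Outcome of a multi-day outdoor simulation."""

    daily_ee_kj: tuple[float, ...]
    period_mean_ee_kj: float
    teb_ee_kj: float               # time-energy-budget expectation, kJ/day
    solutions: tuple[HourSolution, ...]
    envs: tuple[HourlyEnvironment, ...]


def validation_run(
    plan: BodyPlan,
    envs: Sequence[HourlyEnvironment],
    activity_multipliers: Sequence[float],
    cc_params: Optional[CounterCurrentParams] = None,
    night_posture: bool = True,
) -> ValidationResult:
    """Simulate whole days of hourly heat balance against activity targets.

    The target metabolic rate is the day's activity multiplier times BMR
    during hours with solar radiation and BMR otherwise; between 20:00
    and 5:59 the animal stands on one leg in the consolidated night
    posture.  Wading follows the per-hour fields of the environment
    records.  Daily energy expenditure integrates hourly achieved rates;
    the time-energy-budget expectation uses the same active/rest split.
    """
    if len(envs) % 24 != 0:
        raise ValueError("hourly environments must cover whole days")
    n_days = len(envs) // 24
    if len(activity_multipliers) != n_days:
        raise ValueError("need one activity multiplier per day")
    if cc_params is None:
        cc_params = CounterCurrentParams(ceiling=plan.physiology.core_temp)

    night_plan = consolidate_night_posture(plan) if night_posture else plan
    bmr = plan.physiology.bmr_w

    solutions: list[HourSolution] = []
    daily: list[float] = []
    active_hours = 0
    teb_total = 0.0
    for d in range(n_days):
        day_kj = 0.0
        mult = activity_multipliers[d]
        for h in range(24):
            env = envs[24 * d + h]
            active = env.solar > 0.0
            target = mult * bmr if active else bmr
            the_plan = night_plan if (night_posture and env.hour in NIGHT_HOURS) else plan
            sol = solve_hour(the_plan, env, target, cc_params=cc_params)
            solutions.append(sol)
            day_kj += sol.achieved_mr * 3.6  # W -> kJ over one hour
            teb_total += target * 3.6
            active_hours += int(active)
        daily.append(day_kj)

    return ValidationResult(
        daily_ee_kj=tuple(daily),
        period_mean_ee_kj=float(np.mean(daily)),
        teb_ee_kj=teb_total / n_days,
        solutions=tuple(solutions),
        envs=tuple(envs),
    )
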