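"""The thermoregulatory cascade.

Each hour the animal has a target metabolic rate (basal, or basal times
an activity multiplier).  If holding core temperature requires more heat
than the target produces, heat-conserving mechanisms engage in order —
ptiloerection, vasoconstriction, a slight core-temperature drop — each
stepped until the achieved rate enters the +/-5% band around the target
or the mechanism saturates.  If the environment cannot remove the target
heat production, heat-dumping mechanisms engage — vasodilation, then
raising appendage temperatures toward body core (appendages warm before
any other body part), then panting, then a slight core-temperature rise.
When even maximal appendage warming cannot balance the books the animal
is flagged heat-stressed and the reported rate is the maximum sustainable
without a core-temperature increase; panting itself carries no simulated
energy cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

from .geometry import BodyPlan
from .heat_balance import PartState, whole_body_required_mr
from .microclimate import HourlyEnvironment

#: Half-width of the acceptance band around the target metabolic rate.
MR_BAND = 0.05

#: Stress elevation (C) guaranteed to drive any appendage to its ceiling.
_MAX_ELEVATION = 120.0

_MAX_EVALS = 60


@dataclass(frozen=True)
class CascadeState:
    """Engagement level of every thermoregulatory mechanism."""

    ptiloerection: float          # 0 (rest) .. 1 (fully erect)
    flesh_conductivity: float     # W m^-1 K^-1, vasomotor state
    leg_elevation: float          # C above the counter-current minimum
    core_temp: float              # C
    o2_extraction: float          # %, drops below maximum when panting
    heat_stressed: bool = False

    @property
    def panting(self) -> bool:
        return self.o2_extraction < 31.0 - 1e-12  # below normal extraction


@dataclass(frozen=True)
class HourSolution:
    """Outcome of one hour's thermoregulatory solve."""

    achieved_mr: float            # W
    achieved_heat: float          # W of metabolic heat
    target_mr: float              # W
    cascade: CascadeState
    part_states: tuple[PartState, ...]
    evaluations: int = 0


def _resting_state(plan: BodyPlan) -> CascadeState:
    p = plan.physiology
    return CascadeState(
        ptiloerection=0.0,
        flesh_conductivity=p.flesh_conductivity,
        leg_elevation=0.0,
        core_temp=p.core_temp,
        o2_extraction=p.o2_extraction_max,
    )


def solve_hour(
    plan: BodyPlan,
    env: HourlyEnvironment,
    target_mr: float,
    cc_params=None,
    counter_current: bool = True,
) -> HourSolution:
    """Adjust the cascade until hourly metabolic rate meets the target.

    Deterministic: each mechanism is stepped by bisection (monotone in
    its engagement level) until the achieved rate enters
    ``[0.95, 1.05] * target`` or the mechanism saturates; later-stage
    mechanisms engage only once all earlier stages are saturated.
    """
    physio = plan.physiology
    if target_mr < physio.bmr_w - 1e-9:
        raise ValueError("target metabolic rate must be at least basal")

    evals = 0
    cache: dict = {}

    def evaluate(state: CascadeState):
        nonlocal evals
        key = (state.ptiloerection, state.flesh_conductivity, state.leg_elevation,
               state.core_temp, state.o2_extraction)
        if key not in cache:
            evals += 1
            cache[key] = whole_body_required_mr(
                plan, env, state, cc_params=cc_params,
                counter_current=counter_current, target_mr=target_mr,
            )
        return cache[key]

    band_lo, band_hi = (1.0 - MR_BAND) * target_mr, (1.0 + MR_BAND) * target_mr

    state = _resting_state(plan)
    mr, heat, states = evaluate(state)

    def finish(state: CascadeState, mr: float, heat: float, states) -> HourSolution:
        return HourSolution(
            achieved_mr=max(mr, 0.0),
            achieved_heat=heat,
            target_mr=target_mr,
            cascade=state,
            part_states=tuple(states),
            evaluations=evals,
        )

    if band_lo <= mr <= band_hi:
        return finish(state, max(mr, target_mr * (1.0 - MR_BAND)), heat, states)

    def run_mechanisms(mechanisms, state, mr, heat, states, cold: bool):
        """Engage mechanisms in order; returns (entered_band, ...state)."""
        for apply_level in mechanisms:
            saturated = apply_level(state, 1.0)
            mr_sat, heat_sat, states_sat = evaluate(saturated)
            still_short = mr_sat > band_hi if cold else mr_sat < band_lo
            if still_short:
                state, mr, heat, states = saturated, mr_sat, heat_sat, states_sat
                continue
            # The band is crossed inside this mechanism's range: bisect.
            lo, hi = 0.0, 1.0
            best = (saturated, mr_sat, heat_sat, states_sat)
            while evals < _MAX_EVALS:
                mid = 0.5 * (lo + hi)
                trial = apply_level(state, mid)
                mr_m, heat_m, states_m = evaluate(trial)
                if band_lo <= mr_m <= band_hi:
                    best = (trial, mr_m, heat_m, states_m)
                    break
                overshoot = mr_m < band_lo if cold else mr_m > band_hi
                if overshoot:
                    hi = mid
                else:
                    lo = mid
                best = (trial, mr_m, heat_m, states_m)
                if hi - lo < 1e-6:
                    break
            return True, *best
        return False, state, mr, heat, states

    if mr > band_hi:
        # COLD side: reduce the requirement.
        p = physio
        mechanisms = [
            lambda s, lv: replace(s, ptiloerection=lv),
            lambda s, lv: replace(
                s,
                flesh_conductivity=p.flesh_conductivity
                + lv * (p.flesh_conductivity_min - p.flesh_conductivity),
            ),
            lambda s, lv: replace(
                s, core_temp=p.core_temp + lv * (p.core_temp_min - p.core_temp)
            ),
        ]
        ok, state, mr, heat, states = run_mechanisms(mechanisms, state, mr, heat, states, cold=True)
        if not ok:
            # Everything saturated: the extra heat is a thermoregulatory cost.
            return finish(state, mr, heat, states)
        return finish(state, mr, heat, states)

    # HOT side: the environment cannot remove the target heat production.
    p = physio
    dump_mechanisms = [
        lambda s, lv: replace(
            s,
            flesh_conductivity=p.flesh_conductivity
            + lv * (p.flesh_conductivity_max - p.flesh_conductivity),
        ),
        lambda s, lv: replace(s, leg_elevation=lv * _MAX_ELEVATION),
    ]
    ok, state, mr, heat, states = run_mechanisms(dump_mechanisms, state, mr, heat, states, cold=False)
    if ok:
        return finish(state, mr, heat, states)

    # Low-cost options exhausted at the core set point: heat stress.  The
    # reported rate is the maximum sustainable without raising core
    # temperature; panting (no energy cost) and, as a last resort, a core
    # rise are engaged to balance the remaining heat.
    sustainable_mr, sustainable_heat, sustainable_states = mr, heat, states
    state = replace(state, heat_stressed=True)

    relief_mechanisms = [
        lambda s, lv: replace(
            s,
            o2_extraction=p.o2_extraction_max
            + lv * (p.o2_extraction_min - p.o2_extraction_max),
        ),
        lambda s, lv: replace(
            s, core_temp=p.core_temp + lv * (p.core_temp_max - p.core_temp)
        ),
    ]
    ok, state, _, _, _ = run_mechanisms(relief_mechanisms, state, mr, heat, states, cold=False)
    return finish(state, sustainable_mr, sustainable_heat, sustainable_states)
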