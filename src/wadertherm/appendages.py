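"""Counter-current appendages and the wading split-leg model.

A counter-current heat exchange system lets the average temperature of a
bare appendage approach local ambient temperature, collapsing the
skin-to-environment gradient and with it convective and radiant heat
loss.  Appendage "core" temperature is modelled as a user-set offset
above local ambient, clamped between a freezing-protection floor and the
body core temperature; under heat stress the offset is raised (venous
shunting) before any other body part warms.

A wading leg is split at the waterline into a submerged segment (losing
heat to water by convection only, ambient = water) and an emergent
segment (full air-side exchange, ambient = air); the hour's energy is the
wading-fraction-weighted mix of the wading and dry solutions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from .constants import APPENDAGE_TISSUE_SHELL
from .geometry import BodyPart, ShapeSpec
from .heat_balance import PartState, PhysioParams, solve_surface
from .microclimate import HourlyEnvironment


@dataclass(frozen=True)
class CounterCurrentParams:
    """Parameters of the counter-current temperature rule."""

    dt_min: float = 1.0      # minimum offset above local ambient, C
    floor: float = 3.0       # absolute minimum appendage temperature, C
    ceiling: float = 40.7    # body core temperature, C

    def __post_init__(self) -> None:
        if self.dt_min < 0:
            raise ValueError("minimum offset must be non-negative")
        if self.floor >= self.ceiling:
            raise ValueError("appendage floor must lie below the ceiling")


@dataclass(frozen=True)
class WadingState:
    """One hour's wading conditions."""

    water_depth: float = 0.0       # m
    fraction: float = 0.0          # fraction of the hour spent wading
    water_temp: float = 15.0       # C
    water_velocity: float = 0.0    # m/s
    water_type: str = "fresh"

    def __post_init__(self) -> None:
        if self.water_depth < 0:
            raise ValueError("water depth cannot be negative")
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("wading fraction must lie in [0, 1]")

    def applied_to(self, env: HourlyEnvironment) -> HourlyEnvironment:
        """Stamp this hour's wading conditions onto an environment record."""
        from dataclasses import replace as _replace

        return _replace(
            env,
            water_depth=self.water_depth,
            wading_fraction=self.fraction,
            water_temp=self.water_temp,
            water_velocity=self.water_velocity,
        )


def appendage_core_temperature(
    local_ambient: float, params: CounterCurrentParams, elevation: float = 0.0
) -> float:
    """Average appendage temperature under counter-current exchange.

    ``clamp(ambient + dt_min + elevation, floor, ceiling)`` — the
    elevation term models reduced use of the counter-current vessels
    (venous shunting) during heat stress.
    """
    if elevation < 0:
        raise ValueError("stress elevation must be non-negative")
    t = local_ambient + params.dt_min + elevation
    return min(max(t, params.floor), params.ceiling)


def split_leg(leg: BodyPart, water_depth: float) -> tuple[Optional[BodyPart], Optional[BodyPart]]:
    """(submerged segment, emergent segment) of a leg standing in water.

    The cut is at the waterline: submerged length ``min(depth, leg
    length)``, cross-section unchanged.  Either segment may be ``None``
    when its length is zero.
    """
    if water_depth < 0:
        raise ValueError("water depth cannot be negative")
    length = leg.shape.length
    sub_len = min(water_depth, length)
    if sub_len <= 0.0:
        return None, leg
    if sub_len >= length:
        return leg, None
    submerged = replace(leg, name=leg.name + ":submerged",
                        shape=replace(leg.shape, length=sub_len))
    emergent = replace(leg, name=leg.name + ":emergent",
                       shape=replace(leg.shape, length=length - sub_len))
    return submerged, emergent


def _segment_state(
    segment: BodyPart,
    env: HourlyEnvironment,
    core_temp: float,
    physio: PhysioParams,
    medium: str,
) -> PartState:
    """Solve one leg segment, isothermal at its appendage core temperature
    with a thin conductive tissue shell (legs are mostly tendon and bone,
    so skin and core barely differ)."""
    area = segment.skin_area
    r_shell = APPENDAGE_TISSUE_SHELL / (physio.flesh_conductivity * area)
    return solve_surface(
        core_temp=core_temp,
        internal_resistance=r_shell,
        flesh_gamma=0.0,
        outer_area=area,
        char_dim=segment.shape.characteristic_dimension,
        env=env,
        medium=medium,
        absorptivity=(1.0 - segment.reflectivity) if medium == "air" else 0.0,
        wet_fraction=physio.skin_wetness if medium == "air" else 0.0,
        physio=physio,
        name=segment.name,
    )


def leg_hour_energy(
    leg: BodyPart,
    env: HourlyEnvironment,
    cc: CounterCurrentParams,
    physio: PhysioParams,
    elevation: float = 0.0,
    counter_current: bool = True,
    body_core_temp: Optional[float] = None,
) -> tuple[float, list[PartState]]:
    """Hourly mean heat loss (W) of one appendage, and its segment states.

    Wading and dry solutions are blended by the fraction of the hour
    spent wading.  With counter-current exchange disabled the appendage
    is held at body core temperature throughout.
    """
    if body_core_temp is None:
        body_core_temp = physio.core_temp

    def core_for(ambient: float) -> float:
        if not counter_current:
            return body_core_temp
        return appendage_core_temperature(ambient, cc, elevation)

    water = "salt_water" if getattr(env, "water_type", "fresh") == "salt" else "water"

    dry_state = _segment_state(leg, env, core_for(env.air_temp), physio, "air")
    states = [dry_state]
    dry_energy = dry_state.fluxes.generation

    frac = env.wading_fraction
    if frac <= 0.0 or env.water_depth <= 0.0:
        return dry_energy, states

    submerged, emergent = split_leg(leg, env.water_depth)
    wading_energy = 0.0
    if submerged is not None:
        st = _segment_state(submerged, env, core_for(env.water_temp), physio, water)
        wading_energy += st.fluxes.generation
        states.append(st)
    if emergent is not None:
        st = _segment_state(emergent, env, core_for(env.air_temp), physio, "air")
        wading_energy += st.fluxes.generation
        states.append(st)

    return frac * wading_energy + (1.0 - frac) * dry_energy, states
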