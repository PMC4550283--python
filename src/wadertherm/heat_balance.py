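"""Steady-state heat balance of body parts and the whole animal.

Each part is a series thermal circuit: distributed heat generation in the
flesh (giving the core-to-skin gradient), an optional subcutaneous fat
slab (torso), the feather layer, and a nonlinear outer-surface balance of
convection, long-wave radiation to sky/ground/surroundings, absorbed
solar, and cutaneous evaporation.  The solver finds the generation rate
that closes the balance at the prescribed core temperature; the whole-body
requirement sums the parts, adds respiratory evaporation, and converts
heat demand to metabolic rate through the activity-heat fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

from scipy.optimize import brentq

from .constants import (
    CONVECTIVE_ENHANCEMENT_AIR,
    CONVECTIVE_ENHANCEMENT_WATER,
    FAT_CONDUCTIVITY,
    FAT_DENSITY,
    GRAVITY,
    JOULES_PER_LITRE_O2,
    KELVIN,
    LATENT_HEAT_VAPORISATION,
    O2_FRACTION,
    SILHOUETTE_FRACTION,
    STEFAN_BOLTZMANN,
    SURFACE_EMISSIVITY,
    FluidProperties,
    air_properties,
    vapor_density,
    water_properties,
)
from .geometry import BodyPart, BodyPlan, ShapeSpec, surface_area
from .insulation import effective_conductivity, ptiloerect
from .microclimate import HourlyEnvironment

if TYPE_CHECKING:  # pragma: no cover
    from .appendages import CounterCurrentParams
    from .thermoregulation import CascadeState


class SolverError(RuntimeError):
    """The surface balance failed to converge."""


# ---------------------------------------------------------------------------
# Physiology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhysioParams:
    """Physiological inputs of the endotherm model."""

    bmr_w: float
    core_temp: float = 40.7
    core_temp_max: float = 44.0
    core_temp_min: float = 37.7
    flesh_conductivity: float = 0.5      # resting, W m^-1 K^-1
    flesh_conductivity_min: float = 0.4  # full vasoconstriction
    flesh_conductivity_max: float = 2.5  # full vasodilation
    fat_conductivity: float = FAT_CONDUCTIVITY
    activity_heat_fraction: float = 0.8
    o2_extraction_max: float = 31.0      # %, normal breathing
    o2_extraction_min: float = 2.12      # %, full pant
    skin_wetness: float = 0.002          # fraction of skin acting as free water
    config_factor_sky: float = 0.5
    config_factor_ground: float = 0.3

    def __post_init__(self) -> None:
        if not (self.core_temp_min <= self.core_temp <= self.core_temp_max):
            raise ValueError("core temperature outside [min, max] bounds")
        for f in (self.activity_heat_fraction, self.skin_wetness,
                  self.config_factor_sky, self.config_factor_ground):
            if not (0.0 <= f <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        if self.config_factor_sky + self.config_factor_ground > 1.0:
            raise ValueError("radiant configuration factors exceed 1")

    @property
    def config_factor_surroundings(self) -> float:
        return 1.0 - self.config_factor_sky - self.config_factor_ground

    def heat_from_mr(self, mr_w: float) -> float:
        """Metabolic heat released at metabolic rate ``mr_w`` when the rate
        is spent on basal functions plus activity: the basal component is
        all heat; the activity increment loses a fraction to external
        work."""
        return self.bmr_w + self.activity_heat_fraction * (mr_w - self.bmr_w)

    def mr_from_heat(self, heat_w: float, target_mr_w: float | None = None) -> float:
        """Metabolic rate producing ``heat_w`` of heat.

        Up to the target rate the above-basal increment is activity
        (fractionally lost to external work); heat demand beyond the
        target's heat output is met by thermogenesis at unit efficiency
        (shivering produces essentially pure heat).  Below basal the rate
        equals the sustainable heat output directly.
        """
        if target_mr_w is None:
            target_mr_w = self.bmr_w
        target_heat = self.heat_from_mr(target_mr_w)
        if heat_w >= target_heat:
            return target_mr_w + (heat_w - target_heat)
        if heat_w >= self.bmr_w:
            return self.bmr_w + (heat_w - self.bmr_w) / self.activity_heat_fraction
        return heat_w


@dataclass(frozen=True)
class Fluxes:
    """Per-part energy fluxes, W (losses positive)."""

    convection: float = 0.0
    ir_sky: float = 0.0
    ir_ground: float = 0.0
    ir_surroundings: float = 0.0
    solar_absorbed: float = 0.0
    cutaneous_evap: float = 0.0
    respiratory_evap: float = 0.0
    generation: float = 0.0

    @property
    def total_loss(self) -> float:
        return (
            self.convection + self.ir_sky + self.ir_ground + self.ir_surroundings
            + self.cutaneous_evap + self.respiratory_evap - self.solar_absorbed
        )


@dataclass(frozen=True)
class PartState:
    """Thermal state of one body part at a converged solution."""

    name: str
    core_temp: float
    skin_temp: float
    surface_temp: float
    fluxes: Fluxes


# ---------------------------------------------------------------------------
# Convection
# ---------------------------------------------------------------------------

_HILPERT_BANDS = (
    (0.4, 4.0, 0.989, 0.330),
    (4.0, 40.0, 0.911, 0.385),
    (40.0, 4.0e3, 0.683, 0.466),
    (4.0e3, 4.0e4, 0.193, 0.618),
    (4.0e4, 4.0e7, 0.027, 0.805),
)


def _forced_nusselt(re: float, pr: float) -> float:
    """Hilpert power-law for a cylinder in crossflow."""
    for lo, hi, c, m in _HILPERT_BANDS:
        if re < hi or (lo, hi) == _HILPERT_BANDS[-1][:2]:
            return c * re ** m * pr ** (1.0 / 3.0)
    raise AssertionError  # pragma: no cover


def _free_nusselt(ra: float, pr: float) -> float:
    """Churchill-Chu correlation for a horizontal cylinder."""
    ra = max(ra, 1e-10)
    return (
        0.60 + 0.387 * ra ** (1.0 / 6.0)
        / (1.0 + (0.559 / pr) ** (9.0 / 16.0)) ** (8.0 / 27.0)
    ) ** 2


def convection_coefficient(
    char_dim: float,
    speed: float,
    fluid: str,
    fluid_temp: float,
    surface_temp: Optional[float] = None,
    shape: Optional[ShapeSpec] = None,
) -> float:
    """Surface convection coefficient, W m^-2 K^-1.

    Forced convection from the Hilpert cylinder-in-crossflow correlation
    combined with a free-convection floor (Churchill-Chu); the larger of
    the two governs.  Fluid properties are evaluated at the film
    temperature.  Water yields coefficients more than an order of
    magnitude above air at equal speed and geometry.
    """
    if char_dim <= 0:
        raise ValueError("characteristic dimension must be positive")
    if speed < 0:
        raise ValueError("fluid speed cannot be negative")
    if surface_temp is None:
        surface_temp = fluid_temp + 5.0
    film = 0.5 * (fluid_temp + surface_temp)
    props: FluidProperties
    if fluid == "air":
        props = air_properties(film)
    elif fluid in ("water", "salt_water"):
        props = water_properties(film, salt=(fluid == "salt_water"))
    else:
        raise ValueError(f"unknown fluid {fluid!r}")

    h_forced = 0.0
    if speed > 0:
        re = speed * char_dim / props.kinematic_viscosity
        if re > 0.4:
            h_forced = _forced_nusselt(re, props.prandtl) * props.conductivity / char_dim

    delta_t = max(abs(surface_temp - fluid_temp), 0.1)
    alpha = props.kinematic_viscosity / props.prandtl
    ra = (
        GRAVITY * props.expansion_coeff * delta_t * char_dim ** 3
        / (props.kinematic_viscosity * alpha)
    )
    h_free = _free_nusselt(ra, props.prandtl) * props.conductivity / char_dim
    enhancement = CONVECTIVE_ENHANCEMENT_AIR if fluid == "air" else CONVECTIVE_ENHANCEMENT_WATER
    return enhancement * max(h_forced, h_free)


# ---------------------------------------------------------------------------
# Part-level balance
# ---------------------------------------------------------------------------

def _flesh_gamma(shape: ShapeSpec, flesh_k: float) -> float:
    """Core-to-skin resistance of distributed generation, K/W.

    From the steady conduction solutions with uniform volumetric heating:
    ``dT = G R^2 / (4 k V)`` for cylinder-like parts and
    ``dT = G c^2 / (6 k V)`` for ellipsoids (c the smallest semi-axis).
    """
    from .geometry import volume

    v = volume(shape)
    if shape.kind == "ellipsoid":
        r = min(shape.a, shape.b, shape.c)
        return r * r / (6.0 * flesh_k * v)
    r = math.sqrt(shape.a * shape.b)
    return r * r / (4.0 * flesh_k * v)


def _feather_network(
    part: BodyPart, ptilo_level: float, mean_layer_temp: float
) -> tuple[float, float]:
    """(thermal resistance K/W, outer surface area m^2) of the coat.

    The torso keeps separate dorsal (sky-facing) and ventral
    (ground-facing) resistances in parallel; other parts use the
    area-weighted mean layer.
    """
    layer = ptiloerect(part.feather, ptilo_level)
    skin_area = part.skin_area
    sides = (("dorsal", 0.5), ("ventral", 0.5)) if part.name == "torso" else (("mean", 1.0),)
    conductance = 0.0
    for side, weight in sides:
        depth = layer.mean_depth_m if side == "mean" else layer.depth_m(side)
        if depth <= 0:
            return 0.0, skin_area
        k_eff = effective_conductivity(layer, mean_layer_temp, side)
        outer_side = surface_area(part.shape.inflated(depth))
        mean_area = math.sqrt(skin_area * outer_side)
        conductance += weight * k_eff * mean_area / depth
    outer_area = surface_area(part.shape.inflated(layer.mean_depth_m))
    return 1.0 / conductance, outer_area


def _surface_loss(
    ts: float,
    *,
    outer_area: float,
    char_dim: float,
    env: HourlyEnvironment,
    medium: str,
    absorptivity: float,
    wet_fraction: float,
    physio: PhysioParams,
    emissivity: float = SURFACE_EMISSIVITY,
) -> Fluxes:
    """All outward surface fluxes at surface temperature ``ts``."""
    if medium != "air":
        h = convection_coefficient(char_dim, env.water_velocity, medium, env.water_temp, ts)
        return Fluxes(convection=h * outer_area * (ts - env.water_temp))

    h = convection_coefficient(char_dim, env.wind, "air", env.air_temp, ts)
    conv = h * outer_area * (ts - env.air_temp)
    ts_k4 = (ts + KELVIN) ** 4
    rad = emissivity * STEFAN_BOLTZMANN * outer_area
    ir_sky = rad * physio.config_factor_sky * (ts_k4 - (env.sky_temp + KELVIN) ** 4)
    ir_ground = rad * physio.config_factor_ground * (ts_k4 - (env.ground_temp + KELVIN) ** 4)
    ir_sur = rad * physio.config_factor_surroundings * (ts_k4 - (env.air_temp + KELVIN) ** 4)
    solar = absorptivity * SILHOUETTE_FRACTION * outer_area * env.solar

    evap = 0.0
    if wet_fraction > 0:
        props = air_properties(0.5 * (ts + env.air_temp))
        h_m = h / (props.density * props.specific_heat * 0.89 ** (2.0 / 3.0))
        dvap = vapor_density(ts, 100.0) - vapor_density(env.air_temp, env.rh)
        evap = max(
            wet_fraction * outer_area * h_m * dvap * LATENT_HEAT_VAPORISATION, 0.0
        )
    return Fluxes(
        convection=conv,
        ir_sky=ir_sky,
        ir_ground=ir_ground,
        ir_surroundings=ir_sur,
        solar_absorbed=solar,
        cutaneous_evap=evap,
    )


def solve_surface(
    *,
    core_temp: float,
    internal_resistance: float,
    flesh_gamma: float,
    outer_area: float,
    char_dim: float,
    env: HourlyEnvironment,
    medium: str = "air",
    absorptivity: float = 0.0,
    wet_fraction: float = 0.0,
    physio: PhysioParams,
    name: str = "part",
) -> PartState:
    """Find the generation rate closing the balance at ``core_temp``.

    Solves ``(core - Ts) / R_internal = Q_out(Ts)`` for the outer-surface
    temperature by bracketed root finding, then reads off the generation
    and the intermediate skin temperature.
    """
    ref = env.water_temp if medium != "air" else env.air_temp

    def residual(ts: float) -> float:
        loss = _surface_loss(
            ts,
            outer_area=outer_area,
            char_dim=char_dim,
            env=env,
            medium=medium,
            absorptivity=absorptivity,
            wet_fraction=wet_fraction,
            physio=physio,
        ).total_loss
        return (core_temp - ts) / internal_resistance - loss

    lo = min(core_temp, ref, env.sky_temp if medium == "air" else ref) - 60.0
    hi = max(core_temp, ref) + 80.0
    try:
        ts = brentq(residual, lo, hi, xtol=1e-9, rtol=1e-12, maxiter=200)
    except ValueError as exc:  # pragma: no cover - diagnostics path
        raise SolverError(
            f"surface balance failed for {name!r}: core={core_temp}, env={ref}"
        ) from exc

    generation = (core_temp - ts) / internal_resistance
    fluxes = _surface_loss(
        ts,
        outer_area=outer_area,
        char_dim=char_dim,
        env=env,
        medium=medium,
        absorptivity=absorptivity,
        wet_fraction=wet_fraction,
        physio=physio,
    )
    fluxes = Fluxes(
        convection=fluxes.convection,
        ir_sky=fluxes.ir_sky,
        ir_ground=fluxes.ir_ground,
        ir_surroundings=fluxes.ir_surroundings,
        solar_absorbed=fluxes.solar_absorbed,
        cutaneous_evap=fluxes.cutaneous_evap,
        generation=generation,
    )
    skin = core_temp - generation * flesh_gamma
    return PartState(name=name, core_temp=core_temp, skin_temp=skin,
                     surface_temp=ts, fluxes=fluxes)


def part_required_generation(
    part: BodyPart,
    env: HourlyEnvironment,
    core_temp: float,
    flesh_k: float,
    physio: PhysioParams,
    ptilo_level: float = 0.0,
    fat_thickness: float = 0.0,
) -> PartState:
    """Required generation of one (non-appendage) body part.

    The series network is distributed-generation flesh, an optional fat
    slab, the feather layer, and the nonlinear surface balance.
    """
    gamma = _flesh_gamma(part.shape, flesh_k)
    skin_area = part.skin_area
    r_internal = gamma
    if fat_thickness > 0:
        r_internal += fat_thickness / (physio.fat_conductivity * skin_area)
    if part.feather is not None:
        mean_layer_t = 0.5 * (core_temp + env.air_temp)
        r_feather, outer_area = _feather_network(part, ptilo_level, mean_layer_t)
        r_internal += r_feather
        absorptivity = 1.0 - part.feather.reflectivity
        char_dim = part.shape.inflated(
            ptiloerect(part.feather, ptilo_level).mean_depth_m
        ).characteristic_dimension
    else:
        outer_area = skin_area
        absorptivity = 1.0 - part.reflectivity
        char_dim = part.shape.characteristic_dimension
    return solve_surface(
        core_temp=core_temp,
        internal_resistance=r_internal,
        flesh_gamma=gamma,
        outer_area=outer_area,
        char_dim=char_dim,
        env=env,
        absorptivity=absorptivity,
        wet_fraction=physio.skin_wetness,
        physio=physio,
        name=part.name,
    )


# ---------------------------------------------------------------------------
# Respiration
# ---------------------------------------------------------------------------

def respiratory_evaporation(
    mr_w: float,
    air_temp: float,
    rh: float,
    o2_extraction_percent: float,
    core_temp: float = 40.7,
) -> float:
    """Respiratory latent heat loss, W.

    Ventilation follows from the O2 demand of the metabolic rate and the
    extraction efficiency; exhaled air is saturated at core temperature,
    inhaled air at ambient temperature and humidity.  Panting is modelled
    as a drop in extraction efficiency (more air moved per unit O2).
    """
    if not (0.0 < o2_extraction_percent <= 100.0):
        raise ValueError("O2 extraction must lie in (0, 100]%")
    if mr_w <= 0:
        return 0.0
    o2_demand_l_s = mr_w / JOULES_PER_LITRE_O2
    ventilation_m3_s = o2_demand_l_s / (o2_extraction_percent / 100.0 * O2_FRACTION) * 1e-3
    dvap = vapor_density(core_temp, 100.0) - vapor_density(air_temp, rh)
    return max(ventilation_m3_s * dvap * LATENT_HEAT_VAPORISATION, 0.0)


# ---------------------------------------------------------------------------
# Whole-body requirement
# ---------------------------------------------------------------------------

def fat_slab_thickness(plan: BodyPlan) -> float:
    """Uniform subcutaneous fat thickness on the torso, m."""
    fat_mass = plan.mass * plan.fat_fraction
    torso = plan.part("torso")
    return fat_mass / (FAT_DENSITY * torso.skin_area)


def whole_body_required_mr(
    plan: BodyPlan,
    env: HourlyEnvironment,
    cascade: "CascadeState",
    cc_params: Optional["CounterCurrentParams"] = None,
    counter_current: bool = True,
    target_mr: Optional[float] = None,
) -> tuple[float, float, list[PartState]]:
    """(required metabolic rate W, required heat W, per-part states).

    Appendage parts (counter-current flag) are delegated to the appendage
    model, which handles the wading split and hour-fraction weighting; the
    respiratory-evaporation balance closes a small fixed point because
    ventilation scales with the metabolic rate itself.
    """
    from .appendages import CounterCurrentParams, leg_hour_energy

    physio = plan.physiology
    if cc_params is None:
        cc_params = CounterCurrentParams(ceiling=physio.core_temp)
    fat_t = fat_slab_thickness(plan) if any(p.name == "torso" for p in plan.parts) else 0.0

    states: list[PartState] = []
    heat_parts = 0.0
    for part in plan.parts:
        if part.counter_current:
            energy, seg_states = leg_hour_energy(
                part,
                env,
                cc_params,
                physio,
                elevation=cascade.leg_elevation,
                counter_current=counter_current,
                body_core_temp=cascade.core_temp,
            )
            heat_parts += energy
            states.extend(seg_states)
        else:
            st = part_required_generation(
                part,
                env,
                cascade.core_temp,
                cascade.flesh_conductivity,
                physio,
                ptilo_level=cascade.ptiloerection if part.feather is not None else 0.0,
                fat_thickness=fat_t if part.name == "torso" else 0.0,
            )
            heat_parts += st.fluxes.generation
            states.append(st)

    # Fixed point: respiratory loss depends on the metabolic rate whose
    # heat must cover it.  Converges in a few iterations (small coupling).
    mr = max(physio.bmr_w, physio.mr_from_heat(heat_parts, target_mr))
    for _ in range(8):
        q_resp = respiratory_evaporation(
            mr, env.air_temp, env.rh, cascade.o2_extraction, cascade.core_temp
        )
        heat = heat_parts + q_resp
        mr_for_resp = max(physio.mr_from_heat(heat, target_mr), physio.bmr_w)
        if abs(mr_for_resp - mr) < 1e-10:
            mr = mr_for_resp
            break
        mr = mr_for_resp
    q_resp = respiratory_evaporation(
        mr, env.air_temp, env.rh, cascade.o2_extraction, cascade.core_temp
    )
    heat = heat_parts + q_resp
    return physio.mr_from_heat(heat, target_mr), heat, states
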