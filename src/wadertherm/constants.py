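"""Physical constants, fluid-property correlations, and model-wide defaults.

Every coefficient that enters the heat-balance equations is named here so
that sensitivity experiments can perturb them and tests can pin them down.
Temperatures are degrees Celsius at module boundaries; radiation terms
convert to Kelvin internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# ---------------------------------------------------------------------------
# Universal constants
# ---------------------------------------------------------------------------

STEFAN_BOLTZMANN = 5.670374419e-8  # W m^-2 K^-4
KELVIN = 273.15
GRAVITY = 9.80665  # m s^-2

#: Thermal emissivity of biological surfaces (feathers, skin, bare legs).
SURFACE_EMISSIVITY = 0.98

#: Convective enhancement of rough, textured animal surfaces in air over
#: smooth-cylinder engineering correlations (feather texture and
#: irregular outline thin the boundary layer; measured convection from
#: animal shapes exceeds smooth-shape predictions by ~1.3-1.7x).  Smooth
#: wetted skin in water gets no enhancement.
CONVECTIVE_ENHANCEMENT_AIR = 1.5
CONVECTIVE_ENHANCEMENT_WATER = 1.0

#: Heat equivalent of oxygen consumption, J per litre O2 (mixed diet).
JOULES_PER_LITRE_O2 = 20_100.0

#: Ambient mole fraction of O2 in dry air.
O2_FRACTION = 0.2095

#: Latent heat of vaporisation of water, J g^-1 (at ~35 C).
LATENT_HEAT_VAPORISATION = 2_420.0

#: Thermal conductivity of keratin (feather elements), W m^-1 K^-1.
KERATIN_CONDUCTIVITY = 0.20

#: Density of subcutaneous fat, kg m^-3.
FAT_DENSITY = 900.0

#: Thermal conductivity of subcutaneous fat, W m^-1 K^-1 (not printed in the
#: source tables; standard adipose value).
FAT_CONDUCTIVITY = 0.20

#: Watts -> kJ/day conversion (86_400 s / 1000).
WATTS_TO_KJ_PER_DAY = 86.4

#: Conductive tissue shell assumed for counter-current appendages, m.
#: Appendages are treated as near-isothermal at their computed core
#: temperature (mostly tendon and bone, small diameter); this thin
#: conductive offset separates core from skin.
APPENDAGE_TISSUE_SHELL = 0.001

#: Default whole-animal flesh density target, kg m^-3.
FLESH_DENSITY_TARGET = 633.3

#: Fraction of total surface area intercepting the direct solar beam
#: (orientation-averaged silhouette).
SILHOUETTE_FRACTION = 0.5

#: Solar constant, W m^-2.
SOLAR_CONSTANT = 1361.0

#: Clear-sky broadband atmospheric transmittance (per unit air mass).
ATMOSPHERIC_TRANSMITTANCE = 0.72

#: Fraction of the flux removed from the direct beam that reappears as
#: diffuse sky radiation on a horizontal surface.
DIFFUSE_FRACTION = 0.3

#: Cloud attenuation: flux multiplied by (1 - CLOUD_ATTENUATION * c^2) with
#: c the cloud fraction in [0, 1].
CLOUD_ATTENUATION = 0.65

#: Aerodynamic roughness length used for the log wind profile, m.
ROUGHNESS_LENGTH = 0.02

#: Reference height of wind-speed inputs, m.
WIND_REFERENCE_HEIGHT = 2.0


# ---------------------------------------------------------------------------
# Fluid properties at film temperature
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FluidProperties:
    """Thermophysical properties of the convective medium."""

    density: float            # kg m^-3
    conductivity: float       # W m^-1 K^-1
    kinematic_viscosity: float  # m^2 s^-1
    prandtl: float
    expansion_coeff: float    # K^-1
    specific_heat: float      # J kg^-1 K^-1


def air_properties(temp_c: float) -> FluidProperties:
    """Dry-air properties, linearised around typical outdoor temperatures.

    Fits to standard property tables over -50..+50 C; adequate to well
    under 1% for conductivity and a few percent for viscosity.
    """
    t_k = temp_c + KELVIN
    density = 101_325.0 / (287.05 * t_k)
    conductivity = 0.0241 + 7.6e-5 * temp_c
    dyn_visc = 1.716e-5 * (t_k / 273.15) ** 1.5 * (273.15 + 110.4) / (t_k + 110.4)
    kin_visc = dyn_visc / density
    return FluidProperties(
        density=density,
        conductivity=conductivity,
        kinematic_viscosity=kin_visc,
        prandtl=0.71,
        expansion_coeff=1.0 / t_k,
        specific_heat=1006.0,
    )


def water_properties(temp_c: float, salt: bool = False) -> FluidProperties:
    """Liquid-water properties over 0..45 C (quadratic fits to tables)."""
    t = max(temp_c, 0.0)
    density = 1000.0 - 0.0863 * t - 0.0035 * t * t
    if salt:
        density += 25.0
    conductivity = 0.561 + 0.0019 * t - 7.0e-6 * t * t
    kin_visc = 1.79e-6 / (1.0 + 0.0337 * t + 0.000221 * t * t)
    # Thermal expansion of water is strongly T dependent near 4 C.
    expansion = max(1.0e-5, -68.0e-6 + 17.1e-6 * t - 0.066e-6 * t * t)
    specific_heat = 4186.0
    alpha = conductivity / (density * specific_heat)
    prandtl = kin_visc / alpha
    return FluidProperties(
        density=density,
        conductivity=conductivity,
        kinematic_viscosity=kin_visc,
        prandtl=prandtl,
        expansion_coeff=expansion,
        specific_heat=specific_heat,
    )


def saturation_vapor_pressure(temp_c: float) -> float:
    """Saturation vapour pressure over water, Pa (Tetens formula)."""
    import math

    return 610.78 * math.exp(17.269 * temp_c / (temp_c + 237.3))


def vapor_density(temp_c: float, rh_percent: float) -> float:
    """Absolute humidity, g m^-3, at the given temperature and RH."""
    e = saturation_vapor_pressure(temp_c) * rh_percent / 100.0
    return e / (461.5 * (temp_c + KELVIN)) * 1000.0


# ---------------------------------------------------------------------------
# Energy equivalents of metabolic substrates (per gram oxidised)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Substrate:
    """Oxidation bookkeeping for one dietary substrate."""

    energy_kj_per_g: float
    o2_l_per_g: float
    co2_l_per_g: float

    @property
    def rq(self) -> float:
        return self.co2_l_per_g / self.o2_l_per_g


SUBSTRATES: dict[str, Substrate] = {
    "carbohydrate": Substrate(energy_kj_per_g=17.5, o2_l_per_g=0.84, co2_l_per_g=0.84),
    "fat": Substrate(energy_kj_per_g=39.6, o2_l_per_g=2.02, co2_l_per_g=1.43),
    "protein": Substrate(energy_kj_per_g=18.1, o2_l_per_g=0.96, co2_l_per_g=0.78),
}

#: Molar volume of an ideal gas at STP, L mol^-1.
MOLAR_VOLUME_STP = 22.414

#: One-pool CO2-production coefficients: rCO2 = (N / ONE_POOL_DIVISOR)
#: * (k_o - k_d) - ONE_POOL_FRACTIONATION * k_d * N, with N the body water
#: pool in moles and rates in day^-1.
ONE_POOL_DIVISOR = 2.078
ONE_POOL_FRACTIONATION = 0.0062
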