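"""Hourly microclimate at the animal's position.

Daily weather records (min/max air temperature, wind, relative humidity,
plus cloud cover and the timing of the extremes) are expanded into hourly
series with piecewise-cosine interpolation between consecutive extremes.
Solar radiation comes from a clear-sky solar-position model attenuated by
cloud; the effective radiant sky temperature from a vapour-pressure
emissivity correlation.  Directly measured hourly records pass through
unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .constants import (
    ATMOSPHERIC_TRANSMITTANCE,
    CLOUD_ATTENUATION,
    DIFFUSE_FRACTION,
    KELVIN,
    ROUGHNESS_LENGTH,
    SOLAR_CONSTANT,
    WIND_REFERENCE_HEIGHT,
    saturation_vapor_pressure,
)


@dataclass(frozen=True)
class Site:
    """Location and terrain of the study site."""

    latitude: float = 43.47     # degrees; defaults: southern Wisconsin pond
    longitude: float = -89.74
    elevation: float = 260.0    # m
    slope: float = 0.0          # degrees
    aspect: float = 0.0         # degrees from north

    def __post_init__(self) -> None:
        if abs(self.latitude) > 90.0:
            raise ValueError("latitude must lie in [-90, 90]")


@dataclass(frozen=True)
class DailyWeather:
    """One day's extremes, expanded to hourly series by interpolation.

    ``t_min_offset`` is hours after sunrise at which the air-temperature
    minimum occurs; ``t_max_offset`` hours after solar noon for the
    maximum.  Wind shares the temperature phase; relative humidity is
    anti-phased (highest RH at the temperature minimum).
    """

    julian_day: int
    air_min: float
    air_max: float
    wind_min: float = 0.1
    wind_max: float = 1.0
    rh_min: float = 40.0
    rh_max: float = 90.0
    cloud_percent: float = 0.0
    t_min_offset: float = 0.0
    t_max_offset: float = 1.0

    def __post_init__(self) -> None:
        for lo, hi, what in (
            (self.air_min, self.air_max, "air temperature"),
            (self.wind_min, self.wind_max, "wind"),
            (self.rh_min, self.rh_max, "relative humidity"),
        ):
            if lo > hi:
                raise ValueError(f"daily {what} minimum exceeds maximum")
        if not (0.0 <= self.cloud_percent <= 100.0):
            raise ValueError("cloud cover must lie in [0, 100]%")


@dataclass(frozen=True)
class HourlyEnvironment:
    """One hour's microclimate at animal height (interval [hour, hour+1))."""

    hour: int
    air_temp: float          # C
    wind: float              # m/s at animal mid-height
    rh: float                # %
    solar: float             # W/m^2, horizontal global
    sky_temp: float          # C
    ground_temp: float       # C
    water_temp: float = 15.0  # C
    water_depth: float = 0.0  # m
    water_velocity: float = 0.0  # m/s
    wading_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rh <= 100.0):
            raise ValueError("relative humidity must lie in [0, 100]%")
        if not (0.0 <= self.wading_fraction <= 1.0):
            raise ValueError("wading fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Solar geometry
# ---------------------------------------------------------------------------

def solar_declination(julian_day: int) -> float:
    """Solar declination, degrees."""
    return 23.45 * math.sin(2.0 * math.pi * (284 + julian_day) / 365.0)


def cos_zenith(site: Site, julian_day: int, hour: float) -> float:
    """Cosine of the solar zenith angle at local solar ``hour``."""
    decl = math.radians(solar_declination(julian_day))
    lat = math.radians(site.latitude)
    hour_angle = math.radians(15.0 * (hour - 12.0))
    return math.sin(lat) * math.sin(decl) + math.cos(lat) * math.cos(decl) * math.cos(hour_angle)


def sunrise_hour(site: Site, julian_day: int) -> float:
    """Local solar hour of sunrise (6.0 for a polar day/night fallback)."""
    decl = math.radians(solar_declination(julian_day))
    lat = math.radians(site.latitude)
    x = -math.tan(lat) * math.tan(decl)
    if not (-1.0 < x < 1.0):
        return 6.0
    return 12.0 - math.degrees(math.acos(x)) / 15.0


def clear_sky_solar(
    site: Site,
    julian_day: int,
    hour: float,
    cloud_percent: float = 0.0,
    transmittance: float = ATMOSPHERIC_TRANSMITTANCE,
) -> float:
    """Horizontal global solar flux, W m^-2.

    Beam transmission uses the broadband transmittance raised to the
    optical air mass (Kasten-Young); cloud attenuates the global flux by
    ``1 - 0.65 c^2``.  Zero whenever the sun is below the horizon.
    """
    mu = cos_zenith(site, julian_day, hour)
    if mu <= 0.0:
        return 0.0
    zenith_deg = math.degrees(math.acos(mu))
    air_mass = 1.0 / (mu + 0.50572 * (96.07995 - zenith_deg) ** -1.6364)
    global_flux = SOLAR_CONSTANT * transmittance ** air_mass * mu
    cloud = cloud_percent / 100.0
    return max(global_flux * (1.0 - CLOUD_ATTENUATION * cloud * cloud), 0.0)


def sky_temperature(air_temp: float, rh: float, cloud_percent: float = 0.0) -> float:
    """Effective radiant sky temperature, C.

    Clear-sky atmospheric emissivity from the vapour-pressure correlation
    of Idso (monotone in humidity), blended linearly toward blackbody
    (sky temperature = air temperature) at full cloud cover.
    """
    t_k = air_temp + KELVIN
    e_hpa = saturation_vapor_pressure(air_temp) * rh / 100.0 / 100.0
    emissivity_clear = min(0.70 + 5.95e-5 * e_hpa * math.exp(1500.0 / t_k), 1.0)
    cloud = cloud_percent / 100.0
    emissivity = emissivity_clear + cloud * (1.0 - emissivity_clear)
    return t_k * emissivity ** 0.25 - KELVIN


def wind_at_height(wind_ref: float, height: float) -> float:
    """Log-profile interpolation of the reference-height wind speed."""
    if height <= ROUGHNESS_LENGTH:
        return 0.0
    scale = math.log(height / ROUGHNESS_LENGTH) / math.log(
        WIND_REFERENCE_HEIGHT / ROUGHNESS_LENGTH
    )
    return max(wind_ref * scale, 0.0)


# ---------------------------------------------------------------------------
# Diurnal interpolation
# ---------------------------------------------------------------------------

def interpolate_diurnal(
    vmin: float, vmax: float, t_min: float, t_max: float, hours: Sequence[float] | None = None
) -> list[float]:
    """Piecewise-cosine diurnal curve attaining ``vmin`` at ``t_min`` and
    ``vmax`` at ``t_max`` (hours, wrap-around), evaluated hourly.

    Values never leave ``[vmin, vmax]``.
    """
    if vmin > vmax:
        raise ValueError("diurnal minimum exceeds maximum")
    if hours is None:
        hours = range(24)
    t_min %= 24.0
    t_max %= 24.0
    rise_span = (t_max - t_min) % 24.0 or 24.0    # min -> max
    fall_span = (t_min - t_max) % 24.0 or 24.0    # max -> next min

    out = []
    for h in hours:
        since_min = (h - t_min) % 24.0
        if since_min <= rise_span:
            phase = since_min / rise_span
            v = vmin + (vmax - vmin) * 0.5 * (1.0 - math.cos(math.pi * phase))
        else:
            phase = ((h - t_max) % 24.0) / fall_span
            v = vmax - (vmax - vmin) * 0.5 * (1.0 - math.cos(math.pi * phase))
        out.append(v)
    return out


def hourly_from_daily(
    day: DailyWeather,
    site: Site | None = None,
    ground_temp: Sequence[float] | None = None,
    water_temp: Sequence[float] | None = None,
) -> list[HourlyEnvironment]:
    """Expand one day of extremes into 24 hourly environment records.

    Ground temperature defaults to air temperature; water temperature (if
    given) is merged in, otherwise left at the record default.  Wading
    fields are filled in later from a wading schedule.
    """
    site = site or Site()
    rise = sunrise_hour(site, day.julian_day)
    t_min = rise + day.t_min_offset
    t_max = 12.0 + day.t_max_offset

    air = interpolate_diurnal(day.air_min, day.air_max, t_min, t_max)
    wind = interpolate_diurnal(day.wind_min, day.wind_max, t_min, t_max)
    # RH anti-phased with temperature: driest at the warmest hour.
    rh = interpolate_diurnal(day.rh_min, day.rh_max, t_max, t_min)

    records = []
    for h in range(24):
        solar = clear_sky_solar(site, day.julian_day, h + 0.5, day.cloud_percent)
        records.append(
            HourlyEnvironment(
                hour=h,
                air_temp=air[h],
                wind=wind[h],
                rh=rh[h],
                solar=solar,
                sky_temp=sky_temperature(air[h], rh[h], day.cloud_percent),
                ground_temp=ground_temp[h] if ground_temp is not None else air[h],
                water_temp=water_temp[h] if water_temp is not None else 15.0,
            )
        )
    return records


def chamber_environment(air_temp: float, wind: float = 0.01, rh: float = 5.0) -> HourlyEnvironment:
    """Metabolic-chamber conditions: all radiant surfaces at air temperature,
    no solar, still air, dry."""
    return HourlyEnvironment(
        hour=0,
        air_temp=air_temp,
        wind=wind,
        rh=rh,
        solar=0.0,
        sky_temp=air_temp,
        ground_temp=air_temp,
        water_temp=max(air_temp, 0.1),
    )
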