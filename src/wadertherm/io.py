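"""Configuration and tabular I/O.

Animal configurations are YAML (one block per body part plus mass and
physiology); weather, wading schedules, behavior observations and model
output are CSV with fixed, documented headers.  Temperatures are degrees
Celsius, wind and water velocity m/s, solar W/m^2, dimensions metres.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .appendages import CounterCurrentParams
from .geometry import BodyPart, BodyPlan, ShapeSpec, adjust_to_density
from .heat_balance import PhysioParams
from .insulation import FeatherLayer
from .microclimate import DailyWeather, HourlyEnvironment
from .thermoregulation import HourSolution

log = logging.getLogger("wadertherm")


class ConfigError(ValueError):
    """The animal configuration violates the schema."""


# ---------------------------------------------------------------------------
# Animal configuration
# ---------------------------------------------------------------------------

_PHYSIO_KEYS = {
    "bmr_w": ("bmr_w", None),
    "core_temp_c": ("core_temp", 40.7),
    "core_temp_max_c": ("core_temp_max", 44.0),
    "core_temp_min_c": ("core_temp_min", 37.7),
    "flesh_conductivity_w_mk": ("flesh_conductivity", 0.5),
    "flesh_conductivity_min_w_mk": ("flesh_conductivity_min", 0.4),
    "flesh_conductivity_max_w_mk": ("flesh_conductivity_max", 2.5),
    "activity_heat_fraction": ("activity_heat_fraction", 0.8),
    "o2_extraction_max_pct": ("o2_extraction_max", 31.0),
    "o2_extraction_min_pct": ("o2_extraction_min", 2.1),
    "skin_wetness_fraction": ("skin_wetness", 0.002),
    "config_factor_sky": ("config_factor_sky", 0.5),
    "config_factor_ground": ("config_factor_ground", 0.3),
}

_TOP_KEYS = {"name", "mass_kg", "fat_fraction", "density_target_kg_m3",
             "physiology", "counter_current", "parts"}
_PART_KEYS = {"shape", "semi_axes_m", "length_m", "proximal_semi_axes_m",
              "distal_semi_axes_m", "feather", "reflectivity", "counter_current"}
_FEATHER_KEYS = {"diameter_um", "density_per_cm2", "length_mm", "depth_mm",
                 "reflectivity"}


def _reject_unknown(mapping: Mapping[str, Any], allowed: set[str], context: str) -> None:
    unknown = sorted(set(mapping) - allowed)
    if unknown:
        raise ConfigError(f"unknown keys in {context}: {', '.join(unknown)}")


def _parse_feather(block: Mapping[str, Any], context: str) -> FeatherLayer:
    _reject_unknown(block, _FEATHER_KEYS, context)
    try:
        return FeatherLayer(
            element_diameter_um=float(block["diameter_um"]),
            element_density_per_cm2=float(block["density_per_cm2"]),
            length_dorsal_mm=float(block["length_mm"]["dorsal"]),
            length_ventral_mm=float(block["length_mm"]["ventral"]),
            depth_dorsal_mm=float(block["depth_mm"]["dorsal"]),
            depth_ventral_mm=float(block["depth_mm"]["ventral"]),
            reflectivity=float(block.get("reflectivity", 0.0)),
        )
    except KeyError as exc:
        raise ConfigError(f"missing feather key {exc} in {context}") from None


def _parse_shape(block: Mapping[str, Any], context: str) -> ShapeSpec:
    kind = block.get("shape")
    if kind == "ellipsoid":
        a, b, c = block["semi_axes_m"]
        return ShapeSpec(kind="ellipsoid", a=float(a), b=float(b), c=float(c))
    if kind == "elliptical_cylinder":
        a, b = block["semi_axes_m"]
        return ShapeSpec(kind="elliptical_cylinder", a=float(a), b=float(b),
                         length=float(block["length_m"]))
    if kind == "truncated_cone":
        pa, pb = block["proximal_semi_axes_m"]
        da, _db = block["distal_semi_axes_m"]
        return ShapeSpec(kind="truncated_cone", a=float(pa), b=float(pb),
                         length=float(block["length_m"]),
                         distal_ratio=float(da) / float(pa))
    raise ConfigError(f"unknown or missing shape kind in {context}: {kind!r}")


def parse_animal_config(doc: Mapping[str, Any], adjust_density: bool = True
                        ) -> tuple[BodyPlan, CounterCurrentParams]:
    """Validate a parsed YAML document into a BodyPlan (+ counter-current
    parameters).  Unknown keys are rejected; omitted physiological values
    fall back to documented defaults with a logged notice."""
    _reject_unknown(doc, _TOP_KEYS, "animal config")
    for required in ("mass_kg", "parts", "physiology"):
        if required not in doc:
            raise ConfigError(f"animal config missing required key {required!r}")

    phys_block = dict(doc["physiology"])
    _reject_unknown(phys_block, set(_PHYSIO_KEYS), "physiology")
    kwargs: dict[str, float] = {}
    for yaml_key, (field_name, default) in _PHYSIO_KEYS.items():
        if yaml_key in phys_block:
            kwargs[field_name] = float(phys_block[yaml_key])
        elif default is None:
            raise ConfigError(f"physiology missing required key {yaml_key!r}")
        else:
            log.info("physiology key %s absent; using default %s", yaml_key, default)
            kwargs[field_name] = default
    physio = PhysioParams(**kwargs)

    parts = []
    for name, block in doc["parts"].items():
        _reject_unknown(block, _PART_KEYS, f"part {name!r}")
        feather = _parse_feather(block["feather"], f"part {name!r}") \
            if "feather" in block else None
        parts.append(
            BodyPart(
                name=name,
                shape=_parse_shape(block, f"part {name!r}"),
                feather=feather,
                counter_current=bool(block.get("counter_current", False)),
                reflectivity=float(block.get("reflectivity", 0.0)),
            )
        )

    plan = BodyPlan(
        parts=tuple(parts),
        mass=float(doc["mass_kg"]),
        fat_fraction=float(doc.get("fat_fraction", 0.0)),
        physiology=physio,
        flesh_density_target=float(doc.get("density_target_kg_m3", 633.3)),
        name=str(doc.get("name", "animal")),
    )
    if adjust_density:
        plan = adjust_to_density(plan)

    cc_block = doc.get("counter_current", {})
    cc = CounterCurrentParams(
        dt_min=float(cc_block.get("dt_min_c", 1.0)),
        floor=float(cc_block.get("floor_c", 3.0)),
        ceiling=physio.core_temp,
    )
    return plan, cc


def read_animal_config(path: str | Path, adjust_density: bool = True
                       ) -> tuple[BodyPlan, CounterCurrentParams]:
    """Read and validate an animal YAML configuration file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ConfigError(f"{path}: not a mapping")
    return parse_animal_config(doc, adjust_density=adjust_density)


def load_crane(sex: str = "female", adjust_density: bool = True
               ) -> tuple[BodyPlan, CounterCurrentParams]:
    """Load a packaged whooping-crane configuration ('female' or 'male')."""
    if sex not in ("female", "male"):
        raise ValueError("sex must be 'female' or 'male'")
    ref = resources.files("wadertherm.data") / f"crane_{sex}.yaml"
    doc = yaml.safe_load(ref.read_text())
    return parse_animal_config(doc, adjust_density=adjust_density)


# ---------------------------------------------------------------------------
# Weather / schedule CSV dialects
# ---------------------------------------------------------------------------

DAILY_WEATHER_COLUMNS = ["julian_day", "Tmin", "Tmax", "Wmin", "Wmax",
                         "RHmin", "RHmax", "cloud"]
HOURLY_WEATHER_COLUMNS = ["day", "hour", "Ta", "wind", "RH", "solar", "water_T"]
WADING_COLUMNS = ["hour", "depth_m", "fraction", "water_T_C", "water_velocity_m_s"]
BEHAVIOR_COLUMNS = ["day", "time_s", "behavior", "water_depth_class"]
COST_COLUMNS = ["behavior", "cost_xbmr"]


def read_daily_weather(path: str | Path) -> list[DailyWeather]:
    df = pd.read_csv(path)
    _check_columns(df, DAILY_WEATHER_COLUMNS, path)
    return [
        DailyWeather(
            julian_day=int(r.julian_day), air_min=r.Tmin, air_max=r.Tmax,
            wind_min=r.Wmin, wind_max=r.Wmax, rh_min=r.RHmin, rh_max=r.RHmax,
            cloud_percent=r.cloud,
        )
        for r in df.itertuples()
    ]


def write_daily_weather(days: Sequence[DailyWeather], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"julian_day": d.julian_day, "Tmin": d.air_min, "Tmax": d.air_max,
             "Wmin": d.wind_min, "Wmax": d.wind_max, "RHmin": d.rh_min,
             "RHmax": d.rh_max, "cloud": d.cloud_percent}
            for d in days
        ],
        columns=DAILY_WEATHER_COLUMNS,
    ).to_csv(path, index=False)


def read_hourly_weather(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, HOURLY_WEATHER_COLUMNS, path)
    return df


def read_wading_schedule(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, WADING_COLUMNS, path)
    return df


def read_behavior_observations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, BEHAVIOR_COLUMNS, path)
    return df


def read_cost_table(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path)
    _check_columns(df, COST_COLUMNS, path)
    return dict(zip(df.behavior, df.cost_xbmr))


def _check_columns(df: pd.DataFrame, expected: Sequence[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing columns {missing}")


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

def hourly_log_frame(
    envs: Sequence[HourlyEnvironment], solutions: Sequence[HourSolution]
) -> pd.DataFrame:
    """Hour-by-hour cascade and flux log (mirrors the mechanism traces)."""
    rows = []
    for env, sol in zip(envs, solutions):
        c = sol.cascade
        total = {k: 0.0 for k in ("convection", "ir", "solar", "evap")}
        for st in sol.part_states:
            total["convection"] += st.fluxes.convection
            total["ir"] += st.fluxes.ir_sky + st.fluxes.ir_ground + st.fluxes.ir_surroundings
            total["solar"] += st.fluxes.solar_absorbed
            total["evap"] += st.fluxes.cutaneous_evap
        rows.append({
            "hour": env.hour, "Ta": env.air_temp, "wind": env.wind, "RH": env.rh,
            "solar": env.solar, "water_T": env.water_temp,
            "wading_fraction": env.wading_fraction,
            "target_MR_W": sol.target_mr, "achieved_MR_W": sol.achieved_mr,
            "heat_W": sol.achieved_heat,
            "ptiloerection": c.ptiloerection, "flesh_k": c.flesh_conductivity,
            "leg_elevation": c.leg_elevation, "core_T": c.core_temp,
            "O2_extraction": c.o2_extraction, "heat_stressed": c.heat_stressed,
            "convection_W": total["convection"], "ir_net_W": total["ir"],
            "solar_absorbed_W": total["solar"], "cutaneous_evap_W": total["evap"],
        })
    return pd.DataFrame(rows)


def write_results(
    out_dir: str | Path,
    hourly: pd.DataFrame,
    daily: pd.DataFrame | None = None,
    summary: Mapping[str, Any] | None = None,
    provenance: Mapping[str, Any] | None = None,
) -> None:
    """Write hourly/daily CSV logs, a text summary, and a provenance record."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hourly.to_csv(out / "hourly.csv", index=False, float_format="%.10g")
    if daily is not None:
        daily.to_csv(out / "daily.csv", index=False, float_format="%.10g")
    if summary:
        with open(out / "summary.txt", "w") as fh:
            for key, value in summary.items():
                fh.write(f"{key}: {value}\n")
    if provenance:
        with open(out / "provenance.json", "w") as fh:
            json.dump(dict(provenance), fh, indent=2, sort_keys=True)


def provenance_record(seed: int | None = None, **extra: Any) -> dict[str, Any]:
    from . import __version__

    rec: dict[str, Any] = {"version": __version__, "seed": seed}
    rec.update(extra)
    return rec


def config_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
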