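"""Feather-layer insulation.

Heat crosses the plumage by three parallel paths: conduction through the
still air trapped between feather elements, conduction along the keratin
elements themselves, and infrared radiation between surfaces inside the
coat.  The layer is characterised by the element diameter, the areal
element density on the skin, the element length, and the layer depth
(dorsal and ventral values may differ).  Ptiloerection deepens the layer
toward the full feather length, diluting the elements and lengthening the
insulating air columns.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

from .constants import KERATIN_CONDUCTIVITY, KELVIN, STEFAN_BOLTZMANN

#: Maximum feather volume fraction; denser layers are thinned to fit and a
#: warning is emitted (elements cannot overfill the layer).
MAX_VOLUME_FRACTION = 0.95


class OverfilledLayerWarning(UserWarning):
    """Element density reduced so the elements fit inside the layer."""


@dataclass(frozen=True)
class FeatherLayer:
    """Plumage description for one body part.

    ``depth`` is the resting thickness of the insulating layer;
    ``length`` is the full feather length, which bounds how far
    ptiloerection can deepen the layer.  Dorsal/ventral pairs are in mm,
    matching how they are measured; conversions to SI happen internally.
    """

    element_diameter_um: float
    element_density_per_cm2: float
    length_dorsal_mm: float
    length_ventral_mm: float
    depth_dorsal_mm: float
    depth_ventral_mm: float
    reflectivity: float = 0.0

    def __post_init__(self) -> None:
        if self.element_diameter_um <= 0 or self.element_density_per_cm2 <= 0:
            raise ValueError("feather element diameter and density must be positive")
        if self.depth_dorsal_mm > self.length_dorsal_mm + 1e-9:
            raise ValueError("dorsal layer depth cannot exceed feather length")
        if self.depth_ventral_mm > self.length_ventral_mm + 1e-9:
            raise ValueError("ventral layer depth cannot exceed feather length")
        if not (0.0 <= self.reflectivity <= 1.0):
            raise ValueError("reflectivity must lie in [0, 1]")
        # Elements must not overfill a unit of skin area.
        d = self.element_diameter_um * 1e-6
        n = self.element_density_per_cm2 * 1e4
        if n * math.pi * d * d / 4.0 >= 1.0:
            raise ValueError("feather elements overfill the skin surface")

    # -- SI accessors -------------------------------------------------------

    @property
    def mean_depth_m(self) -> float:
        return 0.5 * (self.depth_dorsal_mm + self.depth_ventral_mm) * 1e-3

    @property
    def mean_length_m(self) -> float:
        return 0.5 * (self.length_dorsal_mm + self.length_ventral_mm) * 1e-3

    def depth_m(self, side: str) -> float:
        return {"dorsal": self.depth_dorsal_mm, "ventral": self.depth_ventral_mm}[side] * 1e-3

    def length_m(self, side: str) -> float:
        return {"dorsal": self.length_dorsal_mm, "ventral": self.length_ventral_mm}[side] * 1e-3


def _still_air_conductivity(temp_c: float) -> float:
    return 0.0241 + 7.6e-5 * temp_c


def effective_conductivity(
    layer: FeatherLayer, mean_layer_temp_c: float, side: str = "mean"
) -> float:
    """Effective thermal conductivity of the feather layer, W m^-1 K^-1.

    Parallel combination of still-air conduction, keratin-element
    conduction weighted by the element volume fraction, and a radiative
    conductivity ``4*sigma*T^3*L`` whose photon free path ``L`` is limited
    by element packing and never exceeds the layer depth.  The result is
    bounded below by the still-air conductivity of the same layer.
    """
    if side == "mean":
        depth, length = layer.mean_depth_m, layer.mean_length_m
    else:
        depth, length = layer.depth_m(side), layer.length_m(side)
    d = layer.element_diameter_um * 1e-6
    n = layer.element_density_per_cm2 * 1e4  # elements per m^2 of skin

    # Fibre length per unit layer volume, m m^-3, and volume fraction.
    fibre_per_volume = n * length / depth
    fraction = fibre_per_volume * math.pi * d * d / 4.0
    if fraction > MAX_VOLUME_FRACTION:
        warnings.warn(
            "feather elements overfill the layer; element density reduced to fit",
            OverfilledLayerWarning,
            stacklevel=2,
        )
        shrink = MAX_VOLUME_FRACTION / fraction
        fraction = MAX_VOLUME_FRACTION
        fibre_per_volume *= shrink

    k_air = _still_air_conductivity(mean_layer_temp_c)
    k_cond = (1.0 - fraction) * k_air + fraction * KERATIN_CONDUCTIVITY

    # Radiative path: extinction coefficient ~ projected fibre area per
    # volume; free path capped at the layer depth (empty-layer limit).
    t_k = mean_layer_temp_c + KELVIN
    extinction = fibre_per_volume * d
    free_path = 1.0 / (extinction + 1.0 / depth)
    k_rad = 4.0 * STEFAN_BOLTZMANN * t_k ** 3 * free_path

    return max(k_cond + k_rad, k_air)


def thermal_resistance(
    layer: FeatherLayer, mean_layer_temp_c: float, side: str = "mean"
) -> float:
    """Area-specific resistance of the layer, m^2 K W^-1 (depth / k_eff)."""
    if side == "mean":
        depth = layer.mean_depth_m
    else:
        depth = layer.depth_m(side)
    return depth / effective_conductivity(layer, mean_layer_temp_c, side)


def ptiloerect(layer: FeatherLayer, level: float) -> FeatherLayer:
    """Erect the feathers: interpolate layer depth toward feather length.

    ``level`` 0 leaves the resting layer unchanged; 1 deepens each side to
    its full feather length.  The areal element density is unchanged, so
    the element volume fraction falls as the layer deepens.
    """
    if not (0.0 <= level <= 1.0):
        raise ValueError("ptiloerection level must lie in [0, 1]")
    if level == 0.0:
        return layer
    new_dorsal = layer.depth_dorsal_mm + level * (layer.length_dorsal_mm - layer.depth_dorsal_mm)
    new_ventral = layer.depth_ventral_mm + level * (
        layer.length_ventral_mm - layer.depth_ventral_mm
    )
    return replace(
        layer,
        depth_dorsal_mm=min(new_dorsal, layer.length_dorsal_mm),
        depth_ventral_mm=min(new_ventral, layer.length_ventral_mm),
    )
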