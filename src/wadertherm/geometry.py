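"""Body geometry: simple shapes, composite body plans, and posture changes.

An animal is modelled as a connected set of simple shapes with well-known
heat-transfer properties: an ellipsoidal torso, cylindrical neck and legs,
and truncated-cone head and beak.  This module provides those shapes
(surface areas, volumes, perimeters), assembly of a whole-body plan with a
mass budget, adjustment of photograph-derived dimensions to a whole-body
flesh density, and consolidation into the one-legged night roosting
posture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Literal, Optional, Sequence

from .constants import FLESH_DENSITY_TARGET

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .heat_balance import PhysioParams
    from .insulation import FeatherLayer


class InvalidDimensionError(ValueError):
    """A shape dimension is non-positive or otherwise impossible."""


class UnsupportedShapeError(ValueError):
    """The requested shape kind is not one of the supported primitives."""


class InvalidPlanError(ValueError):
    """A body plan is incomplete or degenerate."""


ShapeKind = Literal["ellipsoid", "elliptical_cylinder", "truncated_cone"]


def ellipse_circumference(a: float, b: float) -> float:
    """Perimeter of an ellipse with semi-axes ``a`` and ``b`` (metres).

    Uses Ramanujan's first approximation
    ``C ~= pi * [3(a+b) - sqrt((3a+b)(a+3b))]``, accurate to well within
    0.5% for aspect ratios up to ~5.
    """
    if a <= 0 or b <= 0:
        raise InvalidDimensionError(f"ellipse semi-axes must be positive, got {a}, {b}")
    return math.pi * (3.0 * (a + b) - math.sqrt((3.0 * a + b) * (a + 3.0 * b)))


def _ellipse_area(a: float, b: float) -> float:
    return math.pi * a * b


@dataclass(frozen=True)
class ShapeSpec:
    """Geometric primitive for one body part.

    Parameters are metres.  Meaning by ``kind``:

    ellipsoid
        semi-axes ``a`` (half length), ``b``, ``c`` (half diameters).
    elliptical_cylinder
        cross-section semi-axes ``a``, ``b``; ``length`` along the axis.
    truncated_cone
        proximal end semi-axes ``a``, ``b``; distal end scaled by
        ``distal_ratio`` in (0, 1]; ``length`` along the axis.  Ends keep a
        constant a:b ratio, so ``distal_ratio = 0`` is a full cone and
        ``distal_ratio = 1`` a cylinder.
    """

    kind: ShapeKind
    a: float
    b: float
    c: float = 0.0
    length: float = 0.0
    distal_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("ellipsoid", "elliptical_cylinder", "truncated_cone"):
            raise UnsupportedShapeError(f"unknown shape kind {self.kind!r}")
        if self.a <= 0 or self.b <= 0:
            raise InvalidDimensionError("semi-axes must be positive")
        if self.kind == "ellipsoid" and self.c <= 0:
            raise InvalidDimensionError("ellipsoid needs three positive semi-axes")
        if self.kind != "ellipsoid" and self.length <= 0:
            raise InvalidDimensionError("cylinder/cone needs a positive length")
        if self.kind == "truncated_cone" and not (0.0 <= self.distal_ratio <= 1.0):
            raise InvalidDimensionError("distal end must not exceed the proximal end")

    # -- derived quantities -------------------------------------------------

    def scaled(self, factor: float) -> "ShapeSpec":
        """Uniformly rescale every linear dimension by ``factor``."""
        if factor <= 0:
            raise InvalidDimensionError("scale factor must be positive")
        return replace(
            self,
            a=self.a * factor,
            b=self.b * factor,
            c=self.c * factor,
            length=self.length * factor,
        )

    def inflated(self, depth: float) -> "ShapeSpec":
        """Shape with every transverse dimension grown radially by ``depth``
        (used to build the outer feather surface around a flesh core)."""
        if depth <= 0:
            return self
        if self.kind == "ellipsoid":
            return replace(self, a=self.a + depth, b=self.b + depth, c=self.c + depth)
        if self.kind == "elliptical_cylinder":
            return replace(self, a=self.a + depth, b=self.b + depth)
        # Truncated cone: grow both ends by the same depth; keep length.
        new_a = self.a + depth
        new_ratio = (self.a * self.distal_ratio + depth) / new_a
        return replace(self, a=new_a, b=self.b + depth, distal_ratio=min(new_ratio, 1.0))

    @property
    def characteristic_dimension(self) -> float:
        """Length scale for convection correlations (flow across the part)."""
        if self.kind == "ellipsoid":
            return self.b + self.c  # mean transverse diameter
        if self.kind == "elliptical_cylinder":
            return self.a + self.b
        mid = 0.5 * (1.0 + self.distal_ratio)
        return (self.a + self.b) * mid


def volume(shape: ShapeSpec) -> float:
    """Volume of a shape, m^3."""
    if shape.kind == "ellipsoid":
        return 4.0 / 3.0 * math.pi * shape.a * shape.b * shape.c
    if shape.kind == "elliptical_cylinder":
        return math.pi * shape.a * shape.b * shape.length
    if shape.kind == "truncated_cone":
        s1 = _ellipse_area(shape.a, shape.b)
        s2 = _ellipse_area(shape.a * shape.distal_ratio, shape.b * shape.distal_ratio)
        return shape.length / 3.0 * (s1 + math.sqrt(s1 * s2) + s2)
    raise UnsupportedShapeError(shape.kind)  # pragma: no cover


_THOMSEN_P = 1.6075


def surface_area(shape: ShapeSpec, end_caps: bool = False) -> float:
    """Surface area of a shape, m^2.

    Ellipsoids use the Thomsen approximation (p = 1.6075, error < ~1%);
    cylinders and cones use the lateral area from the Ramanujan perimeter
    (plus elliptical end caps when ``end_caps`` is set).
    """
    if shape.kind == "ellipsoid":
        ap, bp, cp = (x ** _THOMSEN_P for x in (shape.a, shape.b, shape.c))
        return 4.0 * math.pi * ((ap * bp + ap * cp + bp * cp) / 3.0) ** (1.0 / _THOMSEN_P)
    if shape.kind == "elliptical_cylinder":
        area = ellipse_circumference(shape.a, shape.b) * shape.length
        if end_caps:
            area += 2.0 * _ellipse_area(shape.a, shape.b)
        return area
    if shape.kind == "truncated_cone":
        r = shape.distal_ratio
        mean_circ = 0.5 * (
            ellipse_circumference(shape.a, shape.b)
            + (ellipse_circumference(shape.a * r, shape.b * r) if r > 0 else 0.0)
        )
        dr = 0.5 * (shape.a + shape.b) * (1.0 - r)  # mean radial shrink
        slant = math.hypot(shape.length, dr)
        area = mean_circ * slant
        if end_caps:
            area += _ellipse_area(shape.a, shape.b) + _ellipse_area(shape.a * r, shape.b * r)
        return area
    raise UnsupportedShapeError(shape.kind)  # pragma: no cover


# ---------------------------------------------------------------------------
# Body parts and whole-body plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BodyPart:
    """One body part: a flesh shape, optional feather layer, radiative
    properties, and whether it carries counter-current heat exchange."""

    name: str
    shape: ShapeSpec
    feather: Optional["FeatherLayer"] = None
    counter_current: bool = False
    reflectivity: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.reflectivity <= 1.0):
            raise InvalidDimensionError("reflectivity must lie in [0, 1]")

    @property
    def flesh_volume(self) -> float:
        return volume(self.shape)

    @property
    def skin_area(self) -> float:
        return surface_area(self.shape)


@dataclass(frozen=True)
class BodyPlan:
    """The whole animal: parts, mass budget, and physiology."""

    parts: tuple[BodyPart, ...]
    mass: float  # kg
    fat_fraction: float
    physiology: "PhysioParams"
    flesh_density_target: float = FLESH_DENSITY_TARGET
    name: str = "animal"

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise InvalidPlanError("body mass must be positive")
        if not (0.0 <= self.fat_fraction < 1.0):
            raise InvalidPlanError("fat fraction must lie in [0, 1)")

    # -- lookups ------------------------------------------------------------

    def part(self, name: str) -> BodyPart:
        for p in self.parts:
            if p.name == name:
                return p
        raise InvalidPlanError(f"body plan has no part named {name!r}")

    @property
    def total_flesh_volume(self) -> float:
        return sum(p.flesh_volume for p in self.parts)

    @property
    def flesh_density(self) -> float:
        v = self.total_flesh_volume
        if v <= 0:
            raise InvalidPlanError("body plan has zero flesh volume")
        return self.mass / v

    def part_mass(self, name: str) -> float:
        """Mass allocated to one part, proportional to its flesh volume."""
        return self.mass * self.part(name).flesh_volume / self.total_flesh_volume


#: Relative density mismatch above which dimensions are rescaled.
DENSITY_TOLERANCE = 0.05


def adjust_to_density(plan: BodyPlan) -> BodyPlan:
    """Rescale photograph-derived dimensions onto the mass budget.

    Morphometric dimensions measured from photographs are subject to
    foreshortening error, while body mass is measured directly.  If the
    implied whole-body flesh density differs from the target (633.3 kg/m^3
    for plucked birds) by more than 5%, every linear flesh dimension is
    multiplied by the common cube-root factor that restores the target
    density exactly.  Aspect ratios are preserved and feather layers are
    untouched.  Idempotent: a conforming plan is returned unchanged.
    """
    density = plan.flesh_density
    target = plan.flesh_density_target
    if abs(density - target) / target <= DENSITY_TOLERANCE:
        return plan
    factor = (density / target) ** (1.0 / 3.0)
    parts = tuple(replace(p, shape=p.shape.scaled(factor)) for p in plan.parts)
    return replace(plan, parts=parts)


_NIGHT_ABSORBED = ("torso", "head", "neck", "beak")


def consolidate_night_posture(
    plan: BodyPlan, standing_leg: str = "left_leg", tucked_leg: str = "right_leg"
) -> BodyPlan:
    """Collapse the plan into the one-legged roosting posture.

    While sleeping the bird stands on one leg with the head, neck, beak and
    second leg tucked into the torso plumage.  The consolidated plan is a
    two-part body: an enlarged ellipsoid whose flesh volume equals the sum
    of torso + head + neck + beak + tucked leg (torso axis ratios and torso
    feather layer preserved) standing on the unchanged remaining leg.
    """
    for required in _NIGHT_ABSORBED + (standing_leg, tucked_leg):
        plan.part(required)  # raises InvalidPlanError when missing

    torso = plan.part("torso")
    absorbed = sum(plan.part(n).flesh_volume for n in _NIGHT_ABSORBED)
    absorbed += plan.part(tucked_leg).flesh_volume
    scale = (absorbed / torso.flesh_volume) ** (1.0 / 3.0)
    night_torso = replace(torso, shape=torso.shape.scaled(scale))
    leg = plan.part(standing_leg)
    return replace(plan, parts=(night_torso, leg), name=plan.name + "-night")
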