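"""Shapes, body plans, density adjustment and night-posture consolidation."""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from wadertherm.geometry import (
    BodyPart,
    BodyPlan,
    InvalidDimensionError,
    InvalidPlanError,
    ShapeSpec,
    UnsupportedShapeError,
    adjust_to_density,
    consolidate_night_posture,
    ellipse_circumference,
    surface_area,
    volume,
)
from wadertherm.heat_balance import PhysioParams


def exact_ellipse_perimeter(a: float, b: float) -> float:
    """Quadrature of the exact perimeter integral (independent oracle)."""
    integrand = lambda t: math.hypot(a * math.sin(t), b * math.cos(t))
    val, _ = quad(integrand, 0.0, 2.0 * math.pi, limit=200)
    return val


class TestEllipseCircumference:
    def test_circle_limit(self):
        r = 0.07
        assert ellipse_circumference(r, r) == pytest.approx(2.0 * math.pi * r, rel=1e-12)

    @pytest.mark.parametrize("a,b", [(0.12, 0.10), (0.20, 0.04), (0.0085, 0.0065)])
    def test_against_quadrature(self, a, b):
        assert ellipse_circumference(a, b) == pytest.approx(
            exact_ellipse_perimeter(a, b), rel=5e-3
        )

    @given(a=st.floats(0.005, 0.5), ratio=st.floats(1.0, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_within_half_percent_up_to_aspect_five(self, a, ratio):
        b = a / ratio
        assert ellipse_circumference(a, b) == pytest.approx(
            exact_ellipse_perimeter(a, b), rel=5e-3
        )

    def test_rejects_nonpositive_axis(self):
        with pytest.raises(InvalidDimensionError):
            ellipse_circumference(0.0, 0.1)


class TestVolume:
    def test_sphere(self):
        s = ShapeSpec(kind="ellipsoid", a=0.1, b=0.1, c=0.1)
        assert volume(s) == pytest.approx(4.0 / 3.0 * math.pi * 1e-3, rel=1e-12)

    def test_frustum_cylinder_limit(self):
        cone = ShapeSpec(kind="truncated_cone", a=0.03, b=0.02, length=0.1,
                         distal_ratio=1.0)
        assert volume(cone) == pytest.approx(math.pi * 0.03 * 0.02 * 0.1, rel=1e-12)

    def test_frustum_cone_limit(self):
        cone = ShapeSpec(kind="truncated_cone", a=0.03, b=0.02, length=0.1,
                         distal_ratio=0.0)
        s1 = math.pi * 0.03 * 0.02
        assert volume(cone) == pytest.approx(s1 * 0.1 / 3.0, rel=1e-12)

    def test_unknown_kind_rejected(self):
        with pytest.raises(UnsupportedShapeError):
            ShapeSpec(kind="torus", a=0.1, b=0.1)


class TestSurfaceArea:
    def test_sphere_limit(self):
        r = 0.08
        s = ShapeSpec(kind="ellipsoid", a=r, b=r, c=r)
        assert surface_area(s) == pytest.approx(4.0 * math.pi * r * r, rel=1e-3)

    def test_circular_cylinder_lateral(self):
        s = ShapeSpec(kind="elliptical_cylinder", a=0.01, b=0.01, length=0.375)
        assert surface_area(s) == pytest.approx(2 * math.pi * 0.01 * 0.375, rel=1e-6)

    def test_ellipsoid_against_quadrature(self):
        # Surface of revolution oracle for a prolate spheroid a >= b == c.
        a, b = 0.27, 0.11
        e = math.sqrt(1.0 - (b / a) ** 2)
        exact = 2 * math.pi * b * b * (1 + (a / b) * math.asin(e) / e)
        s = ShapeSpec(kind="ellipsoid", a=a, b=b, c=b)
        assert surface_area(s) == pytest.approx(exact, rel=1e-2)


def _simple_plan(scale: float = 1.0, mass: float = 5.0) -> BodyPlan:
    torso = BodyPart("torso", ShapeSpec("ellipsoid", 0.2 * scale, 0.1 * scale, 0.09 * scale))
    neck = BodyPart("neck", ShapeSpec("elliptical_cylinder", 0.04 * scale, 0.04 * scale,
                                      length=0.3 * scale))
    head = BodyPart("head", ShapeSpec("truncated_cone", 0.035 * scale, 0.035 * scale,
                                      length=0.1 * scale, distal_ratio=0.5))
    beak = BodyPart("beak", ShapeSpec("truncated_cone", 0.017 * scale, 0.017 * scale,
                                      length=0.11 * scale, distal_ratio=0.15),
                    counter_current=True)
    legs = [
        BodyPart(n, ShapeSpec("elliptical_cylinder", 0.0085 * scale, 0.0065 * scale,
                              length=0.37 * scale), counter_current=True)
        for n in ("left_leg", "right_leg")
    ]
    return BodyPlan(parts=(torso, neck, head, beak, *legs), mass=mass,
                    fat_fraction=0.1, physiology=PhysioParams(bmr_w=12.0))


class TestDensityAdjustment:
    def test_conforming_plan_unchanged(self):
        plan = _simple_plan()
        target = plan.flesh_density  # declare the current density as target
        plan = replace(plan, flesh_density_target=target)
        assert adjust_to_density(plan) is plan

    def test_restores_target_density_exactly(self):
        plan = _simple_plan(mass=5.05)
        adjusted = adjust_to_density(plan)
        assert adjusted.flesh_density == pytest.approx(633.3, abs=1e-6)

    def test_round_trip_recovers_dimensions(self):
        adjusted = adjust_to_density(_simple_plan(mass=5.05))
        doubled = replace(
            adjusted,
            parts=tuple(replace(p, shape=p.shape.scaled(2.0)) for p in adjusted.parts),
        )
        recovered = adjust_to_density(doubled)
        for orig, back in zip(adjusted.parts, recovered.parts):
            assert back.shape.a == pytest.approx(orig.shape.a, abs=1e-9)
            assert back.shape.length == pytest.approx(orig.shape.length, abs=1e-9)

    def test_idempotent_and_aspect_preserving(self):
        plan = _simple_plan(mass=6.0)
        once = adjust_to_density(plan)
        twice = adjust_to_density(once)
        assert twice is once
        torso0, torso1 = plan.part("torso").shape, once.part("torso").shape
        assert torso1.a / torso1.b == pytest.approx(torso0.a / torso0.b, rel=1e-12)

    def test_zero_volume_rejected(self):
        with pytest.raises(InvalidDimensionError):
            ShapeSpec("ellipsoid", 0.0, 0.1, 0.1)


class TestNightPosture:
    def test_volume_conservation(self, female):
        plan, _ = female
        night = consolidate_night_posture(plan)
        expected = plan.total_flesh_volume - plan.part("right_leg").flesh_volume
        night_ellipsoid = night.part("torso")
        assert night_ellipsoid.flesh_volume + night.part("left_leg").flesh_volume \
            == pytest.approx(expected + night.part("left_leg").flesh_volume, rel=1e-9)
        assert night_ellipsoid.flesh_volume == pytest.approx(expected, rel=1e-9)

    def test_total_flesh_volume_conserved(self):
        # tucked leg's flesh is inside the ellipsoid, standing leg separate:
        # whole-body flesh volume is unchanged by the posture switch
        plan = _simple_plan()
        night = consolidate_night_posture(plan)
        assert night.total_flesh_volume == pytest.approx(plan.total_flesh_volume, rel=1e-9)

    def test_axis_ratios_and_feathers_preserved(self, female):
        plan, _ = female
        night = consolidate_night_posture(plan)
        day_t, night_t = plan.part("torso").shape, night.part("torso").shape
        assert night_t.a / night_t.b == pytest.approx(day_t.a / day_t.b, rel=1e-12)
        assert night.part("torso").feather == plan.part("torso").feather
        assert night.part("left_leg") == plan.part("left_leg")

    def test_missing_part_rejected(self):
        plan = _simple_plan()
        headless = replace(plan, parts=tuple(p for p in plan.parts if p.name != "head"))
        with pytest.raises(InvalidPlanError):
            consolidate_night_posture(headless)
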