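"""Probe contact geometry and a quasi-static penetration force model.

Covers the three texture-analyzer probes used on gel cylinders: a
cylindrical punch, a spherical (ball) plunger, and a conical probe.
``contact_area`` gives the instantaneous wetted surface of the probe at a
penetration depth, used to normalize measured force per unit contact area.

``simulate_penetration`` is a transparent effective-stress closure, not a
finite-element model: the measured force is flow stress at a nominal
strain times a weighted combination of the projected tip area (normal
contribution) and the engaged side area (shear contribution),

    F(z) = sigma_flow(z / h_gel) * (A_normal(z) + k_shear * A_lateral(z)),

with a per-shape shear coefficient k_shear and a per-shape tip
strain-concentration factor that decides when the Johnson-Cook damage
criterion trips at the tip.  After the break the force falls to a
residual fraction of the breaking force, mimicking the post-breakpoint
plateau of a puncture record.  Coefficients are calibrated to the
qualitative contrasts of the instrumented tests (probe-force ordering and
the conical-to-cylindrical peak ratio), not to FEM magnitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .material import MaterialCard, failure_strain, jc_flow_stress
from .mechanics import ForceDisplacementCurve

__all__ = ["ProbeGeometry", "PenetrationSetup", "contact_area",
           "normalized_force", "simulate_penetration",
           "DEFAULT_SHEAR_COEFFICIENTS", "DEFAULT_TIP_CONCENTRATION"]

#: Shear-area weight per probe shape; inclined surfaces shear more per
#: unit area, so cone > sphere > cylinder.
DEFAULT_SHEAR_COEFFICIENTS = {"conical": 1.8, "spherical": 1.3, "cylindrical": 1.0}
#: Tip strain-concentration factor: how fast tip strain accrues relative
#: to the nominal strain z / gel height.  The sharp cone concentrates
#: strain and fails mid-stroke; the blunt probes survive a 20 mm stroke.
DEFAULT_TIP_CONCENTRATION = {"conical": 0.70, "spherical": 0.35, "cylindrical": 0.35}
#: Force retained after the tip breaks the gel, as a fraction of the
#: breaking force.
DEFAULT_RESIDUAL_FRACTION = 0.2

_SHAPES = ("cylindrical", "spherical", "conical")


@dataclass(frozen=True)
class ProbeGeometry:
    """Penetration probe: shape plus defining dimensions (mm, degrees).

    ``diameter`` is the shaft diameter (cylindrical), ball diameter
    (spherical) or base diameter (conical).  ``cone_angle`` is the full
    apex angle.
    """

    shape: str
    diameter: float
    shaft_length: float | None = None
    cone_angle: float | None = None

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"shape must be one of {_SHAPES}")
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.shape == "conical":
            if self.cone_angle is None or not 0 < self.cone_angle < 180:
                raise ValueError("conical probe needs cone_angle in (0, 180)")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def half_angle_rad(self) -> float:
        return math.radians(self.cone_angle) / 2.0

    @property
    def full_cone_depth(self) -> float:
        """Depth at which the conical tip is fully engaged."""
        return self.radius / math.tan(self.half_angle_rad)


def cylindrical_probe(diameter: float = 4.0, shaft_length: float = 35.0) -> ProbeGeometry:
    return ProbeGeometry("cylindrical", diameter, shaft_length=shaft_length)


def spherical_probe(diameter: float = 4.0) -> ProbeGeometry:
    return ProbeGeometry("spherical", diameter)


def conical_probe(base_diameter: float = 12.66, cone_angle: float = 60.0) -> ProbeGeometry:
    return ProbeGeometry("conical", base_diameter, cone_angle=cone_angle)


def contact_area(probe: ProbeGeometry, depth_z):
    """Instantaneous wetted probe surface (mm^2) at penetration depth z (mm).

    Cylinder: flat tip pi r^2 plus engaged wall 2 pi r z.  Sphere of
    radius R: spherical cap 2 pi R z up to z = 2R, then the full ball plus
    a shaft of radius R.  Cone of half-angle alpha: lateral slant area
    pi (z tan a)(z / cos a) up to the full cone depth, then the full cone
    slant plus a shaft at the base radius.  Continuous and non-decreasing
    in depth for every shape.
    """
    z = np.asarray(depth_z, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth must be non-negative")
    r = probe.radius
    if probe.shape == "cylindrical":
        area = math.pi * r ** 2 + 2.0 * math.pi * r * z
    elif probe.shape == "spherical":
        cap = 2.0 * math.pi * r * np.minimum(z, 2.0 * r)
        shaft = 2.0 * math.pi * r * np.maximum(z - 2.0 * r, 0.0)
        area = cap + shaft
    else:
        alpha = probe.half_angle_rad
        h_c = probe.full_cone_depth
        zc = np.minimum(z, h_c)
        slant = math.pi * (zc * math.tan(alpha)) * (zc / math.cos(alpha))
        shaft = 2.0 * math.pi * r * np.maximum(z - h_c, 0.0)
        area = slant + shaft
    return float(area) if area.ndim == 0 else area


def projected_tip_area(probe: ProbeGeometry, depth_z):
    """Depth-projected (normal-direction) contact area (mm^2)."""
    z = np.asarray(depth_z, dtype=float)
    r = probe.radius
    if probe.shape == "cylindrical":
        area = np.full_like(z, math.pi * r ** 2)
    elif probe.shape == "spherical":
        zc = np.minimum(z, r)
        area = math.pi * (2.0 * r * zc - zc ** 2)
    else:
        zc = np.minimum(z, probe.full_cone_depth)
        area = math.pi * (zc * math.tan(probe.half_angle_rad)) ** 2
    return float(area) if area.ndim == 0 else area


def normalized_force(curve: ForceDisplacementCurve, probe: ProbeGeometry):
    """Force per instantaneous wetted contact area (MPa) along a record.

    Depths where the contact area is zero yield NaN (undefined), not an
    error.
    """
    area = contact_area(probe, curve.displacement)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(area > 0, curve.force / np.where(area > 0, area, 1.0), np.nan)
    return out


@dataclass(frozen=True)
class PenetrationSetup:
    """Probe, material and stroke of a simulated puncture run."""

    probe: ProbeGeometry
    card: MaterialCard
    speed: float = 1.0        # mm/s
    max_depth: float = 20.0   # mm
    gel_height: float = 30.0  # mm
    shear_coefficient: float | None = None
    tip_concentration: float | None = None
    residual_fraction: float = DEFAULT_RESIDUAL_FRACTION
    triaxiality: float = 1.0 / 3.0
    n_points: int = 400

    def __post_init__(self) -> None:
        if self.max_depth <= 0:
            raise ValueError("max_depth must be positive")
        if self.max_depth > self.gel_height:
            raise ValueError("max_depth cannot exceed the gel height")

    @property
    def k_shear(self) -> float:
        if self.shear_coefficient is not None:
            return self.shear_coefficient
        return DEFAULT_SHEAR_COEFFICIENTS[self.probe.shape]

    @property
    def kappa_tip(self) -> float:
        if self.tip_concentration is not None:
            return self.tip_concentration
        return DEFAULT_TIP_CONCENTRATION[self.probe.shape]


def simulate_penetration(setup: PenetrationSetup) -> ForceDisplacementCurve:
    """Quasi-static effective-stress penetration force curve.

    See the module docstring for the closure.  The returned record carries
    the break depth (if the tip damage criterion tripped) in its metadata.
    """
    probe, card = setup.probe, setup.card
    z = np.linspace(0.0, setup.max_depth, setup.n_points)
    eps_eff = z / setup.gel_height
    rate = setup.speed / setup.gel_height
    sigma = jc_flow_stress(eps_eff, rate, card)
    a_normal = projected_tip_area(probe, z)
    a_lateral = contact_area(probe, z) - a_normal
    force = sigma * (a_normal + setup.k_shear * a_lateral)

    # Tip damage: concentrated strain kappa * eps_eff against the fracture
    # strain; constant eps_f makes D = eps_tip / eps_f in closed form.
    eps_f = failure_strain(setup.triaxiality, rate, card)
    eps_tip = setup.kappa_tip * eps_eff
    break_depth = None
    if eps_tip[-1] >= eps_f:
        i_break = int(np.argmax(eps_tip >= eps_f))
        break_depth = float(z[i_break])
        force[i_break + 1:] = setup.residual_fraction * force[i_break]
    return ForceDisplacementCurve(
        displacement=z, force=force, time=z / setup.speed, speed=setup.speed,
        metadata={"probe_shape": probe.shape, "break_depth": break_depth,
                  "k_shear": setup.k_shear, "kappa_tip": setup.kappa_tip,
                  "eps_f": float(eps_f)},
    )
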