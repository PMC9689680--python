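"""Quasi-static ring tensile simulation with Johnson-Cook damage.

A zero-dimensional, rigid-plastic closure of the ring tensile test: the
top pin moves at constant speed, the taut ring converts pin displacement u
into a membrane strain (both arms stretch, elongation 2u over the mean
circumference L0), the Johnson-Cook law gives the flow stress, and plastic
strain increments are integrated against the fracture strain until the
damage variable reaches 1.

The gel is far softer than a metal (E ~ 0.017 MPa), so a textbook
elastic-plastic split would place almost half the kinematic strain in the
elastic part and push the predicted failure displacement well past the
measured band.  The rigid-plastic closure instead counts all kinematic
strain beyond the yield point as plastic; with the engineering strain
measure (the natural taut-ring measure, default) the predicted failure
displacement lands inside the experimental band.  See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .material import DamageState, MaterialCard, failure_strain, jc_flow_stress
from .mechanics import RingGeometry

__all__ = ["RingTensileSetup", "SimulationResult", "ring_kinematics",
           "simulate_ring_tensile"]

#: Stress triaxiality assumed in the ring wall (uniaxial tension).
UNIAXIAL_TRIAXIALITY = 1.0 / 3.0
#: Largest admissible plastic-strain increment per time step.
MAX_STEP_STRAIN = 0.01


@dataclass(frozen=True)
class RingTensileSetup:
    """Geometry, material and loading program of a ring tensile run."""

    geometry: RingGeometry
    card: MaterialCard
    pin_speed: float = 0.5          # mm/s
    max_displacement: float = 50.0  # mm
    dt: float = 0.05                # s
    triaxiality: float = UNIAXIAL_TRIAXIALITY
    strain_measure: str = "engineering"  # damage-driving measure: engineering|true
    damage_enabled: bool = True
    clamp_rate: bool = True

    def __post_init__(self) -> None:
        if self.pin_speed <= 0 or self.max_displacement <= 0 or self.dt <= 0:
            raise ValueError("pin_speed, max_displacement and dt must be positive")
        if self.strain_measure not in ("engineering", "true"):
            raise ValueError("strain_measure must be 'engineering' or 'true'")


@dataclass
class SimulationResult:
    """Time series of the simulated test plus the predicted failure point."""

    time: np.ndarray
    displacement: np.ndarray
    eps_eng: np.ndarray
    eps_true: np.ndarray
    sigma_true: np.ndarray
    force: np.ndarray
    D: np.ndarray
    failure_displacement: float | None = None
    failure_time: float | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def failed(self) -> bool:
        return self.failure_displacement is not None


def ring_kinematics(u, geometry: RingGeometry):
    """Engineering strain of the taut ring at pin displacement u (mm).

    Both arms of the ring stretch, so the elongation is 2u over the
    initial length L0 (mean circumference by default).
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("pin displacement must be non-negative")
    out = 2.0 * u / geometry.L0
    return float(out) if out.ndim == 0 else out


def simulate_ring_tensile(setup: RingTensileSetup) -> SimulationResult:
    """Run the quasi-static ring tensile simulation to failure.

    Time-steps the pin displacement, evaluates strain, Johnson-Cook flow
    stress and damage per step, and stops at the first step with D >= 1
    (or at max_displacement if damage never reaches 1 or is disabled).
    Engineering stress is converted back to force through the wall
    cross-section w*H.
    """
    geo, card = setup.geometry, setup.card
    L0 = geo.L0
    n_steps = int(np.ceil(setup.max_displacement / (setup.pin_speed * setup.dt)))
    t = setup.dt * np.arange(1, n_steps + 1)
    u = np.minimum(setup.pin_speed * t, setup.max_displacement)

    eps_eng = 2.0 * u / L0
    eps_true = np.log1p(eps_eng)
    eps_dmg = eps_eng if setup.strain_measure == "engineering" else eps_true

    d_eps = np.diff(np.concatenate(([0.0], eps_dmg)))
    if np.max(d_eps) > MAX_STEP_STRAIN:
        raise ValueError(
            f"plastic strain increment {np.max(d_eps):.3g} per step exceeds "
            f"{MAX_STEP_STRAIN}; use a smaller dt")

    # Rigid-plastic closure: all kinematic strain past yield is plastic.
    eps_plastic = eps_dmg
    rate = 2.0 * setup.pin_speed / L0  # d(eps_eng)/dt, constant
    sigma_true = jc_flow_stress(eps_plastic, rate, card,
                                clamp_rate=setup.clamp_rate)
    eps_f = failure_strain(setup.triaxiality, rate, card,
                           clamp_rate=setup.clamp_rate)
    D = np.cumsum(d_eps / eps_f) if setup.damage_enabled else np.zeros_like(u)

    failure_displacement = failure_time = None
    last = u.size
    if setup.damage_enabled and np.any(D >= 1.0):
        i_fail = int(np.argmax(D >= 1.0))
        failure_displacement = float(u[i_fail])
        failure_time = float(t[i_fail])
        last = i_fail + 1

    sigma_eng = sigma_true[:last] / (1.0 + eps_eng[:last])
    force = sigma_eng * geo.width_w * geo.height_H
    return SimulationResult(
        time=t[:last], displacement=u[:last], eps_eng=eps_eng[:last],
        eps_true=eps_true[:last], sigma_true=sigma_true[:last], force=force,
        D=D[:last], failure_displacement=failure_displacement,
        failure_time=failure_time,
        metadata={"eps_f": float(eps_f), "strain_rate": rate,
                  "strain_measure": setup.strain_measure},
    )


def final_damage_state(result: SimulationResult) -> DamageState:
    """Damage state at the end of a simulation (convenience accessor)."""
    return DamageState(D=float(result.D[-1]),
                       eps_plastic_cum=float(result.eps_eng[-1]))
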