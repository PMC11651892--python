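"""Knee-spanning muscle-tendon actuators.

Muscles are rigid-tendon geometric paths with a constant maximum isometric
force; the force transmitted is ``activation * F_max`` (no force-length or
force-velocity scaling — the gait-cycle outcomes of interest depend on the
per-frame force balance, not contraction dynamics).  Paths are straight
segments between body-fixed points with optional cylinder wrapping, shared
with the ligament machinery.  The quadriceps insert on the patella, so the
extensor mechanism transmits to the tibia only through patellofemoral
contact and the patellar tendon.

Moment arms follow the tendon-excursion definition
``r = -dL/dq`` (central finite difference; rotational coordinates in
radians).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import COORD_NAMES, DEG, KneePose, body_transform, transform_points
from .pathgeom import WrapCylinder, segment_length


class MuscleError(ValueError):
    pass


@dataclass
class MuscleActuator:
    """Geometric muscle-tendon path: list of ``(body, point_mm)`` way points."""

    name: str
    path: list
    max_isometric_force: float
    wrap: WrapCylinder | None = None

    def __post_init__(self) -> None:
        if len(self.path) < 2:
            raise MuscleError(f"{self.name}: a path needs at least two points")
        if self.max_isometric_force <= 0:
            raise MuscleError(f"{self.name}: max isometric force must be positive")
        self.path = [(body, np.asarray(pt, dtype=float)) for body, pt in self.path]


def _body_transforms(pose: KneePose) -> dict:
    return {
        "tibia": np.eye(4),
        "femur": pose.femur_transform(),
        "patella": pose.patella_transform(),
    }


def musculotendon_length(actuator: MuscleActuator, pose: KneePose) -> float:
    """Total path length (mm) at a pose, with cylinder wrapping."""
    T = _body_transforms(pose)
    pts = [transform_points(T[body], pt[None, :])[0] for body, pt in actuator.path]
    cyl_T = T[actuator.wrap.body] if actuator.wrap is not None else None
    total = 0.0
    for a, bpt in zip(pts[:-1], pts[1:]):
        total += float(segment_length(a, bpt, actuator.wrap, cyl_T))
    return total


def moment_arm(actuator: MuscleActuator, pose: KneePose, coordinate: str, step: float = 1e-4) -> float:
    """Tendon-excursion moment arm about one knee coordinate.

    mm for translational coordinates; mm (per radian) for rotations.
    """
    i = COORD_NAMES.index(coordinate)
    h = step
    qp = pose.q.copy()
    qm = pose.q.copy()
    qp[i] += h
    qm[i] -= h
    lp = musculotendon_length(actuator, KneePose(qp))
    lm = musculotendon_length(actuator, KneePose(qm))
    d = (lp - lm) / (2.0 * h)
    if i in (0, 1, 2, 6, 7, 8):  # stored in degrees -> per radian
        d = d / DEG
    return -d


def muscle_generalized_forces(
    actuators: list, activations: np.ndarray, pose: KneePose
) -> np.ndarray:
    """Generalised force on every knee coordinate, linear in activations."""
    activations = np.asarray(activations, dtype=float)
    if activations.shape != (len(actuators),):
        raise MuscleError("need one activation per actuator")
    if np.any((activations < -1e-12) | (activations > 1.0 + 1e-12)):
        raise MuscleError("activations must lie in [0, 1]")
    out = np.zeros(len(COORD_NAMES))
    for m, a in zip(actuators, activations):
        if a == 0.0:
            continue
        for j, name in enumerate(COORD_NAMES):
            out[j] += a * m.max_isometric_force * moment_arm(m, pose, name)
    return out


def default_muscles() -> list[MuscleActuator]:
    """Reduced 12-unit knee-spanning set with literature-typical F_max.

    Hip and ankle are kinematically prescribed, so proximal anchors live in
    the femoral frame and the gastrocnemius' distal anchor in the tibial
    frame.  The quadriceps share a wrapping cylinder over the anterior
    femur so their paths stay clear of the trochlea in flexion.
    """
    quad_wrap = WrapCylinder(point=(0.0, 2.0, 0.0), axis=(0.0, 0.0, 1.0), radius=32.0, body="femur")
    m = [
        MuscleActuator("vas_med", [("femur", (6.0, 120.0, -10.0)), ("patella", (-2.0, 18.0, -8.0))], 1300.0, wrap=quad_wrap),
        MuscleActuator("vas_lat", [("femur", (6.0, 120.0, 12.0)), ("patella", (-2.0, 18.0, 8.0))], 1900.0, wrap=quad_wrap),
        MuscleActuator("vas_int", [("femur", (9.0, 130.0, 0.0)), ("patella", (-2.0, 20.0, 0.0))], 1200.0, wrap=quad_wrap),
        MuscleActuator("rect_fem", [("femur", (12.0, 160.0, 2.0)), ("patella", (-2.0, 20.0, 2.0))], 1200.0, wrap=quad_wrap),
        MuscleActuator("bifemlh", [("femur", (-35.0, 150.0, 8.0)), ("tibia", (-22.0, -45.0, 30.0))], 800.0),
        MuscleActuator("bifemsh", [("femur", (-22.0, 80.0, 15.0)), ("tibia", (-22.0, -45.0, 30.0))], 400.0),
        MuscleActuator("semimem", [("femur", (-35.0, 150.0, -8.0)), ("tibia", (-28.0, -35.0, -22.0))], 1300.0),
        MuscleActuator("semiten", [("femur", (-33.0, 150.0, -12.0)), ("tibia", (-15.0, -50.0, -20.0))], 400.0),
        MuscleActuator("gas_med", [("femur", (-26.0, 4.0, -20.0)), ("tibia", (-40.0, -300.0, -5.0))], 1600.0),
        MuscleActuator("gas_lat", [("femur", (-26.0, 4.0, 20.0)), ("tibia", (-40.0, -300.0, 5.0))], 700.0),
        MuscleActuator("tfl", [("femur", (5.0, 130.0, 35.0)), ("tibia", (15.0, -22.0, 26.0))], 200.0),
        MuscleActuator("popliteus", [("femur", (-5.0, 0.0, 30.0)), ("tibia", (-25.0, -25.0, -10.0))], 150.0),
    ]
    return m
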