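"""Coordinate frames, poses and rigid-body kinematics for the 12-d.f. knee.

Convention (right knee, tibial frame is the world frame):

* ``+X`` anterior, ``+Y`` superior, ``+Z`` lateral; medial is ``-Z``.
* The femur pose is parametrised by the tibiofemoral coordinates
  ``(flexion, adduction, internal rotation, AP, SI, ML)``; flexion is a
  rotation about ``+Z`` (the femoral shaft leans posteriorly for positive
  flexion), adduction a rotation about ``-X`` (medial side drops for
  positive adduction), internal rotation about ``+Y``.
* The patella pose is parametrised by six analogous coordinates expressed
  relative to the tibia.  Patellofemoral coordinates relative to the femur
  are derived quantities (:meth:`KneePose.patella_in_femur`).

Angles are stored in degrees, translations in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEG = np.pi / 180.0

#: order of the twelve generalised coordinates
COORD_NAMES = (
    "tf_flexion",
    "tf_adduction",
    "tf_rotation",
    "tf_ap",
    "tf_si",
    "tf_ml",
    "pf_flexion",
    "pf_tilt",
    "pf_spin",
    "pf_ap",
    "pf_si",
    "pf_ml",
)

#: indices of the eleven secondary coordinates (everything but tf_flexion)
SECONDARY_IDX = tuple(range(1, 12))
ROTATION_IDX = (0, 1, 2, 6, 7, 8)
TRANSLATION_IDX = (3, 4, 5, 9, 10, 11)


def rot_x(deg: float) -> np.ndarray:
    c, s = np.cos(deg * DEG), np.sin(deg * DEG)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rot_y(deg: float) -> np.ndarray:
    c, s = np.cos(deg * DEG), np.sin(deg * DEG)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(deg * DEG), np.sin(deg * DEG)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def body_transform(q6: np.ndarray) -> np.ndarray:
    """4x4 pose of a body from its six coordinates.

    ``q6 = (flexion, adduction, internal rotation, ap, si, ml)`` with the
    rotation composed body-fixed as ``Rz(flex) @ Rx(-add) @ Ry(rot)`` and the
    translation expressed directly in the world (tibial) frame.
    """
    flex, add, rot, ap, si, ml = q6
    T = np.eye(4)
    T[:3, :3] = rot_z(flex) @ rot_x(-add) @ rot_y(rot)
    T[:3, 3] = (ap, si, ml)
    return T


def body_twists(q6: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit twists (omega_i, v_i) of the six coordinates at the current pose.

    ``omega_i`` is the angular velocity (rad per rad) of a unit rate of
    coordinate ``i``; ``v_i`` is the velocity of the body origin.  Needed to
    project wrenches onto generalised forces.
    """
    flex, add, rot = q6[:3]
    Rz = rot_z(flex)
    Rzx = Rz @ rot_x(-add)
    omega = np.zeros((6, 3))
    v = np.zeros((6, 3))
    omega[0] = (0.0, 0.0, 1.0)          # flexion about +Z
    omega[1] = Rz @ (-1.0, 0.0, 0.0)    # adduction about body -X
    omega[2] = Rzx @ (0.0, 1.0, 0.0)    # internal rotation about body +Y
    v[3] = (1.0, 0.0, 0.0)
    v[4] = (0.0, 1.0, 0.0)
    v[5] = (0.0, 0.0, 1.0)
    return omega, v


def generalized_force_from_wrench(
    q6: np.ndarray, force: np.ndarray, moment_about_origin: np.ndarray
) -> np.ndarray:
    """Generalised forces on the six body coordinates from a wrench.

    The wrench acts on the body; ``moment_about_origin`` is the moment of the
    force system about the world origin.  Rotational entries are torques
    (N*mm per radian); they are converted to per-degree by the solver only
    when building Jacobians, never here.
    """
    t = q6[3:]
    omega, v = body_twists(q6)
    # velocity of the body-fixed point instantaneously at the origin
    v0 = v - np.cross(omega, t[None, :])
    return v0 @ force + omega @ moment_about_origin


@dataclass
class KneePose:
    """Twelve generalised coordinates of the replaced knee.

    ``q`` follows :data:`COORD_NAMES`: tibiofemoral flexion (primary),
    adduction, internal rotation (deg), AP/SI/ML translations (mm), then the
    six patellar coordinates relative to the tibia.
    """

    q: np.ndarray = field(default_factory=lambda: np.zeros(12))

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (12,):
            raise ValueError("KneePose requires 12 coordinates")
        if not np.all(np.isfinite(self.q)):
            raise ValueError("KneePose coordinates must be finite")

    # -- named accessors ---------------------------------------------------
    @property
    def flexion(self) -> float:
        return float(self.q[0])

    @property
    def tf(self) -> np.ndarray:
        return self.q[:6]

    @property
    def pf(self) -> np.ndarray:
        return self.q[6:]

    def femur_transform(self) -> np.ndarray:
        return body_transform(self.q[:6])

    def patella_transform(self) -> np.ndarray:
        return body_transform(self.q[6:])

    def patella_in_femur(self) -> np.ndarray:
        """4x4 pose of the patella relative to the femur (for reporting)."""
        Tf = self.femur_transform()
        Tp = self.patella_transform()
        Rf, tf_ = Tf[:3, :3], Tf[:3, 3]
        out = np.eye(4)
        out[:3, :3] = Rf.T @ Tp[:3, :3]
        out[:3, 3] = Rf.T @ (Tp[:3, 3] - tf_)
        return out

    def replace(self, **kwargs: float) -> "KneePose":
        q = self.q.copy()
        for name, value in kwargs.items():
            q[COORD_NAMES.index(name)] = value
        return KneePose(q)

    def copy(self) -> "KneePose":
        return KneePose(self.q.copy())


def transform_points(T: np.ndarray, pts: np.ndarray) -> np.ndarray:
    return pts @ T[:3, :3].T + T[:3, 3]


def batch_body_transforms(Q: np.ndarray) -> np.ndarray:
    """Vectorised :func:`body_transform` for a (P, 6) coordinate batch."""
    Q = np.asarray(Q, dtype=float)
    flex, add, rot = Q[:, 0] * DEG, Q[:, 1] * DEG, Q[:, 2] * DEG
    cf, sf = np.cos(flex), np.sin(flex)
    ca, sa = np.cos(-add), np.sin(-add)
    cr, sr = np.cos(rot), np.sin(rot)
    P = len(Q)
    T = np.zeros((P, 4, 4))
    # Rz(flex) @ Rx(-add) @ Ry(rot)
    T[:, 0, 0] = cf * cr - sf * sa * sr
    T[:, 0, 1] = -sf * ca
    T[:, 0, 2] = cf * sr + sf * sa * cr
    T[:, 1, 0] = sf * cr + cf * sa * sr
    T[:, 1, 1] = cf * ca
    T[:, 1, 2] = sf * sr - cf * sa * cr
    T[:, 2, 0] = -ca * sr
    T[:, 2, 1] = sa
    T[:, 2, 2] = ca * cr
    T[:, 0, 3] = Q[:, 3]
    T[:, 1, 3] = Q[:, 4]
    T[:, 2, 3] = Q[:, 5]
    T[:, 3, 3] = 1.0
    return T
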