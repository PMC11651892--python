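"""Shortest-path geometry for ligament fibers and muscle-tendon paths.

A path segment between two attachment points is either a straight line or,
when the straight segment would pass through a virtual wrapping cylinder,
the frictionless geodesic over that cylinder: tangent line - helical arc -
tangent line.  In the plane perpendicular to the cylinder axis this is the
classical tangent-arc-tangent construction; the axial travel distributes
uniformly along the unrolled path, so the three-dimensional length is
``hypot(planar wrapped length, axial offset)``.

The wrapped length is continuous through grazing contact: as the straight
segment approaches tangency the arc angle goes to zero and the length tends
to the straight distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class WrapError(ValueError):
    pass


@dataclass
class WrapCylinder:
    """Infinite virtual wrapping cylinder, fixed in ``body``'s frame."""

    point: np.ndarray        # a point on the axis (mm, body frame)
    axis: np.ndarray         # axis direction (normalised on init)
    radius: float            # mm
    body: str = "femur"

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(self.axis)
        if n == 0 or self.radius <= 0:
            raise WrapError("cylinder needs a nonzero axis and positive radius")
        self.axis = self.axis / n


def wrapped_length(
    p1: np.ndarray,
    p2: np.ndarray,
    point: np.ndarray,
    axis: np.ndarray,
    radius: float,
    clamp_inside: bool = False,
) -> np.ndarray:
    """Path length from ``p1`` to ``p2`` around a cylinder (vectorised).

    ``p1``/``p2`` may be (..., 3); the cylinder is shared.  Attachments
    inside the cylinder raise :class:`WrapError`; with ``clamp_inside`` they
    are instead treated as lying on the cylinder surface (a continuous
    extension the equilibrium solver relies on to survive wild trial poses,
    which it then rejects on merit).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    w1 = p1 - point
    w2 = p2 - point
    s1 = w1 @ axis
    s2 = w2 @ axis
    q1 = w1 - s1[..., None] * axis
    q2 = w2 - s2[..., None] * axis
    r1 = np.linalg.norm(q1, axis=-1)
    r2 = np.linalg.norm(q2, axis=-1)
    if np.any(r1 < radius * (1 - 1e-9)) or np.any(r2 < radius * (1 - 1e-9)):
        if not clamp_inside:
            raise WrapError("attachment point lies inside a wrapping cylinder")
        r1 = np.maximum(r1, radius)
        r2 = np.maximum(r2, radius)
    straight = np.linalg.norm(p2 - p1, axis=-1)

    cosphi = np.clip(
        np.einsum("...j,...j->...", q1, q2) / np.maximum(r1 * r2, 1e-300), -1.0, 1.0
    )
    phi12 = np.arccos(cosphi)
    beta1 = np.arccos(np.clip(radius / np.maximum(r1, radius), -1.0, 1.0))
    beta2 = np.arccos(np.clip(radius / np.maximum(r2, radius), -1.0, 1.0))
    theta = phi12 - beta1 - beta2
    wrap = theta > 0.0

    t1 = np.sqrt(np.maximum(r1 * r1 - radius * radius, 0.0))
    t2 = np.sqrt(np.maximum(r2 * r2 - radius * radius, 0.0))
    planar = t1 + radius * np.where(wrap, theta, 0.0) + t2
    ds = s2 - s1
    wrapped = np.sqrt(planar * planar + ds * ds)
    return np.where(wrap, wrapped, straight)


def segment_length(
    p1: np.ndarray, p2: np.ndarray, cylinder: WrapCylinder | None, cyl_transform: np.ndarray | None
) -> np.ndarray:
    """Length of one path segment, wrapping over ``cylinder`` if given.

    ``cyl_transform`` maps the cylinder's body frame to world; ``None`` means
    the cylinder is already in world coordinates.
    """
    if cylinder is None:
        return np.linalg.norm(
            np.asarray(p2, float) - np.asarray(p1, float), axis=-1
        )
    point = cylinder.point
    axis = cylinder.axis
    if cyl_transform is not None:
        point = cyl_transform[:3, :3] @ point + cyl_transform[:3, 3]
        axis = cyl_transform[:3, :3] @ cylinder.axis
    return wrapped_length(p1, p2, point, axis, cylinder.radius)
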