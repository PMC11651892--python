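"""Nonlinear-spring ligament bundles with reference-strain calibration.

Each ligament is a named bundle of point-to-point fibers.  A fiber carries
the classic quadratic-toe / linear spring law

* ``f = 0``                                  for ``eps <= 0``
* ``f = k (L - L0)^2 / (4 eps_t L0)``        for ``0 < eps <= 2 eps_t``
* ``f = k (L - L0 - eps_t L0)``              for ``eps > 2 eps_t``

with ``eps = (L - L0) / L0``; the two branches agree in value and slope at
``eps = 2 eps_t``.  Slack lengths ``L0`` are not free parameters: they are
calibrated so that every fiber carries the bundle's reference strain
``eps_ref`` at the 0-degree-flexion assembled reference pose.  The PCL
tensioning experiment perturbs the PCL reference strain (baseline 2%) on a
``-10..+10`` percentage-point grid and recalibrates; all other bundles are
untouched.

Attachment coordinates below are a literature-guided default table for a
right knee in the package's tibial frame (+X anterior, +Y superior,
+Z lateral); they are plain data and fully overridable through the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .pathgeom import WrapCylinder

PRESTRAIN_DELTAS = tuple(range(-10, 11, 2))
CONFORMITIES = ("standard", "low")
BASELINE_PCL_REFERENCE_STRAIN = 0.02
PCL_BUNDLES = ("aPCL", "pPCL")


class LigamentError(ValueError):
    pass


@dataclass
class PrestrainScenario:
    """One cell of the tensioning experiment: PCL pre-strain delta x inlay."""

    delta: int = 0
    conformity: str = "standard"

    def __post_init__(self) -> None:
        if self.delta not in PRESTRAIN_DELTAS:
            raise LigamentError(
                f"delta must be one of {PRESTRAIN_DELTAS}, got {self.delta}"
            )
        if self.conformity not in CONFORMITIES:
            raise LigamentError(f"conformity must be one of {CONFORMITIES}")

    @property
    def pcl_reference_strain(self) -> float:
        return BASELINE_PCL_REFERENCE_STRAIN + self.delta / 100.0

    @property
    def label(self) -> str:
        return f"{self.conformity}_delta{self.delta:+d}"


def fiber_force(length, slack_length, stiffness_n_per_mm, transition_strain):
    """Piecewise toe/linear fiber tension (N); vectorised and tension-only."""
    L = np.asarray(length, dtype=float)
    L0 = np.asarray(slack_length, dtype=float)
    k = np.asarray(stiffness_n_per_mm, dtype=float)
    et = np.asarray(transition_strain, dtype=float)
    if np.any(L0 <= 0):
        raise LigamentError("slack length must be positive")
    e = (L - L0) / L0
    dl = L - L0
    toe = k * dl * dl / (4.0 * et * L0)
    lin = k * (dl - et * L0)
    out = np.where(e <= 0.0, 0.0, np.where(e <= 2.0 * et, toe, lin))
    return out if out.ndim else float(out)


def fiber_stiffness(length, slack_length, stiffness_n_per_mm, transition_strain):
    """d(force)/d(length); used only for diagnostics."""
    L = np.asarray(length, dtype=float)
    L0 = np.asarray(slack_length, dtype=float)
    k = np.asarray(stiffness_n_per_mm, dtype=float)
    et = np.asarray(transition_strain, dtype=float)
    e = (L - L0) / L0
    toe = k * (L - L0) / (2.0 * et * L0)
    out = np.where(e <= 0.0, 0.0, np.where(e <= 2.0 * et, toe, k))
    return out if out.ndim else float(out)


@dataclass
class LigamentBundle:
    """Named fiber set spanning two bodies.

    ``proximal_points`` live in ``proximal_body``'s frame, ``distal_points``
    in ``distal_body``'s frame.  ``stiffness_n_per_mm`` is the bundle total,
    split evenly across fibers.  ``slack_lengths`` is ``None`` until
    :meth:`calibrated` is called with the fiber lengths at the reference
    pose.
    """

    name: str
    proximal_points: np.ndarray
    distal_points: np.ndarray
    stiffness_n_per_mm: float
    reference_strain: float
    transition_strain: float = 0.03
    proximal_body: str = "femur"
    distal_body: str = "tibia"
    slack_lengths: np.ndarray | None = None
    wrap: WrapCylinder | None = None

    def __post_init__(self) -> None:
        self.proximal_points = np.atleast_2d(np.asarray(self.proximal_points, float))
        self.distal_points = np.atleast_2d(np.asarray(self.distal_points, float))
        if self.proximal_points.shape != self.distal_points.shape:
            raise LigamentError(f"{self.name}: attachment arrays must match")
        if self.stiffness_n_per_mm < 0:
            raise LigamentError(f"{self.name}: stiffness must be non-negative")
        if self.transition_strain <= 0:
            raise LigamentError(f"{self.name}: transition strain must be positive")
        if self.reference_strain <= -1.0:
            raise LigamentError(f"{self.name}: reference strain must exceed -100%")
        if self.slack_lengths is not None:
            self.slack_lengths = np.asarray(self.slack_lengths, float)

    @property
    def n_fibers(self) -> int:
        return len(self.proximal_points)

    @property
    def fiber_stiffness_n_per_mm(self) -> float:
        return self.stiffness_n_per_mm / self.n_fibers

    def calibrated(self, reference_lengths: np.ndarray) -> "LigamentBundle":
        """Bundle with slack lengths set from lengths at the reference pose.

        ``L0 = L_ref / (1 + eps_ref)`` per fiber, so re-evaluating the strain
        at the reference pose returns exactly ``eps_ref``.
        """
        ref = np.asarray(reference_lengths, dtype=float)
        if ref.shape != (self.n_fibers,):
            raise LigamentError(f"{self.name}: need one reference length per fiber")
        if self.reference_strain <= -1.0:
            raise LigamentError(f"{self.name}: reference strain must exceed -100%")
        return replace(self, slack_lengths=ref / (1.0 + self.reference_strain))

    def with_reference_strain(self, eps_ref: float) -> "LigamentBundle":
        if eps_ref <= -1.0:
            raise LigamentError(f"{self.name}: reference strain must exceed -100%")
        return replace(self, reference_strain=eps_ref)

    def forces(self, lengths: np.ndarray) -> np.ndarray:
        if self.slack_lengths is None:
            raise LigamentError(f"{self.name}: bundle is not calibrated")
        return fiber_force(
            lengths,
            self.slack_lengths,
            self.fiber_stiffness_n_per_mm,
            self.transition_strain,
        )

    def strains(self, lengths: np.ndarray) -> np.ndarray:
        if self.slack_lengths is None:
            raise LigamentError(f"{self.name}: bundle is not calibrated")
        return (np.asarray(lengths, float) - self.slack_lengths) / self.slack_lengths


def _spread(base, direction, n, pitch=3.0):
    """n attachment points spread about ``base`` along ``direction``."""
    base = np.asarray(base, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    offsets = (np.arange(n) - (n - 1) / 2.0) * pitch
    return base[None, :] + offsets[:, None] * d[None, :]


def default_ligaments() -> list[LigamentBundle]:
    """Default bundle table (uncalibrated) for the shipped knee model.

    The PCL carries the 2% baseline reference strain and 180 N/mm bundle
    stiffness; remaining properties are literature-typical defaults.
    """
    ez = np.array([0.0, 0.0, 1.0])
    ey = np.array([0.0, 1.0, 0.0])
    ex = np.array([1.0, 0.0, 0.0])
    b: list[LigamentBundle] = []
    b.append(
        LigamentBundle(
            "aPCL",
            _spread((1.0, -1.2, -6.0), ex, 2, 3.0),
            _spread((-33.0, -16.0, -2.0), ex, 2, 3.0),
            stiffness_n_per_mm=180.0,
            reference_strain=BASELINE_PCL_REFERENCE_STRAIN,
        )
    )
    b.append(
        LigamentBundle(
            "pPCL",
            _spread((-4.0, -2.2, -7.0), ez, 2, 3.0),
            _spread((-36.0, -18.0, -4.0), ez, 2, 3.0),
            stiffness_n_per_mm=180.0,
            reference_strain=BASELINE_PCL_REFERENCE_STRAIN,
        )
    )
    b.append(
        LigamentBundle(
            "sMCL",
            _spread((0.0, 5.0, -33.0), ex, 3, 4.0),
            _spread((5.0, -70.0, -18.0), ex, 3, 4.0),
            stiffness_n_per_mm=100.0,
            reference_strain=0.02,
        )
    )
    b.append(
        LigamentBundle(
            "dMCL",
            _spread((0.0, 3.0, -33.0), ex, 3, 4.0),
            _spread((0.0, -25.0, -24.0), ex, 3, 4.0),
            stiffness_n_per_mm=45.0,
            reference_strain=0.0,
        )
    )
    b.append(
        LigamentBundle(
            "LCL",
            _spread((0.0, 5.0, 33.0), ex, 3, 4.0),
            _spread((-8.0, -55.0, 28.0), ex, 3, 4.0),
            stiffness_n_per_mm=90.0,
            reference_strain=0.01,
        )
    )
    # posterior capsule: crossed fiber fans (femoral and tibial spreads run
    # in opposite senses), giving first-order internal/external-rotation
    # restraint as the real capsule does
    b.append(
        LigamentBundle(
            "CAPm",
            _spread((-18.0, 0.0, -15.0), ez, 3, 5.0),
            _spread((-28.0, -18.0, -15.0), ez, 3, -5.0),
            stiffness_n_per_mm=80.0,
            reference_strain=0.005,
        )
    )
    b.append(
        LigamentBundle(
            "CAPl",
            _spread((-18.0, 0.0, 15.0), ez, 3, 5.0),
            _spread((-28.0, -18.0, 15.0), ez, 3, -5.0),
            stiffness_n_per_mm=80.0,
            reference_strain=0.005,
        )
    )
    b.append(
        LigamentBundle(
            "MPFL",
            _spread((0.0, 1.0, -32.0), ey, 3, 8.0),
            _spread((-4.0, 2.0, -11.0), ey, 3, 8.0),
            stiffness_n_per_mm=50.0,
            reference_strain=0.02,
            distal_body="patella",
        )
    )
    b.append(
        LigamentBundle(
            "LPFL",
            _spread((0.0, 1.0, 32.0), ey, 3, 8.0),
            _spread((-4.0, 2.0, 11.0), ey, 3, 8.0),
            stiffness_n_per_mm=50.0,
            reference_strain=0.02,
            distal_body="patella",
        )
    )
    # passive quadriceps-tendon tone: keeps the patellar suspension taut when
    # the extensor muscles are silent (swing phase)
    b.append(
        LigamentBundle(
            "QT",
            _spread((8.0, 100.0, 0.0), ez, 3, 14.0),
            _spread((-2.0, 18.0, 0.0), ez, 3, -8.0),
            stiffness_n_per_mm=25.0,
            reference_strain=0.015,
            distal_body="patella",
        )
    )
    b.append(
        LigamentBundle(
            "ITB",
            np.array([[5.0, 120.0, 38.0]]),
            np.array([[15.0, -22.0, 26.0]]),
            stiffness_n_per_mm=40.0,
            reference_strain=0.005,
        )
    )
    # extensor mechanism: stiff tendon from the patellar inferior pole to the
    # tibial tuberosity, same spring law as the ligaments
    b.append(
        LigamentBundle(
            "PT",
            _spread((-2.0, -18.0, 0.0), ez, 3, 8.0),
            _spread((38.0, -60.0, 0.0), ez, 3, 8.0),
            stiffness_n_per_mm=800.0,
            reference_strain=0.005,
            proximal_body="patella",
            distal_body="tibia",
        )
    )
    return b
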