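"""The assembled 12-d.f. knee model.

:class:`KneeModel` bundles the implant surfaces, ligament bundles, muscle
actuators, the elastic-foundation law and the solver settings into one
object, statsmodels-style: build the model (``KneeModel.default()`` or
``KneeModel.from_config``), then ``fit(gait)`` to obtain a
:class:`~kneemech.results.GaitResults`.

The model owns the reference assembly: at 0 degrees flexion the femur is
settled onto the inlay (and the patellar button onto the trochlea) under a
small compressive preload, and every ligament's slack lengths are
calibrated there from its reference strain.  PCL tensioning scenarios
re-calibrate only the two PCL bundles at the unchanged reference pose.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .contact import ContactEngine, EfLaw
from .frames import (
    COORD_NAMES,
    DEG,
    KneePose,
    batch_body_transforms,
    body_transform,
    generalized_force_from_wrench,
)
from .geometry import InlaySpec, TriSurface, make_femoral_component, make_patellar_button, make_tibial_inlay
from .ligaments import (
    BASELINE_PCL_REFERENCE_STRAIN,
    LigamentBundle,
    PCL_BUNDLES,
    PrestrainScenario,
    default_ligaments,
)
from .muscles import MuscleActuator, default_muscles
from .pathgeom import wrapped_length

_BODY_CODE = {"tibia": 0, "femur": 1, "patella": 2}


class ModelError(RuntimeError):
    pass


@dataclass
class SolverSettings:
    """Equilibrium-solver tolerances and steps (config-exposed)."""

    translation_tol_n: float = 0.5
    rotation_tol_nmm: float = 50.0
    max_iterations: int = 160
    fd_step_translation_mm: float = 2e-3
    fd_step_rotation_deg: float = 5e-3
    step_cap_translation_mm: float = 1.2
    step_cap_rotation_deg: float = 2.0
    reference_preload_n: float = 100.0
    patellar_preload_n: float = 30.0


@dataclass
class _PathTable:
    """Flattened straight-line elements (ligament fibers) for fast batching."""

    prox: np.ndarray       # (E, 3)
    dist: np.ndarray       # (E, 3)
    prox_body: np.ndarray  # (E,)
    dist_body: np.ndarray  # (E,)
    owner: list            # bundle index per element


class KneeModel:
    """Musculoskeletal knee with implant contact, ligaments and muscles."""

    def __init__(
        self,
        femur: TriSurface,
        inlay: TriSurface,
        button: TriSurface,
        ligaments: list[LigamentBundle],
        muscles: list[MuscleActuator],
        ef_law: EfLaw | None = None,
        settings: SolverSettings | None = None,
        inlay_spec: InlaySpec | None = None,
        patella_weight_n: float = 2.0,
        button_mount: np.ndarray | None = None,
        conformity: str = "standard",
        patella_settle_distance_mm: float = 40.0,
    ) -> None:
        self.femur = femur
        self.inlay = inlay
        self.ef_law = ef_law or EfLaw()
        self.settings = settings or SolverSettings()
        self.ligaments = ligaments
        self.muscles = muscles
        self.inlay_spec = inlay_spec
        self.patella_weight_n = patella_weight_n
        self.conformity = conformity
        self.patella_settle_distance_mm = patella_settle_distance_mm
        if button_mount is None:
            # dome apex points posteriorly (-X); base plane 5 mm behind the
            # patellar body origin
            button_mount = np.eye(4)
            button_mount[:3, :3] = np.array(
                [[0.0, 0.0, -1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]]
            )
            button_mount[:3, 3] = (-5.0, 0.0, 0.0)
        self.button_mount = button_mount
        self.button = button.transformed(button_mount)

        self.tf_engine = ContactEngine(self.inlay, self.femur, self.ef_law)
        self.pf_engine = ContactEngine(
            self.button, self.femur, self.ef_law, compression_axis=(1.0, 0.0, 0.0)
        )
        self._build_path_table()
        self.reference_pose: KneePose | None = None

    # ------------------------------------------------------------------
    # construction helpers
    # ------------------------------------------------------------------
    @classmethod
    def default(
        cls,
        conformity: str = "standard",
        ef_law: EfLaw | None = None,
        settings: SolverSettings | None = None,
        mesh_resolution_mm: float = 1.5,
    ) -> "KneeModel":
        spec = InlaySpec(mesh_resolution_mm=mesh_resolution_mm)
        if conformity == "low":
            spec = spec.low_conformity()
        elif conformity != "standard":
            raise ModelError("conformity must be 'standard' or 'low'")
        model = cls(
            femur=make_femoral_component(resolution=mesh_resolution_mm),
            inlay=make_tibial_inlay(spec),
            button=make_patellar_button(resolution=mesh_resolution_mm),
            ligaments=default_ligaments(),
            muscles=default_muscles(),
            ef_law=ef_law,
            settings=settings,
            inlay_spec=spec,
            conformity=conformity,
        )
        model.assemble_reference()
        return model

    def _build_path_table(self) -> None:
        prox, dist, pb, db, owner = [], [], [], [], []
        for bi, b in enumerate(self.ligaments):
            for j in range(b.n_fibers):
                prox.append(b.proximal_points[j])
                dist.append(b.distal_points[j])
                pb.append(_BODY_CODE[b.proximal_body])
                db.append(_BODY_CODE[b.distal_body])
                owner.append(bi)
        self._paths = _PathTable(
            np.asarray(prox, dtype=float).reshape(-1, 3),
            np.asarray(dist, dtype=float).reshape(-1, 3),
            np.asarray(pb, dtype=np.int64),
            np.asarray(db, dtype=np.int64),
            owner,
        )
        # muscles: single-segment paths; wrapped ones handled in femur frame
        mp, md, mpb, mdb, wrapped = [], [], [], [], []
        for m in self.muscles:
            (b0, p0), (b1, p1) = m.path[0], m.path[-1]
            mp.append(p0)
            md.append(p1)
            mpb.append(_BODY_CODE[b0])
            mdb.append(_BODY_CODE[b1])
            wrapped.append(m.wrap is not None)
        self._mpaths = _PathTable(
            np.asarray(mp, dtype=float).reshape(-1, 3),
            np.asarray(md, dtype=float).reshape(-1, 3),
            np.asarray(mpb, dtype=np.int64),
            np.asarray(mdb, dtype=np.int64),
            [],
        )
        self._m_wrapped = np.asarray(wrapped)
        wraps = {id(m.wrap): m.wrap for m in self.muscles if m.wrap is not None}
        if len(wraps) > 1:
            raise ModelError("at most one shared muscle wrap cylinder is supported")
        self._m_wrap = next(iter(wraps.values())) if wraps else None

    # ------------------------------------------------------------------
    # batched path lengths
    # ------------------------------------------------------------------
    def element_lengths(self, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Fiber and muscle path lengths for a (P, 12) pose batch.

        Returns ``(lig_lengths (P, E), muscle_lengths (P, M))``.
        """
        Q = np.atleast_2d(np.asarray(Q, dtype=float))
        P = len(Q)
        Tf = batch_body_transforms(Q[:, :6])
        Tp = batch_body_transforms(Q[:, 6:])
        Tt = np.broadcast_to(np.eye(4), (P, 4, 4))
        T = np.stack([Tt, Tf, Tp], axis=1)  # (P, 3 bodies, 4, 4)

        def world(pts, codes):
            Tb = T[:, codes]  # (P, E, 4, 4)
            return np.einsum("peij,ej->pei", Tb[:, :, :3, :3], pts) + Tb[:, :, :3, 3]

        wp = world(self._paths.prox, self._paths.prox_body)
        wd = world(self._paths.dist, self._paths.dist_body)
        lig = np.linalg.norm(wd - wp, axis=-1)

        mp = world(self._mpaths.prox, self._mpaths.prox_body)
        md = world(self._mpaths.dist, self._mpaths.dist_body)
        mus = np.linalg.norm(md - mp, axis=-1)
        if self._m_wrap is not None and np.any(self._m_wrapped):
            sel = np.flatnonzero(self._m_wrapped)
            # work in the wrap body's (femur) frame so the cylinder is fixed
            Rf = Tf[:, :3, :3]
            tf_ = Tf[:, :3, 3]
            p1 = np.einsum("pij,pei->pej", Rf, mp[:, sel] - tf_[:, None, :])
            p2 = np.einsum("pij,pei->pej", Rf, md[:, sel] - tf_[:, None, :])
            mus[:, sel] = wrapped_length(
                p1,
                p2,
                self._m_wrap.point,
                self._m_wrap.axis,
                self._m_wrap.radius,
                clamp_inside=True,
            )
        return lig, mus

    def perturbed_lengths(self, q: np.ndarray):
        """Lengths at ``q`` and central-difference gradients w.r.t. all coords.

        Returns ``(lig0, mus0, dlig (12, E), dmus (12, M))`` with gradients
        per native coordinate unit (mm or deg).
        """
        s = self.settings
        steps = np.array(
            [s.fd_step_rotation_deg] * 3 + [s.fd_step_translation_mm] * 3
        )
        steps = np.concatenate([steps, steps])
        batch = [q]
        for i in range(12):
            qp = q.copy()
            qp[i] += steps[i]
            qm = q.copy()
            qm[i] -= steps[i]
            batch.append(qp)
            batch.append(qm)
        lig, mus = self.element_lengths(np.asarray(batch))
        dlig = (lig[1::2] - lig[2::2]) / (2.0 * steps[:, None])
        dmus = (mus[1::2] - mus[2::2]) / (2.0 * steps[:, None])
        return lig[0], mus[0], dlig, dmus

    # ------------------------------------------------------------------
    # forces
    # ------------------------------------------------------------------
    def ligament_fiber_forces(self, lig_lengths: np.ndarray) -> np.ndarray:
        out = np.empty_like(lig_lengths)
        i = 0
        for b in self.ligaments:
            n = b.n_fibers
            out[i : i + n] = b.forces(lig_lengths[i : i + n])
            i += n
        return out

    def bundle_forces(self, lig_lengths: np.ndarray) -> dict:
        fib = self.ligament_fiber_forces(lig_lengths)
        out = {}
        i = 0
        for b in self.ligaments:
            out[b.name] = float(fib[i : i + b.n_fibers].sum())
            i += b.n_fibers
        return out

    def contact_wrenches(self, pose: KneePose, anchored: bool = True):
        """Tibiofemoral and patellofemoral contact results at a pose."""
        Tf = pose.femur_transform()
        Tp = pose.patella_transform()
        tf_res = self.tf_engine.resolve(Tf, anchored=anchored)
        Tfp = np.linalg.inv(Tp) @ Tf
        pf_res = self.pf_engine.resolve(Tfp, anchored=anchored)
        return tf_res, pf_res

    # ------------------------------------------------------------------
    # reference assembly & calibration
    # ------------------------------------------------------------------
    def assemble_reference(self) -> KneePose:
        """Settle the 0-degree-flexion pose and calibrate all slack lengths."""
        s = self.settings

        def tf_axial(si: float) -> float:
            T = body_transform(np.array([0.0, 0.0, 0.0, 0.0, si, 0.0]))
            return self.tf_engine.resolve(T).total_force - s.reference_preload_n

        si = brentq(tf_axial, -2.0, 1.0, xtol=1e-10)

        # patellar button settled along the proximal-trochlea normal, with
        # the dome axis aligned to that normal (patella flexed with the track)
        theta_p_deg = -70.0
        theta_p = np.radians(theta_p_deg)
        u = np.array([-np.sin(theta_p), -np.cos(theta_p), 0.0])
        p_flex = -(theta_p_deg + 90.0)  # rotates the dome axis (-X) onto -u

        settle = self.patella_settle_distance_mm

        def pf_force(shift: float) -> float:
            center = (settle - shift) * u
            q = np.array([0.0, 0.0, 0.0, 0.0, si, 0.0, p_flex, 0.0, 0.0, *center])
            pose = KneePose(q)
            T = np.linalg.inv(pose.patella_transform()) @ pose.femur_transform()
            return self.pf_engine.resolve(T).total_force - s.patellar_preload_n

        shift = brentq(pf_force, -3.0, 3.0, xtol=1e-10)
        center = (settle - shift) * u
        q_ref = np.array([0.0, 0.0, 0.0, 0.0, si, 0.0, p_flex, 0.0, 0.0, *center])
        self.reference_pose = KneePose(q_ref)
        self.calibrate_ligaments()
        return self.reference_pose

    def calibrate_ligaments(self) -> None:
        if self.reference_pose is None:
            raise ModelError("assemble_reference must run before calibration")
        lig, _ = self.element_lengths(self.reference_pose.q[None, :])
        lengths = lig[0]
        i = 0
        for bi, b in enumerate(self.ligaments):
            n = b.n_fibers
            self.ligaments[bi] = b.calibrated(lengths[i : i + n])
            i += n

    def apply_prestrain(self, scenario: PrestrainScenario) -> "KneeModel":
        """Model copy with the PCL reference strain set per the scenario.

        Both PCL bundles are re-calibrated at the unchanged reference pose;
        every other bundle is untouched.  The returned model shares the
        (immutable) surfaces and engines with the original.
        """
        if self.conformity != scenario.conformity:
            raise ModelError(
                f"scenario requires a {scenario.conformity}-conformity model"
            )
        new = copy.copy(self)
        new.ligaments = list(self.ligaments)
        lig, _ = self.element_lengths(self.reference_pose.q[None, :])
        lengths = lig[0]
        i = 0
        for bi, b in enumerate(self.ligaments):
            n = b.n_fibers
            if b.name in PCL_BUNDLES:
                new.ligaments[bi] = b.with_reference_strain(
                    scenario.pcl_reference_strain
                ).calibrated(lengths[i : i + n])
            i += n
        return new

    # ------------------------------------------------------------------
    # generalised forces
    # ------------------------------------------------------------------
    def generalized_forces(
        self,
        q: np.ndarray,
        activations: np.ndarray,
        external_force_n: np.ndarray,
        external_moment_nmm: np.ndarray,
    ):
        """All 12 generalised forces plus the pieces the solver needs.

        Rotational entries are torques (N*mm), translational entries forces
        (N).  Returns ``(Q_total, info)`` where ``info`` carries the contact
        results, fiber forces and muscle moment-arm matrix of this pose.
        """
        pose = KneePose(q)
        lig0, mus0, dlig, dmus = self.perturbed_lengths(q)
        fib = self.ligament_fiber_forces(lig0)

        # unit conversion: gradients w.r.t. degrees -> per radian for torques
        conv = np.ones(12)
        for i in (0, 1, 2, 6, 7, 8):
            conv[i] = 1.0 / DEG
        dlig_t = dlig * conv[:, None]
        dmus_t = dmus * conv[:, None]

        Q_lig = -(dlig_t @ fib)
        fmax = np.array([m.max_isometric_force for m in self.muscles])
        moment_arms = -dmus_t.T  # (M, 12): tendon-excursion moment arms
        Q_mus = (activations * fmax) @ moment_arms

        tf_res, pf_res = self.contact_wrenches(pose)
        # reaction of tibiofemoral contact on the femur
        Q_con = np.zeros(12)
        Q_con[:6] += generalized_force_from_wrench(q[:6], -tf_res.force, -tf_res.moment)
        # patellofemoral: result is in the patella frame
        Tp = pose.patella_transform()
        Rp, tp = Tp[:3, :3], Tp[:3, 3]
        f_pat = Rp @ pf_res.force
        m_pat = Rp @ pf_res.moment + np.cross(tp, f_pat)
        Q_con[6:] += generalized_force_from_wrench(q[6:], f_pat, m_pat)
        Q_con[:6] += generalized_force_from_wrench(q[:6], -f_pat, -m_pat)

        Q_ext = np.zeros(12)
        Q_ext[:6] += generalized_force_from_wrench(
            q[:6], external_force_n, external_moment_nmm
        )
        w = np.array([0.0, -self.patella_weight_n, 0.0])
        Q_ext[6:] += generalized_force_from_wrench(q[6:], w, np.cross(tp, w))

        Q_total = Q_lig + Q_mus + Q_con + Q_ext
        info = {
            "tf": tf_res,
            "pf": pf_res,
            "fiber_forces": fib,
            "fiber_lengths": lig0,
            "muscle_lengths": mus0,
            "moment_arms": moment_arms,
            "passive_flexion_torque": Q_lig[0] + Q_con[0] + Q_ext[0],
            "Q_passive": Q_lig + Q_con + Q_ext,
        }
        return Q_total, info

    def residuals_batch(
        self,
        Qs: np.ndarray,
        external_force_n: np.ndarray,
        external_moment_nmm: np.ndarray,
    ):
        """Generalised forces for a pose batch (used by the solver's
        finite-difference Jacobian).

        Returns ``(Q_zero (P, 12), moment_arms (P, M, 12), fiber_forces)``
        where ``Q_zero`` excludes muscle contributions.
        """
        Qs = np.atleast_2d(np.asarray(Qs, dtype=float))
        P = len(Qs)
        s = self.settings
        steps = np.array(
            [s.fd_step_rotation_deg] * 3 + [s.fd_step_translation_mm] * 3
        )
        steps = np.concatenate([steps, steps])

        big = np.empty((P, 25, 12))
        big[:, 0] = Qs
        for i in range(12):
            big[:, 1 + 2 * i] = Qs
            big[:, 1 + 2 * i, i] += steps[i]
            big[:, 2 + 2 * i] = Qs
            big[:, 2 + 2 * i, i] -= steps[i]
        lig, mus = self.element_lengths(big.reshape(P * 25, 12))
        E = lig.shape[1]
        M = mus.shape[1]
        lig = lig.reshape(P, 25, E)
        mus = mus.reshape(P, 25, M)
        dlig = (lig[:, 1::2] - lig[:, 2::2]) / (2.0 * steps[None, :, None])
        dmus = (mus[:, 1::2] - mus[:, 2::2]) / (2.0 * steps[None, :, None])
        conv = np.ones(12)
        for i in (0, 1, 2, 6, 7, 8):
            conv[i] = 1.0 / DEG
        dlig *= conv[None, :, None]
        dmus *= conv[None, :, None]

        fib = np.empty((P, E))
        i0 = 0
        for b in self.ligaments:
            n = b.n_fibers
            fib[:, i0 : i0 + n] = b.forces(lig[:, 0, i0 : i0 + n])
            i0 += n
        Q_lig = -np.einsum("pie,pe->pi", dlig, fib)
        moment_arms = -np.transpose(dmus, (0, 2, 1))  # (P, M, 12)

        Tf = batch_body_transforms(Qs[:, :6])
        Tp = batch_body_transforms(Qs[:, 6:])
        Rp = Tp[:, :3, :3]
        tp = Tp[:, :3, 3]
        # femur pose in the patella frame
        Tfp = np.zeros((P, 4, 4))
        Tfp[:, 3, 3] = 1.0
        Tfp[:, :3, :3] = np.einsum("pji,pjk->pik", Rp, Tf[:, :3, :3])
        Tfp[:, :3, 3] = np.einsum("pji,pj->pi", Rp, Tf[:, :3, 3] - tp)
        tf_b = self.tf_engine.resolve_batch(Tf)
        pf_b = self.pf_engine.resolve_batch(Tfp)

        Q_rest = np.zeros((P, 12))
        w_pat = np.array([0.0, -self.patella_weight_n, 0.0])
        for p in range(P):
            q = Qs[p]
            Q_rest[p, :6] += generalized_force_from_wrench(
                q[:6], -tf_b["force"][p], -tf_b["moment"][p]
            )
            f_pat = Rp[p] @ pf_b["force"][p]
            m_pat = Rp[p] @ pf_b["moment"][p] + np.cross(tp[p], f_pat)
            Q_rest[p, 6:] += generalized_force_from_wrench(q[6:], f_pat, m_pat)
            Q_rest[p, :6] += generalized_force_from_wrench(q[:6], -f_pat, -m_pat)
            Q_rest[p, :6] += generalized_force_from_wrench(
                q[:6], external_force_n, external_moment_nmm
            )
            Q_rest[p, 6:] += generalized_force_from_wrench(
                q[6:], w_pat, np.cross(tp[p], w_pat)
            )
        return Q_lig + Q_rest, moment_arms, fib

    # ------------------------------------------------------------------
    # serialisation
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        def bundle_dict(b: LigamentBundle) -> dict:
            return {
                "name": b.name,
                "proximal_points": b.proximal_points.tolist(),
                "distal_points": b.distal_points.tolist(),
                "stiffness_n_per_mm": b.stiffness_n_per_mm,
                "reference_strain": b.reference_strain,
                "transition_strain": b.transition_strain,
                "proximal_body": b.proximal_body,
                "distal_body": b.distal_body,
                "slack_lengths": None
                if b.slack_lengths is None
                else b.slack_lengths.tolist(),
            }

        def muscle_dict(m: MuscleActuator) -> dict:
            return {
                "name": m.name,
                "path": [[b, p.tolist()] for b, p in m.path],
                "max_isometric_force": m.max_isometric_force,
                "wrap": None
                if m.wrap is None
                else {
                    "point": m.wrap.point.tolist(),
                    "axis": m.wrap.axis.tolist(),
                    "radius": m.wrap.radius,
                    "body": m.wrap.body,
                },
            }

        return {
            "conformity": self.conformity,
            "ef_law": asdict(self.ef_law),
            "settings": asdict(self.settings),
            "inlay_spec": None if self.inlay_spec is None else asdict(self.inlay_spec),
            "patella_weight_n": self.patella_weight_n,
            "ligaments": [bundle_dict(b) for b in self.ligaments],
            "muscles": [muscle_dict(m) for m in self.muscles],
            "reference_pose": None
            if self.reference_pose is None
            else self.reference_pose.q.tolist(),
        }

    def save_resolved(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict, mesh_resolution_mm: float = 1.5) -> "KneeModel":
        from .pathgeom import WrapCylinder

        spec = InlaySpec(**d["inlay_spec"]) if d.get("inlay_spec") else InlaySpec()
        ligaments = []
        for bd in d["ligaments"]:
            slack = bd.pop("slack_lengths", None)
            b = LigamentBundle(
                name=bd["name"],
                proximal_points=np.asarray(bd["proximal_points"]),
                distal_points=np.asarray(bd["distal_points"]),
                stiffness_n_per_mm=bd["stiffness_n_per_mm"],
                reference_strain=bd["reference_strain"],
                transition_strain=bd["transition_strain"],
                proximal_body=bd["proximal_body"],
                distal_body=bd["distal_body"],
                slack_lengths=None if slack is None else np.asarray(slack),
            )
            ligaments.append(b)
        wrap_cache: dict = {}
        muscles = []
        for md in d["muscles"]:
            wrap = None
            if md["wrap"] is not None:
                key = json.dumps(md["wrap"], sort_keys=True)
                if key not in wrap_cache:
                    wrap_cache[key] = WrapCylinder(
                        point=np.asarray(md["wrap"]["point"]),
                        axis=np.asarray(md["wrap"]["axis"]),
                        radius=md["wrap"]["radius"],
                        body=md["wrap"]["body"],
                    )
                wrap = wrap_cache[key]
            muscles.append(
                MuscleActuator(
                    md["name"],
                    [(b, np.asarray(p)) for b, p in md["path"]],
                    md["max_isometric_force"],
                    wrap=wrap,
                )
            )
        model = cls(
            femur=make_femoral_component(resolution=mesh_resolution_mm),
            inlay=make_tibial_inlay(spec),
            button=make_patellar_button(resolution=mesh_resolution_mm),
            ligaments=ligaments,
            muscles=muscles,
            ef_law=EfLaw(**d["ef_law"]),
            settings=SolverSettings(**d["settings"]),
            inlay_spec=spec,
            patella_weight_n=d["patella_weight_n"],
            conformity=d["conformity"],
        )
        if d.get("reference_pose") is not None:
            model.reference_pose = KneePose(np.asarray(d["reference_pose"]))
        return model

    @classmethod
    def load_resolved(cls, path: str | Path) -> "KneeModel":
        return cls.from_dict(json.loads(Path(path).read_text()))

    # ------------------------------------------------------------------
    def fit(self, gait, scenario: PrestrainScenario | None = None):
        """Run the concurrent activation/kinematics solver through a gait
        cycle; returns :class:`~kneemech.results.GaitResults`."""
        from .solver import run_gait

        return run_gait(self, gait, scenario=scenario)
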