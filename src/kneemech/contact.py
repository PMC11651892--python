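"""Elastic-foundation contact between rigid triangulated surfaces.

One surface (the polyethylene inlay or patellar button) is treated as a bed
of independent springs of thickness ``h``; the opposing surface (the metal
femoral component) is rigid.  Per foundation face, the penetration depth is
measured by casting a ray from the face centroid along the inward normal
(into the foundation material): a first hit on a back-face of the opposing
surface within the layer thickness means the centroid lies inside the
opposing body, and the hit distance is the local indentation.  Faces whose
ray misses, or whose first hit is a front face, are not in contact.

Pressure follows the foundation law

* linear:  ``p = K * d / h``
* log:     ``p = -K * ln(1 - d / h)``  (d < h)

with ``K = (1 - nu) E / ((1 + nu)(1 - 2 nu))`` the confined foundation
modulus.  Resultants, compartmental (medial/lateral) splits and pressure
centroids (CoP) are accumulated from the per-face pressures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import COMPARTMENT_CODES, COMPARTMENT_NAMES, TriSurface


class ContactError(ValueError):
    pass


class OverclosureError(ContactError):
    """Penetration reached the foundation layer thickness."""

    def __init__(self, face_indices, depths):
        self.face_indices = np.atleast_1d(face_indices)
        self.depths = np.atleast_1d(depths)
        super().__init__(
            f"contact overclosure on {len(self.face_indices)} foundation face(s); "
            f"max depth {float(np.max(self.depths)):.3f} mm reached the layer thickness "
            f"(worst face {int(self.face_indices[np.argmax(self.depths)])})"
        )


@dataclass
class EfLaw:
    """Elastic-foundation pressure law (polyethylene layer on a rigid tray)."""

    law: str = "linear"
    elastic_modulus_mpa: float = 463.0
    poisson_ratio: float = 0.46
    layer_thickness_mm: float = 6.0

    def __post_init__(self) -> None:
        if self.law not in ("linear", "log"):
            raise ContactError("law must be 'linear' or 'log'")
        if self.layer_thickness_mm <= 0:
            raise ContactError("layer thickness must be positive")
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise ContactError("poisson ratio must be in [0, 0.5)")
        if self.elastic_modulus_mpa <= 0:
            raise ContactError("elastic modulus must be positive")

    @property
    def foundation_modulus_mpa(self) -> float:
        e, nu = self.elastic_modulus_mpa, self.poisson_ratio
        return (1.0 - nu) * e / ((1.0 + nu) * (1.0 - 2.0 * nu))


def ef_pressure(depth, law: EfLaw):
    """Pressure (MPa) from penetration depth (mm); vectorised, tension-free."""
    d = np.asarray(depth, dtype=float)
    if np.any(d < 0):
        raise ContactError("penetration depth must be non-negative")
    h = law.layer_thickness_mm
    k = law.foundation_modulus_mpa
    if law.law == "linear":
        out = k * d / h
    else:
        if np.any(d >= h):
            bad = np.flatnonzero(np.atleast_1d(d) >= h)
            raise OverclosureError(bad, np.atleast_1d(d)[bad])
        out = -k * np.log1p(-d / h)
    return out if out.ndim else float(out)


@dataclass
class ContactResult:
    """Resultants of one elastic-foundation evaluation, in the foundation frame.

    ``force`` is the resultant on the foundation body (sum of
    ``p * A * (-n)``), ``moment`` its moment about the foundation-frame
    origin.  ``compartment_force`` maps compartment name to its force vector;
    the partition is exact by construction.
    """

    pressure: np.ndarray
    force: np.ndarray
    moment: np.ndarray
    compartment_force: dict
    cop: dict
    contact_area: float
    compression_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, -1.0, 0.0]))

    @property
    def total_force(self) -> float:
        """Total compressive force (component along the compression axis)."""
        return float(self.force @ self.compression_axis)

    def compartment_compression(self, name: str) -> float:
        f = self.compartment_force.get(name)
        return 0.0 if f is None else float(f @ self.compression_axis)

    @property
    def force_medial(self) -> float:
        return self.compartment_compression("medial")

    @property
    def force_lateral(self) -> float:
        return self.compartment_compression("lateral")

    @property
    def cop_medial(self):
        return self.cop.get("medial")

    @property
    def cop_lateral(self):
        return self.cop.get("lateral")


def center_of_pressure(result: ContactResult, compartment: str):
    """Pressure-weighted centroid for a compartment; None when unloaded."""
    return result.cop.get(compartment)


class ContactEngine:
    """Reusable ray-cast elastic-foundation solver for one surface pair.

    The opposing (rigid) surface's triangles and KD-tree are cached in its
    own frame; per evaluation the foundation centroids are transformed into
    that frame, so only the relative pose changes between calls.
    """

    #: soft search depth (mm) for the fast candidate pass; deeper penetrations
    #: fall through to an exact ball-query pass
    SOFT_DEPTH = 1.5
    KNN = 32
    KNN_ANCHOR = 32

    def __init__(
        self,
        foundation: TriSurface,
        opposing: TriSurface,
        law: EfLaw,
        compression_axis=(0.0, -1.0, 0.0),
    ):
        self.foundation = foundation
        self.opposing = opposing
        self.law = law
        self.compression_axis = np.asarray(compression_axis, dtype=float)
        self._centroids = foundation.face_centroids
        self._normals = foundation.face_normals
        self._areas = foundation.face_areas
        tri = opposing.vertices[opposing.faces]
        self._v0 = tri[:, 0]
        self._e1 = tri[:, 1] - tri[:, 0]
        self._e2 = tri[:, 2] - tri[:, 0]
        self._tri_n = opposing.face_normals
        self._tri_c = opposing.face_centroids
        self._tree = cKDTree(self._tri_c)
        edges = np.linalg.norm(
            np.stack([self._e1, self._e2, self._e2 - self._e1]), axis=-1
        )
        self._circum = float(edges.max()) / np.sqrt(3.0) + 1e-9
        self._n_tris = len(self._v0)

    # ------------------------------------------------------------------
    @staticmethod
    def _cross(ax, ay, az, bx, by, bz):
        return ay * bz - az * by, az * bx - ax * bz, ax * by - ay * bx

    def _raycast(self, origins, dirs, cand, t_cap):
        """Batched Moller-Trumbore over per-origin candidate triangles.

        ``cand`` is (n, k) int indices (may repeat); returns per-origin depth
        of the nearest hit and whether that hit was a back face.
        """
        e1 = self._e1[cand]
        e2 = self._e2[cand]
        dx, dy, dz = dirs[:, 0:1], dirs[:, 1:2], dirs[:, 2:3]
        px, py, pz = self._cross(dx, dy, dz, e2[..., 0], e2[..., 1], e2[..., 2])
        det = e1[..., 0] * px + e1[..., 1] * py + e1[..., 2] * pz
        ok = np.abs(det) > 1e-12
        inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        s = origins[:, None, :] - self._v0[cand]
        sx, sy, sz = s[..., 0], s[..., 1], s[..., 2]
        u = (sx * px + sy * py + sz * pz) * inv_det
        qx, qy, qz = self._cross(sx, sy, sz, e1[..., 0], e1[..., 1], e1[..., 2])
        v = (dx * qx + dy * qy + dz * qz) * inv_det
        t = (e2[..., 0] * qx + e2[..., 1] * qy + e2[..., 2] * qz) * inv_det
        eps = 1e-9
        hit = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1.0 + eps) & (t > 1e-9) & (t <= t_cap)
        t_masked = np.where(hit, t, np.inf)
        best = np.argmin(t_masked, axis=1)
        rows = np.arange(len(origins))
        t_best = t_masked[rows, best]
        n_best = self._tri_n[cand[rows, best]]
        back = np.einsum("nj,nj->n", n_best, dirs) > 0.0
        return t_best, back

    # ------------------------------------------------------------------
    # anchored candidate caching: within one solver frame the pose moves by
    # fractions of a millimetre, so the pruning/candidate queries from a
    # nearby anchor pose remain valid (the thresholds carry the anchor
    # margin).  ``resolve`` transparently re-anchors when the pose drifts.
    ANCHOR_MARGIN = 0.35
    ANCHOR_SOFT = 0.8

    def _anchor(self, origins, dirs):
        h = self.law.layer_thickness_mm
        d0, nearest = self._tree.query(origins)
        side = np.einsum(
            "nj,nj->n", origins - self._tri_c[nearest], self._tri_n[nearest]
        )
        m = self.ANCHOR_MARGIN
        live = (d0 <= self.ANCHOR_SOFT + self._circum + m) & (side <= 0.3 + m)
        idx = np.flatnonzero(live)
        if len(idx):
            r_ball = self.ANCHOR_SOFT + self.ANCHOR_MARGIN + 1.5 * self._circum
            balls = self._tree.query_ball_point(origins[idx], r=r_ball)
            width = max(max((len(b) for b in balls), default=1), 1)
            width = min(width, self._n_tris)
            cand = np.empty((len(idx), width), dtype=np.int64)
            keep = np.ones(len(idx), dtype=bool)
            for i, b in enumerate(balls):
                if len(b) == 0:
                    keep[i] = False
                    continue
                bb = np.asarray(b, dtype=np.int64)[:width]
                cand[i, : len(bb)] = bb
                cand[i, len(bb):] = bb[-1]
            idx = idx[keep]
            cand = cand[keep]
        else:
            cand = np.empty((0, 1), dtype=np.int64)
        self._anchor_idx = idx
        self._anchor_cand = cand
        self._anchor_origins = origins

    def _anchored_depths(self, origins, dirs):
        h = self.law.layer_thickness_mm
        depth = np.zeros(len(origins))
        idx = self._anchor_idx
        if len(idx):
            t_best, back = self._raycast(
                origins[idx], dirs[idx], self._anchor_cand, t_cap=h * 1.5
            )
            found = np.isfinite(t_best) & back
            depth[idx[found]] = t_best[found]
        over = depth >= h * (1.0 - 1e-12)
        if np.any(over):
            raise OverclosureError(np.flatnonzero(over), depth[over])
        return depth

    def depths(self, T_opposing: np.ndarray, anchored: bool = False) -> np.ndarray:
        """Per-foundation-face penetration depth under the given pose.

        ``T_opposing`` maps opposing-surface coordinates into the foundation
        frame.  With ``anchored=True`` the candidate sets cached at a nearby
        anchor pose are reused (re-anchoring automatically when the pose has
        drifted more than half the anchor margin).
        """
        R = T_opposing[:3, :3]
        t = T_opposing[:3, 3]
        if not np.all(np.isfinite(T_opposing)):
            raise ContactError("degenerate (non-finite) pose")
        if anchored:
            origins = (self._centroids - t) @ R
            dirs = (-self._normals) @ R
            if getattr(self, "_anchor_origins", None) is not None:
                drift = float(
                    np.max(np.abs(origins - self._anchor_origins))
                ) if len(origins) == len(self._anchor_origins) else np.inf
                if drift <= self.ANCHOR_MARGIN * 0.45:
                    return self._anchored_depths(origins, dirs)
            self._anchor(origins, dirs)
            return self._anchored_depths(origins, dirs)
        # into opposing frame
        origins = (self._centroids - t) @ R
        dirs = (-self._normals) @ R

        h = self.law.layer_thickness_mm
        depth = np.zeros(len(origins))

        d0, nearest = self._tree.query(origins)
        # signed side of the nearest opposing face plane: negative means the
        # centroid sits inside the opposing body (up to curvature error)
        side = np.einsum("nj,nj->n", origins - self._tri_c[nearest], self._tri_n[nearest])
        live = (d0 <= self.SOFT_DEPTH + self._circum) & (side <= 0.3)
        if np.any(live):
            idx_live = np.flatnonzero(live)
            k = min(self.KNN, self._n_tris)
            _, cand = self._tree.query(origins[idx_live], k=k)
            cand = np.atleast_2d(cand)
            t_best, back = self._raycast(
                origins[idx_live], dirs[idx_live], cand, t_cap=h * 1.5
            )
            found = np.isfinite(t_best) & back
            depth[idx_live[found]] = t_best[found]

        # exact fallback for points that look inside but found no hit in the
        # k-NN candidate set (deep penetration beyond the soft search radius)
        maybe_deep = (side < 0.0) & (depth == 0.0) & (d0 <= h * 1.5 + self._circum)
        if np.any(maybe_deep):
            idx_deep = np.flatnonzero(maybe_deep)
            balls = self._tree.query_ball_point(
                origins[idx_deep], r=h * 1.5 + 2.0 * self._circum
            )
            lens = np.array([len(b) for b in balls])
            keep = lens > 0
            if np.any(keep):
                idx_deep = idx_deep[keep]
                balls = [np.asarray(b, dtype=np.int64) for b, k in zip(balls, keep) if k]
                width = int(lens[keep].max())
                cand = np.stack(
                    [np.pad(b, (0, width - len(b)), mode="edge") for b in balls]
                )
                t_b, back_b = self._raycast(
                    origins[idx_deep], dirs[idx_deep], cand, t_cap=h * 1.5
                )
                found = np.isfinite(t_b) & back_b
                depth[idx_deep[found]] = t_b[found]

        over = depth >= h * (1.0 - 1e-12)
        if np.any(over):
            raise OverclosureError(np.flatnonzero(over), depth[over])
        return depth

    def resolve_batch(self, Ts: np.ndarray) -> dict:
        """Anchored force/moment resultants for a (P, 4, 4) pose batch.

        All poses must lie within the anchor margin of each other (the
        solver's finite-difference and line-search clusters do).  CoPs and
        per-face pressures are not computed here; use :meth:`resolve` for a
        full single-pose result.
        """
        Ts = np.asarray(Ts, dtype=float)
        P = len(Ts)
        R0, t0 = Ts[0, :3, :3], Ts[0, :3, 3]
        origins0 = (self._centroids - t0) @ R0
        dirs0 = (-self._normals) @ R0
        if getattr(self, "_anchor_origins", None) is None or (
            float(np.max(np.abs(origins0 - self._anchor_origins)))
            > self.ANCHOR_MARGIN * 0.45
        ):
            self._anchor(origins0, dirs0)
        idx = self._anchor_idx
        h = self.law.layer_thickness_mm
        n_live = len(idx)
        out_force = np.zeros((P, 3))
        out_moment = np.zeros((P, 3))
        comp_codes = np.unique(self.foundation.compartment)
        out_comp = {
            COMPARTMENT_NAMES[int(c)]: np.zeros((P, 3)) for c in comp_codes
        }
        if n_live == 0:
            return {"force": out_force, "moment": out_moment, "compartments": out_comp}
        C = self._centroids[idx]
        Nrm = self._normals[idx]
        A = self._areas[idx]
        Rb = Ts[:, :3, :3]
        tb = Ts[:, :3, 3]
        origins = np.einsum("nj,pji->pni", C, Rb) - np.einsum("pj,pji->pi", tb, Rb)[:, None, :]
        dirs = -np.einsum("nj,pji->pni", Nrm, Rb)
        cand = np.broadcast_to(self._anchor_cand, (P,) + self._anchor_cand.shape)
        t_best, back = self._raycast(
            origins.reshape(P * n_live, 3),
            dirs.reshape(P * n_live, 3),
            cand.reshape(P * n_live, -1),
            t_cap=h * 1.5,
        )
        depth = np.where(np.isfinite(t_best) & back, t_best, 0.0).reshape(P, n_live)
        if np.any(depth >= h * (1.0 - 1e-12)):
            bad = np.argwhere(depth >= h * (1.0 - 1e-12))
            raise OverclosureError(idx[bad[:, 1]], depth[bad[:, 0], bad[:, 1]])
        k = self.law.foundation_modulus_mpa
        if self.law.law == "linear":
            pressure = k * depth / h
        else:
            pressure = -k * np.log1p(-depth / h)
        pa = pressure * A[None, :]
        fvec = -Nrm[None, :, :] * pa[:, :, None]
        out_force[:] = fvec.sum(axis=1)
        out_moment[:] = np.cross(C[None, :, :], fvec).sum(axis=1)
        comp_live = self.foundation.compartment[idx]
        for c in comp_codes:
            sel = comp_live == c
            if np.any(sel):
                out_comp[COMPARTMENT_NAMES[int(c)]][:] = fvec[:, sel].sum(axis=1)
        return {"force": out_force, "moment": out_moment, "compartments": out_comp}

    def resolve(self, T_opposing: np.ndarray, anchored: bool = False) -> ContactResult:
        depth = self.depths(T_opposing, anchored=anchored)
        pressure = np.zeros_like(depth)
        loaded = depth > 0.0
        if np.any(loaded):
            pressure[loaded] = ef_pressure(depth[loaded], self.law)
        pa = pressure * self._areas
        fvec = -self._normals * pa[:, None]
        force = fvec.sum(axis=0)
        moment = np.cross(self._centroids, fvec).sum(axis=0)

        comp_force: dict = {}
        cop: dict = {}
        for code in np.unique(self.foundation.compartment):
            name = COMPARTMENT_NAMES[int(code)]
            sel = self.foundation.compartment == code
            comp_force[name] = fvec[sel].sum(axis=0)
            w = pa[sel]
            wsum = w.sum()
            if wsum > 0.0:
                cop[name] = (self._centroids[sel] * w[:, None]).sum(axis=0) / wsum
            else:
                cop[name] = None
        return ContactResult(
            pressure=pressure,
            force=force,
            moment=moment,
            compartment_force=comp_force,
            cop=cop,
            contact_area=float(self._areas[loaded].sum()),
            compression_axis=self.compression_axis.copy(),
        )


def resolve_contact(
    foundation: TriSurface,
    opposing: TriSurface,
    relative_pose: np.ndarray | None = None,
    law: EfLaw | None = None,
) -> ContactResult:
    """One-shot elastic-foundation evaluation (see :class:`ContactEngine`).

    ``relative_pose`` maps the opposing surface into the foundation frame
    (identity when both are already expressed there).
    """
    engine = ContactEngine(foundation, opposing, law or EfLaw())
    T = np.eye(4) if relative_pose is None else np.asarray(relative_pose, dtype=float)
    if T.shape != (4, 4):
        raise ContactError("relative_pose must be a 4x4 transform")
    return engine.resolve(T)
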