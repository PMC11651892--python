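"""Parametric implant articular surfaces.

The package ships stand-in component geometry for a fixed-bearing,
cruciate-retaining total knee replacement: a toroidal-dished tibial inlay
(two compartments), a multi-radius bicondylar femoral component with a
trochlear groove, and a dome patellar button.  All surfaces are generated
analytically and triangulated on regular grids, so geometric statements
(dwell-point location, symmetry, refinement behaviour) hold by construction.

The low-conformity inlay variant doubles the sagittal dish radius while
keeping the dwell (lowest-contact) points fixed, which preserves the joint
line and permits direct kinematic comparison between conformities.

Units are millimetres throughout.  Frame convention: ``+X`` anterior,
``+Y`` superior, ``+Z`` lateral (right knee); medial is ``-Z``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh

COMPARTMENT_CODES = {"none": 0, "medial": 1, "lateral": 2, "patellar": 3}
COMPARTMENT_NAMES = {v: k for k, v in COMPARTMENT_CODES.items()}


class GeometryError(ValueError):
    """Invalid geometric specification."""


@dataclass
class TriSurface:
    """Triangulated articular surface with consistent outward normals.

    ``compartment`` is a per-face integer code (see
    :data:`COMPARTMENT_CODES`).  Normals point away from the component
    material (out of the metal / polyethylene).
    """

    vertices: np.ndarray
    faces: np.ndarray
    compartment: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise GeometryError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise GeometryError("faces must be (m, 3)")
        if len(self.faces) == 0:
            raise GeometryError("surface has no faces")
        if not np.all(np.isfinite(self.vertices)):
            raise GeometryError("vertex coordinates must be finite")
        key = np.sort(self.faces, axis=1)
        if len(np.unique(key, axis=0)) != len(key):
            raise GeometryError("mesh contains duplicate faces")
        if self.compartment is None:
            self.compartment = np.zeros(len(self.faces), dtype=np.int8)
        else:
            self.compartment = np.asarray(self.compartment, dtype=np.int8)
            if self.compartment.shape != (len(self.faces),):
                raise GeometryError("compartment labels must be per-face")
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(cross, axis=1)
        if np.any(norm <= 0):
            raise GeometryError("degenerate (zero-area) faces present")
        self.face_areas = 0.5 * norm
        self.face_normals = cross / norm[:, None]
        self.face_centroids = tri.mean(axis=1)

    # ------------------------------------------------------------------
    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def compartment_label(self) -> np.ndarray:
        return np.array([COMPARTMENT_NAMES[c] for c in self.compartment])

    def faces_in(self, compartment: str) -> np.ndarray:
        return np.flatnonzero(self.compartment == COMPARTMENT_CODES[compartment])

    def transformed(self, T: np.ndarray) -> "TriSurface":
        verts = self.vertices @ T[:3, :3].T + T[:3, 3]
        return TriSurface(verts, self.faces.copy(), self.compartment.copy())

    def max_edge_length(self) -> float:
        tri = self.vertices[self.faces]
        e = np.concatenate(
            [tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 1], tri[:, 0] - tri[:, 2]]
        )
        return float(np.linalg.norm(e, axis=1).max())

    def total_area(self) -> float:
        return float(self.face_areas.sum())

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)


# ----------------------------------------------------------------------
# grid triangulation helper
# ----------------------------------------------------------------------

def _grid_faces(ni: int, nj: int) -> np.ndarray:
    """Faces of an (ni x nj) vertex grid, split along alternating diagonals."""
    idx = np.arange(ni * nj).reshape(ni, nj)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    return np.concatenate([np.stack([a, b, c], 1), np.stack([a, c, d], 1)])


def _orient(surface_verts: np.ndarray, faces: np.ndarray, outward: np.ndarray) -> np.ndarray:
    """Flip face winding where the winding normal opposes the analytic one."""
    tri = surface_verts[faces]
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    flip = np.einsum("ij,ij->i", n, outward) < 0
    out = faces.copy()
    out[flip] = out[flip][:, ::-1]
    return out


# ----------------------------------------------------------------------
# tibial inlay
# ----------------------------------------------------------------------

@dataclass
class InlaySpec:
    """Parametric description of the tibial-inlay articular surface.

    The dish is the sum of a sagittal and a coronal circular sag about the
    dwell point, sampled on a regular AP x ML grid; the dwell point is the
    exact minimum of the surface for any radius, which is what makes the
    conformity variants directly comparable.
    """

    sagittal_radius_mm: float = 43.0
    coronal_radius_mm: float | None = None  # defaults to sagittal (spherical dish)
    dwell_point_ap_mm: float = 0.0
    dwell_point_ml_mm: float = 22.0  # magnitude; compartments sit at +/- this
    dwell_si_mm: float = -26.0
    compartment_halfwidth_mm: float = 16.0  # anteroposterior half-extent
    ml_halfwidth_mm: float = 9.0  # mediolateral half-extent (keeps the
    # compartments clear of the trochlear groove's z-range)
    mesh_resolution_mm: float = 1.5

    def __post_init__(self) -> None:
        if self.sagittal_radius_mm <= 0:
            raise GeometryError("sagittal radius must be positive")
        if self.coronal_radius_mm is None:
            self.coronal_radius_mm = self.sagittal_radius_mm
        if self.coronal_radius_mm <= 0:
            raise GeometryError("coronal radius must be positive")
        if self.mesh_resolution_mm <= 0:
            raise GeometryError("mesh resolution must be positive")
        if self.compartment_halfwidth_mm <= 0 or self.ml_halfwidth_mm <= 0:
            raise GeometryError("compartment halfwidths must be positive")
        if self.compartment_halfwidth_mm >= self.sagittal_radius_mm:
            raise GeometryError("AP halfwidth must be smaller than the sagittal radius")
        if self.ml_halfwidth_mm >= self.coronal_radius_mm:
            raise GeometryError("ML halfwidth must be smaller than the coronal radius")

    def low_conformity(self) -> "InlaySpec":
        """Variant with doubled sagittal radius and identical dwell points."""
        return replace(self, sagittal_radius_mm=2.0 * self.sagittal_radius_mm)


def make_tibial_inlay(spec: InlaySpec) -> TriSurface:
    """Two dished compartments; lowest point of each at its dwell point."""
    hw_ap = spec.compartment_halfwidth_mm
    hw_ml = spec.ml_halfwidth_mm
    # odd vertex counts centred on the dwell point, so the dwell is an exact
    # grid sample at every resolution
    nx = 2 * max(int(np.ceil(hw_ap / spec.mesh_resolution_mm)), 2) + 1
    nz = 2 * max(int(np.ceil(hw_ml / spec.mesh_resolution_mm)), 2) + 1
    ux = np.linspace(-hw_ap, hw_ap, nx)
    uz = np.linspace(-hw_ml, hw_ml, nz)
    rs, rc = spec.sagittal_radius_mm, spec.coronal_radius_mm

    verts_all, faces_all, comp_all = [], [], []
    offset = 0
    for zd_sign, label in ((-1.0, "medial"), (1.0, "lateral")):
        xd = spec.dwell_point_ap_mm
        zd = zd_sign * spec.dwell_point_ml_mm
        x, z = np.meshgrid(xd + ux, zd + uz, indexing="ij")
        y = (
            spec.dwell_si_mm
            + rs
            - np.sqrt(rs * rs - (x - xd) ** 2)
            + rc
            - np.sqrt(rc * rc - (z - zd) ** 2)
        )
        verts = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
        faces = _grid_faces(nx, nz)
        # outward is up out of the polyethylene; the dish is shallow so +Y works
        faces = _orient(verts, faces, np.tile([0.0, 1.0, 0.0], (len(faces), 1)))
        verts_all.append(verts)
        faces_all.append(faces + offset)
        comp_all.append(np.full(len(faces), COMPARTMENT_CODES[label], dtype=np.int8))
        offset += len(verts)

    return TriSurface(
        np.concatenate(verts_all), np.concatenate(faces_all), np.concatenate(comp_all)
    )


# ----------------------------------------------------------------------
# femoral component
# ----------------------------------------------------------------------

def _profile_center(theta_deg: np.ndarray, radii, boundaries_deg) -> tuple[np.ndarray, np.ndarray]:
    """Sagittal profile of a multi-radius condyle with tangent-continuous arcs.

    Returns (center_xy, radius) for each theta.  theta is measured in the
    sagittal plane from the distal direction (-Y), increasing posteriorly.
    """
    radii = np.asarray(radii, dtype=float)
    boundaries = np.asarray(boundaries_deg, dtype=float)
    centers = [np.zeros(2)]
    for j, tb in enumerate(boundaries):
        ub = np.array([-np.sin(np.radians(tb)), -np.cos(np.radians(tb))])
        centers.append(centers[-1] + (radii[j] - radii[j + 1]) * ub)
    centers = np.array(centers)
    zone = np.searchsorted(boundaries, theta_deg, side="right")
    return centers[zone], radii[zone]


def make_femoral_component(
    condyle_radii=(26.0, 22.0),
    condyle_spacing: float = 44.0,
    resolution: float = 1.5,
    *,
    zone_boundaries_deg=(40.0),
    coronal_radius: float = 20.0,
    theta_range_deg=(-30.0, 120.0),
    psi_max_deg: float = 25.0,
    trochlea_theta_deg=(-75.0, 25.0),
    trochlea_halfwidth: float = 11.0,
    sulcus_offset: float = 1.0,
    groove_depth: float = 3.0,
    trochlea_distal_taper: float = 5.0,
    medial_radii=None,
    lateral_radii=None,
) -> TriSurface:
    """Bicondylar femoral component with a trochlear groove.

    The sagittal profile is a sequence of tangent-continuous arcs whose radii
    decrease posteriorly (``condyle_radii`` per flexion zone, boundaries at
    ``zone_boundaries_deg``); each condyle is a toroidal sweep of coronal
    radius ``coronal_radius`` about that profile.  The trochlea is a grooved
    sweep between the condyles whose sulcus is recessed by ``groove_depth``
    relative to its facets, giving the patellar button medial-lateral
    stability.
    """
    condyle_radii = np.atleast_1d(np.asarray(condyle_radii, dtype=float))
    boundaries = np.atleast_1d(np.asarray(zone_boundaries_deg, dtype=float))[: len(condyle_radii) - 1]
    if np.any(condyle_radii <= 0):
        raise GeometryError("condyle radii must be positive")
    if len(condyle_radii) > 1 and np.any(np.diff(condyle_radii) >= 0):
        raise GeometryError("condyle radii must decrease posteriorly")
    if coronal_radius <= 0 or resolution <= 0:
        raise GeometryError("coronal radius and resolution must be positive")
    if np.any(condyle_radii < coronal_radius):
        raise GeometryError(
            "sagittal radii must not be smaller than the coronal radius "
            "(self-intersecting torus)"
        )
    med_radii = np.asarray(medial_radii if medial_radii is not None else condyle_radii, float)
    lat_radii = np.asarray(lateral_radii if lateral_radii is not None else condyle_radii, float)

    verts_all, faces_all, comp_all = [], [], []
    offset = 0

    # condyles ---------------------------------------------------------
    t0, t1 = theta_range_deg
    arc_len = np.radians(t1 - t0) * float(np.max(condyle_radii))
    ntheta = max(int(np.ceil(arc_len / resolution)) + 1, 8)
    theta = np.linspace(t0, t1, ntheta)
    psi_len = 2 * np.radians(psi_max_deg) * coronal_radius
    npsi = max(int(np.ceil(psi_len / resolution)) + 1, 6)
    psi = np.radians(np.linspace(-psi_max_deg, psi_max_deg, npsi))

    for z_sign, radii, label in ((-1.0, med_radii, "medial"), (1.0, lat_radii, "lateral")):
        centers, R = _profile_center(theta, radii, boundaries)
        u = np.stack([-np.sin(np.radians(theta)), -np.cos(np.radians(theta))], axis=1)
        spine = centers + (R - coronal_radius)[:, None] * u  # (ntheta, 2)
        # p(theta, psi) = spine + r_cor * (cos(psi) u + sin(psi) z)
        cx = spine[:, None, 0] + coronal_radius * np.cos(psi)[None, :] * u[:, None, 0]
        cy = spine[:, None, 1] + coronal_radius * np.cos(psi)[None, :] * u[:, None, 1]
        cz = np.broadcast_to(
            z_sign * condyle_spacing / 2.0 + coronal_radius * np.sin(psi)[None, :],
            (ntheta, npsi),
        )
        verts = np.stack([cx.ravel(), cy.ravel(), cz.ravel()], axis=1)
        nx = (np.cos(psi)[None, :] * u[:, None, 0]).ravel()
        ny = (np.cos(psi)[None, :] * u[:, None, 1]).ravel()
        nz = np.broadcast_to(np.sin(psi)[None, :], (ntheta, npsi)).ravel()
        outward_v = np.stack([nx, ny, nz], axis=1)
        faces = _grid_faces(ntheta, npsi)
        outward_f = outward_v[faces].mean(axis=1)
        faces = _orient(verts, faces, outward_f)
        verts_all.append(verts)
        faces_all.append(faces + offset)
        comp_all.append(np.full(len(faces), COMPARTMENT_CODES[label], dtype=np.int8))
        offset += len(verts)

    # trochlea ---------------------------------------------------------
    tt0, tt1 = trochlea_theta_deg
    r_sulcus = float(condyle_radii[0]) + sulcus_offset
    arc_len = np.radians(tt1 - tt0) * (r_sulcus + groove_depth)
    ntheta_t = max(int(np.ceil(arc_len / resolution)) + 1, 8)
    theta_t = np.linspace(tt0, tt1, ntheta_t)
    nz_t = max(int(np.ceil(2 * trochlea_halfwidth / resolution)) + 1, 6)
    zt = np.linspace(-trochlea_halfwidth, trochlea_halfwidth, nz_t)
    # distal taper keeps the groove proud of the tibial joint line as it
    # blends toward the intercondylar region
    taper = trochlea_distal_taper * np.clip((theta_t + 35.0) / (tt1 + 35.0), 0.0, 1.0)
    r_t = (r_sulcus - taper)[:, None] + groove_depth * (zt[None, :] / trochlea_halfwidth) ** 2
    u = np.stack([-np.sin(np.radians(theta_t)), -np.cos(np.radians(theta_t))], axis=1)
    cx = r_t * u[:, None, 0]
    cy = r_t * u[:, None, 1]
    cz = np.broadcast_to(zt[None, :], (ntheta_t, nz_t))
    verts = np.stack([cx.ravel(), cy.ravel(), cz.ravel()], axis=1)
    outward_v = np.stack(
        [
            np.broadcast_to(u[:, None, 0], (ntheta_t, nz_t)).ravel(),
            np.broadcast_to(u[:, None, 1], (ntheta_t, nz_t)).ravel(),
            np.zeros(ntheta_t * nz_t),
        ],
        axis=1,
    )
    faces = _grid_faces(ntheta_t, nz_t)
    faces = _orient(verts, faces, outward_v[faces].mean(axis=1))
    verts_all.append(verts)
    faces_all.append(faces + offset)
    comp_all.append(np.full(len(faces), COMPARTMENT_CODES["patellar"], dtype=np.int8))

    return TriSurface(
        np.concatenate(verts_all), np.concatenate(faces_all), np.concatenate(comp_all)
    )


# ----------------------------------------------------------------------
# patellar button
# ----------------------------------------------------------------------

def make_patellar_button(
    radius: float = 13.0, thickness: float = 8.0, resolution: float = 1.5
) -> TriSurface:
    """Dome (spherical-cap) patellar button; apex at ``(0, 0, thickness)``.

    ``radius`` is the spherical radius of the dome, ``thickness`` the cap
    height along the local ``+Z`` axis (the articulating direction).
    """
    if radius <= 0 or thickness <= 0 or resolution <= 0:
        raise GeometryError("radius, thickness and resolution must be positive")
    if thickness > radius:
        raise GeometryError("cap height cannot exceed the dome radius")
    center_z = thickness - radius
    phi_max = np.arccos(np.clip((radius - thickness) / radius, -1.0, 1.0))
    nphi = max(int(np.ceil(phi_max * radius / resolution)) + 1, 3)
    phis = np.linspace(0.0, phi_max, nphi)

    apex = np.array([[0.0, 0.0, thickness]])
    flat = [apex]
    ring_index: list[np.ndarray] = []
    count = 1
    for phi in phis[1:]:
        ring_r = radius * np.sin(phi)
        nseg = max(int(np.ceil(2 * np.pi * ring_r / resolution)), 6)
        ang = np.linspace(0.0, 2 * np.pi, nseg, endpoint=False)
        ring = np.stack(
            [
                ring_r * np.cos(ang),
                ring_r * np.sin(ang),
                center_z + radius * np.cos(phi) * np.ones(nseg),
            ],
            axis=1,
        )
        ring_index.append(np.arange(count, count + nseg))
        flat.append(ring)
        count += nseg
    V = np.concatenate(flat)

    faces = []
    # apex fan
    first = ring_index[0]
    for i in range(len(first)):
        faces.append((0, first[i], first[(i + 1) % len(first)]))
    # ring-to-ring strips (rings may differ in segment count)
    for ra, rb in zip(ring_index[:-1], ring_index[1:]):
        na, nb = len(ra), len(rb)
        ia = ib = 0
        fa = fb = 0.0
        while ia < na or ib < nb:
            if ib < nb and (ia >= na or (fb + 1.0 / nb) <= (fa + 1.0 / na)):
                faces.append((ra[ia % na], rb[ib % nb], rb[(ib + 1) % nb]))
                ib += 1
                fb += 1.0 / nb
            else:
                faces.append((ra[ia % na], rb[ib % nb], ra[(ia + 1) % na]))
                ia += 1
                fa += 1.0 / na
    F = np.array(faces, dtype=np.int64)
    ctr = np.array([0.0, 0.0, center_z])
    outward = V[F].mean(axis=1) - ctr
    F = _orient(V, F, outward)
    comp = np.full(len(F), COMPARTMENT_CODES["patellar"], dtype=np.int8)
    return TriSurface(V, F, comp)


# ----------------------------------------------------------------------
# analytic primitives (used for contact verification against quadrature)
# ----------------------------------------------------------------------

def make_plane_patch(half_extent: float = 15.0, resolution: float = 1.5) -> TriSurface:
    """Flat foundation patch in the y=0 plane, outward normal +Y."""
    n = max(int(np.ceil(2 * half_extent / resolution)) + 1, 3)
    u = np.linspace(-half_extent, half_extent, n)
    x, z = np.meshgrid(u, u, indexing="ij")
    verts = np.stack([x.ravel(), np.zeros(n * n), z.ravel()], axis=1)
    faces = _grid_faces(n, n)
    faces = _orient(verts, faces, np.tile([0.0, 1.0, 0.0], (len(faces), 1)))
    return TriSurface(verts, faces)


def make_spherical_dish(
    radius: float = 25.0, half_extent: float = 12.0, resolution: float = 1.5
) -> TriSurface:
    """Concave spherical dish opening upward; lowest point at the origin."""
    if half_extent >= radius:
        raise GeometryError("half extent must be smaller than the dish radius")
    n = max(int(np.ceil(2 * half_extent / resolution)) + 1, 3)
    u = np.linspace(-half_extent, half_extent, n)
    x, z = np.meshgrid(u, u, indexing="ij")
    y = radius - np.sqrt(radius**2 - x**2 - z**2)
    verts = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
    faces = _grid_faces(n, n)
    center = np.array([0.0, radius, 0.0])
    outward = center - verts[faces].mean(axis=1)  # toward sphere center = out of material
    faces = _orient(verts, faces, outward)
    return TriSurface(verts, faces)


def make_sphere(radius: float, resolution: float = 1.0) -> TriSurface:
    """Closed sphere (rigid indenter for contact checks)."""
    sub = int(np.ceil(np.log2(max(1.05 * radius / resolution, 2.0))))
    m = trimesh.creation.icosphere(subdivisions=max(2, min(sub, 7)), radius=radius)
    return TriSurface(np.asarray(m.vertices), np.asarray(m.faces))


# ----------------------------------------------------------------------
# mesh io
# ----------------------------------------------------------------------

def export_mesh(surface: TriSurface, path: str | Path, file_format: str | None = None) -> Path:
    """Write a surface to STL or OBJ (format inferred from the suffix)."""
    path = Path(path)
    fmt = (file_format or path.suffix.lstrip(".")).lower()
    if fmt not in ("stl", "obj"):
        raise GeometryError(f"unsupported mesh format: {fmt!r}")
    mesh = surface.to_trimesh()
    if fmt == "stl":
        path.write_bytes(trimesh.exchange.stl.export_stl(mesh))
    else:
        path.write_text(trimesh.exchange.obj.export_obj(mesh, include_normals=False))
    return path


def load_mesh(path: str | Path) -> TriSurface:
    mesh = trimesh.load(str(path), process=False, force="mesh")
    return TriSurface(np.asarray(mesh.vertices, float), np.asarray(mesh.faces, np.int64))
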