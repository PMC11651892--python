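import numpy as np
import pytest
from scipy.integrate import quad

from kneemech.contact import (
    ContactError,
    ContactEngine,
    EfLaw,
    OverclosureError,
    center_of_pressure,
    ef_pressure,
    resolve_contact,
)
from kneemech.geometry import (
    TriSurface,
    make_plane_patch,
    make_sphere,
    make_spherical_dish,
)

LAW = EfLaw()


def sphere_on_plane_oracle(radius, delta, law):
    """Dense quadrature of the foundation pressure over the analytic overlap disc."""
    k, h = law.foundation_modulus_mpa, law.layer_thickness_mm
    a = np.sqrt(radius**2 - (radius - delta) ** 2)

    def p(r):
        d = np.sqrt(radius**2 - r**2) - (radius - delta)
        return ef_pressure(d, law) * 2 * np.pi * r

    return quad(p, 0.0, a)[0]


def sphere_in_dish_oracle(dish_r, sphere_r, delta, law, half_extent, n=3000):
    """Quadrature over the analytic dish with closed-form ray-sphere depth."""
    k, h = law.foundation_modulus_mpa, law.layer_thickness_mm
    C = np.array([0.0, dish_r, 0.0])
    S = np.array([0.0, sphere_r - delta, 0.0])
    phimax = np.arcsin(half_extent / dish_r)
    phis = np.linspace(0.0, phimax, n)
    F = np.zeros(3)
    naz = 360
    az = np.linspace(0.0, 2 * np.pi, naz, endpoint=False)
    for lo, hi in zip(phis[:-1], phis[1:]):
        phi = 0.5 * (lo + hi)
        d = np.stack(
            [np.sin(phi) * np.cos(az), -np.cos(phi) * np.ones(naz), np.sin(phi) * np.sin(az)],
            axis=1,
        )
        P = C + dish_r * d
        ps = P - S
        b = np.einsum("ij,ij->i", ps, d)
        c = np.einsum("ij,ij->i", ps, ps) - sphere_r**2
        disc = np.maximum(b * b - c, 0.0)
        depth = np.where(c < 0.0, -b + np.sqrt(disc), 0.0)
        p = k * depth / h
        dA = dish_r**2 * np.sin(phi) * (hi - lo) * (2 * np.pi / naz)
        F += (p[:, None] * d).sum(axis=0) * dA
    return F


class TestPressureLaw:
    def test_zero_depth_zero_pressure(self):
        assert ef_pressure(0.0, LAW) == 0.0
        assert ef_pressure(0.0, EfLaw(law="log")) == 0.0

    def test_linear_and_log_agree_at_small_depth(self):
        d = 0.01 * LAW.layer_thickness_mm
        p_lin = ef_pressure(d, LAW)
        p_log = ef_pressure(d, EfLaw(law="log"))
        assert abs(p_lin - p_log) / p_lin < 0.01

    def test_linear_reduces_to_e_d_over_h_at_zero_poisson(self):
        law = EfLaw(poisson_ratio=0.0, elastic_modulus_mpa=100.0, layer_thickness_mm=5.0)
        assert np.isclose(ef_pressure(1.0, law), 100.0 * 1.0 / 5.0, rtol=1e-12)

    def test_monotone_in_depth(self):
        d = np.linspace(0.0, 5.0, 50)
        for law in (LAW, EfLaw(law="log")):
            p = ef_pressure(d, law)
            assert np.all(np.diff(p) > 0)

    def test_log_overcloses_at_layer_thickness(self):
        with pytest.raises(OverclosureError):
            ef_pressure(LAW.layer_thickness_mm, EfLaw(law="log"))

    def test_negative_depth_rejected(self):
        with pytest.raises(ContactError):
            ef_pressure(-0.1, LAW)


class TestResolveContact:
    def test_separated_surfaces_zero_everything(self):
        plane = make_plane_patch(10.0, 1.5)
        sph = make_sphere(20.0, 1.5)
        T = np.eye(4)
        T[:3, 3] = (0.0, 21.0, 0.0)
        res = resolve_contact(plane, sph, T, LAW)
        assert np.allclose(res.force, 0.0)
        assert res.contact_area == 0.0
        assert center_of_pressure(res, "none") is None

    def test_sphere_on_plane_cop_on_symmetry_axis(self):
        plane = make_plane_patch(12.0, 1.0)
        sph = make_sphere(25.0, 1.0)
        T = np.eye(4)
        T[:3, 3] = (2.0, 25.0 - 1.0, 0.0)  # axis at x = 2
        res = resolve_contact(plane, sph, T, LAW)
        cop = center_of_pressure(res, "none")
        assert abs(cop[0] - 2.0) < 0.5
        assert abs(cop[2]) < 0.5

    def test_sphere_on_plane_matches_quadrature(self):
        R, delta = 40.0, 2.0
        plane = make_plane_patch(15.0, 1.5)
        sph = make_sphere(R, 1.5)
        T = np.eye(4)
        T[:3, 3] = (0.0, R - delta, 0.0)
        res = resolve_contact(plane, sph, T, LAW)
        F = sphere_on_plane_oracle(R, delta, LAW)
        assert abs(-res.force[1] - F) / F < 0.02

    def test_moment_consistent_with_force_field(self):
        plane = make_plane_patch(12.0, 1.0)
        sph = make_sphere(25.0, 1.0)
        T = np.eye(4)
        T[:3, 3] = (3.0, 24.0, -1.0)
        engine = ContactEngine(plane, sph, LAW)
        res = engine.resolve(T)
        pa = res.pressure * plane.face_areas
        fvec = -plane.face_normals * pa[:, None]
        m = np.cross(plane.face_centroids, fvec).sum(axis=0)
        assert np.allclose(m, res.moment, rtol=1e-9, atol=1e-9)

    def test_degenerate_pose_rejected(self):
        plane = make_plane_patch(10.0, 1.5)
        sph = make_sphere(20.0, 1.5)
        T = np.eye(4)
        T[1, 3] = np.nan
        with pytest.raises(ContactError):
            resolve_contact(plane, sph, T, LAW)


class TestContactInvariants:
    def test_frame_objectivity(self):
        """Rigidly rotating both surfaces rotates the resultants identically."""
        from kneemech.frames import rot_x, rot_z

        plane = make_plane_patch(12.0, 1.2)
        sph = make_sphere(25.0, 1.2)
        T = np.eye(4)
        T[:3, 3] = (1.0, 24.2, 0.5)
        res0 = resolve_contact(plane, sph, T, LAW)
        R = rot_z(27.0) @ rot_x(-14.0)
        W = np.eye(4)
        W[:3, :3] = R
        plane_r = plane.transformed(W)
        T_r = W @ T
        res1 = resolve_contact(plane_r, sph, T_r, LAW)
        assert np.allclose(res1.force, R @ res0.force, rtol=1e-9, atol=1e-9)
        assert np.allclose(res1.moment, R @ res0.moment, rtol=1e-9, atol=1e-6)

    def test_compartment_partition_exact(self, default_model):
        from kneemech.frames import KneePose

        pose = default_model.reference_pose
        res = default_model.tf_engine.resolve(pose.femur_transform())
        total = sum(res.compartment_force.values())
        assert np.allclose(total, res.force, rtol=0, atol=1e-12)
        assert np.isclose(
            res.force_medial + res.force_lateral, res.total_force, rtol=1e-12
        )

    def test_cop_inside_loaded_compartment_hull(self, default_model):
        pose = default_model.reference_pose
        res = default_model.tf_engine.resolve(pose.femur_transform())
        for comp in ("medial", "lateral"):
            cop = res.cop[comp]
            sel = default_model.inlay.compartment == {"medial": 1, "lateral": 2}[comp]
            loaded = sel & (res.pressure > 0)
            pts = default_model.inlay.face_centroids[loaded]
            lo, hi = pts.min(axis=0), pts.max(axis=0)
            assert np.all(cop >= lo - 1e-9) and np.all(cop <= hi + 1e-9)

    def test_anchored_matches_exact(self, default_model):
        T = default_model.reference_pose.femur_transform()
        exact = default_model.tf_engine.resolve(T)
        anchored = default_model.tf_engine.resolve(T, anchored=True)
        assert np.allclose(exact.force, anchored.force, atol=1e-9)


class TestDishOracle:
    def test_sphere_in_dish_matches_quadrature(self):
        Rd, Rs, delta = 25.0, 15.0, 2.0
        dish = make_spherical_dish(Rd, 14.0, 1.5)
        sph = make_sphere(Rs, 1.5)
        T = np.eye(4)
        T[:3, 3] = (0.0, Rs - delta, 0.0)
        res = resolve_contact(dish, sph, T, LAW)
        F = sphere_in_dish_oracle(Rd, Rs, delta, LAW, 14.0)
        assert abs(res.force[1] - F[1]) / abs(F[1]) < 0.02
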