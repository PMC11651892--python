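import numpy as np
import pytest

from kneemech.geometry import (
    GeometryError,
    InlaySpec,
    TriSurface,
    export_mesh,
    load_mesh,
    make_femoral_component,
    make_patellar_button,
    make_plane_patch,
    make_spherical_dish,
    make_tibial_inlay,
)


def lowest_vertex(surface, compartment):
    idx = surface.faces_in(compartment)
    verts = np.unique(surface.faces[idx])
    pts = surface.vertices[verts]
    return pts[np.argmin(pts[:, 1])]


class TestTibialInlay:
    def test_dwell_points_at_specified_location(self):
        spec = InlaySpec()
        inlay = make_tibial_inlay(spec)
        for comp, z_sign in (("medial", -1), ("lateral", 1)):
            low = lowest_vertex(inlay, comp)
            assert abs(low[1] - spec.dwell_si_mm) < spec.mesh_resolution_mm / 2
            assert abs(low[0] - spec.dwell_point_ap_mm) < spec.mesh_resolution_mm / 2
            assert abs(low[2] - z_sign * spec.dwell_point_ml_mm) < spec.mesh_resolution_mm / 2

    def test_conformity_variants_share_dwell_points_exactly(self):
        spec = InlaySpec()
        std = make_tibial_inlay(spec)
        low = make_tibial_inlay(spec.low_conformity())
        for comp in ("medial", "lateral"):
            a = lowest_vertex(std, comp)
            b = lowest_vertex(low, comp)
            assert np.allclose(a, b, atol=1e-6)

    def test_refinement_keeps_dwell_and_quadruples_faces(self):
        spec = InlaySpec()
        coarse = make_tibial_inlay(spec)
        fine = make_tibial_inlay(
            InlaySpec(mesh_resolution_mm=spec.mesh_resolution_mm / 2)
        )
        assert 3.0 < fine.n_faces / coarse.n_faces < 5.0
        for comp in ("medial", "lateral"):
            assert np.allclose(
                lowest_vertex(coarse, comp), lowest_vertex(fine, comp), atol=1e-9
            )
        # area converges under refinement
        assert abs(fine.total_area() - coarse.total_area()) / coarse.total_area() < 0.005

    def test_compartment_sides_follow_ml_convention(self):
        inlay = make_tibial_inlay(InlaySpec())
        assert np.all(inlay.face_centroids[inlay.faces_in("medial")][:, 2] < 0)
        assert np.all(inlay.face_centroids[inlay.faces_in("lateral")][:, 2] > 0)

    def test_face_count_floor(self):
        inlay = make_tibial_inlay(InlaySpec())
        assert len(inlay.faces_in("medial")) >= 500
        assert len(inlay.faces_in("lateral")) >= 500

    @pytest.mark.parametrize(
        "bad", [dict(sagittal_radius_mm=-1.0), dict(mesh_resolution_mm=0.0)]
    )
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(GeometryError):
            make_tibial_inlay(InlaySpec(**bad))


class TestFemoralComponent:
    def test_equal_radii_mirror_symmetric(self):
        fem = make_femoral_component()
        mirrored = fem.vertices * np.array([1.0, 1.0, -1.0])
        a = np.sort(np.round(fem.vertices, 9).view([("", float)] * 3), axis=0)
        b = np.sort(np.round(mirrored, 9).view([("", float)] * 3), axis=0)
        assert np.array_equal(a, b)

    def test_single_radius_condyle_is_sphere_patch(self):
        fem = make_femoral_component(
            condyle_radii=(30.0,), coronal_radius=30.0, condyle_spacing=44.0
        )
        for comp, z_c in (("medial", -22.0), ("lateral", 22.0)):
            idx = fem.faces_in(comp)
            verts = fem.vertices[np.unique(fem.faces[idx])]
            r = np.linalg.norm(verts - np.array([0.0, 0.0, z_c]), axis=1)
            assert np.allclose(r, 30.0, atol=1e-9)

    def test_trochlear_groove_sulcus_recessed(self):
        fem = make_femoral_component()
        troch = fem.face_centroids[fem.faces_in("patellar")]
        # proximal part of the groove, away from the distal taper
        sel = troch[:, 0] > 20.0
        sulcus = troch[sel & (np.abs(troch[:, 2]) < 2.0)]
        facets = troch[sel & (np.abs(troch[:, 2]) > 8.0)]
        r_sulcus = np.linalg.norm(sulcus[:, :2], axis=1).mean()
        r_facets = np.linalg.norm(facets[:, :2], axis=1).mean()
        assert r_facets > r_sulcus + 1.0  # facets stand proud of the sulcus

    def test_nonmonotone_radii_rejected(self):
        with pytest.raises(GeometryError):
            make_femoral_component(condyle_radii=(30.0, 35.0))
        with pytest.raises(GeometryError):
            make_femoral_component(condyle_radii=(30.0, 15.0), coronal_radius=20.0)


class TestPatellarButton:
    def test_apex_on_axis(self):
        b = make_patellar_button(radius=13.0, thickness=8.0)
        apex = b.vertices[np.argmax(b.vertices[:, 2])]
        assert np.allclose(apex, [0.0, 0.0, 8.0], atol=1e-12)

    def test_dome_area_below_hemisphere_bound(self):
        b = make_patellar_button(radius=13.0, thickness=8.0)
        assert b.total_area() <= 2 * np.pi * 13.0**2

    def test_refinement_halves_max_edge(self):
        coarse = make_patellar_button(resolution=1.5)
        fine = make_patellar_button(resolution=0.75)
        assert fine.max_edge_length() < 0.75 * coarse.max_edge_length()

    def test_thickness_above_radius_rejected(self):
        with pytest.raises(GeometryError):
            make_patellar_button(radius=5.0, thickness=6.0)


class TestMeshIO:
    @pytest.mark.parametrize("fmt", ["stl", "obj"])
    def test_round_trip_preserves_vertices(self, tmp_path, fmt):
        inlay = make_tibial_inlay(InlaySpec())
        path = export_mesh(inlay, tmp_path / f"inlay.{fmt}")
        back = load_mesh(path)
        a = np.sort(inlay.vertices[inlay.faces].reshape(-1, 3), axis=0)
        b = np.sort(back.vertices[back.faces].reshape(-1, 3), axis=0)
        assert np.allclose(a, b, atol=1e-6)

    def test_stl_and_obj_exports_agree(self, tmp_path):
        inlay = make_tibial_inlay(InlaySpec())
        stl = load_mesh(export_mesh(inlay, tmp_path / "m.stl"))
        obj = load_mesh(export_mesh(inlay, tmp_path / "m.obj"))
        a = np.sort(stl.vertices[stl.faces].reshape(-1, 3), axis=0)
        b = np.sort(obj.vertices[obj.faces].reshape(-1, 3), axis=0)
        assert np.allclose(a, b, atol=1e-6)

    def test_empty_mesh_rejected(self):
        with pytest.raises(GeometryError):
            TriSurface(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))

    def test_unknown_format_rejected(self, tmp_path):
        inlay = make_tibial_inlay(InlaySpec())
        with pytest.raises(GeometryError):
            export_mesh(inlay, tmp_path / "m.ply")


class TestSurfaceInvariants:
    @pytest.mark.parametrize(
        "builder",
        [
            lambda: make_tibial_inlay(InlaySpec()),
            make_femoral_component,
            make_patellar_button,
            lambda: make_plane_patch(10.0, 1.5),
            lambda: make_spherical_dish(25.0, 12.0, 1.5),
        ],
    )
    def test_areas_positive_normals_unit(self, builder):
        s = builder()
        assert np.all(s.face_areas > 0)
        assert np.allclose(np.linalg.norm(s.face_normals, axis=1), 1.0, atol=1e-12)
        assert np.all(np.isfinite(s.vertices))
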