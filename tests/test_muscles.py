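import numpy as np
import pytest

from kneemech.frames import DEG, KneePose
from kneemech.muscles import (
    MuscleActuator,
    MuscleError,
    default_muscles,
    moment_arm,
    muscle_generalized_forces,
    musculotendon_length,
)
from kneemech.pathgeom import WrapCylinder


def straight(p_fem, p_tib, fmax=1000.0):
    return MuscleActuator("m", [("femur", p_fem), ("tibia", p_tib)], fmax)


class TestLength:
    def test_two_points_euclidean(self):
        m = straight((0.0, 10.0, 0.0), (0.0, -20.0, 0.0))
        assert np.isclose(musculotendon_length(m, KneePose()), 30.0, rtol=1e-12)

    def test_collinear_via_point_no_change(self):
        m2 = MuscleActuator(
            "m",
            [
                ("femur", (0.0, 10.0, 0.0)),
                ("tibia", (0.0, -5.0, 0.0)),
                ("tibia", (0.0, -20.0, 0.0)),
            ],
            1000.0,
        )
        assert np.isclose(musculotendon_length(m2, KneePose()), 30.0, rtol=1e-12)

    def test_wrap_matches_tangent_arc_closed_form(self):
        cyl = WrapCylinder(point=(0.0, 0.0, 0.0), axis=(0.0, 0.0, 1.0), radius=2.0, body="tibia")
        m = MuscleActuator(
            "m", [("tibia", (6.0, 0.0, 0.0)), ("tibia", (-6.0, 0.0, 0.0))], 500.0, wrap=cyl
        )
        expected = 2 * np.sqrt(32.0) + 2.0 * (np.pi - 2 * np.arccos(2.0 / 6.0))
        assert np.isclose(musculotendon_length(m, KneePose()), expected, rtol=1e-12)


class TestMomentArm:
    def test_hinge_perpendicular_distance(self):
        r = 20.0
        m = straight((r, 50.0, 0.0), (r, -50.0, 0.0))
        arm = moment_arm(m, KneePose(), "tf_flexion")
        # anterior path: extensor, so the flexion moment arm is -r
        assert abs(abs(arm) - r) < 1e-4 * r
        assert arm < 0

    def test_path_through_axis_zero_arm(self):
        m = straight((0.0, 50.0, 5.0), (0.0, -50.0, 5.0))
        assert abs(moment_arm(m, KneePose(), "tf_flexion")) < 1e-6

    def test_sign_flips_across_axis(self):
        ant = straight((15.0, 50.0, 0.0), (15.0, -50.0, 0.0))
        post = straight((-15.0, 50.0, 0.0), (-15.0, -50.0, 0.0))
        a1 = moment_arm(ant, KneePose(), "tf_flexion")
        a2 = moment_arm(post, KneePose(), "tf_flexion")
        assert np.isclose(a1, -a2, rtol=1e-6)


class TestGeneralizedForces:
    def test_zero_activation_zero_force(self):
        ms = default_muscles()
        out = muscle_generalized_forces(ms, np.zeros(len(ms)), KneePose())
        assert np.allclose(out, 0.0)

    def test_single_muscle_full_activation(self):
        m = straight((15.0, 50.0, 0.0), (15.0, -50.0, 0.0), fmax=800.0)
        out = muscle_generalized_forces([m], np.array([1.0]), KneePose())
        assert np.isclose(out[0], 800.0 * moment_arm(m, KneePose(), "tf_flexion"), rtol=1e-9)

    def test_superposition(self):
        m1 = straight((15.0, 50.0, 0.0), (15.0, -50.0, 0.0), fmax=800.0)
        m2 = straight((-20.0, 40.0, 5.0), (-18.0, -60.0, 8.0), fmax=400.0)
        pose = KneePose()
        a = np.array([0.4, 0.7])
        both = muscle_generalized_forces([m1, m2], a, pose)
        solo = muscle_generalized_forces([m1], a[:1], pose) + muscle_generalized_forces(
            [m2], a[1:], pose
        )
        assert np.allclose(both, solo, rtol=1e-12)

    def test_activation_bounds_enforced(self):
        m = straight((15.0, 50.0, 0.0), (15.0, -50.0, 0.0))
        with pytest.raises(MuscleError):
            muscle_generalized_forces([m], np.array([1.5]), KneePose())

    def test_tendon_excursion_consistency(self):
        """Generalised force equals the negative energy gradient for
        wrap-free paths at constant tension."""
        ms = [
            straight((15.0, 50.0, 0.0), (10.0, -50.0, 5.0), fmax=900.0),
            straight((-20.0, 40.0, -8.0), (-18.0, -60.0, -3.0), fmax=500.0),
        ]
        a = np.array([0.6, 0.3])
        q = np.array([20.0, 2.0, -3.0, 1.0, -0.5, 0.8, 0, 0, 0, 40.0, -15.0, 0.0])
        pose = KneePose(q)
        out = muscle_generalized_forces(ms, a, pose)
        h = 1e-5
        for i, name in enumerate(
            ("tf_flexion", "tf_adduction", "tf_rotation", "tf_ap", "tf_si", "tf_ml")
        ):
            qp, qm = q.copy(), q.copy()
            qp[i] += h
            qm[i] -= h
            ep = sum(ai * m.max_isometric_force * musculotendon_length(m, KneePose(qp)) for ai, m in zip(a, ms))
            em = sum(ai * m.max_isometric_force * musculotendon_length(m, KneePose(qm)) for ai, m in zip(a, ms))
            grad = (ep - em) / (2 * h)
            if i < 3:
                grad /= DEG
            assert abs(out[i] + grad) <= 1e-6 * max(1.0, abs(grad))


class TestDefaults:
    def test_twelve_units_with_positive_fmax(self):
        ms = default_muscles()
        assert len(ms) == 12
        assert all(m.max_isometric_force > 0 for m in ms)

    def test_quadriceps_extend_flexors_flex(self, default_model):
        pose = default_model.reference_pose.replace(tf_flexion=20.0)
        for m in default_muscles():
            arm = moment_arm(m, pose, "tf_flexion")
            if m.name.startswith(("vas", "rect")):
                assert arm < 0, m.name  # extensors
            if m.name in ("bifemlh", "semimem", "semiten", "gas_med", "gas_lat"):
                assert arm > 0, m.name  # flexors
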