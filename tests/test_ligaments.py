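import numpy as np
import pytest

from kneemech.ligaments import (
    PRESTRAIN_DELTAS,
    LigamentBundle,
    LigamentError,
    PrestrainScenario,
    default_ligaments,
    fiber_force,
)


class TestFiberLaw:
    def test_slack_fiber_carries_no_force(self):
        assert fiber_force(37.9, 38.0, 180.0, 0.03) == 0.0
        assert fiber_force(38.0, 38.0, 180.0, 0.03) == 0.0

    def test_linear_branch_plug_in(self):
        # k = 180 N/mm, L0 = 38 mm, eps_t = 0.03, L = 41 mm (linear branch)
        f = fiber_force(41.0, 38.0, 180.0, 0.03)
        assert np.isclose(f, 180.0 * (3.0 - 0.03 * 38.0), rtol=1e-12)  # 334.8 N

    def test_value_and_slope_continuous_at_transition(self):
        k, L0, et = 180.0, 38.0, 0.03
        Lt = L0 * (1 + 2 * et)
        below = fiber_force(Lt - 1e-9, L0, k, et)
        above = fiber_force(Lt + 1e-9, L0, k, et)
        assert abs(above - below) < 1e-5  # value continuous
        exact = k * et * L0
        assert abs(fiber_force(Lt, L0, k, et) - exact) < 1e-12
        h = 1e-7
        slope_below = (fiber_force(Lt, L0, k, et) - fiber_force(Lt - h, L0, k, et)) / h
        slope_above = (fiber_force(Lt + h, L0, k, et) - fiber_force(Lt, L0, k, et)) / h
        assert abs(slope_below - k) < 1e-3
        assert abs(slope_above - k) < 1e-3

    def test_monotone_nonnegative(self):
        L = np.linspace(30.0, 50.0, 200)
        f = fiber_force(L, 38.0, 180.0, 0.03)
        assert np.all(f >= 0)
        assert np.all(np.diff(f) >= 0)


class TestCalibration:
    def make_bundle(self, eps_ref):
        return LigamentBundle(
            "test",
            np.array([[0.0, 0.0, 0.0]]),
            np.array([[10.0, 0.0, 0.0]]),
            stiffness_n_per_mm=100.0,
            reference_strain=eps_ref,
        )

    def test_slack_length_arithmetic(self):
        b = self.make_bundle(0.02).calibrated(np.array([38.76]))
        assert np.isclose(b.slack_lengths[0], 38.0, rtol=1e-12)

    def test_zero_reference_strain_keeps_length(self):
        b = self.make_bundle(0.0).calibrated(np.array([41.5]))
        assert b.slack_lengths[0] == 41.5

    def test_negative_reference_strain_slack_at_reference(self):
        b = self.make_bundle(-0.08).calibrated(np.array([40.0]))
        assert b.slack_lengths[0] > 40.0
        assert b.forces(np.array([40.0]))[0] == 0.0

    def test_round_trip_strain_exact(self):
        for eps in (-0.08, -0.02, 0.0, 0.02, 0.12):
            b = self.make_bundle(eps).calibrated(np.array([40.0]))
            assert abs(b.strains(np.array([40.0]))[0] - eps) < 1e-9

    def test_reference_strain_bound(self):
        with pytest.raises(LigamentError):
            self.make_bundle(-1.0)


class TestPrestrainScenario:
    def test_grid_and_absolute_strain(self):
        assert PRESTRAIN_DELTAS == tuple(range(-10, 11, 2))
        assert np.isclose(PrestrainScenario(-10).pcl_reference_strain, -0.08)
        assert np.isclose(PrestrainScenario(10).pcl_reference_strain, 0.12)

    def test_off_grid_delta_rejected(self):
        with pytest.raises(LigamentError):
            PrestrainScenario(3)
        with pytest.raises(LigamentError):
            PrestrainScenario(0, "medium")


class TestModelCalibration:
    def test_all_bundles_round_trip_at_reference(self, default_model):
        lig, _ = default_model.element_lengths(default_model.reference_pose.q[None, :])
        i = 0
        for b in default_model.ligaments:
            strains = b.strains(lig[0][i : i + b.n_fibers])
            assert np.max(np.abs(strains - b.reference_strain)) < 1e-9
            i += b.n_fibers

    @pytest.mark.parametrize("delta", PRESTRAIN_DELTAS)
    def test_prestrain_recalibration_round_trip(self, default_model, delta):
        m = default_model.apply_prestrain(PrestrainScenario(delta, "standard"))
        lig, _ = m.element_lengths(m.reference_pose.q[None, :])
        i = 0
        for b in m.ligaments:
            target = (
                PrestrainScenario(delta).pcl_reference_strain
                if b.name in ("aPCL", "pPCL")
                else b.reference_strain
            )
            strains = b.strains(lig[0][i : i + b.n_fibers])
            assert np.max(np.abs(strains - target)) < 1e-9
            i += b.n_fibers

    def test_zero_delta_scenario_is_identity(self, default_model):
        m = default_model.apply_prestrain(PrestrainScenario(0, "standard"))
        for a, b in zip(default_model.ligaments, m.ligaments):
            assert np.array_equal(a.slack_lengths, b.slack_lengths)
            assert a.reference_strain == b.reference_strain

    def test_non_pcl_bundles_untouched(self, default_model):
        m = default_model.apply_prestrain(PrestrainScenario(8, "standard"))
        for a, b in zip(default_model.ligaments, m.ligaments):
            if a.name not in ("aPCL", "pPCL"):
                assert np.array_equal(a.slack_lengths, b.slack_lengths)

    def test_negative_delta_unloads_pcl_at_reference(self, default_model):
        m = default_model.apply_prestrain(PrestrainScenario(-10, "standard"))
        lig, _ = m.element_lengths(m.reference_pose.q[None, :])
        forces = m.bundle_forces(lig[0])
        assert forces["aPCL"] == 0.0 and forces["pPCL"] == 0.0

    def test_pcl_force_monotone_in_delta_at_fixed_poses(self, default_model):
        """At any frozen pose the PCL tension never decreases with delta."""
        rng = np.random.default_rng(42)
        poses = [default_model.reference_pose.q.copy()]
        for _ in range(5):
            q = default_model.reference_pose.q.copy()
            q[0] = rng.uniform(0, 60)
            q[3] += rng.uniform(-3, 3)
            q[4] += rng.uniform(-0.2, 0.2)
            poses.append(q)
        for q in poses:
            prev = -np.inf
            for delta in PRESTRAIN_DELTAS:
                m = default_model.apply_prestrain(PrestrainScenario(delta, "standard"))
                lig, _ = m.element_lengths(q[None, :])
                f = m.bundle_forces(lig[0])
                pcl = f["aPCL"] + f["pPCL"]
                assert pcl >= prev - 1e-9
                prev = pcl


class TestGeneralizedForces:
    def _no_contact_model(self, default_model, bundles):
        import copy

        m = copy.copy(default_model)
        m.ligaments = bundles
        m.patella_weight_n = 0.0
        m._build_path_table()
        return m

    def test_slack_bundle_no_generalized_force(self, default_model):
        b = LigamentBundle(
            "slack",
            np.array([[0.0, 0.0, 0.0]]),
            np.array([[0.0, -40.0, 0.0]]),
            stiffness_n_per_mm=100.0,
            reference_strain=-0.5,
        ).calibrated(np.array([40.0]))
        m = self._no_contact_model(default_model, [b])
        q = default_model.reference_pose.q.copy()
        q[4] += 30.0  # lift the femur out of contact
        Q, _, _ = m.residuals_batch(q[None, :], np.zeros(3), np.zeros(3))
        assert np.allclose(Q[0], 0.0, atol=1e-9)

    def test_taut_ap_fiber_loads_only_ap(self, default_model):
        b = LigamentBundle(
            "apfiber",
            np.array([[5.0, 0.0, 0.0]]),
            np.array([[-45.0, 30.0, 0.0]]),
            stiffness_n_per_mm=100.0,
            reference_strain=0.05,
        ).calibrated(np.array([50.0]))
        m = self._no_contact_model(default_model, [b])
        q = np.zeros(12)
        q[4] = 30.0  # femur lifted: attachment at (5, 30, 0), fiber along +X
        q[10] = 200.0  # patella far away too
        Q, _, _ = m.residuals_batch(q[None, :], np.zeros(3), np.zeros(3))
        ap = Q[0][3]
        # rotational entries pick up the moment of the AP force about the
        # origin; translational cross-terms must vanish
        assert abs(ap) > 1.0
        assert abs(Q[0][4]) < 1e-9 * abs(ap) and abs(Q[0][5]) < 1e-9 * abs(ap)

    def test_fd_gradient_matches_analytic_for_straight_fiber(self, default_model):
        q = default_model.reference_pose.q.copy()
        lig0, _, dlig, _ = default_model.perturbed_lengths(q)
        # analytic directional derivative w.r.t. AP translation of the femur:
        # d|P_f - P_t|/d(ap) = x-component of the unit fiber vector
        from kneemech.frames import body_transform

        Tf = body_transform(q[:6])
        i = 0
        for b in default_model.ligaments:
            for j in range(b.n_fibers):
                if b.proximal_body == "femur" and b.distal_body == "tibia":
                    pf = Tf[:3, :3] @ b.proximal_points[j] + Tf[:3, 3]
                    pt = b.distal_points[j]
                    unit = (pf - pt) / np.linalg.norm(pf - pt)
                    assert abs(dlig[3, i] - unit[0]) < 1e-6
                i += 1
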