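import numpy as np
import pytest

from kneemech.frames import KneePose, SECONDARY_IDX
from kneemech.solver import (
    InfeasibleActivationError,
    assemble_generalized_forces,
    solve_activations,
    solve_timestep,
)


class TestActivationQP:
    def test_zero_demand_all_zero(self):
        a, obj, rep = solve_activations(np.array([500.0, -300.0, 800.0]), 0.0)
        assert np.allclose(a, 0.0) and obj == 0.0

    def test_single_extensor_closed_form(self):
        fmax_r = 40000.0
        M = 12000.0
        a, obj, _ = solve_activations(np.array([fmax_r]), M)
        assert np.isclose(a[0], M / fmax_r, rtol=1e-12)

    def test_two_equal_synergists_split_evenly(self):
        c = np.array([30000.0, 30000.0])
        M = 18000.0
        a, obj, _ = solve_activations(c, M)
        assert np.allclose(a, M / (2 * 30000.0), rtol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 4))
        c = rng.normal(0.0, 2e4, n)
        lo, hi = np.minimum(c, 0).sum(), np.maximum(c, 0).sum()
        M = float(rng.uniform(0.8 * lo, 0.8 * hi))
        a, obj, _ = solve_activations(c, M)
        # grid oracle: best objective among near-feasible grid points can be
        # slightly optimistic (they relax the equality); the QP optimum must
        # not beat a strictly feasible refined grid candidate by > 1e-3
        n_grid = 81
        axes = [np.linspace(0.0, 1.0, n_grid)] * n
        A = np.stack([g.ravel() for g in np.meshgrid(*axes, indexing="ij")], axis=1)
        cc = float(c @ c)
        proj = A + ((M - A @ c) / cc)[:, None] * c[None, :]
        ok = np.all((proj >= 0) & (proj <= 1), axis=1)
        assert ok.any()
        best = float((proj[ok] ** 2).sum(axis=1).min())
        assert obj <= best + 1e-3
        assert abs(c @ a - M) < 1e-6 * max(1.0, abs(M))

    @pytest.mark.parametrize("seed", range(100))
    def test_kkt_conditions_on_random_instances(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(1, 13))
        c = rng.normal(0.0, 3e4, n)
        lo, hi = np.minimum(c, 0).sum(), np.maximum(c, 0).sum()
        M = float(rng.uniform(lo, hi))
        a, obj, rep = solve_activations(c, M)
        lam = rep["equality_multiplier"]
        # stationarity + complementary slackness: 2 a_i = lam c_i - mu0 + mu1
        for i in range(n):
            if 1e-9 < a[i] < 1 - 1e-9:
                assert abs(2 * a[i] - lam * c[i]) < 1e-8
            elif a[i] <= 1e-9:
                assert lam * c[i] <= 1e-8  # mu0 >= 0
            else:
                assert lam * c[i] >= 2.0 - 1e-8  # mu1 >= 0
        assert abs(c @ a - M) < 1e-8 * max(1.0, abs(M))
        assert np.all(a >= -1e-12) and np.all(a <= 1 + 1e-12)
        assert abs(obj - float(a @ a)) < 1e-10

    def test_infeasible_demand_reports_shortfall(self):
        with pytest.raises(InfeasibleActivationError) as err:
            solve_activations(np.array([1000.0, 2000.0]), 5000.0)
        assert "attainable" in str(err.value)

    def test_clamped_mode_saturates(self):
        a, obj, rep = solve_activations(
            np.array([1000.0, 2000.0]), 5000.0, clamp_infeasible=True
        )
        assert np.allclose(a, 1.0)
        assert rep["clamped_torque"] == 3000.0


class TestAssembly:
    def test_zero_sources_zero_forces(self, default_model):
        import copy

        m = copy.copy(default_model)
        m.ligaments = []
        m._build_path_table()
        m.patella_weight_n = 0.0
        q = default_model.reference_pose.q.copy()
        q[4] += 25.0   # femur clear of the inlay
        q[9] += 40.0   # patella clear of the (lifted) femur
        q[10] += 25.0
        Q = assemble_generalized_forces(
            m, KneePose(q), np.zeros(len(m.muscles)), (np.zeros(3), np.zeros(3))
        )
        assert np.allclose(Q, 0.0, atol=1e-9)

    def test_linear_in_sources(self, default_model):
        pose = default_model.reference_pose
        loads = (np.array([10.0, -50.0, 5.0]), np.array([1000.0, 0.0, -2000.0]))
        zero = (np.zeros(3), np.zeros(3))
        a0 = np.zeros(len(default_model.muscles))
        q_ext = assemble_generalized_forces(default_model, pose, a0, loads)
        q_zero = assemble_generalized_forces(default_model, pose, a0, zero)
        # external contribution adds linearly on the femoral coordinates
        loads2 = (2 * loads[0], 2 * loads[1])
        q_ext2 = assemble_generalized_forces(default_model, pose, a0, loads2)
        assert np.allclose(q_ext2 - q_zero, 2 * (q_ext - q_zero), rtol=1e-9)

    def test_pure_superior_force_loads_si_only(self, default_model):
        import copy

        m = copy.copy(default_model)
        m.ligaments = []
        m._build_path_table()
        m.patella_weight_n = 0.0
        q = default_model.reference_pose.q.copy()
        q[4] += 25.0
        q[9] += 40.0
        q[10] += 25.0
        Q = assemble_generalized_forces(
            m, KneePose(q), np.zeros(len(m.muscles)), (np.array([0.0, 100.0, 0.0]), np.zeros(3))
        )
        assert np.isclose(Q[4], 100.0, rtol=1e-12)
        assert abs(Q[3]) < 1e-9 and abs(Q[5]) < 1e-9


class TestTimestep:
    def test_passive_equilibrium_converges(self, default_model):
        pose, a, (tf, pf), diag, J, info = solve_timestep(
            default_model, 0.0, (np.zeros(3), np.zeros(3)), default_model.reference_pose
        )
        assert diag.converged
        assert np.max(np.abs(diag.residuals[[0, 1, 5, 6, 7]])) <= 50.0
        assert np.max(np.abs(diag.residuals[[2, 3, 4, 8, 9, 10]])) <= 0.5
        assert np.all(a >= 0) and np.all(a <= 1)

    def test_warm_start_insensitivity(self, default_model):
        """Nearby warm starts land on the same equilibrium."""
        load = (np.array([0.0, -500.0, 0.0]), np.array([-5000.0, 0.0, 15000.0]))
        p0, *_ = solve_timestep(default_model, 10.0, load, default_model.reference_pose)
        q1 = p0.q.copy()
        q1[3] += 0.8
        q1[1] += 0.8
        p1, a1, c1, d1, J1, i1 = solve_timestep(default_model, 10.0, load, KneePose(q1))
        q2 = p0.q.copy()
        q2[3] -= 0.8
        q2[4] += 0.05
        p2, a2, c2, d2, J2, i2 = solve_timestep(default_model, 10.0, load, KneePose(q2))
        assert d1.converged and d2.converged
        assert np.allclose(p1.q[3:6], p2.q[3:6], atol=0.05)
        assert np.allclose(p1.q[1:3], p2.q[1:3], atol=0.2)

    def test_objective_matches_activations(self, default_model):
        load = (np.array([0.0, -500.0, 0.0]), np.array([0.0, 0.0, 20000.0]))
        pose, a, _, diag, *_ = solve_timestep(
            default_model, 15.0, load, default_model.reference_pose
        )
        assert abs(diag.objective - float(a @ a)) < 1e-10

    def test_nonfinite_load_rejected(self, default_model):
        from kneemech.solver import SolverError

        with pytest.raises(SolverError):
            solve_timestep(
                default_model,
                10.0,
                (np.array([np.nan, 0, 0]), np.zeros(3)),
                default_model.reference_pose,
            )
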