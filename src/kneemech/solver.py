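"""Concurrent activation / secondary-kinematics equilibrium solver.

Per gait frame the primary flexion angle and the external intersegmental
load are prescribed; the solver finds the eleven secondary coordinates
(five tibiofemoral + six patellofemoral) and the muscle activations such
that

* the net generalised force on every secondary coordinate is zero (within
  0.5 N for translations, 50 N*mm for rotations), and
* the muscles balance the net flexion torque while minimising the sum of
  squared activations subject to 0 <= a <= 1 (a strictly convex QP with a
  single equality constraint, solved exactly by an active-set method).

The outer iteration is a damped Newton method on the 11-coordinate
residual with a finite-difference Jacobian, Broyden rank-one updates, step
capping and backtracking; the Jacobian is carried across frames (the gait
is solved sequentially with warm starts).  Everything is deterministic:
fixed coordinate ordering, no randomisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frames import COORD_NAMES, KneePose, SECONDARY_IDX
from .ligaments import PrestrainScenario


class SolverError(RuntimeError):
    pass


class InfeasibleActivationError(SolverError):
    def __init__(self, demand: float, attainable: tuple):
        self.demand = demand
        self.attainable = attainable
        super().__init__(
            f"required flexion torque {demand:.1f} N*mm outside the attainable "
            f"muscle range [{attainable[0]:.1f}, {attainable[1]:.1f}] N*mm "
            f"(shortfall {min(abs(demand - attainable[0]), abs(demand - attainable[1])):.1f})"
        )


# ----------------------------------------------------------------------
# muscle redundancy QP
# ----------------------------------------------------------------------

def solve_activations(
    coefficients: np.ndarray,
    required_torque: float,
    clamp_infeasible: bool = False,
):
    """Minimise sum of squared activations subject to the torque balance.

    ``coefficients[m] = F_max,m * r_m`` (N*mm of flexion torque at full
    activation); the constraint is ``c . a = required_torque`` with
    ``0 <= a <= 1``.  The strictly convex QP has the closed-form KKT
    solution ``a_i = clip(lambda * c_i / 2, 0, 1)`` where the multiplier
    ``lambda`` solves the monotone piecewise-linear equation
    ``sum c_i a_i(lambda) = M``; it is found exactly from the breakpoint
    structure (no iteration, no cycling).  Returns
    ``(activations, objective, report)``.
    """
    c = np.asarray(coefficients, dtype=float)
    lo = float(np.minimum(c, 0.0).sum())
    hi = float(np.maximum(c, 0.0).sum())
    M = float(required_torque)
    feasible = lo - 1e-9 <= M <= hi + 1e-9
    if not feasible:
        if not clamp_infeasible:
            raise InfeasibleActivationError(M, (lo, hi))
        M = float(np.clip(M, lo, hi))

    def a_of(lam: float) -> np.ndarray:
        return np.clip(lam * c / 2.0, 0.0, 1.0)

    nz = np.abs(c) > 0.0
    if not np.any(nz) or M == 0.0:
        lam = 0.0
    else:
        # g(lam) = sum c_i a_i(lam) is piecewise linear and nondecreasing;
        # breakpoints where each muscle saturates: lam = 2 / |c_i| * sign...
        if M > 0.0:
            bps = np.unique(2.0 / c[c > 0.0]) if np.any(c > 0.0) else np.array([])
        else:
            bps = -np.unique(-2.0 / c[c < 0.0]) if np.any(c < 0.0) else np.array([])
            bps = np.sort(bps)[::-1]
        lam = 0.0
        g_prev = 0.0
        lam_prev = 0.0
        solved = False
        for bp in bps:
            g_bp = float(c @ a_of(bp))
            if (M > 0.0 and g_bp >= M) or (M < 0.0 and g_bp <= M):
                # crossing within (lam_prev, bp]: linear there
                slope = (g_bp - g_prev) / (bp - lam_prev)
                lam = lam_prev + (M - g_prev) / slope
                solved = True
                break
            lam_prev, g_prev = bp, g_bp
        if not solved:
            # all same-sign muscles saturated short of |M| (clamped case)
            lam = bps[-1] if len(bps) else 0.0
    a = a_of(lam)
    report = {
        "at_upper_bound": np.flatnonzero(a >= 1.0).tolist(),
        "at_lower_bound": np.flatnonzero((a <= 0.0) & (np.abs(c) > 0.0)).tolist(),
        "equality_multiplier": float(lam),
        "clamped_torque": M if not feasible else None,
    }
    return a, float((a * a).sum()), report


# ----------------------------------------------------------------------
# assembly
# ----------------------------------------------------------------------

def assemble_generalized_forces(model, pose, activations, external_loads):
    """Net generalised force on all 12 coordinates (N / N*mm).

    ``external_loads = (force_n, moment_nmm)`` applied to the femur at the
    knee centre in the tibial frame.
    """
    q = pose.q if isinstance(pose, KneePose) else np.asarray(pose, float)
    f_ext, m_ext = external_loads
    Q, _ = model.generalized_forces(q, np.asarray(activations, float), f_ext, m_ext)
    return Q


@dataclass
class SolveDiagnostics:
    residuals: np.ndarray
    iterations: int
    converged: bool
    objective: float
    activation_report: dict = field(default_factory=dict)


def _residual(model, q, f_ext, m_ext, flexion_idx=0):
    """Secondary-coordinate residual with concurrently solved activations.

    Single-pose, detailed variant: also returns the contact results and
    fiber forces for reporting.
    """
    Q_zero, info = model.generalized_forces(
        q, np.zeros(len(model.muscles)), f_ext, m_ext
    )
    fmax = np.array([m.max_isometric_force for m in model.muscles])
    c = fmax * info["moment_arms"][:, flexion_idx]
    demand = -Q_zero[flexion_idx]
    a, obj, report = solve_activations(c, demand, clamp_infeasible=True)
    Q = Q_zero + (a * fmax) @ info["moment_arms"]
    r = Q[list(SECONDARY_IDX)]
    return r, a, obj, report, info, Q


def _residual_batch(model, Qs, f_ext, m_ext, flexion_idx=0):
    """Vectorised residuals for a pose batch (no per-face detail)."""
    Qs = np.atleast_2d(Qs)
    Q_zero, arms, _fib = model.residuals_batch(Qs, f_ext, m_ext)
    fmax = np.array([m.max_isometric_force for m in model.muscles])
    P = len(Qs)
    r = np.empty((P, 11))
    acts = np.empty((P, len(fmax)))
    objs = np.empty(P)
    sec = list(SECONDARY_IDX)
    for p in range(P):
        c = fmax * arms[p, :, flexion_idx]
        demand = -Q_zero[p, flexion_idx]
        a, obj, _rep = solve_activations(c, demand, clamp_infeasible=True)
        Q = Q_zero[p] + (a * fmax) @ arms[p]
        r[p] = Q[sec]
        acts[p] = a
        objs[p] = obj
    return r, acts, objs


_SCALE = np.array([50.0, 50.0, 0.5, 0.5, 0.5, 50.0, 50.0, 50.0, 0.5, 0.5, 0.5])

#: positions of the translational coordinates within the secondary vector
_TRANS = np.array([2, 3, 4, 8, 9, 10])

#: the solver drives residuals to this fraction of the reported tolerance,
#: so an independent re-check at the full tolerance has margin
_SAFETY = 0.9


def _scale_vector(settings) -> np.ndarray:
    rot = settings.rotation_tol_nmm
    tr = settings.translation_tol_n
    return np.array([rot, rot, tr, tr, tr, rot, rot, rot, tr, tr, tr])


def _scaled_norm(r: np.ndarray, scale=None) -> float:
    return float(np.max(np.abs(r) / (_SCALE if scale is None else scale)))


_ROT = np.array([0, 1, 5, 6, 7])


def _nested_block_solve(model, q, r, f_ext, m_ext, scale, fd_steps, settings, budget=25):
    """Fallback: alternate a translation-only Newton (fresh sub-Jacobian,
    backtracked) with a Schur-complement step on the five rotations.

    Robust against the stiff/soft two-timescale structure that occasionally
    defeats the joint Levenberg-Marquardt iteration.
    """
    sec = list(SECONDARY_IDX)
    trans_coords = [sec[t] for t in _TRANS]
    rot_coords = [sec[t] for t in _ROT]
    tol_t = 0.9 * settings.translation_tol_n * _SAFETY

    def eval_r(qq):
        rb, ab, ob = _residual_batch(model, qq[None, :], f_ext, m_ext)
        return rb[0], ab[0], float(ob[0])

    def trans_jacobian(qq, rr):
        Qs = np.tile(qq, (6, 1))
        for j, idx in enumerate(trans_coords):
            Qs[j, idx] += fd_steps[_TRANS[j]]
        rb, _, _ = _residual_batch(model, Qs, f_ext, m_ext)
        return (rb[:, _TRANS] - rr[_TRANS][None, :]).T / fd_steps[_TRANS][None, :]

    def solve_translations(qq, rr):
        Jtt = None
        for _ in range(14):
            if np.max(np.abs(rr[_TRANS])) <= tol_t:
                return qq, rr, True
            if Jtt is None:
                Jtt = trans_jacobian(qq, rr)
            try:
                dqt = np.linalg.solve(Jtt, -rr[_TRANS])
            except np.linalg.LinAlgError:
                dqt = np.linalg.lstsq(Jtt, -rr[_TRANS], rcond=None)[0]
            nrm = np.max(np.abs(dqt))
            if nrm > 0.25:
                dqt *= 0.25 / nrm
            cur = np.max(np.abs(rr[_TRANS]))
            ok = False
            for _bt in range(5):
                q_c = qq.copy()
                for j, idx in enumerate(trans_coords):
                    q_c[idx] += dqt[j]
                r_c = eval_r(q_c)[0]
                if np.max(np.abs(r_c[_TRANS])) < cur:
                    qq, rr = q_c, r_c
                    ok = True
                    break
                dqt *= 0.25
            if not ok:
                if Jtt is None:
                    return qq, rr, False
                Jtt = None  # refresh once, then give up next round
        return qq, rr, np.max(np.abs(rr[_TRANS])) <= tol_t

    a = obj = None
    q, r, _ = solve_translations(q, r)
    for outer in range(budget):
        if _scaled_norm(r, scale) <= 1.0:
            break
        # full finite-difference Jacobian for the Schur step
        Qs = np.tile(q, (11, 1))
        for j, idx in enumerate(sec):
            Qs[j, idx] += fd_steps[j]
        rb, _, _ = _residual_batch(model, Qs, f_ext, m_ext)
        J = (rb - r[None, :]).T / fd_steps[None, :]
        Jtt = J[np.ix_(_TRANS, _TRANS)]
        Jtr = J[np.ix_(_TRANS, _ROT)]
        Jrt = J[np.ix_(_ROT, _TRANS)]
        Jrr = J[np.ix_(_ROT, _ROT)]
        try:
            X = np.linalg.solve(Jtt, Jtr)
            y = np.linalg.solve(Jtt, r[_TRANS])
        except np.linalg.LinAlgError:
            X = np.linalg.lstsq(Jtt, Jtr, rcond=None)[0]
            y = np.linalg.lstsq(Jtt, r[_TRANS], rcond=None)[0]
        S = Jrr - Jrt @ X
        rhs = r[_ROT] - Jrt @ y
        try:
            drot = np.linalg.solve(S, -rhs)
        except np.linalg.LinAlgError:
            drot = np.linalg.lstsq(S, -rhs, rcond=None)[0]
        nrm = np.max(np.abs(drot))
        if nrm > 1.0:
            drot *= 1.0 / nrm
        improved = False
        cur = _scaled_norm(r, scale)
        for _bt in range(6):
            q_t = q.copy()
            for j, idx in enumerate(rot_coords):
                q_t[idx] += drot[j]
            r_t, _, _ = eval_r(q_t)
            q_t, r_t, _ = solve_translations(q_t, r_t)
            if _scaled_norm(r_t, scale) < cur:
                q, r = q_t, r_t
                improved = True
                break
            drot *= 0.4
        if not improved:
            break
    return q, r


def solve_timestep(
    model,
    flexion_deg: float,
    external_loads,
    warm_start: KneePose,
    jacobian: np.ndarray | None = None,
):
    """Equilibrate the 11 secondary coordinates at one prescribed flexion.

    Returns ``(pose, activations, contact_results, diagnostics, jacobian)``;
    the Jacobian is returned for reuse by the next frame.
    """
    s = model.settings
    f_ext, m_ext = external_loads
    f_ext = np.asarray(f_ext, dtype=float)
    m_ext = np.asarray(m_ext, dtype=float)
    if not (np.all(np.isfinite(f_ext)) and np.all(np.isfinite(m_ext))):
        raise SolverError("external loads must be finite")

    q = warm_start.q.copy()
    q[0] = float(flexion_deg)
    sec = list(SECONDARY_IDX)
    scale = _scale_vector(s) * _SAFETY

    fd_steps = np.array(
        [s.fd_step_rotation_deg] * 2
        + [s.fd_step_translation_mm] * 3
        + [s.fd_step_rotation_deg] * 3
        + [s.fd_step_translation_mm] * 3
    )
    caps = np.array(
        [s.step_cap_rotation_deg] * 2
        + [s.step_cap_translation_mm] * 3
        + [s.step_cap_rotation_deg] * 3
        + [s.step_cap_translation_mm] * 3
    )
    caps[[3]] = min(caps[3], 0.25)  # SI rides the stiff contact direction

    def fd_jacobian(q0, r0):
        Qs = np.tile(q0, (11, 1))
        for j, idx in enumerate(sec):
            Qs[j, idx] += fd_steps[j]
        rb, _, _ = _residual_batch(model, Qs, f_ext, m_ext)
        return (rb - r0[None, :]).T / fd_steps[None, :]

    rb, ab, ob = _residual_batch(model, q[None, :], f_ext, m_ext)
    r, a, obj = rb[0], ab[0], float(ob[0])
    best = _scaled_norm(r, scale)
    J = None if jacobian is None else jacobian
    if best > 1.0:
        J = fd_jacobian(q, r)
    it = 0
    lam = 1e-3
    fresh = False
    updates_since_fresh = 0
    failed_fresh = 0
    while best > 1.0 and it < s.max_iterations:
        it += 1
        if J is None:
            J = fd_jacobian(q, r)
            fresh = True
            updates_since_fresh = 0
            lam = 1e-3
        # weighted Levenberg-Marquardt step on the scaled residual, with a
        # nested correction of the stiff (translational) coordinates: large
        # moves of the soft rotational coordinates perturb the contact
        # equilibrium at second order, so each trial point re-balances the
        # translations against the current Jacobian sub-block before the
        # merit comparison
        Jw = J / scale[:, None]
        rw = r / scale
        A = Jw.T @ Jw
        g = Jw.T @ rw
        D = np.diag(np.maximum(np.diag(A), 1e-12))
        Jtt = J[np.ix_(_TRANS, _TRANS)]
        accepted = False
        for _ in range(10):
            try:
                dq = np.linalg.solve(A + lam * D, -g)
            except np.linalg.LinAlgError:
                dq = np.linalg.lstsq(A + lam * D, -g, rcond=None)[0]
            over = np.max(np.abs(dq) / caps)
            if over > 1.0:
                dq = dq / over
            q_try = q.copy()
            q_try[sec] += dq
            rb, ab, ob = _residual_batch(model, q_try[None, :], f_ext, m_ext)
            r_try, a_t, obj_t = rb[0], ab[0], float(ob[0])
            for _inner in range(5):
                rt = r_try[_TRANS]
                cur = float(np.max(np.abs(rt)))
                if cur <= 0.9 * s.translation_tol_n * _SAFETY:
                    break
                try:
                    dqt = np.linalg.solve(Jtt, -rt)
                except np.linalg.LinAlgError:
                    break
                nrm = np.max(np.abs(dqt))
                if nrm > 0.4:
                    dqt *= 0.4 / nrm
                # backtrack the correction against contact-onset overshoot
                improved_inner = False
                for _bt in range(4):
                    q_c = q_try.copy()
                    for jj, tt in enumerate(_TRANS):
                        q_c[sec[tt]] += dqt[jj]
                    rb, ab2, ob2 = _residual_batch(model, q_c[None, :], f_ext, m_ext)
                    if float(np.max(np.abs(rb[0][_TRANS]))) < cur:
                        q_try, r_try, a_t, obj_t = q_c, rb[0], ab2[0], float(ob2[0])
                        improved_inner = True
                        break
                    dqt *= 0.25
                if not improved_inner:
                    break
            norm_try = _scaled_norm(r_try, scale)
            merit_try = float(np.sum((r_try / scale) ** 2))
            merit_cur = float(np.sum(rw**2))
            if norm_try < best or merit_try < merit_cur:
                dstep = q_try[sec] - q[sec]
                if float(dstep @ dstep) > 0.0:
                    J = J + np.outer(r_try - r - J @ dstep, dstep) / float(dstep @ dstep)
                    updates_since_fresh += 1
                q, r, a, obj = q_try, r_try, a_t, obj_t
                best = norm_try
                lam = max(lam / 3.0, 1e-7)
                accepted = True
                break
            lam *= 5.0
            if lam > 1e4 and not fresh:
                break
        if not accepted:
            if fresh:
                failed_fresh += 1
                if failed_fresh >= 2:
                    # the joint LM iteration is stuck: switch to the nested
                    # translations-inner / rotations-outer block solver
                    q, r = _nested_block_solve(
                        model, q, r, f_ext, m_ext, scale, fd_steps, s
                    )
                    best = _scaled_norm(r, scale)
                    break
            J = None
            fresh = False
        else:
            failed_fresh = 0
            if updates_since_fresh > 8:
                J = None
                fresh = False

    converged = best <= 1.0
    # detailed evaluation at the accepted pose (contact results, fiber forces)
    r, a, obj, report, info, _ = _residual(model, q, f_ext, m_ext)
    pose = KneePose(q)
    diag = SolveDiagnostics(
        residuals=r.copy(),
        iterations=it,
        converged=bool(converged),
        objective=obj,
        activation_report=report,
    )
    return pose, a, (info["tf"], info["pf"]), diag, J, info


def run_gait(model, gait, scenario: PrestrainScenario | None = None):
    """Sequential solve over the gait grid with warm starts.

    Returns :class:`~kneemech.results.GaitResults`; unconverged frames are
    reported in the diagnostics, never silently dropped.
    """
    from .results import GaitResults

    if model.reference_pose is None:
        raise SolverError("model must be reference-assembled before fitting")

    n = gait.n_frames
    poses = np.empty((n, 12))
    acts = np.empty((n, len(model.muscles)))
    diags: list[SolveDiagnostics] = []
    tf_list, pf_list = [], []
    lig_forces = {b.name: np.zeros(n) for b in model.ligaments}

    warm = model.reference_pose
    J = None
    for i in range(n):
        loads = (gait.force_n[i], gait.moment_nmm[i])
        target_flex = float(gait.flexion_deg[i])
        if i == 0:
            # continuation from the reference assembly to the first frame
            start_flex = warm.q[0]
            nsub = max(int(np.ceil(abs(target_flex - start_flex) / 3.0)), 1)
            for k in range(1, nsub + 1):
                fsub = start_flex + (target_flex - start_flex) * k / nsub
                sub_loads = (gait.force_n[i] * k / nsub, gait.moment_nmm[i] * k / nsub)
                pose, a, (tf_res, pf_res), diag, J, info = solve_timestep(
                    model, fsub, sub_loads, warm, J
                )
                warm = pose
        else:
            # linear extrapolation of the secondary coordinates as warm start
            if i >= 2 and diags[i - 1].converged and diags[i - 2].converged:
                qw = warm.q.copy()
                qw[1:] += 0.5 * (poses[i - 1, 1:] - poses[i - 2, 1:])
                warm_i = KneePose(qw)
            else:
                warm_i = warm
            pose, a, (tf_res, pf_res), diag, J, info = solve_timestep(
                model, target_flex, loads, warm_i, J
            )
            if not diag.converged:
                # retry from the last converged frame (prevents one bad frame
                # from cascading through its successors)
                fallback_warm = None
                for k in range(i - 1, -1, -1):
                    if diags[k].converged:
                        fallback_warm = KneePose(poses[k].copy())
                        break
                if fallback_warm is None:
                    fallback_warm = model.reference_pose
                pose2, a2, c2, diag2, J2, info2 = solve_timestep(
                    model, target_flex, loads, fallback_warm, None
                )
                if diag2.converged or _scaled_norm(diag2.residuals) < _scaled_norm(
                    diag.residuals
                ):
                    pose, a, diag, J, info = pose2, a2, diag2, J2, info2
                    tf_res, pf_res = c2
        if i == 0 and nsub > 1:
            # re-solve at the exact frame loads (last continuation step already
            # used them; this is a no-op guard)
            pass
        poses[i] = pose.q
        acts[i] = a
        diags.append(diag)
        tf_list.append(tf_res)
        pf_list.append(pf_res)
        for name, f in model.bundle_forces(info["fiber_lengths"]).items():
            lig_forces[name][i] = f
        warm = pose

    return GaitResults(
        model=model,
        gait=gait,
        scenario=scenario,
        poses=poses,
        activations=acts,
        tf_contacts=tf_list,
        pf_contacts=pf_list,
        ligament_forces=lig_forces,
        diagnostics=diags,
    )
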