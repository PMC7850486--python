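"""Body-level solver: force personalisation, inverse dynamics, recruitment,
joint reaction analysis."""
import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

from femoneck import msk
from femoneck.msk import (LinkageModel, fmax_from_volume, fmax_scaled_generic,
                          filter_coordinates, inverse_dynamics,
                          newton_euler_chain, static_optimization)
from femoneck.subject import DOF_NAMES, GaitTrial


class TestFmaxPersonalisation:
    def test_pcsa_route(self):
        assert fmax_from_volume(100.0, 10.0, 61.0) == pytest.approx(610.0)
        assert fmax_from_volume(0.0, 10.0) == 0.0
        assert fmax_from_volume(200.0, 10.0) == 2 * fmax_from_volume(100.0, 10.0)
        with pytest.raises(ValueError):
            fmax_from_volume(100.0, 0.0)

    def test_mass_scaling_route(self):
        assert fmax_scaled_generic(11.78, 11.78, 1500.0) == pytest.approx(1500.0)
        assert fmax_scaled_generic(2 * 11.78, 11.78, 1500.0) == pytest.approx(3000.0)
        assert fmax_scaled_generic(0.0, 11.78, 1500.0) == 0.0
        with pytest.raises(ValueError):
            fmax_scaled_generic(10.0, 0.0, 1500.0)


class TestCoordinateFilter:
    fs = 100.0

    def test_dc_preserved(self):
        x = np.full(300, 7.5)
        assert np.allclose(filter_coordinates(x, 6.0, self.fs), x, atol=1e-10)

    @pytest.mark.parametrize("freq,check", [(1.0, "pass"), (30.0, "stop")])
    def test_frequency_response(self, freq, check):
        # 4th-order Butterworth |H| = 1/sqrt(1+(f/fc)^8); filtfilt squares it
        t = np.arange(2000) / self.fs
        x = np.sin(2 * np.pi * freq * t)
        y = filter_coordinates(x, 6.0, self.fs)
        amp = np.abs(y[500:1500]).max()
        expected = 1.0 / (1.0 + (freq / 6.0) ** 8)
        assert amp == pytest.approx(expected, abs=0.01)
        if check == "pass":
            assert amp > 0.99
        else:
            assert amp < 0.05

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            filter_coordinates(np.zeros(100), 50.0, 100.0)


def _massless(linkage):
    segs = {k: {**v, "mass": 0.0} for k, v in linkage.segments.items()}
    return dataclasses.replace(linkage, segments=segs)


def _static_trial(linkage, cop, grf, body_mass=70.0):
    ang = pd.DataFrame(0.0, index=np.arange(1, 101), columns=DOF_NAMES)
    return GaitTrial(np.arange(1, 101), ang, np.tile(grf, (100, 1)),
                     np.tile(cop, (100, 1)), body_mass)


class TestInverseDynamics:
    def test_grf_under_hip_gives_zero_hip_moment(self, linkage):
        lk = _massless(linkage)
        cop = np.array([lk.hip_lab[0], lk.hip_lab[1], 0.0])
        trial = _static_trial(lk, cop, np.array([0.0, 0.0, 700.0]))
        m = inverse_dynamics(lk, trial)
        # vertical force through the hip: no flexion (y) moment
        assert np.abs(m["hip_y"]).max() < 1e-6

    def test_ankle_moment_equals_force_times_lever(self, linkage):
        lk = _massless(linkage)
        pose = lk.forward_kinematics({d: 0.0 for d in DOF_NAMES})
        cop = pose["ankle_pos"] + np.array([100.0, 0.0, 0.0])
        trial = _static_trial(lk, cop, np.array([0.0, 0.0, 700.0]))
        m = inverse_dynamics(lk, trial)
        assert np.abs(m["ankle"]).max() == pytest.approx(70.0, rel=1e-9)

    def test_missing_dof_column_raises(self, linkage, gait_trial):
        bad = GaitTrial(gait_trial.pct, gait_trial.angles.drop(columns=["knee_flexion"]),
                        gait_trial.grf, gait_trial.cop, gait_trial.body_mass)
        with pytest.raises(ValueError, match="knee_flexion"):
            inverse_dynamics(linkage, bad)

    def test_double_pendulum_matches_lagrangian_closed_form(self):
        """Dynamic-mode recursive Newton-Euler vs a symbolic Lagrangian
        oracle on a planar two-link pendulum with prescribed motion."""
        import sympy as sp

        l1, l2 = 400.0, 350.0          # mm
        m1, m2 = 7.0, 3.5              # kg
        I1 = m1 * (l1 / 1000) ** 2 / 12
        I2 = m2 * (l2 / 1000) ** 2 / 12
        T_cycle, n = 2.0, 400
        t = np.arange(n) * T_cycle / n
        q1 = 0.3 * np.sin(2 * np.pi * t / T_cycle) + 0.1
        q2 = 0.4 + 0.2 * np.sin(4 * np.pi * t / T_cycle + 0.5)

        # symbolic oracle (planar x-z, rotation about +y, gravity -z)
        ts = sp.symbols("t")
        q1f, q2f = sp.Function("q1")(ts), sp.Function("q2")(ts)
        L1, L2 = l1 / 1000, l2 / 1000
        g = 9.81
        c1 = sp.Matrix([-L1 / 2 * sp.sin(q1f), -L1 / 2 * sp.cos(q1f)])
        c2 = sp.Matrix([-L1 * sp.sin(q1f) - L2 / 2 * sp.sin(q1f + q2f),
                        -L1 * sp.cos(q1f) - L2 / 2 * sp.cos(q1f + q2f)])
        v1, v2 = c1.diff(ts), c2.diff(ts)
        T_kin = (m1 * v1.dot(v1) / 2 + I1 * q1f.diff(ts) ** 2 / 2
                 + m2 * v2.dot(v2) / 2 + I2 * (q1f + q2f).diff(ts) ** 2 / 2)
        V = g * (m1 * c1[1] + m2 * c2[1])
        Lag = sp.simplify(T_kin - V)
        traj = {q1f: 0.3 * sp.sin(2 * sp.pi * ts / T_cycle) + sp.Rational(1, 10),
                q2f: sp.Rational(2, 5)
                + 0.2 * sp.sin(4 * sp.pi * ts / T_cycle + sp.Rational(1, 2))}
        tau = []
        for qf in (q1f, q2f):
            el = (sp.diff(Lag, qf.diff(ts)).diff(ts) - sp.diff(Lag, qf))
            tau.append(el.subs(traj).doit())
        tau_f = sp.lambdify(ts, tau, "numpy")
        tau1, tau2 = (np.asarray(v) for v in tau_f(t))

        def rot_y(a):
            c, s = np.cos(a), np.sin(a)
            return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
        R1 = np.stack([rot_y(a) for a in q1])
        R2 = np.stack([rot_y(a) for a in q1 + q2])
        jp1 = np.zeros((n, 3))
        jp2 = np.einsum("tij,j->ti", R1, [0, 0, -l1])
        F, M = newton_euler_chain(
            np.stack([jp1, jp2]), np.stack([R1, R2]),
            np.array([[0, 0, -l1 / 2], [0, 0, -l2 / 2]]),
            np.array([m1, m2]),
            np.array([np.diag([I1, I1, 1e-9]), np.diag([I2, I2, 1e-9])]),
            np.zeros((n, 3)), np.zeros((n, 3)), T_cycle / n)
        scale = max(np.abs(tau1).max(), np.abs(tau2).max())
        assert np.abs(M[0][:, 1] - tau1).max() < 0.01 * scale
        assert np.abs(M[1][:, 1] - tau2).max() < 0.01 * scale


def _toy_problem(seed=0, n_mus=3, n_dof=2):
    rng = np.random.default_rng(seed)
    A = rng.uniform(-40, 40, size=(n_dof, n_mus))  # N.m at full activation
    M = rng.uniform(-25, 25, size=n_dof)
    return A, M


def _solve_toy(A, M):
    from scipy.optimize import lsq_linear
    n = A.shape[1]
    res = lsq_linear(np.vstack([np.eye(n), A]),
                     np.concatenate([np.zeros(n), M]), bounds=(0, 1),
                     tol=1e-12)
    return res.x


def _grid_oracle(A, M):
    """Zooming dense grid search of min sum(a^2)+sum((M-Aa)^2), terminal
    resolution well below 1e-3 activation."""
    n = A.shape[1]

    def objective(a_grid):
        res = M[None, :] - a_grid @ A.T
        return (a_grid ** 2).sum(axis=1) + (res ** 2).sum(axis=1)

    best = None
    for window, step in ((None, 0.02), (0.06, 2e-3), (0.005, 2e-4)):
        if window is None:
            axes = [np.arange(0, 1 + 1e-12, step)] * n
        else:
            axes = [np.clip(b + np.arange(-window, window + 1e-12, step), 0, 1)
                    for b in best]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, n)
        best = grid[np.argmin(objective(grid))]
    return best


class TestStaticOptimization:
    def test_single_muscle_unique_solution(self):
        # one muscle, one DOF: r = 0.05 m, F_max = 1000 N, M = 25 N.m
        A = np.array([[0.05 * 1000.0]])
        a = _solve_toy(A, np.array([25.0]))
        # reserve share is ~M/(r F)^2, so a sits within 1e-3 of M/(r F_max)
        assert a[0] == pytest.approx(0.5, abs=1e-3)

    def test_identical_muscles_share_equally(self):
        A = np.array([[30.0, 30.0]])
        a = _solve_toy(A, np.array([20.0]))
        assert a[0] == pytest.approx(a[1], abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_grid_search_oracle(self, seed):
        A, M = _toy_problem(seed)
        a = _solve_toy(A, M)
        oracle = _grid_oracle(A, M)
        assert np.abs(a - oracle).max() < 1e-2

    def test_optimality_against_random_perturbations(self, linkage,
                                                     body_solution):
        moments, sol, _ = body_solution
        t = 14
        A = msk._muscle_rows(linkage, sol.poses[t])
        M = moments.iloc[t].to_numpy()
        a0 = sol.activations[t]

        def objective(a):
            return (a ** 2).sum() + ((M - A @ a) ** 2).sum()
        j0 = objective(a0)
        rng = np.random.default_rng(42)
        for scale in (1e-3, 1e-2, 1e-1):
            pert = rng.normal(0, scale, size=(334, len(a0)))
            js = [objective(np.clip(a0 + p, 0, 1)) for p in pert]
            assert min(js) >= j0 - 1e-9

    def test_reserves_below_one_percent_on_default_gait(self, body_solution):
        moments, sol, _ = body_solution
        peak = moments.abs().max().max()
        assert np.abs(sol.reserves).max() < 0.01 * peak

    def test_activation_bounds_respected(self, body_solution):
        _, sol, _ = body_solution
        assert sol.activations.min() >= -1e-12
        assert sol.activations.max() <= 1 + 1e-12

    def test_recovery_of_generating_forces(self):
        """Moments generated by a known activation set (one muscle per DOF)
        are recovered by re-solving, since that set is the unique minimiser."""
        A = np.diag([40.0, 55.0, 30.0])
        a_true = np.array([0.3, 0.6, 0.2])
        M = A @ a_true
        a = _solve_toy(A, M)
        assert np.abs(a - a_true).max() < 0.05 * a_true.max()


class TestJointReaction:
    def test_unloaded_static_jcf_equals_supported_weight(self, linkage):
        lk = linkage
        trial = _static_trial(lk, np.zeros(3), np.zeros(3))
        poses = [lk.forward_kinematics(trial.angles.iloc[i].to_dict())
                 for i in range(100)]
        sol = msk.MuscleForceSolution(
            [m.name for m in lk.muscles],
            np.zeros((100, len(lk.muscles))), np.zeros((100, len(lk.muscles))),
            np.zeros((100, 5)), np.zeros(100), poses)
        loads = msk.joint_reaction(sol, lk, trial)
        m_leg = sum(lk.segments[s]["mass"] for s in
                    ("femur_r", "tibia_r", "foot_r"))
        assert np.linalg.norm(loads.jcf_hip[0]) == pytest.approx(
            m_leg * 9.81, rel=1e-9)

    def test_added_hip_muscle_shifts_jcf_by_its_force(self, linkage):
        lk = linkage
        trial = _static_trial(lk, np.zeros(3), np.zeros(3))
        poses = [lk.forward_kinematics(trial.angles.iloc[i].to_dict())
                 for i in range(100)]
        n = len(lk.muscles)
        zeros = msk.MuscleForceSolution([m.name for m in lk.muscles],
                                        np.zeros((100, n)), np.zeros((100, n)),
                                        np.zeros((100, 5)), np.zeros(100), poses)
        one = msk.MuscleForceSolution([m.name for m in lk.muscles],
                                      np.zeros((100, n)), np.zeros((100, n)),
                                      np.zeros((100, 5)), np.zeros(100), poses)
        i = [m.name for m in lk.muscles].index("gluteus_medius")
        one.forces[:, i] = 500.0
        l0 = msk.joint_reaction(zeros, lk, trial)
        l1 = msk.joint_reaction(one, lk, trial)
        mus = lk.muscles[i]
        u = lk.pull_direction(mus, "insertion", poses[0])
        dv = poses[0]["R_fem"].T @ (500.0 * u)
        # the joint carries the reaction of the added muscle pull
        assert np.allclose(l1.jcf_hip[0] - l0.jcf_hip[0], -dv, atol=1e-9)
        assert np.linalg.norm(l1.jcf_hip[0] - l0.jcf_hip[0]) == \
            pytest.approx(500.0, rel=1e-12)

    def test_stance_peak_hip_jcf_within_physiological_band(self, default_spec,
                                                           body_solution):
        """Independent single-leg-stance free-body estimate bounds the hip
        JCF at the stance peak between 1.5 and 6 body weights."""
        _, _, loads = body_solution
        bw = default_spec.body_weight
        peak = np.linalg.norm(loads.jcf_hip, axis=1).max()
        assert 1.5 * bw < peak < 6.0 * bw

    def test_femur_free_body_equilibrium(self, linkage, gait_trial,
                                         body_solution):
        """Muscle forces + joint forces + weight on the femur cancel at
        every interval (the quasi-static force balance)."""
        _, sol, loads = body_solution
        m_f = linkage.segments["femur_r"]["mass"]
        scale = np.linalg.norm(loads.jcf_hip, axis=1).max()
        for t in range(0, 100, 7):
            pose = sol.poses[t]
            total = loads.jcf_hip[t] + loads.jcf_knee[t]
            total = total + pose["R_fem"].T @ np.array([0, 0, -m_f * 9.81])
            for mus, po, fo, pi, fi in msk._muscle_world_forces(linkage, sol, t):
                if mus.seg_o == "femur":
                    total = total + pose["R_fem"].T @ fo
                if mus.seg_i == "femur":
                    total = total + pose["R_fem"].T @ fi
            assert np.linalg.norm(total) < 1e-6 * max(scale, 1.0)
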