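"""Rigid-body dynamics checked against closed-form and symbolic oracles."""

import numpy as np
import pytest

from sit2walk import model_core as mc
from sit2walk.model_core import (ModelValidationError, SystemState,
                                 build_default_model, forward_dynamics,
                                 integrate, mechanical_energy, muscle_geometry)
from sit2walk import fixtures_synthetic as fx


def total_energy(model, q, qd):
    ke, pe = mechanical_energy(model, SystemState(0.0, q, qd))
    return ke + pe


class TestForwardDynamics:
    def test_free_fall(self, model, seated_state):
        """With contacts and muscles exerting nothing, gravity is all there is."""
        import copy
        m = copy.deepcopy(model)
        m.contacts = []
        m.surfaces = []
        qdd = forward_dynamics(m, seated_state)
        assert qdd[1] == pytest.approx(-9.81, rel=1e-12)
        assert np.allclose(np.delete(qdd, 1), 0.0, atol=1e-9)

    @pytest.mark.parametrize("theta", [-1.2, -0.3, 0.0, 0.3, 0.9, 2.0])
    def test_pendulum_closed_form(self, scenes, theta):
        pend = scenes["pendulum"]
        qdd = forward_dynamics(pend.model, SystemState(0.0, [theta], [0.0]))
        assert qdd[0] == pytest.approx(pend.oracle(theta), rel=1e-8, abs=1e-10)

    def test_double_pendulum_symbolic_oracle(self, scenes):
        """Accelerations match an independent Lagrangian derivation (sympy)."""
        sympy = pytest.importorskip("sympy")
        scene = scenes["double_pendulum"]
        m1, m2 = 1.5, 1.0
        l1 = 0.6
        c1, c2 = 0.3, 0.25
        I1, I2 = 0.02, 0.01
        g = 9.81

        q1, q2, w1, w2 = sympy.symbols("q1 q2 w1 w2")
        t = sympy.Symbol("t")
        f1 = sympy.Function("f1")(t)
        f2 = sympy.Function("f2")(t)
        # COM positions (pivot at origin; absolute angles th1=f1, th2=f1+f2)
        th1, th2 = f1, f1 + f2
        x1 = c1 * sympy.sin(th1)
        y1 = -c1 * sympy.cos(th1)
        x2 = l1 * sympy.sin(th1) + c2 * sympy.sin(th2)
        y2 = -l1 * sympy.cos(th1) - c2 * sympy.cos(th2)
        v1sq = sympy.diff(x1, t) ** 2 + sympy.diff(y1, t) ** 2
        v2sq = sympy.diff(x2, t) ** 2 + sympy.diff(y2, t) ** 2
        T = (m1 * v1sq + m2 * v2sq) / 2 \
            + I1 * sympy.diff(th1, t) ** 2 / 2 + I2 * sympy.diff(th2, t) ** 2 / 2
        V = m1 * g * y1 + m2 * g * y2
        L = T - V
        eqs = [sympy.diff(sympy.diff(L, sympy.diff(f, t)), t) - sympy.diff(L, f)
               for f in (f1, f2)]
        acc = sympy.symbols("a1 a2")
        sub = {sympy.diff(f1, t, 2): acc[0], sympy.diff(f2, t, 2): acc[1],
               sympy.diff(f1, t): w1, sympy.diff(f2, t): w2, f1: q1, f2: q2}
        sol = sympy.solve([e.subs(sub).doit() for e in eqs], acc, dict=True)[0]
        fns = [sympy.lambdify((q1, q2, w1, w2), sympy.simplify(sol[a])) for a in acc]

        rng = np.random.default_rng(42)
        for _ in range(5):
            q = rng.uniform(-1.5, 1.5, 2)
            qd = rng.uniform(-2.0, 2.0, 2)
            qdd = forward_dynamics(scene.model, SystemState(0.0, q, qd))
            expect = np.array([f(q[0], q[1], qd[0], qd[1]) for f in fns])
            np.testing.assert_allclose(qdd, expect, rtol=1e-8, atol=1e-10)

    def test_singularity_free_for_tree(self, model, seated_state):
        qdd = forward_dynamics(model, seated_state)
        assert np.all(np.isfinite(qdd))


class TestIntegrate:
    def test_zero_duration_returns_initial_state(self, scenes):
        pend = scenes["pendulum"]
        traj = integrate(pend.model, pend.initial_state, None, duration=0.0)
        assert len(traj.t) == 1
        assert traj.q[0, 0] == pytest.approx(0.3)

    def test_pendulum_energy_conservation(self, scenes):
        """Unactuated, contact-free: energy drift < 0.1% over 5 s."""
        pend = scenes["pendulum"]
        traj = integrate(pend.model, pend.initial_state, None, duration=5.0,
                         dt=5e-4)
        E = np.array([total_energy(pend.model, q, qd)
                      for q, qd in zip(traj.q, traj.qd)])
        # measure against the energy scale (PE measured from the pivot)
        scale = abs(E[0])
        assert np.abs(E - E[0]).max() / scale < 1e-3

    def test_pendulum_period_small_amplitude(self, scenes):
        pend = scenes["pendulum"]
        traj = integrate(pend.model, SystemState(0.0, [0.05], [0.0]), None,
                         duration=4.2, dt=5e-4, out_dt=0.002)
        th = traj.q[:, 0]
        # zero crossings (downward) give the period
        sgn = np.sign(th)
        crossings = traj.t[1:][(sgn[1:] < 0) & (sgn[:-1] >= 0)]
        period = np.mean(np.diff(crossings))
        assert period == pytest.approx(2 * np.pi * np.sqrt(1.0 / 9.81), rel=5e-3)

    def test_determinism(self, scenes):
        drop = scenes["drop_test"]
        t1 = integrate(drop.model, drop.initial_state, None, duration=1.0)
        t2 = integrate(drop.model, drop.initial_state, None, duration=1.0)
        np.testing.assert_array_equal(t1.q, t2.q)
        np.testing.assert_array_equal(t1.sph_n, t2.sph_n)

    def test_blowup_flags_failed_rollout(self, scenes):
        pend = scenes["pendulum"]
        traj = integrate(pend.model, SystemState(0.0, [0.0], [500.0]), None,
                         duration=1.0, qd_cap=50.0)
        assert traj.failed


class TestMuscleGeometry:
    def test_moment_arm_is_length_gradient(self, model):
        """Moment arms equal central finite differences of MTU length."""
        rng = np.random.default_rng(0)
        h = 1e-6
        base = fx.seated_initial_state(model).q
        for _ in range(4):
            q = base + rng.uniform(-0.4, 0.4, 11)
            _, arms = muscle_geometry(model, q)
            for j in range(11):
                qp = q.copy()
                qp[j] += h
                qm = q.copy()
                qm[j] -= h
                Lp, _ = muscle_geometry(model, qp)
                Lm, _ = muscle_geometry(model, qm)
                fd = -(Lp - Lm) / (2 * h)
                np.testing.assert_allclose(arms[:, j], fd, atol=1e-6)

    def test_constant_arm_length_change(self, scenes):
        """Small rotation: length change = -arm * dtheta to first order."""
        scene = scenes["lever_muscle"]
        q = np.array([0.0, 0.3])
        L0, arms = muscle_geometry(scene.model, q)
        d = 1e-5
        q2 = q + np.array([0.0, d])
        L1, _ = muscle_geometry(scene.model, q2)
        assert L1[0] - L0[0] == pytest.approx(-arms[0, 1] * d, rel=1e-3)


class TestValidation:
    def test_zero_mass_rejected(self):
        cfg = fx.default_model_config()
        cfg["segments"][0]["mass"] = 0.0
        with pytest.raises(ModelValidationError):
            build_default_model(cfg)

    def test_dof_count_checked(self):
        cfg = fx.default_model_config()
        cfg["expect_dof"] = 12
        with pytest.raises(ModelValidationError, match="DOF"):
            build_default_model(cfg)

    def test_single_free_joint_required(self):
        cfg = fx.default_model_config()
        cfg["joints"][1]["kind"] = "planar_free"
        cfg.pop("expect_dof")
        with pytest.raises(ModelValidationError, match="planar_free"):
            build_default_model(cfg)

    def test_default_build_shape(self, model):
        assert model.ndof == 11
        assert len(model.muscles) == 20
        assert model.total_mass == pytest.approx(75.0)
        assert model.height == pytest.approx(1.80)
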