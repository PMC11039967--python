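"""Objective terms on hand-integrable fixtures and the weighted total."""

import numpy as np
import pytest

from conftest import synthetic_trajectory
from sit2walk import model_core as mc
from sit2walk import objective as ob
from sit2walk.analysis_io import MovementEvents

BW = 735.75


@pytest.fixture()
def t100():
    return np.arange(0, 2.0 + 1e-9, 0.01)


class TestRangePenalty:
    def test_inside_range_is_free(self, t100):
        assert ob.range_penalty(t100, np.full_like(t100, 5.0), -50, 50) == 0.0

    def test_rectangle_integral(self, t100):
        # constant 5 deg beyond hi for 2 s -> 10 deg s
        assert ob.range_penalty(t100, np.full_like(t100, 55.0), -50, 50) == \
            pytest.approx(10.0)

    def test_boundary_touch_is_free(self, t100):
        assert ob.range_penalty(t100, np.full_like(t100, 50.0), -50, 50) == 0.0

    def test_invalid_limits(self, t100):
        with pytest.raises(ValueError):
            ob.range_penalty(t100, t100, 10, -10)


class TestKneeLimit:
    def test_within_range_free(self, t100):
        assert ob.knee_limit_term(t100, np.full_like(t100, -60.0)) == 0.0

    def test_spring_law_integral(self):
        t = np.arange(0, 1.0 + 1e-9, 0.01)
        # constant 1 unit excursion for 1 s -> 500 x 1 x 1
        assert ob.knee_limit_term(t, np.full_like(t, 11.0)) == pytest.approx(500.0)

    def test_both_bounds_additive(self):
        t = np.arange(0, 1.0 + 1e-9, 0.01)
        a = ob.knee_limit_term(t, np.full_like(t, 11.0))
        b = ob.knee_limit_term(t, np.full_like(t, -121.0))
        mixed = np.where(t < 0.5, 11.0, -121.0)
        assert ob.knee_limit_term(t, mixed) == pytest.approx((a + b) / 2, rel=0.05)


class TestHeadAcc:
    def test_below_threshold_free(self, t100):
        assert ob.head_acc_term(t100, np.full_like(t100, 0.8)) == 0.0

    def test_rectangle(self):
        t = np.arange(0, 0.5 + 1e-9, 0.01)
        assert ob.head_acc_term(t, np.full_like(t, 3.0)) == pytest.approx(1.0)


class TestPain:
    def test_below_threshold_zero(self, t100):
        t = np.arange(0, 1.0 + 1e-9, 0.01)
        assert ob.pain_term(t, np.full_like(t, 3.0), 4.0, BW) == 0.0

    def test_rectangle_in_newton_seconds(self):
        t = np.arange(0, 1.0 + 1e-9, 0.01)
        assert ob.pain_term(t, np.full_like(t, 3.0), 2.0, BW) == \
            pytest.approx(735.75)

    @pytest.mark.parametrize("thresholds", [(4.0, 3.0, 2.0)])
    def test_monotone_nonincreasing_in_threshold(self, thresholds):
        rng = np.random.default_rng(3)
        t = np.arange(0, 1.0 + 1e-9, 0.01)
        load = 3.0 + rng.uniform(-1.5, 2.5, t.size)
        costs = [ob.pain_term(t, load, thr, BW) for thr in thresholds]
        assert costs == sorted(costs)


class TestVelocityAndEffort:
    def test_velocity_above_threshold_free(self, model):
        t = np.arange(0, 2.0 + 1e-9, 0.01)
        q = np.zeros((t.size, 11))
        q[:, 0] = 0.9 * t
        traj = synthetic_trajectory(model, t, q=q)
        ev = MovementEvents(heel_strikes=[0.5])
        assert ob.velocity_term(traj, 0.8, events=ev) == 0.0

    def test_velocity_exact_threshold_free(self, model):
        t = np.arange(0, 2.0 + 1e-9, 0.01)
        q = np.zeros((t.size, 11))
        q[:, 0] = 0.8 * t
        traj = synthetic_trajectory(model, t, q=q)
        assert ob.velocity_term(traj, 0.8, events=MovementEvents(
            heel_strikes=[0.5])) == pytest.approx(0.0, abs=1e-12)

    def test_velocity_squared_shortfall(self, model):
        t = np.arange(0, 2.0 + 1e-9, 0.01)
        q = np.zeros((t.size, 11))
        q[:, 0] = 0.6 * t
        traj = synthetic_trajectory(model, t, q=q)
        assert ob.velocity_term(traj, 0.8, events=MovementEvents(
            heel_strikes=[0.0])) == pytest.approx(0.04, rel=1e-6)

    def test_cubed_activation_integral(self, model):
        t = np.arange(0, 2.0 + 1e-9, 0.01)
        a = np.zeros((t.size, 20))
        a[:, 3] = 0.5
        traj = synthetic_trajectory(model, t, a=a)
        _, j_act, _ = ob.effort_terms(traj, events=MovementEvents())
        assert j_act == pytest.approx(0.5 ** 3 * 2.0)

    def test_trunk_torque_integral(self, model):
        t = np.arange(0, 2.0 + 1e-9, 0.01)
        tt = np.zeros((t.size, 2))
        tt[:, 0] = 10.0
        tt[:, 1] = 5.0
        traj = synthetic_trajectory(model, t, trunk_tau=tt)
        _, _, j_T = ob.effort_terms(traj, events=MovementEvents())
        assert j_T == pytest.approx((100 + 25) * 2.0)

    def test_metabolic_decreases_with_weaker_muscle(self, model):
        """Replaying the same motion with halved VAS f_max lowers J_mb."""
        import copy
        t = np.arange(0, 1.0 + 1e-9, 0.01)
        a = np.full((t.size, 20), 0.4)
        traj = synthetic_trajectory(model, t, a=a)
        j_mb, _, _ = ob.effort_terms(traj, events=MovementEvents())
        weak = copy.deepcopy(model)
        for m in weak.muscles:
            if m.name.startswith("VAS"):
                m.f_max *= 0.5
        traj2 = synthetic_trajectory(weak, t, a=a)
        j_mb_weak, _, _ = ob.effort_terms(traj2, events=MovementEvents())
        assert j_mb_weak < j_mb


class TestEvaluate:
    def _clean_traj(self, model):
        """A fabricated movement satisfying every hard measure."""
        t = np.arange(0, 2.0 + 1e-9, 0.01)
        q = np.zeros((t.size, 11))
        q[:, 0] = 0.9 * t          # walks at 0.9 m/s
        q[:, 1] = 0.95
        a = np.zeros((t.size, 20))
        a[:, 5] = 0.5
        tt = np.zeros((t.size, 2))
        tt[:, 0] = 8.0
        ar = mc.compile_model(model)
        sph = np.zeros((t.size, ar.ns))
        chair_idx = np.nonzero(ar.sp_target[:ar.ns] == 1)[0]
        grf_idx = np.nonzero(ar.sp_target[:ar.ns] == 0)[0]
        sph[t < 0.4, chair_idx[0]] = 400.0       # seated then seat-off
        sph[:, grf_idx] = 200.0
        left = np.nonzero(ar.sp_leg[:ar.ns] == 0)[0]
        sph[np.ix_((t > 0.6) & (t < 0.7), left)] = 0.0   # one toe-off + strike
        return synthetic_trajectory(model, t, q=q, a=a, trunk_tau=tt, sph_n=sph)

    def test_total_reduces_to_weighted_effort(self, model):
        traj = self._clean_traj(model)
        cfg = ob.ObjectiveConfig()
        rep = ob.evaluate(traj, cfg)
        assert rep.j_velocity == 0.0
        assert rep.j_range_total == 0.0
        assert rep.j_knee_limit == 0.0
        assert rep.j_pain == 0.0
        expect = (cfg.w_mb * rep.j_mb + cfg.w_act * rep.j_act
                  + cfg.w_T * rep.j_T + rep.j_head_acc)
        assert rep.j_total == pytest.approx(expect)
        # uniform motion: the head never accelerates
        assert rep.j_head_acc == pytest.approx(0.0, abs=1e-6)

    def test_termwise_additivity(self, model):
        traj = self._clean_traj(model)
        cfg = ob.ObjectiveConfig(pain_threshold_bw=2.0)
        rep = ob.evaluate(traj, cfg)
        hand = (rep.j_velocity + rep.j_range_total + rep.j_knee_limit
                + rep.j_head_acc + cfg.w_mb * rep.j_mb + cfg.w_act * rep.j_act
                + cfg.w_T * rep.j_T + rep.j_pain)
        assert rep.j_total == pytest.approx(hand)

    def test_failed_rollout_above_any_success(self, model, scenes):
        pend = scenes["pendulum"]
        bad = mc.integrate(pend.model, mc.SystemState(0.0, [0.0], [500.0]),
                           None, duration=0.5, qd_cap=50.0)
        rep = ob.evaluate(bad, ob.ObjectiveConfig())
        assert rep.failed
        assert rep.j_total >= 1.0e4


class TestJointLoad:
    def test_static_two_legged_stance_ankle_load(self, model):
        """Settled upright stance: each ankle carries ~0.5 BW."""
        q = np.zeros(11)
        q[1] = 0.954
        mask = np.zeros(11, dtype=bool)
        mask[1] = True
        traj = mc.integrate(model, mc.SystemState(0.0, q, np.zeros(11)), None,
                            duration=1.5, dt=5e-4, free_mask=mask)
        loads = ob.joint_load_series(traj)
        # average over the settled tail
        for leg in (0, 1):
            ankle = loads[("ankle", leg)][-30:].mean()
            assert ankle == pytest.approx(0.5, rel=0.05)

    def test_bw_normalization(self, model):
        assert model.body_weight == pytest.approx(735.75)
        assert 1471.5 / model.body_weight == pytest.approx(2.0)
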