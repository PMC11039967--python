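"""Reflex control law, delays, schedule, parameter vector round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sit2walk.controller import (ControllerSchedule, ParamVector,
                                 ReflexController, advance_state_machine,
                                 build_param_specs, delayed, pack,
                                 stand_excitations, unpack)


class TestDelayed:
    def test_zero_delay_is_identity(self):
        t = np.linspace(0, 1, 11)
        assert delayed(t, t ** 2, 0.0) == pytest.approx(1.0)

    def test_constant_signal(self):
        t = np.linspace(0, 1, 11)
        assert delayed(t, np.full(11, 3.3), 0.4) == pytest.approx(3.3)

    def test_ramp_interpolation(self):
        t = np.linspace(0, 0.1, 101)
        assert delayed(t, t, 0.02, t=0.1) == pytest.approx(0.08)

    def test_zero_padded_before_start(self):
        t = np.linspace(0, 0.1, 101)
        assert delayed(t, t + 1.0, 0.5, t=0.1) == 0.0

    def test_negative_delay_rejected(self):
        with pytest.raises(ValueError):
            delayed([0, 1], [0, 1], -0.1)


class TestStandLaw:
    def test_constant_drive(self):
        u = stand_excitations(Ld=np.ones(3), Fd_self=np.zeros(3),
                              Fd_ant=np.zeros(3), theta_d=0.0, thetad_d=0.0,
                              KC=np.full(3, 0.3), KL=np.zeros(3), LO=np.ones(3),
                              KFp=np.zeros(3), KFm=np.zeros(3), KP=np.zeros(3),
                              KV=np.zeros(3), theta_o=0.0)
        np.testing.assert_allclose(u, 0.3)

    def test_length_feedback_positive_part(self):
        u = stand_excitations(Ld=0.9, Fd_self=0.0, Fd_ant=0.0, theta_d=0.0,
                              thetad_d=0.0, KC=0.0, KL=2.0, LO=1.0, KFp=0.0,
                              KFm=0.0, KP=0.0, KV=0.0, theta_o=0.0)
        assert u == 0.0

    def test_hand_evaluated_force_feedback(self):
        u = stand_excitations(Ld=1.0, Fd_self=0.4, Fd_ant=0.0, theta_d=0.0,
                              thetad_d=0.0, KC=0.1, KL=0.0, LO=1.0, KFp=0.5,
                              KFm=0.0, KP=0.0, KV=0.0, theta_o=0.0)
        assert u == pytest.approx(0.3)

    @given(KC=st.floats(0, 1), KL=st.floats(0, 10), KFp=st.floats(0, 10),
           KFm=st.floats(0, 10), KP=st.floats(-5, 5), KV=st.floats(-5, 5),
           Ld=st.floats(0.2, 1.8), F=st.floats(0, 1.4), Fa=st.floats(0, 1.4),
           th=st.floats(-1.5, 1.5), thd=st.floats(-10, 10))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_excitations_always_bounded(self, KC, KL, KFp, KFm, KP, KV,
                                        Ld, F, Fa, th, thd):
        u = stand_excitations(Ld, F, Fa, th, thd, KC, KL, 1.0, KFp, KFm,
                              KP, KV, 0.0)
        assert 0.0 <= u <= 1.0


class TestSchedule:
    def test_modes_and_boundaries(self):
        s = ControllerSchedule(0.3, 1.0)
        assert advance_state_machine(0.0, s) == "stand1"
        assert advance_state_machine(0.3, s) == "stand2"  # boundary included
        assert advance_state_machine(0.999, s) == "stand2"
        assert advance_state_machine(1.0, s) == "gait"

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            ControllerSchedule(1.0, 0.5)
        with pytest.raises(ValueError):
            ControllerSchedule(0.0, 1.0)


class TestParamVector:
    def test_pack_unpack_roundtrip(self):
        structured = {"st0_VAS_KC": 0.4, "sched_t_state2": 0.7, "g2_TA_KC": 0.3}
        pv = pack(structured)
        back = unpack(pv)
        for k, v in structured.items():
            assert back[k] == v
        assert unpack(pack(back)) == back

    def test_unknown_block_rejected(self):
        with pytest.raises(KeyError, match="st9_XYZ"):
            pack({"st9_XYZ_KC": 1.0})

    def test_length_matches_declared_layout(self):
        specs = build_param_specs()
        assert len(pack({})) == len(specs)

    def test_perturbing_one_entry_changes_one_scalar(self):
        pv = pack({})
        for i in (0, len(pv) // 2, len(pv) - 1):
            vals = pv.values.copy()
            vals[i] += 0.123
            changed = [k for k, (a, b) in enumerate(zip(pv.values, vals)) if a != b]
            assert changed == [i]
            back = unpack(pv.with_values(vals))
            assert back[pv.names[i]] == pytest.approx(pv.values[i] + 0.123)

    def test_file_roundtrip(self, tmp_path):
        pv = pack({"st0_VAS_KC": 0.42})
        pv.free[3] = False
        path = tmp_path / "params.txt"
        pv.to_file(path)
        pv2 = ParamVector.from_file(path)
        assert pv2.names == pv.names
        np.testing.assert_allclose(pv2.values, pv.values)
        np.testing.assert_array_equal(pv2.free, pv.free)


class TestDenseMirrorSymmetry:
    def test_left_right_share_parameters(self, model):
        rc = ReflexController(model.muscle_names, pack({"st1_VAS_KC": 0.37}))
        d = rc.dense()
        names = model.muscle_names
        for g in ("VAS", "HAM", "SOL", "TA", "GMAX"):
            il, ir = names.index(f"{g}_l"), names.index(f"{g}_r")
            np.testing.assert_array_equal(d.st_KC[:, il], d.st_KC[:, ir])
            np.testing.assert_array_equal(d.g_KF[:, il], d.g_KF[:, ir])
        assert d.st_KC[1, names.index("VAS_l")] == pytest.approx(0.37)

    def test_antagonist_wiring_stays_ipsilateral(self, model):
        rc = ReflexController(model.muscle_names)
        d = rc.dense()
        names = model.muscle_names
        for m, nm in enumerate(names):
            ant = names[d.ant[m]]
            assert nm.rsplit("_", 1)[1] == ant.rsplit("_", 1)[1]

    def test_repair_fixes_schedule_ordering(self, model):
        pv = pack({"sched_t_state2": 1.2, "sched_t_gait": 0.5})
        rc = ReflexController(model.muscle_names, pv).repaired()
        assert rc.params["sched_t_gait"] > rc.params["sched_t_state2"]
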