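"""Movement measures (trunk flexion, events, metrics) and file writers."""

import numpy as np
import pytest

from conftest import synthetic_trajectory
from sit2walk import analysis_io as aio
from sit2walk import model_core as mc


class TestTrunkFlexion:
    def test_upright_zero(self):
        assert aio.trunk_flexion(np.zeros(11)) == 0.0

    def test_sum_of_three_angles(self):
        q = np.zeros(11)
        q[2] = np.deg2rad(-20.0)   # anterior pelvis tilt
        q[9] = np.deg2rad(-15.0)   # lumbar flexion
        q[10] = np.deg2rad(-5.0)   # thoracic flexion
        assert aio.trunk_flexion(q) == pytest.approx(40.0)

    def test_single_term(self):
        q = np.zeros(11)
        q[2] = np.deg2rad(-10.0)
        assert aio.trunk_flexion(q) == pytest.approx(10.0)

    def test_property_sum_over_random_poses(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            q = rng.uniform(-1, 1, 11)
            expect = -np.rad2deg(q[2] + q[9] + q[10])
            assert aio.trunk_flexion(q) == pytest.approx(expect)


def step_series(t, drop_at, rise_at=None, hi=400.0):
    x = np.full_like(t, hi)
    x[t >= drop_at] = 0.0
    if rise_at is not None:
        x[t >= rise_at] = hi
    return x


class TestEvents:
    def test_seat_off_detection(self):
        t = np.arange(0, 2.0, 0.01)
        ev = aio.detect_events_from_series(t, step_series(t, 0.42),
                                           np.full_like(t, 300.0),
                                           np.full_like(t, 300.0))
        assert ev.seat_off == pytest.approx(0.42)

    def test_never_unloading_chair(self):
        t = np.arange(0, 2.0, 0.01)
        ev = aio.detect_events_from_series(t, np.full_like(t, 400.0),
                                           np.full_like(t, 300.0),
                                           np.full_like(t, 300.0))
        assert ev.seat_off is None

    def test_multiple_toe_offs_in_order(self):
        t = np.arange(0, 4.0, 0.01)
        grf_l = np.full_like(t, 300.0)
        grf_r = np.full_like(t, 300.0)
        for lo, hi in ((0.5, 0.8), (1.5, 1.8)):
            grf_l[(t >= lo) & (t < hi)] = 0.0
        for lo, hi in ((1.0, 1.3), (2.0, 2.3)):
            grf_r[(t >= lo) & (t < hi)] = 0.0
        ev = aio.detect_events_from_series(t, step_series(t, 0.2), grf_l, grf_r)
        assert ev.toe_offs == pytest.approx([0.5, 1.0, 1.5, 2.0])
        assert ev.heel_strikes == pytest.approx([0.8, 1.3, 1.8, 2.3])

    def test_debounce_ignores_short_flickers(self):
        t = np.arange(0, 2.0, 0.01)
        chair = step_series(t, 0.9)
        # sub-50 ms dips must not create events
        chair[(t >= 0.30) & (t < 0.33)] = 0.0
        grf = np.full_like(t, 300.0)
        grf[(t >= 0.50) & (t < 0.52)] = 0.0
        ev = aio.detect_events_from_series(t, chair, grf, grf)
        assert ev.seat_off == pytest.approx(0.9)
        assert ev.toe_offs == []

    def test_seat_unloading_start_95_percent_rule(self):
        t = np.arange(0, 2.0, 0.01)
        chair = np.full_like(t, 400.0)
        chair[t >= 0.6] = 370.0   # below 95% of settled
        chair[t >= 1.0] = 0.0
        ev = aio.detect_events_from_series(t, chair, np.full_like(t, 300.0),
                                           np.full_like(t, 300.0))
        assert ev.seat_unloading_start == pytest.approx(0.6)


class TestMetrics:
    def _traj(self, model):
        t = np.arange(0, 2.0, 0.01)
        q = np.zeros((t.size, 11))
        q[:, 2] = np.deg2rad(-20.0) * np.minimum(t, 1.0)  # leans to 20 deg
        ar = mc.compile_model(model)
        sph = np.zeros((t.size, ar.ns))
        chair_idx = np.nonzero(ar.sp_target[:ar.ns] == 1)[0]
        grf_idx = np.nonzero(ar.sp_target[:ar.ns] == 0)[0]
        sph[:, chair_idx[0]] = step_series(t, 0.8)
        sph[:, grf_idx] = 200.0
        left = np.nonzero(ar.sp_leg[:ar.ns] == 0)[0]
        sph[np.ix_((t >= 1.0) & (t < 1.2), left)] = 0.0   # left step
        return synthetic_trajectory(model, t, q=q, sph_n=sph)

    def test_metrics_from_constructed_fixture(self, model):
        traj = self._traj(model)
        ev = aio.detect_events(traj)
        rep = aio.metrics(traj, events=ev)
        assert ev.seat_off == pytest.approx(0.8)
        assert rep.trunk_flexion_at_seat_off == pytest.approx(16.0, abs=0.3)
        assert rep.max_trunk_flexion <= 20.0 + 1e-9
        assert rep.time_to_first_heel_strike == pytest.approx(
            1.2 - ev.movement_onset, abs=0.05)
        assert rep.peak_activations["VAS_l"] == 0.0
        assert not rep.missing

    def test_missing_events_reported_not_raised(self, model):
        t = np.arange(0, 1.0, 0.01)
        traj = synthetic_trajectory(model, t)
        rep = aio.metrics(traj)
        assert "seat_off" in rep.missing
        assert rep.trunk_flexion_at_seat_off is None


class TestWriters:
    def test_csv_roundtrip(self, tmp_path, scenes):
        drop = scenes["drop_test"]
        traj = mc.integrate(drop.model, drop.initial_state, None, duration=0.3)
        path = tmp_path / "traj.csv"
        aio.write_trajectory_csv(traj, path)
        import pandas as pd
        df = pd.read_csv(path)
        assert list(df.columns) == traj.column_names()
        np.testing.assert_allclose(df["time"].to_numpy(), traj.t)
        np.testing.assert_allclose(
            df[[c for c in df.columns if c.startswith("q_")]].to_numpy(), traj.q)

    def test_sto_header_matches_rows(self, tmp_path, scenes):
        drop = scenes["drop_test"]
        traj = mc.integrate(drop.model, drop.initial_state, None, duration=0.3)
        path = tmp_path / "traj.sto"
        aio.write_sto(traj, path)
        lines = path.read_text().splitlines()
        n_rows = int(next(l for l in lines if l.startswith("nRows")).split("=")[1])
        n_cols = int(next(l for l in lines if l.startswith("nColumns")).split("=")[1])
        header_i = lines.index("endheader")
        data = lines[header_i + 2:]
        assert len(data) == n_rows == len(traj.t)
        assert len(data[0].split("\t")) == n_cols

    def test_column_schema_stable(self, model):
        t = np.arange(0, 0.1, 0.01)
        traj = synthetic_trajectory(model, t)
        cols = traj.column_names()
        assert cols[0] == "time"
        assert "q_knee_l" in cols and "a_VAS_r" in cols
        assert cols == synthetic_trajectory(model, t).column_names()

    def test_write_outputs_files(self, tmp_path, scenes):
        drop = scenes["drop_test"]
        traj = mc.integrate(drop.model, drop.initial_state, None, duration=0.2)
        written = aio.write_outputs(traj, {"metrics": {"answer": 1}}, tmp_path,
                                    plots=False)
        names = {p.split("/")[-1] for p in map(str, written)}
        assert {"trajectory.csv", "trajectory.sto", "metrics.json"} <= names
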