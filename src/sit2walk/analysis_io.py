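"""Movement measures and output writers: trunk flexion, movement events
(seat-off, toe-offs, heel strikes), timing, joint loads, activation peaks,
plus CSV / OpenSim-storage (.sto) / JSON / plot outputs.

Event detection works on contact force series: compliant contact never
reaches exactly zero numerically, so a force threshold (5 N default) with a
50 ms debounce defines unloading/loading instants.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import objective as _objective

__all__ = [
    "MovementEvents", "MetricsReport", "trunk_flexion", "trunk_flexion_series",
    "detect_events", "detect_events_from_series", "metrics", "write_outputs",
    "write_trajectory_csv", "write_sto",
]

EVENT_FORCE_EPS = 5.0       # N
EVENT_DEBOUNCE = 0.05       # s
SEAT_UNLOAD_FRACTION = 0.95  # of the settled chair load = seat-unloading onset

_TRUNK_DOFS = ("pelvis_ground_tilt", "lumbar", "thoracic")


@dataclass
class MovementEvents:
    seat_off: float | None = None
    toe_offs: list = field(default_factory=list)
    heel_strikes: list = field(default_factory=list)
    movement_onset: float = 0.0
    seat_unloading_start: float | None = None

    def to_dict(self):
        return {"seat_off": self.seat_off, "toe_offs": list(self.toe_offs),
                "heel_strikes": list(self.heel_strikes),
                "movement_onset": self.movement_onset,
                "seat_unloading_start": self.seat_unloading_start}


@dataclass
class MetricsReport:
    trunk_flexion_at_seat_off: float | None = None   # deg
    max_trunk_flexion: float | None = None           # deg
    time_to_first_heel_strike: float | None = None   # s
    peak_joint_loads: dict = field(default_factory=dict)   # (joint, leg) -> BW
    peak_activations: dict = field(default_factory=dict)   # muscle -> [0,1]
    events: MovementEvents = field(default_factory=MovementEvents)
    missing: list = field(default_factory=list)

    def to_dict(self):
        return {
            "trunk_flexion_at_seat_off_deg": self.trunk_flexion_at_seat_off,
            "max_trunk_flexion_deg": self.max_trunk_flexion,
            "time_to_first_heel_strike_s": self.time_to_first_heel_strike,
            "peak_joint_loads_bw": {f"{j}_{'lr'[leg]}": v for (j, leg), v
                                    in self.peak_joint_loads.items()},
            "peak_activations": dict(self.peak_activations),
            "events": self.events.to_dict(),
            "missing": list(self.missing),
        }


def trunk_flexion(state, dof_names=None) -> float:
    """Trunk forward lean vs global vertical in degrees (forward positive).

    The trunk angle is the sum of pelvis tilt, lumbar and thoracic angles;
    with CCW-positive internal angles forward lean is negative, so the
    reported value is the negated sum.
    """
    q = state.q if hasattr(state, "q") else np.asarray(state, dtype=float)
    if dof_names is None:
        idx = (2, len(q) - 2, len(q) - 1)
    else:
        idx = tuple(dof_names.index(n) for n in _TRUNK_DOFS)
    return float(-np.rad2deg(q[idx[0]] + q[idx[1]] + q[idx[2]]))


def trunk_flexion_series(traj) -> np.ndarray:
    names = traj.arrays.dof_names
    idx = [names.index(n) for n in _TRUNK_DOFS]
    return -np.rad2deg(traj.q[:, idx].sum(axis=1))


def _sustained_crossings(t, x, eps, debounce, direction):
    """Times where x crosses below (direction=-1) or above (+1) eps and stays
    there for at least `debounce` seconds."""
    x = np.asarray(x, dtype=float)
    below = x < eps if direction < 0 else x > eps
    events = []
    i = 1
    n = len(t)
    while i < n:
        if below[i] and not below[i - 1]:
            j = i
            while j < n and below[j]:
                j += 1
            if (t[min(j, n - 1)] - t[i] >= debounce) or (j >= n and t[n - 1] - t[i] >= 0):
                # sustained until debounce expires or trajectory end
                if t[min(j, n - 1)] - t[i] >= debounce or j >= n:
                    events.append(float(t[i]))
            i = j
        else:
            i += 1
    return events


def detect_events_from_series(t, chair, grf_left, grf_right,
                              eps: float = EVENT_FORCE_EPS,
                              debounce: float = EVENT_DEBOUNCE) -> MovementEvents:
    """Detect seat-off, toe-offs and heel strikes from force series."""
    t = np.asarray(t, dtype=float)
    ev = MovementEvents()
    chair = np.asarray(chair, dtype=float)
    offs = _sustained_crossings(t, chair, eps, debounce, -1)
    ev.seat_off = offs[0] if offs else None

    settled = float(np.median(chair[: max(3, int(0.1 * len(chair)))]))
    if settled > eps:
        idx = np.nonzero(chair < SEAT_UNLOAD_FRACTION * settled)[0]
        ev.seat_unloading_start = float(t[idx[0]]) if idx.size else None

    toe_offs = []
    heel_strikes = []
    # gait events belong to the locomotor phase: brief foot unloading while
    # still seated (weight shifts during the lean) is not a toe-off
    t_min = ev.seat_off if ev.seat_off is not None else -np.inf
    for grf in (grf_left, grf_right):
        t_offs = [x for x in _sustained_crossings(t, grf, eps, debounce, -1)
                  if x >= t_min]
        t_ons = _sustained_crossings(t, grf, eps, debounce, +1)
        toe_offs += t_offs
        heel_strikes += [ton for ton in t_ons
                         if t_offs and ton > t_offs[0]]
    ev.toe_offs = sorted(toe_offs)
    ev.heel_strikes = sorted(heel_strikes)
    return ev


def detect_events(traj, eps: float = EVENT_FORCE_EPS,
                  debounce: float = EVENT_DEBOUNCE) -> MovementEvents:
    ev = detect_events_from_series(traj.t, traj.chair_load(),
                                   traj.leg_grf(0), traj.leg_grf(1),
                                   eps=eps, debounce=debounce)
    # movement onset: first visible trunk motion (fallback: rollout start)
    tf = trunk_flexion_series(traj)
    moved = np.nonzero(np.abs(tf - tf[0]) > 0.5)[0]
    ev.movement_onset = float(traj.t[moved[0]]) if moved.size else 0.0
    if ev.seat_off is not None and ev.movement_onset > ev.seat_off:
        ev.movement_onset = float(ev.seat_off)
    return ev


def metrics(traj, events: MovementEvents | None = None,
            loads: dict | None = None) -> MetricsReport:
    """The study's movement measures for one rollout; missing events yield a
    partial report with explicit absences instead of raising."""
    rep = MetricsReport()
    ev = events or detect_events(traj)
    rep.events = ev
    t = traj.t
    tf = trunk_flexion_series(traj)
    if ev.seat_off is not None:
        rep.trunk_flexion_at_seat_off = float(np.interp(ev.seat_off, t, tf))
        w = (t >= ev.movement_onset) & (t <= ev.seat_off)
        rep.max_trunk_flexion = float(tf[w].max()) if w.any() else None
    else:
        rep.missing.append("seat_off")
    if ev.heel_strikes:
        rep.time_to_first_heel_strike = float(ev.heel_strikes[0] - ev.movement_onset)
    else:
        rep.missing.append("first_heel_strike")
    if loads is None:
        loads = _objective.joint_load_series(traj)
    rep.peak_joint_loads = {key: float(v.max()) for key, v in loads.items()}
    names = traj.arrays.muscle_names
    for m, name in enumerate(names):
        rep.peak_activations[name] = float(traj.a[:, m].max())
    return rep


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_trajectory_csv(traj, path):
    df = traj.to_dataframe()
    df.to_csv(path, index=False)
    return path


def write_sto(traj, path, name="sit2walk"):
    """OpenSim storage motion file: coordinates in degrees, translations in m."""
    arrays = traj.arrays
    cols = ["time"] + list(arrays.dof_names)
    data = np.column_stack([traj.t] + [
        traj.q[:, j] if arrays.dof_kind[j] != 2 else np.rad2deg(traj.q[:, j])
        for j in range(arrays.ndof)])
    with open(path, "w") as fh:
        fh.write(f"{name}\nversion=1\n")
        fh.write(f"nRows={data.shape[0]}\nnColumns={data.shape[1]}\n")
        fh.write("inDegrees=yes\nendheader\n")
        fh.write("\t".join(cols) + "\n")
        for row in data:
            fh.write("\t".join(f"{v:.8g}" for v in row) + "\n")
    return path


def _plot_activations(traj, path, envelopes=None):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = traj.arrays.muscle_names
    groups = sorted({n.rsplit("_", 1)[0] for n in names})
    fig, axes = plt.subplots(len(groups), 2, figsize=(8, 2 * len(groups)),
                             sharex=True, squeeze=False)
    tspan = traj.t[-1] - traj.t[0] if len(traj.t) > 1 else 1.0
    for gi, g in enumerate(groups):
        for si, sd in enumerate(("l", "r")):
            ax = axes[gi][si]
            nm = f"{g}_{sd}"
            if envelopes and g in envelopes:
                env = envelopes[g]
                ax.fill_between(traj.t[0] + env.phase * tspan, env.lower,
                                env.upper, color="0.85",
                                label="synthetic envelope (not experimental)")
            if nm in names:
                m = names.index(nm)
                ax.plot(traj.t, traj.a[:, m], lw=1.2, label=nm)
            ax.set_ylim(0, 1)
            ax.set_ylabel(nm, fontsize=7)
    axes[0][0].legend(fontsize=6)
    axes[-1][0].set_xlabel("time [s]")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _plot_summary(traj, loads, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(3, 1, figsize=(7, 8), sharex=True)
    axes[0].plot(traj.t, trunk_flexion_series(traj))
    axes[0].set_ylabel("trunk flexion [deg]")
    for (j, leg), v in loads.items():
        axes[1].plot(traj.t, v, label=f"{j}_{'lr'[leg]}", lw=1)
    axes[1].legend(fontsize=7)
    axes[1].set_ylabel("joint load [BW]")
    axes[2].plot(traj.t, traj.chair_load(), label="chair")
    axes[2].plot(traj.t, traj.leg_grf(0), label="GRF left")
    axes[2].plot(traj.t, traj.leg_grf(1), label="GRF right")
    axes[2].legend(fontsize=7)
    axes[2].set_ylabel("contact force [N]")
    axes[2].set_xlabel("time [s]")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def write_outputs(traj, reports: dict, out_dir, envelopes=None, plots=True):
    """Write trajectory CSV + .sto, metric/objective JSON and plots.

    ``reports`` may contain 'metrics' (MetricsReport), 'objective'
    (ObjectiveReport) and arbitrary JSON-serializable extras.
    """
    os.makedirs(out_dir, exist_ok=True)
    written = []
    try:
        written.append(write_trajectory_csv(traj, os.path.join(out_dir, "trajectory.csv")))
        written.append(write_sto(traj, os.path.join(out_dir, "trajectory.sto")))
        loads = None
        for key, rep in reports.items():
            p = os.path.join(out_dir, f"{key}.json")
            payload = rep.to_dict() if hasattr(rep, "to_dict") else rep
            with open(p, "w") as fh:
                json.dump(payload, fh, indent=1, default=float)
            written.append(p)
        if plots:
            loads = _objective.joint_load_series(traj)
            _plot_activations(traj, os.path.join(out_dir, "activations.png"),
                              envelopes=envelopes)
            _plot_summary(traj, loads, os.path.join(out_dir, "summary.png"))
    except OSError as err:
        raise OSError(f"writing outputs under {out_dir}: {err}") from err
    return written
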