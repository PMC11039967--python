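"""Reflex controllers for standing up and gait, and the flat parameter vector.

The standing-up controller has two sequential states, each with its own gain
set.  Per muscle (gains shared bilaterally) the excitation law is::

    u = clip01( KC + KL+ * max(0, L~(t-d) - lo) + KF+ * F~self(t-d)
                - KF- * F~antagonist(t-d) + Kp * (theta(t-d) - theta_o)
                + Kv * thetad(t-d) )

with L~ the MTU length normalized by optimal fiber length, F~ the force
normalized by maximum isometric force, and theta the pelvis tilt (vestibular
channel, wired to hip and trunk-spanning muscles only).  Lumbar and thoracic
joints carry PD torque feedback instead of muscles.

The gait controller is a per-leg five-phase reflex machine (early stance,
late stance, liftoff, swing, landing) with phase-gated length/force/
vestibular reflexes; stance is detected when the leg carries at least the
stance load threshold (fraction of body weight).

All free scalars live in a :class:`ParamVector` with bounds and initial
standard deviations; ``pack``/``unpack`` round-trip exactly between the
structured dict form and the flat vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GROUPS", "VESTIBULAR_GROUPS", "ANTAGONIST", "GROUP_DELAY",
    "ReflexGainSet", "VestibularGainSet", "TrunkJointPD", "ControllerSchedule",
    "ParamVector", "ReflexController", "DenseController",
    "build_param_specs", "pack", "unpack", "delayed",
    "stand_excitations", "gait_excitations", "advance_state_machine",
]

#: bilateral muscle groups of the default 20-muscle build
GROUPS = ["ILPSO", "GMAX", "HAM", "BFSH", "RF", "VAS", "GASM", "GASL", "SOL", "TA"]

#: muscles receiving pelvis-tilt (vestibular) feedback: hip/trunk-spanning
#: plus the ankle pair (pelvis-tilt-driven ankle balance strategy)
VESTIBULAR_GROUPS = ["ILPSO", "GMAX", "HAM", "RF", "VAS", "SOL", "TA"]

#: antagonist wiring for the KF- channel
ANTAGONIST = {
    "ILPSO": "GMAX", "GMAX": "ILPSO", "VAS": "HAM", "HAM": "VAS",
    "BFSH": "VAS", "RF": "HAM", "GASM": "TA", "GASL": "TA",
    "SOL": "TA", "TA": "SOL",
}

#: monosynaptic reflex latency (s) by group, monotone with neural path length
GROUP_DELAY = {
    "ILPSO": 0.010, "GMAX": 0.010, "HAM": 0.020, "BFSH": 0.020, "RF": 0.020,
    "VAS": 0.020, "GASM": 0.035, "GASL": 0.035, "SOL": 0.035, "TA": 0.035,
}

VESTIBULAR_DELAY = 0.005
GAIT_PHASES = ["early_stance", "late_stance", "liftoff", "swing", "landing"]
STAND_GAINS = ["KC", "KL", "LO", "KFp", "KFm"]
GAIT_GAINS = ["KC", "KL", "LO", "KF", "KFm"]


@dataclass
class ReflexGainSet:
    KC: float = 0.0
    KL_plus: float = 0.0
    l_o: float = 1.0
    KF_plus: float = 0.0
    KF_minus: float = 0.0
    delay: float = 0.02

    def __post_init__(self):
        if self.delay < 0:
            raise ValueError("delay must be >= 0")


@dataclass
class VestibularGainSet:
    Kp: float = 0.0
    Kv: float = 0.0
    theta_o: float = 0.0
    delay: float = VESTIBULAR_DELAY

    def __post_init__(self):
        if self.delay < 0:
            raise ValueError("delay must be >= 0")


@dataclass
class TrunkJointPD:
    setpoint: float = 0.0      # rad
    kp: float = 0.0            # N m / rad
    kv: float = 0.0            # N m s / rad

    def __post_init__(self):
        if self.kp < 0 or self.kv < 0:
            raise ValueError("trunk PD gains must be >= 0")


@dataclass
class ControllerSchedule:
    t_state2: float            # s, stand1 -> stand2
    t_gait: float              # s, stand2 -> gait
    stance_load_threshold: float = 0.2   # fraction of BW

    def __post_init__(self):
        if not 0 < self.t_state2 < self.t_gait:
            raise ValueError("schedule requires 0 < t_state2 < t_gait")


def advance_state_machine(t: float, schedule: ControllerSchedule) -> str:
    """Controller mode at time t; transitions are one-way, boundary included."""
    if t >= schedule.t_gait:
        return "gait"
    if t >= schedule.t_state2:
        return "stand2"
    return "stand1"


def delayed(times, values, delay: float, t: float | None = None) -> float:
    """Signal value at t - delay, linearly interpolated, zero-padded before 0."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if delay < 0:
        raise ValueError("delay must be >= 0")
    if t is None:
        t = times[-1]
    tq = t - delay
    if tq < times[0]:
        return 0.0 if tq < 0 else float(values[0])
    return float(np.interp(tq, times, values))


def stand_excitations(Ld, Fd_self, Fd_ant, theta_d, thetad_d,
                      KC, KL, LO, KFp, KFm, KP, KV, theta_o):
    """Vectorized standing reflex law (delayed signals already looked up)."""
    u = (np.asarray(KC, dtype=float)
         + KL * np.maximum(0.0, np.asarray(Ld) - LO)
         + KFp * np.asarray(Fd_self) - KFm * np.asarray(Fd_ant)
         + KP * (theta_d - theta_o) + KV * thetad_d)
    return np.clip(u, 0.0, 1.0)


def gait_excitations(phase, side, Ld, Fd_self, Fd_ant, theta_d, thetad_d,
                     g_KC, g_KL, g_LO, g_KF, g_KFm, g_KP, g_KV, g_theta_o):
    """Phase-gated gait reflex law; ``phase`` is per-leg (2,), side per muscle."""
    phase = np.asarray(phase)
    side = np.asarray(side)
    nm = side.size
    ph = phase[side]
    idx = np.arange(nm)
    u = (g_KC[ph, idx]
         + g_KL[ph, idx] * np.maximum(0.0, np.asarray(Ld) - g_LO[ph, idx])
         + g_KF[ph, idx] * np.asarray(Fd_self) - g_KFm[ph, idx] * np.asarray(Fd_ant))
    in_stance = ph <= 1
    u = u + in_stance * (g_KP[ph, idx] * (theta_d - g_theta_o)
                         + g_KV[ph, idx] * thetad_d)
    return np.clip(u, 0.0, 1.0)


# ---------------------------------------------------------------------------
# parameter vector
# ---------------------------------------------------------------------------

@dataclass
class ParamVector:
    """Ordered flat vector of all free controller scalars with bounds."""
    names: list
    values: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    init_std: np.ndarray
    free: np.ndarray = None  # bool; fixed entries are not optimized

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        self.init_std = np.asarray(self.init_std, dtype=float)
        n = len(self.names)
        for arr, nm in ((self.values, "values"), (self.lower, "lower"),
                        (self.upper, "upper"), (self.init_std, "init_std")):
            if arr.shape != (n,):
                raise ValueError(f"ParamVector field {nm}: length {arr.shape} != {n}")
        if self.free is None:
            self.free = np.ones(n, dtype=bool)
        self.free = np.asarray(self.free, dtype=bool)
        self.index = {nm: i for i, nm in enumerate(self.names)}

    def __len__(self):
        return len(self.names)

    def copy(self):
        return ParamVector(list(self.names), self.values.copy(), self.lower.copy(),
                           self.upper.copy(), self.init_std.copy(), self.free.copy())

    def with_values(self, values):
        pv = self.copy()
        pv.values = np.asarray(values, dtype=float).copy()
        if pv.values.shape != (len(self.names),):
            raise ValueError("values length mismatch")
        return pv

    def clipped(self):
        return self.with_values(np.clip(self.values, self.lower, self.upper))

    def __getitem__(self, name):
        return float(self.values[self.index[name]])

    def to_file(self, path):
        with open(path, "w") as fh:
            fh.write("# name value init_std min max free\n")
            for i, nm in enumerate(self.names):
                fh.write(f"{nm} {self.values[i]:.12g} {self.init_std[i]:.12g} "
                         f"{self.lower[i]:.12g} {self.upper[i]:.12g} "
                         f"{int(self.free[i])}\n")

    @classmethod
    def from_file(cls, path):
        names, vals, stds, los, his, free = [], [], [], [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                names.append(parts[0])
                vals.append(float(parts[1]))
                stds.append(float(parts[2]))
                los.append(float(parts[3]))
                his.append(float(parts[4]))
                free.append(bool(int(parts[5])) if len(parts) > 5 else True)
        return cls(names, np.array(vals), np.array(los), np.array(his),
                   np.array(stds), np.array(free))


def build_param_specs(groups=None, include_gait=True):
    """The canonical ordered parameter layout: (name, init, lo, hi, std) tuples.

    Bounds: KC in [0,1]; length/force gains in [0,10]; length offsets in
    [0.5,1.5]; vestibular gains in [-5,5] (either sign must be reachable);
    setpoints in physiological ranges; init_std = 10% of the box width.
    """
    groups = groups or GROUPS
    specs = []

    def add(name, init, lo, hi):
        specs.append((name, float(init), float(lo), float(hi),
                      0.1 * (float(hi) - float(lo))))

    for s in range(2):
        for g in groups:
            add(f"st{s}_{g}_KC", 0.02, 0.0, 1.0)
            add(f"st{s}_{g}_KL", 0.0, 0.0, 10.0)
            add(f"st{s}_{g}_LO", 1.0, 0.5, 1.5)
            add(f"st{s}_{g}_KFp", 0.0, 0.0, 10.0)
            add(f"st{s}_{g}_KFm", 0.0, 0.0, 10.0)
        for g in VESTIBULAR_GROUPS:
            if g in groups:
                add(f"st{s}_{g}_KP", 0.0, -5.0, 5.0)
                add(f"st{s}_{g}_KV", 0.0, -5.0, 5.0)
        add(f"st{s}_theta_o", 0.0, -1.5, 0.5)
        for joint in ("lumbar", "thoracic"):
            add(f"st{s}_{joint}_set", 0.0, -1.0, 0.3)
            add(f"st{s}_{joint}_kp", 50.0, 0.0, 500.0)
            add(f"st{s}_{joint}_kv", 5.0, 0.0, 50.0)
    add("sched_t_state2", 0.3, 0.05, 1.5)
    add("sched_t_gait", 0.8, 0.3, 3.0)
    add("sched_stance_thr", 0.2, 0.05, 0.5)
    if include_gait:
        for ph in range(5):
            for g in groups:
                add(f"g{ph}_{g}_KC", 0.02, 0.0, 1.0)
                add(f"g{ph}_{g}_KL", 0.0, 0.0, 10.0)
                add(f"g{ph}_{g}_LO", 1.0, 0.5, 1.5)
                add(f"g{ph}_{g}_KF", 0.0, 0.0, 10.0)
                add(f"g{ph}_{g}_KFm", 0.0, 0.0, 10.0)
        for ph in range(2):  # vestibular feedback in stance phases only
            for g in VESTIBULAR_GROUPS:
                if g in groups:
                    add(f"g{ph}_{g}_KP", 0.0, -5.0, 5.0)
                    add(f"g{ph}_{g}_KV", 0.0, -5.0, 5.0)
        add("g_theta_o", -0.1, -1.0, 0.5)
        for joint in ("lumbar", "thoracic"):
            add(f"g_{joint}_set", 0.0, -1.0, 0.3)
            add(f"g_{joint}_kp", 50.0, 0.0, 500.0)
            add(f"g_{joint}_kv", 5.0, 0.0, 50.0)
    return specs


def pack(structured: dict, specs=None) -> ParamVector:
    """Structured {name: value} -> ParamVector in canonical order."""
    specs = specs or build_param_specs()
    known = {nm for nm, *_ in specs}
    extra = set(structured) - known
    if extra:
        raise KeyError(f"unknown parameter block starts at: {sorted(extra)[0]}")
    names, vals, los, his, stds = [], [], [], [], []
    for nm, init, lo, hi, std in specs:
        names.append(nm)
        vals.append(structured.get(nm, init))
        los.append(lo)
        his.append(hi)
        stds.append(std)
    return ParamVector(names, np.array(vals), np.array(los), np.array(his),
                       np.array(stds))


def unpack(pv: ParamVector) -> dict:
    """ParamVector -> structured {name: value}; exact round-trip with pack."""
    return {nm: float(v) for nm, v in zip(pv.names, pv.values)}


# ---------------------------------------------------------------------------
# dense kernel form
# ---------------------------------------------------------------------------

class DenseController:
    """Controller parameters broadcast to per-muscle dense arrays."""

    def __init__(self, nm):
        self.st_KC = np.zeros((2, nm))
        self.st_KL = np.zeros((2, nm))
        self.st_LO = np.ones((2, nm))
        self.st_KFp = np.zeros((2, nm))
        self.st_KFm = np.zeros((2, nm))
        self.st_KP = np.zeros((2, nm))
        self.st_KV = np.zeros((2, nm))
        self.st_theta_o = np.zeros(2)
        self.st_trunk = np.zeros((2, 2, 3))
        self.g_KC = np.zeros((5, nm))
        self.g_KL = np.zeros((5, nm))
        self.g_LO = np.ones((5, nm))
        self.g_KF = np.zeros((5, nm))
        self.g_KFm = np.zeros((5, nm))
        self.g_KP = np.zeros((5, nm))
        self.g_KV = np.zeros((5, nm))
        self.g_theta_o = np.zeros(1)
        self.g_trunk = np.zeros((2, 3))
        self.ant = np.zeros(nm, dtype=np.int64)
        self.delays = np.zeros(nm)
        self.delay_vest = VESTIBULAR_DELAY
        self.t_state2 = 1e9
        self.t_gait = 2e9
        self.stance_thr = 0.2
        self.d_latestance = 0.0
        self.d_landing = 0.15


class ReflexController:
    """A parameter vector bound to a concrete muscle roster.

    ``muscle_names`` are full names like ``VAS_l``; gains are shared between
    sides (the left/right mirror symmetry of the control law).
    """

    def __init__(self, muscle_names, params: ParamVector | None = None,
                 control_dt: float = 0.005):
        self.muscle_names = list(muscle_names)
        self.groups = sorted({n.rsplit("_", 1)[0] for n in self.muscle_names},
                             key=lambda g: GROUPS.index(g) if g in GROUPS else 99)
        if params is None:
            specs = build_param_specs(groups=self.groups)
            params = pack({}, specs=specs)
        self.params = params
        self.control_dt = control_dt

    @classmethod
    def zeros(cls, nm):
        shim = object.__new__(cls)
        shim.muscle_names = [f"m{i}_l" for i in range(nm)]
        shim.groups = []
        shim.params = None
        shim.control_dt = 0.005
        shim._dense_override = DenseController(max(nm, 1))
        return shim

    def with_values(self, values) -> "ReflexController":
        return ReflexController(self.muscle_names, self.params.with_values(values),
                                self.control_dt)

    def repaired(self) -> "ReflexController":
        """Clip to bounds and repair schedule ordering (t_state2 < t_gait)."""
        pv = self.params.clipped()
        i2 = pv.index["sched_t_state2"]
        ig = pv.index["sched_t_gait"]
        if pv.values[ig] <= pv.values[i2]:
            pv.values[ig] = pv.values[i2] + 0.05
        return ReflexController(self.muscle_names, pv, self.control_dt)

    def schedule(self) -> ControllerSchedule:
        return ControllerSchedule(self.params["sched_t_state2"],
                                  max(self.params["sched_t_gait"],
                                      self.params["sched_t_state2"] + 1e-6),
                                  self.params["sched_stance_thr"])

    def dense(self) -> DenseController:
        if hasattr(self, "_dense_override"):
            return self._dense_override
        nm = len(self.muscle_names)
        d = DenseController(nm)
        group_of = [n.rsplit("_", 1)[0] for n in self.muscle_names]
        side_of = [n.rsplit("_", 1)[1] for n in self.muscle_names]
        p = self.params

        def val(name, default=0.0):
            i = p.index.get(name)
            return float(p.values[i]) if i is not None else default

        for m, g in enumerate(group_of):
            d.delays[m] = GROUP_DELAY.get(g, 0.02)
            ant_g = ANTAGONIST.get(g, g)
            ant_name = f"{ant_g}_{side_of[m]}"
            d.ant[m] = (self.muscle_names.index(ant_name)
                        if ant_name in self.muscle_names else m)
            for s in range(2):
                d.st_KC[s, m] = val(f"st{s}_{g}_KC")
                d.st_KL[s, m] = val(f"st{s}_{g}_KL")
                d.st_LO[s, m] = val(f"st{s}_{g}_LO", 1.0)
                d.st_KFp[s, m] = val(f"st{s}_{g}_KFp")
                d.st_KFm[s, m] = val(f"st{s}_{g}_KFm")
                if g in VESTIBULAR_GROUPS:
                    d.st_KP[s, m] = val(f"st{s}_{g}_KP")
                    d.st_KV[s, m] = val(f"st{s}_{g}_KV")
            for ph in range(5):
                d.g_KC[ph, m] = val(f"g{ph}_{g}_KC")
                d.g_KL[ph, m] = val(f"g{ph}_{g}_KL")
                d.g_LO[ph, m] = val(f"g{ph}_{g}_LO", 1.0)
                d.g_KF[ph, m] = val(f"g{ph}_{g}_KF")
                d.g_KFm[ph, m] = val(f"g{ph}_{g}_KFm")
            for ph in range(2):
                if g in VESTIBULAR_GROUPS:
                    d.g_KP[ph, m] = val(f"g{ph}_{g}_KP")
                    d.g_KV[ph, m] = val(f"g{ph}_{g}_KV")
        for s in range(2):
            d.st_theta_o[s] = val(f"st{s}_theta_o")
            for jj, joint in enumerate(("lumbar", "thoracic")):
                d.st_trunk[s, jj, 0] = val(f"st{s}_{joint}_set")
                d.st_trunk[s, jj, 1] = val(f"st{s}_{joint}_kp")
                d.st_trunk[s, jj, 2] = val(f"st{s}_{joint}_kv")
        d.g_theta_o[0] = val("g_theta_o")
        for jj, joint in enumerate(("lumbar", "thoracic")):
            d.g_trunk[jj, 0] = val(f"g_{joint}_set")
            d.g_trunk[jj, 1] = val(f"g_{joint}_kp")
            d.g_trunk[jj, 2] = val(f"g_{joint}_kv")
        d.t_state2 = val("sched_t_state2", 1e9)
        d.t_gait = val("sched_t_gait", 2e9)
        d.stance_thr = val("sched_stance_thr", 0.2)
        return d
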