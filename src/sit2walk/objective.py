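"""The composite movement objective: gait velocity threshold, joint range
penalties, knee limit force, head acceleration, metabolic/activation/torque
effort, and the pain-avoidance (knee unloading) cost.

Hard task measures (velocity, ranges, knee limit, head acceleration, pain)
are summed penalties that reach exactly zero on a satisfying movement, so a
converged solution is ranked purely by the weighted effort estimate

    J_total = w_mb * J_mb + w_act * J_act + w_T * J_T

with default weights w_mb = 0.01, w_act = 0.1, w_T = 0.0003.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import model_core
from .muscle import MetabolicCoefficients, MuscleConstants, muscle_mass, _maintenance_fl

__all__ = [
    "ObjectiveConfig", "ObjectiveReport", "velocity_term", "range_penalty",
    "knee_limit_term", "head_acc_term", "effort_terms", "joint_load",
    "joint_load_series", "pain_term", "evaluate",
]

#: joint range limits in degrees: {dof name: (lo, hi)}
DEFAULT_RANGE_LIMITS = {
    "lumbar": (-50.0, 0.0),
    "thoracic": (-15.0, 15.0),
    "pelvis_ground_tilt": (-50.0, 30.0),
    "ankle_l": (-60.0, 60.0),
    "ankle_r": (-60.0, 60.0),
}


@dataclass
class ObjectiveConfig:
    v_min: float = 0.8                      # m/s minimum average gait speed
    range_limits: dict = field(default_factory=lambda: dict(DEFAULT_RANGE_LIMITS))
    knee_limit_stiffness: float = 500.0     # engages outside [-120, +10] deg
    head_acc_threshold: float = 1.0         # m/s^2
    head_point: tuple = ("torso", (0.0, 0.45))
    w_mb: float = 0.01
    w_act: float = 0.1
    w_T: float = 0.0003
    pain_threshold_bw: float | None = None  # multiples of BW, or None
    pain_leg: str = "stepping"              # stepping = left in this study
    # shaping of infeasible / non-walking rollouts (keeps a gradient toward
    # standing before any rollout succeeds)
    failure_cost: float = 1.0e4
    v_nogait: float = 100.0
    w_seatoff: float = 200.0              # penalty when the chair never unloads
    rise_height: float = 0.75             # m pelvis height that counts as risen
    w_rise: float = 1.0e4                 # per meter of rise-height shortfall
    shaping_h_ref: float = 0.85             # m, near-standing pelvis height
    shaping_d_ref: float = 0.5              # m, forward progress reference
    w_shaping_h: float = 50.0
    w_shaping_d: float = 10.0

    def __post_init__(self):
        if self.v_min <= 0:
            raise ValueError("v_min must be positive")
        for w in (self.w_mb, self.w_act, self.w_T):
            if w < 0:
                raise ValueError("objective weights must be >= 0")


@dataclass
class ObjectiveReport:
    j_velocity: float = 0.0
    j_seatoff: float = 0.0
    j_range: dict = field(default_factory=dict)
    j_knee_limit: float = 0.0
    j_head_acc: float = 0.0
    j_mb: float = 0.0
    j_act: float = 0.0
    j_T: float = 0.0
    j_pain: float = 0.0
    j_total: float = 0.0
    failed: bool = False
    feasible: dict = field(default_factory=dict)

    @property
    def j_range_total(self) -> float:
        return float(sum(self.j_range.values()))

    def to_dict(self):
        return {
            "j_velocity": self.j_velocity, "j_seatoff": self.j_seatoff,
            "j_range": dict(self.j_range),
            "j_knee_limit": self.j_knee_limit, "j_head_acc": self.j_head_acc,
            "j_mb": self.j_mb, "j_act": self.j_act, "j_T": self.j_T,
            "j_pain": self.j_pain, "j_total": self.j_total,
            "failed": self.failed, "feasible": dict(self.feasible),
        }


def _shaping(traj, config: ObjectiveConfig) -> float:
    if len(traj.t) == 0:
        return config.w_shaping_h * config.shaping_h_ref \
            + config.w_shaping_d * config.shaping_d_ref
    y = traj.q[:, 1].max() if traj.q.shape[1] > 1 else 0.0
    x_final = traj.q[-1, 0]
    return (config.w_shaping_h * max(0.0, config.shaping_h_ref - y)
            + config.w_shaping_d * max(0.0, config.shaping_d_ref - x_final))


def velocity_term(traj, v_min: float, events=None,
                  config: ObjectiveConfig | None = None) -> float:
    """Squared shortfall of average forward velocity during the gait phase.

    The gait phase runs from the first heel strike of the first step to the
    end of the rollout.  Without a gait phase the configured maximum penalty
    (plus progress shaping) is returned.
    """
    config = config or ObjectiveConfig(v_min=v_min)
    if events is None:
        from .analysis_io import detect_events
        events = detect_events(traj)
    hs = events.heel_strikes[0] if events.heel_strikes else None
    if hs is None or traj.t[-1] - hs < 0.05:
        return config.v_nogait + _shaping(traj, config)
    i0 = int(np.searchsorted(traj.t, hs))
    dt_span = traj.t[-1] - traj.t[i0]
    v_avg = (traj.q[-1, 0] - traj.q[i0, 0]) / dt_span
    return float(max(0.0, v_min - v_avg) ** 2)


def range_penalty(t, angles_deg, lo: float, hi: float) -> float:
    """Time integral (deg s) of excursion beyond the closed interval [lo, hi]."""
    if not lo < hi:
        raise ValueError("range limits must satisfy lo < hi")
    x = np.asarray(angles_deg, dtype=float)
    excess = np.maximum(0.0, x - hi) + np.maximum(0.0, lo - x)
    return float(np.trapezoid(excess, t))


def knee_limit_term(t, knee_angle_deg, lo: float = -120.0, hi: float = 10.0,
                    stiffness: float = 500.0) -> float:
    """Time integral of the passive knee limit force magnitude.

    The limit acts as a spring of the given stiffness engaging outside
    [120 deg flexion, 10 deg extension].
    """
    x = np.asarray(knee_angle_deg, dtype=float)
    excess = np.maximum(0.0, x - hi) + np.maximum(0.0, lo - x)
    return float(np.trapezoid(stiffness * excess, t))


def head_acc_term(t, head_acc, threshold: float = 1.0) -> float:
    """Time integral of head acceleration magnitude above the threshold."""
    a = np.abs(np.asarray(head_acc, dtype=float))
    return float(np.trapezoid(np.maximum(0.0, a - threshold), t))


def head_acceleration_series(traj, head_point=("torso", (0.0, 0.45))):
    """|linear acceleration| of the head point at every output sample."""
    arrays = traj.arrays
    seg, loc = head_point
    out = np.zeros(len(traj.t))
    for i in range(len(traj.t)):
        _, _, acc = model_core.point_kinematics(
            arrays, traj.q[i], traj.qd[i], traj.qdd[i], seg, loc)
        out[i] = np.hypot(acc[0], acc[1])
    return out


def effort_terms(traj, model=None, events=None):
    """(J_mb, J_act, J_T): metabolic, cubed-activation, trunk-torque efforts.

    J_mb integrates the whole-body muscular metabolic power (activation +
    maintenance + shortening heat + positive work rates), normalized by body
    mass over the stand-up phase and additionally by distance travelled over
    the gait phase (a cost of transport).  J_act = integral of sum a^3.
    J_T = integral of lumbar^2 + thoracic^2 torques.
    """
    model = model or traj.model
    arrays = traj.arrays
    t = traj.t
    if len(t) < 2:
        return 0.0, 0.0, 0.0
    mc_const = model.muscle_constants
    coef = MetabolicCoefficients()
    masses = np.array([muscle_mass(m, mc_const) for m in model.muscles])
    a = traj.a
    ln = traj.lnorm
    g_l = np.vectorize(_maintenance_fl)(ln) if a.size else np.zeros_like(ln)
    v_fiber = traj.vnorm * arrays.vmax * arrays.lopt  # m/s
    Adot = masses * coef.activation_rate * a
    Mdot = masses * coef.maintenance_rate * g_l * a
    Sdot = coef.shortening_frac * traj.F * np.maximum(0.0, -v_fiber)
    Wdot = np.maximum(0.0, -traj.F * v_fiber)
    P = (Adot + Mdot + Sdot + Wdot).sum(axis=1) if a.size else np.zeros(len(t))

    if events is None:
        from .analysis_io import detect_events
        events = detect_events(traj)
    hs = events.heel_strikes[0] if events.heel_strikes else None
    body_mass = model.total_mass
    if hs is None:
        j_mb = float(np.trapezoid(P, t)) / body_mass
    else:
        i0 = int(np.searchsorted(t, hs))
        j_stand = float(np.trapezoid(P[:i0 + 1], t[:i0 + 1])) / body_mass
        dist = max(0.05, traj.q[-1, 0] - traj.q[i0, 0])
        j_gait = float(np.trapezoid(P[i0:], t[i0:])) / (body_mass * dist)
        j_mb = j_stand + j_gait

    j_act = float(np.trapezoid((a ** 3).sum(axis=1), t)) if a.size else 0.0
    j_T = float(np.trapezoid((traj.trunk_tau ** 2).sum(axis=1), t))
    return j_mb, j_act, j_T


# ---------------------------------------------------------------------------
# joint loads
# ---------------------------------------------------------------------------

_JOINT_CHILD = {("hip", 0): "thigh_l", ("hip", 1): "thigh_r",
                ("knee", 0): "shank_l", ("knee", 1): "shank_r",
                ("ankle", 0): "foot_l", ("ankle", 1): "foot_r"}


def _subtree(arrays, root_body):
    sub = {root_body}
    for b in range(arrays.nb):
        cur = b
        while cur >= 0:
            if cur == root_body:
                sub.add(b)
                break
            cur = arrays.parent[cur]
    return sub


def joint_load_series(traj):
    """Joint reaction force magnitude in BW at hip/knee/ankle, both legs.

    The load is the resultant bone-on-bone force on the distal segment:
    subtree inertial forces minus gravity, external contact, and the pull of
    every muscle segment crossing into the subtree.
    """
    arrays = traj.arrays
    bw = arrays.body_weight
    n = len(traj.t)
    joints = [(jn, leg) for jn in ("hip", "knee", "ankle") for leg in (0, 1)
              if _JOINT_CHILD[(jn, leg)] in arrays.body_index]
    subtrees = {key: _subtree(arrays, arrays.body_index[_JOINT_CHILD[key]])
                for key in joints}
    out = {key: np.zeros(n) for key in joints}
    g = arrays.grav
    for i in range(n):
        com_p, _, com_a, th, p, _, _ = model_core.body_com_kinematics(
            arrays, traj.q[i], traj.qd[i], traj.qdd[i])
        # world muscle path points
        mus_pts = []
        for m in range(arrays.nm):
            pts = []
            for s in range(arrays.mp_n[m]):
                b = arrays.mp_body[m, s]
                c, sn = np.cos(th[b]), np.sin(th[b])
                lx, ly = arrays.mp_loc[m, s]
                pts.append((b, p[b, 0] + c * lx - sn * ly,
                            p[b, 1] + sn * lx + c * ly))
            mus_pts.append(pts)
        for key in joints:
            S = subtrees[key]
            fx = fy = 0.0
            for b in S:
                fx += arrays.mass[b] * com_a[b, 0]
                fy += arrays.mass[b] * (com_a[b, 1] + g)
            for s in range(arrays.ns):
                if arrays.sp_body[s] in S:
                    fx -= traj.sph_f[i, s, 0]
                    fy -= traj.sph_f[i, s, 1]
            for m in range(arrays.nm):
                F = traj.F[i, m]
                if F <= 0.0:
                    continue
                pts = mus_pts[m]
                for s in range(len(pts) - 1):
                    bA, ax, ay = pts[s]
                    bB, bx, by = pts[s + 1]
                    inA, inB = bA in S, bB in S
                    if inA == inB:
                        continue
                    if inA:
                        dx, dy = bx - ax, by - ay
                    else:
                        dx, dy = ax - bx, ay - by
                    norm = np.hypot(dx, dy)
                    if norm > 1e-9:
                        fx -= F * dx / norm
                        fy -= F * dy / norm
            out[key][i] = np.hypot(fx, fy) / bw
    return out


def joint_load(traj, joint: str, leg: str = "left"):
    """Load series (BW) of one joint; joint in {hip, knee, ankle}."""
    leg_i = 0 if leg in ("left", "stepping") else 1
    return joint_load_series(traj)[(joint, leg_i)]


def pain_term(t, load_bw, threshold_bw: float, body_weight: float) -> float:
    """Integral (N s) of knee load above threshold; 0 iff peak < threshold."""
    if threshold_bw <= 0:
        raise ValueError("pain threshold must be positive (multiples of BW)")
    load = np.asarray(load_bw, dtype=float) * body_weight
    return float(np.trapezoid(np.maximum(0.0, load - threshold_bw * body_weight), t))


# ---------------------------------------------------------------------------
# full evaluation
# ---------------------------------------------------------------------------

def evaluate(traj, config: ObjectiveConfig | None = None,
             events=None, loads=None) -> ObjectiveReport:
    """Score one rollout; failed rollouts get the failure floor plus shaping."""
    config = config or ObjectiveConfig()
    rep = ObjectiveReport()
    if traj.failed or len(traj.t) < 3:
        rep.failed = True
        rep.j_total = config.failure_cost + 10.0 * _shaping(traj, config)
        return rep

    from .analysis_io import detect_events
    if events is None:
        events = detect_events(traj)

    dof_names = traj.arrays.dof_names
    t = traj.t
    rep.j_velocity = velocity_term(traj, config.v_min, events=events, config=config)
    for name, (lo, hi) in config.range_limits.items():
        if name in dof_names:
            series = np.rad2deg(traj.q[:, dof_names.index(name)])
            rep.j_range[name] = range_penalty(t, series, lo, hi)
    rep.j_knee_limit = float(np.trapezoid(traj.knee_lim.sum(axis=1), t))
    rep.j_head_acc = head_acc_term(
        t, head_acceleration_series(traj, config.head_point),
        config.head_acc_threshold)
    rep.j_mb, rep.j_act, rep.j_T = effort_terms(traj, events=events)

    # the task is to rise unaided: a rollout that never clears the chair, or
    # that leaves it without ever reaching near-standing pelvis height (a
    # slide-off), is shaped away no matter how cheap it is otherwise
    if traj.arrays.chair_on:
        if events.seat_off is None:
            chair = traj.chair_load()
            tail = chair[traj.t >= traj.t[-1] - 0.5]
            residual = float(tail.mean()) / traj.arrays.body_weight
            rep.j_seatoff = config.w_seatoff * (1.0 + residual)
        rise_short = max(0.0, config.rise_height - float(traj.q[:, 1].max()))
        rep.j_seatoff += config.w_rise * rise_short

    if config.pain_threshold_bw is not None:
        if loads is None:
            loads = joint_load_series(traj)
        leg_i = 0 if config.pain_leg in ("stepping", "left") else 1
        rep.j_pain = pain_term(t, loads[("knee", leg_i)],
                               config.pain_threshold_bw,
                               traj.arrays.body_weight)

    rep.j_total = (rep.j_velocity + rep.j_seatoff + rep.j_range_total
                   + rep.j_knee_limit + rep.j_head_acc
                   + config.w_mb * rep.j_mb + config.w_act * rep.j_act
                   + config.w_T * rep.j_T + rep.j_pain)
    rep.feasible = {
        "velocity": rep.j_velocity == 0.0,
        "ranges": rep.j_range_total == 0.0,
        "knee_limit": rep.j_knee_limit == 0.0,
        "head_acc": rep.j_head_acc == 0.0,
        "pain": rep.j_pain == 0.0,
    }
    return rep
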