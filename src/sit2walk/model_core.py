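"""Planar articulated rigid-body model and forward-dynamics integration.

The skeleton is a kinematic tree of rigid segments in the sagittal plane
(x forward, y up, CCW angles).  The pelvis connects to the ground through a
3-dof planar free joint; every other joint is a pin.  The default build has
11 dof and 20 muscle-tendon units.

Dynamics are exact for tree structures: the mass matrix and bias vector come
from a recursive Newton-Euler inverse-dynamics pass (unit-acceleration
method), and rollouts use fixed-step semi-implicit Euler, which is robust
with stiff compliant contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .contact import ContactSphere, ContactSurface
from .muscle import MuscleConstants, MuscleDef, hill_params_array

__all__ = [
    "SegmentParams", "JointDef", "ModelDefinition", "SystemState", "Trajectory",
    "ModelValidationError", "build_default_model", "compile_model",
    "forward_dynamics", "integrate", "muscle_geometry", "mechanical_energy",
    "point_kinematics", "body_com_kinematics",
]


class ModelValidationError(ValueError):
    pass


@dataclass
class SegmentParams:
    name: str
    mass: float              # kg
    com_offset: tuple        # m, in segment frame
    inertia: float           # kg m^2 about COM, out-of-plane axis
    length: float            # m
    attachment_points: tuple = ()

    def __post_init__(self):
        if self.mass <= 0:
            raise ModelValidationError(f"segment {self.name}: mass must be > 0")
        if self.inertia <= 0:
            raise ModelValidationError(f"segment {self.name}: inertia must be > 0")
        if self.length < 0:
            raise ModelValidationError(f"segment {self.name}: length must be >= 0")


@dataclass
class JointDef:
    name: str
    kind: str                # "planar_free" or "pin"
    parent: str              # segment name or "ground"
    child: str
    anchor_parent: tuple = (0.0, 0.0)   # parent frame (world frame if parent=="ground")
    anchor_child: tuple = (0.0, 0.0)    # must be (0,0): child origin sits at the joint
    range: tuple | None = None          # (lo, hi) rad, informational
    limit_stiffness: float = 0.0

    def __post_init__(self):
        if self.kind not in ("planar_free", "pin"):
            raise ModelValidationError(f"joint {self.name}: unknown kind {self.kind}")
        if tuple(self.anchor_child) != (0.0, 0.0):
            raise ModelValidationError(
                f"joint {self.name}: child frames are anchored at the joint "
                "(anchor_child must be (0, 0))")

    @property
    def ndof(self) -> int:
        return 3 if self.kind == "planar_free" else 1


@dataclass
class ModelDefinition:
    """The full plant description: segments, joints, muscles, contacts."""
    segments: list
    joints: list
    muscles: list = field(default_factory=list)
    contacts: list = field(default_factory=list)      # ContactSphere list
    surfaces: list = field(default_factory=list)      # ContactSurface list
    gravity: float = 9.81
    total_mass: float | None = None
    height: float | None = None
    name: str = "model"
    knee_limit: dict = field(default_factory=lambda: {
        "lo_deg": -120.0, "hi_deg": 10.0, "stiffness": 500.0})
    muscle_constants: MuscleConstants = field(default_factory=MuscleConstants)

    def __post_init__(self):
        seg_mass = sum(s.mass for s in self.segments)
        if self.total_mass is None:
            self.total_mass = seg_mass
        elif abs(self.total_mass - seg_mass) > 1e-6 * max(1.0, seg_mass):
            raise ModelValidationError(
                f"total_mass {self.total_mass} != sum of segment masses {seg_mass}")

    @property
    def ndof(self) -> int:
        return sum(j.ndof for j in self.joints)

    @property
    def dof_names(self):
        names = []
        for j in self.joints:
            if j.kind == "planar_free":
                names += [f"{j.name}_x", f"{j.name}_y", f"{j.name}_tilt"]
            else:
                names.append(j.name)
        return names

    @property
    def muscle_names(self):
        return [m.name for m in self.muscles]

    @property
    def body_weight(self) -> float:
        return self.total_mass * self.gravity

    def validate(self, expect_dof=None, expect_muscles=None):
        free = [j for j in self.joints if j.kind == "planar_free"]
        if len(free) != 1:
            raise ModelValidationError(
                f"exactly one planar_free joint required, found {len(free)}")
        if expect_dof is not None and self.ndof != expect_dof:
            raise ModelValidationError(
                f"DOF count {self.ndof} != expected {expect_dof}")
        seg_names = {s.name for s in self.segments}
        children = set()
        for j in self.joints:
            if j.parent != "ground" and j.parent not in seg_names:
                raise ModelValidationError(f"joint {j.name}: unknown parent {j.parent}")
            if j.child not in seg_names:
                raise ModelValidationError(f"joint {j.name}: unknown child {j.child}")
            if j.child in children:
                raise ModelValidationError(f"segment {j.child} has two parent joints")
            children.add(j.child)
        if children != seg_names:
            orphans = seg_names - children
            raise ModelValidationError(f"segments without a joint: {sorted(orphans)}")
        if expect_muscles is not None and len(self.muscles) != expect_muscles:
            raise ModelValidationError(
                f"muscle count {len(self.muscles)} != expected {expect_muscles}")
        return self


@dataclass
class SystemState:
    t: float
    q: np.ndarray
    qd: np.ndarray
    muscle_activations: np.ndarray | None = None

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.qd = np.asarray(self.qd, dtype=float)
        if self.q.shape != self.qd.shape:
            raise ModelValidationError("q and qd must have the same length")
        if self.muscle_activations is not None:
            a = np.asarray(self.muscle_activations, dtype=float)
            if a.size and (a.min() < -1e-12 or a.max() > 1 + 1e-12):
                raise ModelValidationError("activations must lie in [0, 1]")
            self.muscle_activations = a


# ---------------------------------------------------------------------------
# compiled arrays
# ---------------------------------------------------------------------------

class ModelArrays:
    """Flat-array mirror of a ModelDefinition, ready for the numba kernel."""

    def __init__(self, model: ModelDefinition):
        self.model = model
        segs = model.segments
        joints = model.joints
        # order bodies so parents precede children
        order = []
        placed = {"ground"}
        pending = list(joints)
        while pending:
            progressed = False
            for j in list(pending):
                if j.parent in placed:
                    order.append(j)
                    placed.add(j.child)
                    pending.remove(j)
                    progressed = True
            if not progressed:
                raise ModelValidationError("joint graph is not a rooted tree")
        seg_by_name = {s.name: s for s in segs}

        nb = len(order)
        self.nb = nb
        self.body_names = [j.child for j in order]
        self.body_index = {n: i for i, n in enumerate(self.body_names)}
        self.parent = np.empty(nb, dtype=np.int64)
        self.jtype = np.empty(nb, dtype=np.int64)
        self.jq = np.empty(nb, dtype=np.int64)
        self.anc_p = np.zeros((nb, 2))
        self.mass = np.empty(nb)
        self.inertia = np.empty(nb)
        self.com = np.zeros((nb, 2))

        # dof ordering follows the model's joint list (not the tree order)
        dof_of_joint = {}
        k = 0
        for j in joints:
            dof_of_joint[j.name] = k
            k += j.ndof
        self.ndof = k
        self.dof_names = model.dof_names
        self.dof_kind = np.empty(self.ndof, dtype=np.int64)
        self.dof_body = np.empty(self.ndof, dtype=np.int64)

        for i, j in enumerate(order):
            self.parent[i] = -1 if j.parent == "ground" else self.body_index[j.parent]
            self.jtype[i] = _kernel.JT_FREE if j.kind == "planar_free" else _kernel.JT_PIN
            self.jq[i] = dof_of_joint[j.name]
            self.anc_p[i] = np.asarray(j.anchor_parent, dtype=float)
            s = seg_by_name[j.child]
            self.mass[i] = s.mass
            self.inertia[i] = s.inertia
            self.com[i] = np.asarray(s.com_offset, dtype=float)
            if j.kind == "planar_free":
                kk = dof_of_joint[j.name]
                self.dof_kind[kk] = _kernel.DOF_TX
                self.dof_kind[kk + 1] = _kernel.DOF_TY
                self.dof_kind[kk + 2] = _kernel.DOF_RZ
                self.dof_body[kk:kk + 3] = i
            else:
                kk = dof_of_joint[j.name]
                self.dof_kind[kk] = _kernel.DOF_RZ
                self.dof_body[kk] = i

        # ancestor mask: dof j moves body b
        self.ancm = np.zeros((nb, self.ndof), dtype=np.bool_)
        for b in range(nb):
            chain = []
            cur = b
            while cur >= 0:
                chain.append(cur)
                cur = self.parent[cur]
            for j in range(self.ndof):
                if self.dof_body[j] in chain:
                    self.ancm[b, j] = True

        self.grav = float(model.gravity)

        # --- muscles ---
        muscles = model.muscles
        self.nm = len(muscles)
        self.muscle_names = [m.name for m in muscles]
        maxp = max((len(m.path) for m in muscles), default=2)
        self.fmax = np.array([m.f_max for m in muscles], dtype=float)
        self.lopt = np.array([m.l_opt for m in muscles], dtype=float)
        self.lslack = np.array([m.l_slack for m in muscles], dtype=float)
        self.vmax = np.array([m.v_max for m in muscles], dtype=float)
        self.mp_body = np.zeros((max(self.nm, 1), maxp), dtype=np.int64)
        self.mp_loc = np.zeros((max(self.nm, 1), maxp, 2))
        self.mp_n = np.zeros(max(self.nm, 1), dtype=np.int64)
        self.side = np.zeros(max(self.nm, 1), dtype=np.int64)
        for m_i, m in enumerate(muscles):
            self.mp_n[m_i] = len(m.path)
            self.side[m_i] = 0 if m.side == "left" else 1
            for s_i, (seg, loc) in enumerate(m.path):
                self.mp_body[m_i, s_i] = self.body_index[seg]
                self.mp_loc[m_i, s_i] = np.asarray(loc, dtype=float)
        if self.nm == 0:
            self.fmax = np.zeros(0)
            self.lopt = np.zeros(0)
            self.lslack = np.zeros(0)
            self.vmax = np.zeros(0)
        self.hp = hill_params_array()
        self.tau_act = model.muscle_constants.tau_act
        self.tau_deact = model.muscle_constants.tau_deact

        # --- contact spheres ---
        spheres = model.contacts
        self.ns = len(spheres)
        nssafe = max(self.ns, 1)
        self.sphere_names = []
        self.sp_body = np.zeros(nssafe, dtype=np.int64)
        self.sp_off = np.zeros((nssafe, 2))
        self.sp_r = np.zeros(nssafe)
        self.sp_k = np.zeros(nssafe)
        self.sp_c = np.zeros(nssafe)
        self.sp_mu = np.zeros(nssafe)
        self.sp_target = np.zeros(nssafe, dtype=np.int64)
        self.sp_leg = np.full(nssafe, -1, dtype=np.int64)
        for s_i, sp in enumerate(spheres):
            if abs(sp.exponent - 1.5) > 1e-12:
                raise ModelValidationError("kernel supports Hertz exponent 1.5 only")
            self.sphere_names.append(f"{sp.segment}_{sp.target}{s_i}")
            self.sp_body[s_i] = self.body_index[sp.segment]
            self.sp_off[s_i] = np.asarray(sp.offset, dtype=float)
            self.sp_r[s_i] = sp.radius
            self.sp_k[s_i] = sp.stiffness
            self.sp_c[s_i] = sp.damping
            self.sp_mu[s_i] = sp.friction_mu
            self.sp_target[s_i] = 0 if sp.target == "ground" else 1
            self.sp_leg[s_i] = {"left": 0, "right": 1, None: -1}[sp.leg]

        self.ground_y = 0.0
        self.chair_x0 = 0.0
        self.chair_x1 = 0.0
        self.chair_top = 0.0
        self.chair_on = 0
        for surf in model.surfaces:
            if surf.kind == "ground_plane":
                self.ground_y = surf.ground_y
            elif surf.kind == "chair_box" and surf.enabled:
                self.chair_x0, self.chair_x1 = surf.x_range
                self.chair_top = surf.seat_height
                self.chair_on = 1

        # --- special dofs ---
        dn = self.dof_names
        self.knee_dofs = np.array(
            [dn.index(n) if n in dn else -1 for n in ("knee_l", "knee_r")],
            dtype=np.int64)
        self.knee_lo = np.deg2rad(model.knee_limit["lo_deg"])
        self.knee_hi = np.deg2rad(model.knee_limit["hi_deg"])
        self.knee_k = model.knee_limit["stiffness"]
        self.lumbar_dof = dn.index("lumbar") if "lumbar" in dn else -1
        self.thoracic_dof = dn.index("thoracic") if "thoracic" in dn else -1

        # free-root bookkeeping
        self.pelvis_ty_dof = -1
        for i in range(nb):
            if self.jtype[i] == _kernel.JT_FREE:
                self.pelvis_ty_dof = self.jq[i] + 1
        self.foot_body = np.array(
            [self.body_index.get("foot_l", 0), self.body_index.get("foot_r", 0)],
            dtype=np.int64)
        self.body_weight = model.body_weight

    # convenience -----------------------------------------------------------
    def kin(self, q, qd=None):
        th = np.empty(self.nb)
        p = np.empty((self.nb, 2))
        w = np.empty(self.nb)
        v = np.empty((self.nb, 2))
        qd = np.zeros(self.ndof) if qd is None else np.asarray(qd, dtype=float)
        _kernel.kinematics(self.nb, self.parent, self.jtype, self.jq, self.anc_p,
                           np.asarray(q, dtype=float), qd, th, p, w, v)
        return th, p, w, v


def compile_model(model: ModelDefinition) -> ModelArrays:
    if isinstance(model, ModelArrays):
        return model
    return ModelArrays(model)


def build_default_model(config: dict) -> ModelDefinition:
    """Build and validate a model from a nested config record.

    The fixtures module generates the default record (75 kg, 1.80 m, 11 dof,
    20 muscles); any dict with the same schema works.
    """
    segments = [SegmentParams(**s) for s in config["segments"]]
    joints = [JointDef(**j) for j in config["joints"]]
    muscles = [MuscleDef(
        name=m["name"], f_max=m["f_max"], l_opt=m["l_opt"],
        l_slack=m["l_slack"], v_max=m.get("v_max", 10.0), side=m["side"],
        path=[(p["segment"], tuple(p["point"])) for p in m["path"]],
    ) for m in config.get("muscles", [])]
    spheres = [ContactSphere(
        segment=c["segment"], offset=tuple(c["offset"]), radius=c["radius"],
        stiffness=c["stiffness"], exponent=c.get("exponent", 1.5),
        damping=c.get("damping", 1.0), friction_mu=c.get("friction", 0.9),
        target=c.get("target", "ground"), leg=c.get("leg"),
    ) for c in config.get("contact_spheres", [])]
    surfaces = [ContactSurface(
        kind=s["kind"], seat_height=s.get("seat_height", 0.46),
        x_range=tuple(s.get("x_range", (-0.35, 0.08))),
        ground_y=s.get("ground_y", 0.0), enabled=s.get("enabled", True),
    ) for s in config.get("surfaces", [])]
    model = ModelDefinition(
        segments=segments, joints=joints, muscles=muscles, contacts=spheres,
        surfaces=surfaces, gravity=config.get("gravity", 9.81),
        total_mass=config.get("total_mass"), height=config.get("height"),
        name=config.get("name", "model"),
        knee_limit=config.get("knee_limit",
                              {"lo_deg": -120.0, "hi_deg": 10.0, "stiffness": 500.0}),
    )
    model.validate(expect_dof=config.get("expect_dof"),
                   expect_muscles=config.get("expect_muscles"))
    return model


# ---------------------------------------------------------------------------
# dynamics wrappers
# ---------------------------------------------------------------------------

def forward_dynamics(model, state: SystemState, applied=None, free_mask=None):
    """Generalized accelerations solving M(q) qdd = applied - bias(q, qd)."""
    arrays = compile_model(model)
    applied = np.zeros(arrays.ndof) if applied is None else np.asarray(applied, dtype=float)
    if free_mask is None:
        free_mask = np.ones(arrays.ndof, dtype=np.bool_)
    qdd = np.empty(arrays.ndof)
    _kernel.forward_dynamics(
        arrays.nb, arrays.ndof, arrays.parent, arrays.jtype, arrays.jq,
        arrays.anc_p, arrays.mass, arrays.inertia, arrays.com, arrays.grav,
        state.q, state.qd, applied, np.asarray(free_mask, dtype=np.bool_), qdd)
    return qdd


def muscle_geometry(model, q):
    """Per-muscle MTU lengths and moment arms.

    Moment arm about dof j is defined as -dL/dq_j: positive arm means the
    muscle's pull drives the joint toward positive angle.
    """
    arrays = compile_model(model)
    th, p, _, _ = arrays.kin(q)
    L = np.zeros(arrays.nm)
    dLdq = np.zeros((arrays.nm, arrays.ndof))
    if arrays.nm:
        _kernel.muscle_geometry(arrays.nm, arrays.ndof, th, p, arrays.ancm,
                                arrays.dof_kind, arrays.dof_body,
                                arrays.mp_body, arrays.mp_loc, arrays.mp_n,
                                L, dLdq)
    return L, -dLdq


@dataclass
class Trajectory:
    """Time series produced by one rollout (output-rate sampled)."""
    model: ModelDefinition
    t: np.ndarray
    q: np.ndarray
    qd: np.ndarray
    qdd: np.ndarray
    u: np.ndarray
    a: np.ndarray
    F: np.ndarray
    lnorm: np.ndarray
    vnorm: np.ndarray
    sph_f: np.ndarray
    sph_n: np.ndarray
    trunk_tau: np.ndarray
    knee_lim: np.ndarray
    mode: np.ndarray
    phase: np.ndarray
    status: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def failed(self) -> bool:
        return self.status != 0

    @property
    def arrays(self) -> ModelArrays:
        if "_arrays" not in self.meta:
            self.meta["_arrays"] = compile_model(self.model)
        return self.meta["_arrays"]

    def column_names(self):
        ar = self.arrays
        cols = ["time"]
        cols += [f"q_{n}" for n in ar.dof_names]
        cols += [f"qd_{n}" for n in ar.dof_names]
        cols += [f"qdd_{n}" for n in ar.dof_names]
        for pre in ("u", "a", "F", "lnorm", "vnorm"):
            cols += [f"{pre}_{n}" for n in ar.muscle_names]
        for n in ar.sphere_names:
            cols += [f"c_{n}_fx", f"c_{n}_fy", f"c_{n}_fn"]
        cols += ["trunk_tau_lumbar", "trunk_tau_thoracic",
                 "knee_lim_l", "knee_lim_r", "mode", "phase_l", "phase_r"]
        return cols

    def to_matrix(self):
        blocks = [self.t[:, None], self.q, self.qd, self.qdd,
                  self.u, self.a, self.F, self.lnorm, self.vnorm]
        for s in range(self.sph_n.shape[1]):
            blocks += [self.sph_f[:, s, 0][:, None], self.sph_f[:, s, 1][:, None],
                       self.sph_n[:, s][:, None]]
        blocks += [self.trunk_tau, self.knee_lim,
                   self.mode[:, None].astype(float), self.phase.astype(float)]
        return np.hstack(blocks)

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.to_matrix(), columns=self.column_names())

    def chair_load(self):
        ar = self.arrays
        sel = ar.sp_target[:ar.ns] == 1
        return self.sph_n[:, sel].sum(axis=1) if sel.any() else np.zeros(len(self.t))

    def leg_grf(self, leg: int):
        ar = self.arrays
        sel = (ar.sp_leg[:ar.ns] == leg) & (ar.sp_target[:ar.ns] == 0)
        return self.sph_n[:, sel].sum(axis=1) if sel.any() else np.zeros(len(self.t))


def integrate(model, initial_state: SystemState, controller=None,
              duration: float = 1.0, dt: float = 5e-4, out_dt: float = 0.01,
              free_mask=None, fall_y: float | None = None,
              qd_cap: float = 50.0) -> Trajectory:
    """Roll the scene forward with fixed-step semi-implicit Euler.

    ``controller`` is a :class:`sit2walk.controller.ReflexController` (or
    None for a passive scene).  A blow-up or fall marks the trajectory as
    failed rather than raising.
    """
    arrays = compile_model(model)
    ndof, nm, ns = arrays.ndof, arrays.nm, arrays.ns
    if dt <= 0:
        raise ValueError("dt must be positive")
    out_every = max(1, int(round(out_dt / dt)))
    nsteps = int(round(duration / dt))
    n_out = nsteps // out_every + 1

    q0 = np.asarray(initial_state.q, dtype=float).copy()
    qd0 = np.asarray(initial_state.qd, dtype=float).copy()
    a0 = np.zeros(nm)
    if initial_state.muscle_activations is not None and nm:
        a0[:] = initial_state.muscle_activations
    if free_mask is None:
        free_mask = np.ones(ndof, dtype=np.bool_)
    free_mask = np.asarray(free_mask, dtype=np.bool_)
    fall = -1e9 if fall_y is None else float(fall_y)

    if controller is not None:
        ct = controller.dense()
        ctrl_on = True
        cdt = controller.control_dt
    else:
        from .controller import ReflexController
        ct = ReflexController.zeros(nm).dense()
        ctrl_on = False
        cdt = 0.005

    nm1, ns1 = max(nm, 1), max(ns, 1)
    o_t = np.zeros(n_out)
    o_q = np.zeros((n_out, ndof))
    o_qd = np.zeros((n_out, ndof))
    o_qdd = np.zeros((n_out, ndof))
    o_u = np.zeros((n_out, nm1))
    o_a = np.zeros((n_out, nm1))
    o_F = np.zeros((n_out, nm1))
    o_ln = np.zeros((n_out, nm1))
    o_vn = np.zeros((n_out, nm1))
    o_sphf = np.zeros((n_out, ns1, 2))
    o_sphn = np.zeros((n_out, ns1))
    o_trunk = np.zeros((n_out, 2))
    o_klim = np.zeros((n_out, 2))
    o_mode = np.zeros(n_out, dtype=np.int64)
    o_phase = np.zeros((n_out, 2), dtype=np.int64)

    n_rec, status = _kernel.rollout(
        arrays.nb, ndof, arrays.parent, arrays.jtype, arrays.jq, arrays.anc_p,
        arrays.mass, arrays.inertia, arrays.com, arrays.grav,
        arrays.ancm, arrays.dof_kind, arrays.dof_body,
        nm, arrays.fmax, arrays.lopt, arrays.lslack, arrays.vmax,
        arrays.mp_body, arrays.mp_loc, arrays.mp_n, arrays.hp,
        arrays.tau_act, arrays.tau_deact,
        ns, arrays.sp_body, arrays.sp_off, arrays.sp_r, arrays.sp_k,
        arrays.sp_c, arrays.sp_mu, arrays.sp_target, arrays.sp_leg,
        arrays.ground_y, arrays.chair_x0, arrays.chair_x1, arrays.chair_top,
        arrays.chair_on,
        arrays.knee_dofs, arrays.knee_lo, arrays.knee_hi, arrays.knee_k,
        arrays.lumbar_dof, arrays.thoracic_dof,
        ctrl_on,
        ct.st_KC, ct.st_KL, ct.st_LO, ct.st_KFp, ct.st_KFm, ct.st_KP, ct.st_KV,
        ct.st_theta_o, ct.st_trunk,
        ct.g_KC, ct.g_KL, ct.g_LO, ct.g_KF, ct.g_KFm, ct.g_KP, ct.g_KV,
        ct.g_theta_o, ct.g_trunk,
        ct.ant, arrays.side, ct.delays, ct.delay_vest,
        ct.t_state2, ct.t_gait, ct.stance_thr, ct.d_latestance, ct.d_landing,
        q0, qd0, a0, free_mask, float(duration), float(dt), float(cdt),
        out_every, arrays.body_weight, arrays.foot_body, arrays.pelvis_ty_dof,
        fall, qd_cap,
        o_t, o_q, o_qd, o_qdd, o_u, o_a, o_F, o_ln, o_vn, o_sphf, o_sphn,
        o_trunk, o_klim, o_mode, o_phase,
    )
    sl = slice(0, n_rec)
    return Trajectory(
        model=model, t=o_t[sl].copy(), q=o_q[sl].copy(), qd=o_qd[sl].copy(),
        qdd=o_qdd[sl].copy(), u=o_u[sl, :nm].copy(), a=o_a[sl, :nm].copy(),
        F=o_F[sl, :nm].copy(), lnorm=o_ln[sl, :nm].copy(),
        vnorm=o_vn[sl, :nm].copy(), sph_f=o_sphf[sl, :ns].copy(),
        sph_n=o_sphn[sl, :ns].copy(), trunk_tau=o_trunk[sl].copy(),
        knee_lim=o_klim[sl].copy(), mode=o_mode[sl].copy(),
        phase=o_phase[sl].copy(), status=int(status),
        meta={"dt": dt, "out_dt": out_dt, "duration": duration})


# ---------------------------------------------------------------------------
# kinematic helpers (python-side, used by analysis at output rate)
# ---------------------------------------------------------------------------

def body_com_kinematics(arrays: ModelArrays, q, qd, qdd=None):
    """Per-body COM position/velocity/acceleration by propagating the tree."""
    nb = arrays.nb
    th, p, w, v = arrays.kin(q, qd)
    qdd = np.zeros(arrays.ndof) if qdd is None else np.asarray(qdd, dtype=float)
    a = np.zeros((nb, 2))
    al = np.zeros(nb)
    for i in range(nb):
        pa = arrays.parent[i]
        kq = arrays.jq[i]
        if pa == -1:
            if arrays.jtype[i] == _kernel.JT_FREE:
                a[i] = qdd[kq:kq + 2]
                al[i] = qdd[kq + 2]
            else:
                a[i] = 0.0
                al[i] = qdd[kq]
        else:
            r = p[i] - p[pa]
            a[i, 0] = a[pa, 0] - al[pa] * r[1] - w[pa] ** 2 * r[0]
            a[i, 1] = a[pa, 1] + al[pa] * r[0] - w[pa] ** 2 * r[1]
            al[i] = al[pa] + qdd[kq]
    com_p = np.zeros((nb, 2))
    com_v = np.zeros((nb, 2))
    com_a = np.zeros((nb, 2))
    for i in range(nb):
        c, s = np.cos(th[i]), np.sin(th[i])
        rc = np.array([c * arrays.com[i, 0] - s * arrays.com[i, 1],
                       s * arrays.com[i, 0] + c * arrays.com[i, 1]])
        com_p[i] = p[i] + rc
        com_v[i] = v[i] + w[i] * np.array([-rc[1], rc[0]])
        com_a[i, 0] = a[i, 0] - al[i] * rc[1] - w[i] ** 2 * rc[0]
        com_a[i, 1] = a[i, 1] + al[i] * rc[0] - w[i] ** 2 * rc[1]
    return com_p, com_v, com_a, th, p, w, al


def point_kinematics(model, q, qd, qdd, segment: str, loc):
    """World position/velocity/acceleration of a point fixed on a segment."""
    arrays = compile_model(model)
    b = arrays.body_index[segment]
    com_p, com_v, com_a, th, p, w, al = body_com_kinematics(arrays, q, qd, qdd)
    # redo with the requested point instead of the COM
    c, s = np.cos(th[b]), np.sin(th[b])
    loc = np.asarray(loc, dtype=float)
    r = np.array([c * loc[0] - s * loc[1], s * loc[0] + c * loc[1]])
    # body origin acceleration = com_a - (al x rc - w^2 rc)
    cc = np.array([c * arrays.com[b, 0] - s * arrays.com[b, 1],
                   s * arrays.com[b, 0] + c * arrays.com[b, 1]])
    a_origin = com_a[b] - np.array([-al[b] * cc[1] - w[b] ** 2 * cc[0],
                                    al[b] * cc[0] - w[b] ** 2 * cc[1]])
    v_origin = com_v[b] - w[b] * np.array([-cc[1], cc[0]])
    pos = p[b] + r
    vel = v_origin + w[b] * np.array([-r[1], r[0]])
    acc = a_origin + np.array([-al[b] * r[1] - w[b] ** 2 * r[0],
                               al[b] * r[0] - w[b] ** 2 * r[1]])
    return pos, vel, acc


def mechanical_energy(model, state: SystemState):
    """(kinetic, potential) mechanical energy of the articulated body."""
    arrays = compile_model(model)
    com_p, com_v, _, th, p, w, _ = body_com_kinematics(arrays, state.q, state.qd)
    ke = 0.0
    pe = 0.0
    for i in range(arrays.nb):
        ke += 0.5 * arrays.mass[i] * (com_v[i] @ com_v[i]) \
            + 0.5 * arrays.inertia[i] * w[i] ** 2
    pe = float((arrays.mass * com_p[:, 1]).sum() * arrays.grav)
    return float(ke), pe


def _sphere_forces_at_state(arrays: ModelArrays, q, qd):
    """Contact forces of every sphere at one state (python-side)."""
    th, p, w, v = arrays.kin(q, qd)
    forces = np.zeros((arrays.ns, 2))
    normals = np.zeros(arrays.ns)
    for s in range(arrays.ns):
        b = arrays.sp_body[s]
        cx, cy = _kernel.point_world(th, p, b, arrays.sp_off[s, 0], arrays.sp_off[s, 1])
        rx, ry = cx - p[b, 0], cy - p[b, 1]
        vx = v[b, 0] - w[b] * ry
        vy = v[b, 1] + w[b] * rx
        fx, fy, fn, _, _ = _kernel.contact_sphere_force(
            cx, cy, vx, vy, arrays.sp_r[s], arrays.sp_k[s], arrays.sp_c[s],
            arrays.sp_mu[s], arrays.sp_target[s], arrays.ground_y,
            arrays.chair_x0, arrays.chair_x1, arrays.chair_top, arrays.chair_on)
        forces[s] = (fx, fy)
        normals[s] = fn
    return forces, normals
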