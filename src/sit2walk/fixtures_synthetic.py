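"""Generators for every input the package needs: the default model record,
toy oracle scenes, the reduced desk-scale study preset, baseline controller
parameters, and synthetic reference envelopes for plot overlays.

The default plant emulates a planar male adult of 1.80 m and 75 kg with 11
degrees of freedom and 20 Hill-type muscles (10 per leg: ILPSO, GMAX, HAM,
BFSH, RF, VAS, GASM, GASL, SOL, TA; gastrocnemius is split into medial and
lateral heads to reach 10).  Segment inertial parameters follow standard
anthropometric tables (Winter-style mass fractions and radii of gyration)
scaled to total height and mass; arm and head mass is folded into the torso
segment, as usual for planar models.

Tendon slack lengths are calibrated so each MTU sits at optimal fiber length
in a mid-range reference pose, which keeps every muscle on a useful part of
its force-length curve across the sit-to-walk motion.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import model_core
from .model_core import (ModelDefinition, SegmentParams, JointDef, SystemState,
                         build_default_model)

__all__ = [
    "default_model_config", "default_model", "default_model_file",
    "seated_initial_state", "ToyScene", "toy_scenes", "DeskPreset",
    "desk_preset", "baseline_params", "synthetic_envelopes", "SyntheticEnvelope",
]

HEIGHT = 1.80
TOTAL_MASS = 75.0
SEAT_HEIGHT = 0.46

# segment lengths (m), fractions of height per standard tables
FOOT_LEN = 0.152 * HEIGHT      # 0.2736
ANKLE_H = 0.039 * HEIGHT       # 0.0702
SHANK_LEN = 0.246 * HEIGHT     # 0.4428
THIGH_LEN = 0.245 * HEIGHT     # 0.4410
LUMBAR_OFF = 0.12              # pelvis origin (hip) -> lumbar joint
ABDOMEN_LEN = 0.18             # lumbar joint -> thoracic joint

_R6 = lambda x: float(round(float(x), 6))


def _segment_table():
    m_foot = 0.0145 * TOTAL_MASS
    m_shank = 0.0465 * TOTAL_MASS
    m_thigh = 0.100 * TOTAL_MASS
    m_pelvis = 0.142 * TOTAL_MASS
    m_abd = 0.139 * TOTAL_MASS
    m_torso = TOTAL_MASS - 2 * (m_foot + m_shank + m_thigh) - m_pelvis - m_abd
    torso_len = HEIGHT - (ANKLE_H + SHANK_LEN + THIGH_LEN + LUMBAR_OFF + ABDOMEN_LEN)
    segs = []

    def seg(name, mass, com, rog_frac, length):
        segs.append(dict(name=name, mass=_R6(mass),
                         com_offset=[_R6(com[0]), _R6(com[1])],
                         inertia=_R6(max(mass * (rog_frac * max(length, 0.1)) ** 2, 1e-4)),
                         length=_R6(length)))

    seg("pelvis", m_pelvis, (-0.02, 0.05), 0.50, 0.20)
    for sd in ("l", "r"):
        seg(f"thigh_{sd}", m_thigh, (0.0, -0.433 * THIGH_LEN), 0.323, THIGH_LEN)
        seg(f"shank_{sd}", m_shank, (0.0, -0.433 * SHANK_LEN), 0.302, SHANK_LEN)
        seg(f"foot_{sd}", m_foot, (0.06, -0.04), 0.475, FOOT_LEN)
    seg("torso_lower", m_abd, (0.0, 0.5 * ABDOMEN_LEN), 0.45, ABDOMEN_LEN)
    seg("torso", m_torso, (0.0, 0.28), 0.35, torso_len)
    return segs


def _joint_table():
    joints = [dict(name="pelvis_ground", kind="planar_free",
                   parent="ground", child="pelvis")]
    for sd in ("l", "r"):
        joints += [
            dict(name=f"hip_{sd}", kind="pin", parent="pelvis", child=f"thigh_{sd}",
                 anchor_parent=[0.0, 0.0]),
            dict(name=f"knee_{sd}", kind="pin", parent=f"thigh_{sd}",
                 child=f"shank_{sd}", anchor_parent=[0.0, _R6(-THIGH_LEN)]),
            dict(name=f"ankle_{sd}", kind="pin", parent=f"shank_{sd}",
                 child=f"foot_{sd}", anchor_parent=[0.0, _R6(-SHANK_LEN)]),
        ]
    joints += [
        dict(name="lumbar", kind="pin", parent="pelvis", child="torso_lower",
             anchor_parent=[0.0, LUMBAR_OFF]),
        dict(name="thoracic", kind="pin", parent="torso_lower", child="torso",
             anchor_parent=[0.0, ABDOMEN_LEN]),
    ]
    return joints


# muscle architecture: (f_max N, l_opt m, path in segment frames).  Paths use
# pulley-style via points near the hip (pelvic brim for ILPSO) and knee
# (patellar mechanism for VAS/RF) so moment arms stay physiological from
# deep seated flexion through upright standing.
_MUSCLE_TABLE = {
    "ILPSO": (1500.0, 0.10, [("pelvis", (0.05, 0.05)), ("pelvis", (0.04, -0.01)),
                             ("thigh", (0.0, -0.04)), ("thigh", (0.015, -0.12))]),
    "GMAX": (3000.0, 0.14, [("pelvis", (-0.07, 0.04)), ("pelvis", (-0.065, -0.055)),
                            ("thigh", (-0.03, -0.15))]),
    "HAM": (3000.0, 0.10, [("pelvis", (-0.065, -0.05)), ("shank", (-0.03, -0.045))]),
    "BFSH": (800.0, 0.12, [("thigh", (-0.02, -0.30)), ("shank", (-0.03, -0.045))]),
    "RF": (1200.0, 0.09, [("pelvis", (0.05, 0.01)), ("thigh", (0.06, -0.431)),
                          ("shank", (0.06, -0.01))]),
    "VAS": (6000.0, 0.11, [("thigh", (0.035, -0.12)), ("thigh", (0.06, -0.431)),
                           ("shank", (0.06, -0.01))]),
    "GASM": (1150.0, 0.09, [("thigh", (-0.02, -0.425)), ("foot", (-0.055, -0.03))]),
    "GASL": (650.0, 0.09, [("thigh", (-0.025, -0.425)), ("foot", (-0.06, -0.03))]),
    "SOL": (3500.0, 0.04, [("shank", (-0.03, -0.15)), ("foot", (-0.06, -0.03))]),
    "TA": (900.0, 0.07, [("shank", (0.033, -0.20)), ("foot", (0.055, 0.01))]),
}

#: mid-range reference pose used to calibrate tendon slack lengths
_REF_POSE = {"hip": 0.9, "knee": -0.9, "ankle": 0.05, "lumbar": -0.2, "thoracic": 0.0}


def _muscle_table(side):
    sd = "l" if side == "left" else "r"
    out = []
    for g in ("ILPSO", "GMAX", "HAM", "BFSH", "RF", "VAS", "GASM", "GASL", "SOL", "TA"):
        fmax, lopt, path = _MUSCLE_TABLE[g]
        full_path = []
        for seg, pt in path:
            seg_name = seg if seg == "pelvis" else f"{seg}_{sd}"
            full_path.append(dict(segment=seg_name, point=[_R6(pt[0]), _R6(pt[1])]))
        out.append(dict(name=f"{g}_{sd}", side=side, f_max=fmax, l_opt=lopt,
                        l_slack=0.0, v_max=10.0, path=full_path))
    return out


def _contact_table():
    spheres = []
    for sd, leg in (("l", "left"), ("r", "right")):
        spheres += [
            dict(segment=f"foot_{sd}", offset=[-0.04, -0.04], radius=0.03,
                 stiffness=5e6, damping=1.0, friction=1.3, target="ground", leg=leg),
            dict(segment=f"foot_{sd}", offset=[0.16, -0.045], radius=0.025,
                 stiffness=5e6, damping=1.0, friction=1.3, target="ground", leg=leg),
        ]
    # two buttock spheres on the pelvis meeting the chair box
    spheres += [
        dict(segment="pelvis", offset=[-0.06, -0.02], radius=0.06,
             stiffness=2e5, damping=1.0, friction=0.8, target="chair", leg=None),
        dict(segment="pelvis", offset=[-0.11, -0.02], radius=0.06,
             stiffness=2e5, damping=1.0, friction=0.8, target="chair", leg=None),
    ]
    return spheres


def default_model_config(seat_height: float = SEAT_HEIGHT) -> dict:
    """The full H1120-like model record (deterministic, no timestamps)."""
    cfg = dict(
        name="h1120_planar",
        gravity=9.81,
        total_mass=TOTAL_MASS,
        height=HEIGHT,
        expect_dof=11,
        expect_muscles=20,
        anthropometry_source="Winter body-segment tables scaled to 1.80 m / 75 kg",
        segments=_segment_table(),
        joints=_joint_table(),
        muscles=_muscle_table("left") + _muscle_table("right"),
        contact_spheres=_contact_table(),
        surfaces=[
            dict(kind="ground_plane", ground_y=0.0),
            dict(kind="chair_box", seat_height=float(seat_height),
                 x_range=[-0.35, 0.10], enabled=True),
        ],
        knee_limit=dict(lo_deg=-120.0, hi_deg=10.0, stiffness=500.0),
    )
    _calibrate_slack_lengths(cfg)
    return cfg


def _calibrate_slack_lengths(cfg):
    """Set l_slack so l~ = 1 at the mid-range reference pose."""
    tmp = copy.deepcopy(cfg)
    for m in tmp["muscles"]:
        m["l_slack"] = 0.001
    tmp.pop("expect_muscles")
    model = build_default_model(tmp)
    q = np.zeros(11)
    names = model.dof_names
    for i, n in enumerate(names):
        for key, val in _REF_POSE.items():
            if n.startswith(key):
                q[i] = val
    L, _ = model_core.muscle_geometry(model, q)
    for mi, m in enumerate(cfg["muscles"]):
        slack = L[mi] - m["l_opt"]
        # extra slack for the biarticular calves: the deep-squat start combines
        # deep knee flexion with dorsiflexion, which would otherwise leave the
        # gastrocnemii passively taut enough to lift the heels
        if m["name"].startswith(("GASM", "GASL")):
            slack += 0.02
        if slack <= 0.005:
            raise ValueError(f"calibrated l_slack for {m['name']} is non-physical")
        m["l_slack"] = _R6(slack)


def default_model(seat_height: float = SEAT_HEIGHT) -> ModelDefinition:
    return build_default_model(default_model_config(seat_height))


def default_model_file(out_path) -> str:
    """Write the default model record as canonical YAML (byte-stable)."""
    cfg = default_model_config()
    text = yaml.safe_dump(cfg, sort_keys=True, default_flow_style=None, width=100)
    with open(out_path, "w") as fh:
        fh.write(text)
    return str(out_path)


def seated_initial_state(model: ModelDefinition | None = None) -> SystemState:
    """Seated start: trunk upright, thighs near horizontal, feet flat."""
    q = np.zeros(11)
    names = (model or default_model()).dof_names
    # pelvis height chosen so the buttock spheres carry load on the seat pan;
    # hip/knee/ankle follow from two-link leg IK with the feet flat at
    # ankle height and ~0.44 m ahead of the pelvis
    yp, x0, ax_x, ax_y = 0.53, 0.0, 0.20, 0.071
    l1, l2 = THIGH_LEN, SHANK_LEN
    dx, dy = ax_x, yp - ax_y
    D = np.hypot(dx, dy)
    inner = np.arccos(np.clip((l1 ** 2 + l2 ** 2 - D ** 2) / (2 * l1 * l2), -1, 1))
    knee = -(np.pi - inner)
    alpha = np.arccos(np.clip((l1 ** 2 + D ** 2 - l2 ** 2) / (2 * l1 * D), -1, 1))
    hip = np.arctan2(dx, dy) + alpha
    ankle = -(hip + knee)
    pose = {
        "pelvis_ground_x": x0, "pelvis_ground_y": yp, "pelvis_ground_tilt": 0.0,
        "hip_l": hip, "knee_l": knee, "ankle_l": ankle,
        "hip_r": hip, "knee_r": knee, "ankle_r": ankle,
        "lumbar": 0.0, "thoracic": 0.0,
    }
    for i, n in enumerate(names):
        q[i] = pose[n]
    return SystemState(t=0.0, q=q, qd=np.zeros(11))


# ---------------------------------------------------------------------------
# toy scenes
# ---------------------------------------------------------------------------

@dataclass
class ToyScene:
    name: str
    model: ModelDefinition
    closed_form: str
    initial_state: SystemState = None
    oracle: object = None
    free_mask: np.ndarray = None


def _pendulum_scene(length=1.0, mass=1.0, pivot=(0.0, 1.5)):
    seg = SegmentParams(name="rod", mass=mass, com_offset=(0.0, -length),
                        inertia=1e-6, length=length)
    jnt = JointDef(name="pivot", kind="pin", parent="ground", child="rod",
                   anchor_parent=pivot)
    model = ModelDefinition(segments=[seg], joints=[jnt], name="pendulum")

    def qdd_oracle(theta):
        # point-mass physical pendulum about the pivot
        d = length
        i_piv = 1e-6 + mass * d * d
        return -mass * 9.81 * d * np.sin(theta) / i_piv

    return ToyScene(
        name="pendulum", model=model,
        closed_form="qdd = -(m g d / I_pivot) sin(theta); period 2*pi*sqrt(L/g)",
        initial_state=SystemState(0.0, [0.3], [0.0]), oracle=qdd_oracle)


def _double_pendulum_scene():
    l1, l2 = 0.6, 0.5
    segs = [
        SegmentParams(name="link1", mass=1.5, com_offset=(0.0, -0.3),
                      inertia=0.02, length=l1),
        SegmentParams(name="link2", mass=1.0, com_offset=(0.0, -0.25),
                      inertia=0.01, length=l2),
    ]
    joints = [
        JointDef(name="j1", kind="pin", parent="ground", child="link1",
                 anchor_parent=(0.0, 1.5)),
        JointDef(name="j2", kind="pin", parent="link1", child="link2",
                 anchor_parent=(0.0, -l1)),
    ]
    model = ModelDefinition(segments=segs, joints=joints, name="double_pendulum")
    return ToyScene(
        name="double_pendulum", model=model,
        closed_form="Lagrangian 2-link dynamics (symbolic oracle in tests)",
        initial_state=SystemState(0.0, [0.4, -0.2], [0.1, 0.3]))


def _lever_muscle_scene():
    from .muscle import MuscleDef
    segs = [
        SegmentParams(name="base", mass=5.0, com_offset=(0.0, 0.1),
                      inertia=0.05, length=0.4),
        SegmentParams(name="lever", mass=1.0, com_offset=(0.15, 0.0),
                      inertia=0.01, length=0.3),
    ]
    joints = [
        JointDef(name="ground_base", kind="pin", parent="ground", child="base",
                 anchor_parent=(0.0, 0.0)),
        JointDef(name="elbow", kind="pin", parent="base", child="lever",
                 anchor_parent=(0.0, 0.3)),
    ]
    mus = MuscleDef(name="flexor_l", f_max=1000.0, l_opt=0.10, l_slack=0.15,
                    path=[("base", (-0.04, 0.05)), ("lever", (0.10, 0.02))],
                    side="left")
    model = ModelDefinition(segments=segs, joints=joints, muscles=[mus],
                            name="lever_muscle")
    return ToyScene(
        name="lever_muscle", model=model,
        closed_form="isometric joint torque = F(a, l~, 0) x moment arm",
        initial_state=SystemState(0.0, [0.0, 0.3], [0.0, 0.0]),
        free_mask=np.array([False, True]))


def _drop_test_scene():
    from .contact import ContactSphere, ContactSurface
    seg = SegmentParams(name="ball", mass=5.0, com_offset=(0.0, 0.0),
                        inertia=0.02, length=0.2)
    jnt = JointDef(name="ball_ground", kind="planar_free", parent="ground",
                   child="ball")
    sphere = ContactSphere(segment="ball", offset=(0.0, 0.0), radius=0.1,
                           stiffness=1e5, friction_mu=0.8, target="ground")
    model = ModelDefinition(segments=[seg], joints=[jnt], contacts=[sphere],
                            surfaces=[ContactSurface(kind="ground_plane")],
                            name="drop_test")
    return ToyScene(
        name="drop_test", model=model,
        closed_form="settled Hunt-Crossley contact force = m g",
        initial_state=SystemState(0.0, [0.0, 0.12, 0.0], [0.0, 0.0, 0.0]))


def _seated_static_scene():
    model = default_model()
    state = seated_initial_state(model)
    mask = np.zeros(11, dtype=bool)
    mask[model.dof_names.index("pelvis_ground_y")] = True
    return ToyScene(
        name="seated_static", model=model,
        closed_form="settled chair + ground normal loads = body weight (735.75 N)",
        initial_state=state, free_mask=mask)


def toy_scenes() -> dict:
    """All toy oracle scenes keyed by name."""
    scenes = [_pendulum_scene(), _double_pendulum_scene(), _lever_muscle_scene(),
              _drop_test_scene(), _seated_static_scene()]
    return {s.name: s for s in scenes}


# ---------------------------------------------------------------------------
# study presets and baseline controller parameters
# ---------------------------------------------------------------------------

@dataclass
class DeskPreset:
    """Reduced problem sizes for the desk-scale study (stand-up + first steps)."""
    duration: float = 2.5        # s horizon: rise + gait initiation
    dt: float = 1e-3             # s physics step
    control_dt: float = 5e-3     # s reflex sampling
    out_dt: float = 0.01         # s output sampling
    popsize: int = 10
    generations: int = 30
    n_parallel: int = 3          # independent restarts per condition, best kept
    sigma0: float = 0.03
    freeze_gait: bool = True     # gait-block parameters stay at the baseline
    fall_y: float = 0.40
    seat_height: float = SEAT_HEIGHT


def desk_preset() -> DeskPreset:
    return DeskPreset()


@dataclass
class FullPreset:
    duration: float = 5.0
    dt: float = 5e-4
    control_dt: float = 5e-3
    out_dt: float = 0.01
    popsize: int = 10
    generations: int = 2000
    n_parallel: int = 3
    sigma0: float = 0.05
    freeze_gait: bool = False
    fall_y: float = 0.40
    seat_height: float = SEAT_HEIGHT


def baseline_params() -> dict:
    """Hand-tuned structured controller parameters: the optimization seed.

    The standing-up strategy is a slow stoop: state 1 folds the trunk far
    forward over anchored feet (soft lumbar PD plus hamstring/tibialis tone)
    until the center of mass travels over the base of support; state 2
    extends knees and hips through length-feedback servos that fade as the
    joints straighten, with plantarflexor push and pelvis-tilt (vestibular)
    balance reflexes.  The gait block is a conservative phase-gated reflex
    stepper used as the warm start of the gait controller.
    """
    p = {}
    # ---- standing state 1: slow stoop lean, feet anchored ----
    p.update({
        "st0_lumbar_set": -0.85, "st0_lumbar_kp": 70.0, "st0_lumbar_kv": 25.0,
        "st0_thoracic_set": -0.25, "st0_thoracic_kp": 50.0, "st0_thoracic_kv": 10.0,
        "st0_HAM_KC": 0.08, "st0_BFSH_KC": 0.1, "st0_TA_KC": 0.05,
        "st0_GASM_KC": 0.03, "st0_GASL_KC": 0.03,
    })
    # ---- standing state 2: rise and catch ----
    p.update({
        "st1_VAS_KC": 0.05, "st1_VAS_KL": 1.5, "st1_VAS_LO": 0.75,
        "st1_VAS_KP": -0.5,
        "st1_GMAX_KC": 0.05, "st1_GMAX_KL": 2.0, "st1_GMAX_LO": 0.72,
        "st1_GMAX_KP": -1.0, "st1_GMAX_KV": -0.5,
        "st1_HAM_KC": 0.1, "st1_HAM_KL": 1.0, "st1_HAM_LO": 0.85,
        "st1_HAM_KP": -1.0,
        "st1_RF_KC": 0.2, "st1_RF_KP": 0.4,
        "st1_SOL_KC": 0.1, "st1_SOL_KP": -1.0, "st1_SOL_KV": -0.5,
        "st1_GASM_KC": 0.08, "st1_GASL_KC": 0.08,
        "st1_TA_KC": 0.02, "st1_TA_KP": 1.0, "st1_TA_KV": 0.4,
        "st1_ILPSO_KP": 1.2, "st1_ILPSO_KV": 0.3,
        "st1_theta_o": -0.2,
        "st1_lumbar_set": -0.6, "st1_lumbar_kp": 150.0, "st1_lumbar_kv": 20.0,
        "st1_thoracic_set": -0.1, "st1_thoracic_kp": 100.0, "st1_thoracic_kv": 10.0,
    })
    p.update({"sched_t_state2": 0.9, "sched_t_gait": 1.45,
              "sched_stance_thr": 0.35})
    # ---- gait block (phase-gated reflex stepper) ----
    # early stance: load-bearing force feedback + postural length servos
    p.update({
        "g0_SOL_KF": 0.9, "g0_GASM_KF": 0.6, "g0_GASL_KF": 0.6,
        "g0_VAS_KC": 0.12, "g0_VAS_KF": 0.5, "g0_VAS_KL": 1.5, "g0_VAS_LO": 0.8,
        "g0_GMAX_KC": 0.10, "g0_GMAX_KL": 2.0, "g0_GMAX_LO": 0.85,
        "g0_HAM_KC": 0.05, "g0_TA_KL": 1.5, "g0_TA_LO": 0.98, "g0_TA_KFm": 0.3,
        "g0_GMAX_KP": -1.2, "g0_GMAX_KV": -0.3, "g0_ILPSO_KP": 1.0,
        "g0_ILPSO_KV": 0.25, "g0_HAM_KP": -0.5,
    })
    # late stance: push-off
    p.update({
        "g1_SOL_KF": 1.1, "g1_GASM_KF": 0.9, "g1_GASL_KF": 0.9,
        "g1_VAS_KC": 0.06, "g1_VAS_KL": 1.5, "g1_VAS_LO": 0.8,
        "g1_GMAX_KL": 2.0, "g1_GMAX_LO": 0.85,
        "g1_TA_KL": 0.5, "g1_TA_LO": 0.98, "g1_TA_KFm": 0.3,
        "g1_GMAX_KP": -1.0, "g1_GMAX_KV": -0.25, "g1_ILPSO_KP": 0.8,
        "g1_ILPSO_KV": 0.2, "g1_HAM_KC": 0.04,
    })
    # liftoff: vigorous unloading of the stepping leg
    p.update({
        "g2_ILPSO_KC": 0.9, "g2_BFSH_KC": 0.7, "g2_GASM_KC": 0.05,
        "g2_GASL_KC": 0.05, "g2_SOL_KC": 0.05, "g2_TA_KC": 0.4,
    })
    # swing: hip flexion + foot clearance, hamstring braking
    p.update({
        "g3_ILPSO_KC": 0.30, "g3_TA_KC": 0.35, "g3_BFSH_KC": 0.05,
        "g3_HAM_KL": 0.8, "g3_HAM_LO": 1.02, "g3_RF_KC": 0.05,
    })
    # landing: leg stiffening before stance
    p.update({
        "g4_HAM_KC": 0.22, "g4_GMAX_KC": 0.18, "g4_VAS_KC": 0.22,
        "g4_SOL_KC": 0.10, "g4_TA_KC": 0.20,
    })
    p.update({"g_theta_o": -0.08,
              "g_lumbar_set": -0.10, "g_lumbar_kp": 160.0, "g_lumbar_kv": 14.0,
              "g_thoracic_set": 0.0, "g_thoracic_kp": 80.0, "g_thoracic_kv": 8.0})
    return p


# ---------------------------------------------------------------------------
# synthetic reference envelopes (plot overlays only; not experimental data)
# ---------------------------------------------------------------------------

@dataclass
class SyntheticEnvelope:
    """Time-normalized activation band (mean, lower, upper) for one muscle."""
    muscle: str
    phase: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray


_ENVELOPE_SHAPES = {
    # (bump centers on 0..1 movement phase, widths, amplitudes)
    "ILPSO": ([0.15, 0.55], [0.10, 0.08], [0.25, 0.35]),
    "GMAX": ([0.30], [0.12], [0.45]),
    "HAM": ([0.30, 0.80], [0.12, 0.10], [0.35, 0.30]),
    "BFSH": ([0.55], [0.10], [0.25]),
    "RF": ([0.30], [0.10], [0.30]),
    "VAS": ([0.30], [0.10], [0.55]),
    "GASM": ([0.45, 0.75], [0.10, 0.08], [0.35, 0.40]),
    "GASL": ([0.45, 0.75], [0.10, 0.08], [0.30, 0.35]),
    "SOL": ([0.45, 0.75], [0.12, 0.08], [0.40, 0.45]),
    "TA": ([0.10, 0.65], [0.08, 0.10], [0.40, 0.35]),
}


def synthetic_envelopes(seed: int, band_width: float = 0.15,
                        n_points: int = 101) -> dict:
    """Smooth plausible activation bands emulating experimental ranges.

    These are generated from documented basis functions plus seeded noise;
    they are NOT the experimental sEMG dataset and are labeled synthetic
    wherever plotted.
    """
    rng = np.random.default_rng(seed)
    phase = np.linspace(0.0, 1.0, n_points)
    out = {}
    for muscle, (centers, widths, amps) in _ENVELOPE_SHAPES.items():
        mean = np.full(n_points, 0.03)
        for c, w, a in zip(centers, widths, amps):
            jitter = 1.0 + 0.1 * rng.standard_normal()
            mean = mean + a * jitter * np.exp(-((phase - c) / w) ** 2)
        mean = np.clip(mean, 0.0, 1.0)
        half = band_width * (0.5 + mean)
        lower = np.clip(mean - half, 0.0, 1.0)
        upper = np.clip(mean + half, 0.0, 1.0)
        out[muscle] = SyntheticEnvelope(muscle, phase, mean, lower, upper)
    return out
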