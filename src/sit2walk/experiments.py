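"""The study conditions and orchestration: neutral, bilateral vasti-weakness
sweep (VAS maximum isometric force scaled 0.8/0.7/0.6/0.5/0.4, muscle mass
scaling with it), and the pain-avoidance sweep (stepping-knee peak-load
thresholds 4/3/2 x body weight), each optimized with progressive warm starts
from the previous, milder condition.
"""

from __future__ import annotations

import copy
import hashlib
import os
from dataclasses import dataclass, field

import numpy as np

from . import analysis_io, model_core, objective as objective_mod
from .controller import ParamVector, ReflexController, pack
from .fixtures_synthetic import (DeskPreset, FullPreset, baseline_params,
                                 default_model, desk_preset,
                                 seated_initial_state)
from .optimizer import (OptimizationConfig, OptimizationResult,
                        optimize_parallel, warm_start_chain)

__all__ = ["ConditionSpec", "StudyResult", "ConditionRecord", "apply_condition",
           "run_study", "rollout_condition", "make_cost_fn", "study_param_vector"]

VAS_SCALES = (0.8, 0.7, 0.6, 0.5, 0.4)
PAIN_THRESHOLDS = (4.0, 3.0, 2.0)


@dataclass
class ConditionSpec:
    kind: str                              # neutral | weakness | pain
    vas_scale: float | None = None
    pain_threshold_bw: float | None = None
    pain_leg: str = "stepping"

    def __post_init__(self):
        if self.kind == "neutral":
            if self.vas_scale is not None or self.pain_threshold_bw is not None:
                raise ValueError("neutral condition takes no extra fields")
        elif self.kind == "weakness":
            if self.vas_scale is None or self.pain_threshold_bw is not None:
                raise ValueError("weakness condition sets vas_scale only")
            if not 0 < self.vas_scale:
                raise ValueError("vas_scale must be positive")
        elif self.kind == "pain":
            if self.pain_threshold_bw is None or self.vas_scale is not None:
                raise ValueError("pain condition sets pain_threshold_bw only")
            if self.pain_threshold_bw <= 0:
                raise ValueError("pain threshold must be positive")
        else:
            raise ValueError(f"unknown condition kind {self.kind}")

    @property
    def condition_id(self) -> str:
        if self.kind == "neutral":
            return "neutral"
        if self.kind == "weakness":
            return f"weak_vas{self.vas_scale:g}"
        return f"pain_{self.pain_threshold_bw:g}bw"


def apply_condition(model, spec: ConditionSpec,
                    objective_config: objective_mod.ObjectiveConfig | None = None):
    """Return (model', objective_config') for one condition.

    Weakness scales both VAS maximum isometric forces (the metabolic muscle
    mass scales with f_max through the mass formula); pain adds the stepping-
    knee load cost; neutral is the identity.
    """
    cfg = copy.deepcopy(objective_config or objective_mod.ObjectiveConfig())
    if spec.kind == "neutral":
        return model, cfg
    if spec.kind == "weakness":
        model2 = copy.deepcopy(model)
        hit = 0
        for m in model2.muscles:
            if m.name.startswith("VAS"):
                m.f_max *= spec.vas_scale
                hit += 1
        if hit != 2:
            raise ValueError(f"expected bilateral VAS, found {hit}")
        return model2, cfg
    cfg.pain_threshold_bw = float(spec.pain_threshold_bw)
    cfg.pain_leg = spec.pain_leg
    return model, cfg


def params_hash(pv: ParamVector) -> str:
    payload = ",".join(f"{n}={v:.10g}" for n, v in zip(pv.names, pv.values))
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def study_param_vector(preset, start_values: dict | None = None) -> ParamVector:
    """The study's free-parameter vector seeded from the hand-tuned baseline.

    Desk scale freezes the gait-controller block at the baseline (documented
    preset reduction); the standing states and schedule stay free.
    """
    pv = pack({**baseline_params(), **(start_values or {})})
    if getattr(preset, "freeze_gait", False):
        for i, n in enumerate(pv.names):
            if n.startswith("g"):
                pv.free[i] = False
    return pv


def rollout_condition(model, params: ParamVector, preset) -> model_core.Trajectory:
    ctrl = ReflexController(model.muscle_names, params,
                            control_dt=preset.control_dt).repaired()
    state = seated_initial_state(model)
    return model_core.integrate(model, state, ctrl, duration=preset.duration,
                                dt=preset.dt, out_dt=preset.out_dt,
                                fall_y=preset.fall_y)


def make_cost_fn(model, obj_config, preset):
    def cost(params: ParamVector) -> float:
        traj = rollout_condition(model, params, preset)
        return objective_mod.evaluate(traj, obj_config).j_total
    return cost


#: pelvis height (m) that counts as having risen; seated is ~0.53, standing
#: ~0.95, so anything below this is a slide or crouch, not a rise
RISE_HEIGHT = 0.75


def seat_off_achieved(traj) -> bool:
    """Rose unaided: the chair unloads AND the pelvis reaches near-standing
    height (leaving the seat in a collapsed slide does not count)."""
    if traj.failed:
        return False
    ev = analysis_io.detect_events(traj)
    if ev.seat_off is None:
        return False
    return float(traj.q[:, 1].max()) >= RISE_HEIGHT


@dataclass
class ConditionRecord:
    condition: ConditionSpec
    result: OptimizationResult
    trajectory: model_core.Trajectory
    objective_report: objective_mod.ObjectiveReport
    metrics: analysis_io.MetricsReport
    no_solution: bool
    seed: int
    params_hash: str


@dataclass
class StudyResult:
    records: dict = field(default_factory=dict)   # condition_id -> ConditionRecord

    def __getitem__(self, cid):
        return self.records[cid]

    def ids(self):
        return list(self.records)


def _record(cond, res, model, cfg, preset, seed, out_dir=None):
    traj = rollout_condition(model, res.best_params, preset)
    loads = objective_mod.joint_load_series(traj)
    rep = objective_mod.evaluate(traj, cfg, loads=loads)
    met = analysis_io.metrics(traj, loads=loads)
    no_sol = res.no_solution or not seat_off_achieved(traj)
    rec = ConditionRecord(cond, res, traj, rep, met, no_sol, seed,
                          params_hash(res.best_params))
    if out_dir:
        d = os.path.join(out_dir, cond.condition_id)
        os.makedirs(d, exist_ok=True)
        res.best_params.to_file(os.path.join(d, "params.txt"))
        extras = {"condition": cond.condition_id, "seed": seed,
                  "params_hash": rec.params_hash,
                  "no_solution": bool(no_sol),
                  "best_cost": float(res.best_cost),
                  "generations": int(res.generations),
                  "n_evals": int(res.n_evals)}
        analysis_io.write_outputs(traj, {"metrics": met, "objective": rep,
                                         "run": extras}, d)
    return rec


def run_study(grid=None, opt_config: OptimizationConfig | None = None,
              scale: str = "desk", seed: int = 0, out_dir=None,
              kinds=("weakness", "pain"), vas_scales=VAS_SCALES,
              pain_thresholds=PAIN_THRESHOLDS,
              base_params: ParamVector | None = None,
              neutral_opt_config: OptimizationConfig | None = None) -> StudyResult:
    """Run the full study: neutral first, then warm-started sweeps.

    The weakness chain runs 0.8 -> 0.4 (each condition warm-started from the
    previous), the pain chain 4 -> 2 BW.  Desk scale uses the reduced preset
    (short horizon, frozen gait block, small optimization budget).
    """
    preset = desk_preset() if scale == "desk" else FullPreset()
    model = default_model(preset.seat_height)
    if opt_config is None:
        opt_config = OptimizationConfig(
            population_size=preset.popsize, max_generations=preset.generations,
            sigma0=preset.sigma0, n_parallel=preset.n_parallel, seed=seed)
    x0 = base_params if base_params is not None else study_param_vector(preset)

    study = StudyResult()
    if grid is None:
        grid = [ConditionSpec("neutral")]
        if "weakness" in kinds:
            grid += [ConditionSpec("weakness", vas_scale=s) for s in vas_scales]
        if "pain" in kinds:
            grid += [ConditionSpec("pain", pain_threshold_bw=p)
                     for p in pain_thresholds]

    neutral = [c for c in grid if c.kind == "neutral"]
    weak = sorted([c for c in grid if c.kind == "weakness"],
                  key=lambda c: -c.vas_scale)
    pain = sorted([c for c in grid if c.kind == "pain"],
                  key=lambda c: -c.pain_threshold_bw)

    def cost_factory(cond):
        m2, cfg = apply_condition(model, cond)
        return make_cost_fn(m2, cfg, preset)

    def feasibility(cond, params):
        m2, _ = apply_condition(model, cond)
        return seat_off_achieved(rollout_condition(m2, params, preset))

    # neutral (also the warm start of both sweeps); it is the root of every
    # chain, so it may carry a larger budget than the per-condition updates
    if neutral:
        cond = neutral[0]
        res = optimize_parallel(cost_factory(cond), x0,
                                neutral_opt_config or opt_config)
        res.condition_id = cond.condition_id
        res.no_solution = not feasibility(cond, res.best_params)
        m2, cfg = apply_condition(model, cond)
        study.records[cond.condition_id] = _record(cond, res, m2, cfg, preset,
                                                   opt_config.seed, out_dir)
        start = res.best_params if not res.no_solution else x0
    else:
        start = x0

    for chain in (weak, pain):
        if not chain:
            continue
        results = warm_start_chain(chain, start, cost_factory, opt_config,
                                   feasibility_fn=feasibility)
        for cond, res in zip(chain, results):
            m2, cfg = apply_condition(model, cond)
            study.records[cond.condition_id] = _record(
                cond, res, m2, cfg, preset, res.seed, out_dir)
    return study
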