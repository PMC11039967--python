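"""Hill-type muscle-tendon units: force generation, activation dynamics,
muscle mass and metabolic energy rates.

The MTU model is a rigid-tendon Hill muscle: normalized fiber length
``l~ = (L - l_slack) / l_opt``, active force-length (Gaussian), force-velocity
(Hill hyperbola with an eccentric plateau), and an exponential passive
force-length engaging above optimal length.  All curve constants live in
:data:`HILL_CURVES` so that tests and documentation share one source.

Metabolic energy follows the Bhargava-family decomposition into activation
heat, maintenance heat, shortening heat and positive mechanical work rates,
with the mass-dependent terms scaled by the muscle mass estimated from
maximum isometric force, specific tension, density and optimal fiber length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel

__all__ = [
    "MuscleDef", "MuscleConstants", "MetabolicCoefficients", "MuscleSignals",
    "HILL_CURVES", "hill_params_array", "activation_step", "mtu_force",
    "force_length", "force_velocity", "force_passive", "muscle_mass",
    "metabolic_rates",
]

#: Hill curve constants (single source of truth, mirrored into the kernel).
HILL_CURVES = {
    "fl_width": 0.45,       # Gaussian active force-length width
    "hill_shape": 0.25,     # force-velocity curvature a_f
    "ecc_plateau": 1.4,     # eccentric force plateau (x f_max)
    "ecc_rate": 10.0,       # eccentric curve rate constant
    "pas_kpe": 4.0,         # passive exponential shape
    "pas_e0": 0.6,          # passive strain at which f_pas = 1
    "fiber_floor": 0.01,    # fiber-length floor (x l_opt) under rigid tendon
}


def hill_params_array() -> np.ndarray:
    """Pack HILL_CURVES in the order the kernel expects."""
    c = HILL_CURVES
    return np.array([c["fl_width"], c["hill_shape"], c["ecc_plateau"],
                     c["ecc_rate"], c["pas_kpe"], c["pas_e0"],
                     c["fiber_floor"]], dtype=float)


@dataclass
class MuscleDef:
    """One muscle-tendon unit: architecture plus a piecewise-linear path.

    ``path`` is a list of ``(segment_name, (x, y))`` via points expressed in
    segment frames; moment arms follow exactly from this geometry.
    """
    name: str
    f_max: float            # N, maximum isometric force
    l_opt: float            # m, optimal fiber length
    l_slack: float          # m, tendon slack length
    path: list
    side: str = "left"
    v_max: float = 10.0     # l_opt / s

    def __post_init__(self):
        if self.f_max <= 0:
            raise ValueError(f"{self.name}: f_max must be > 0")
        if self.l_opt <= 0:
            raise ValueError(f"{self.name}: l_opt must be > 0")
        if self.v_max <= 0:
            raise ValueError(f"{self.name}: v_max must be > 0")


@dataclass
class MuscleConstants:
    specific_tension: float = 25.0     # N/cm^2
    density: float = 1.0597            # g/cm^3
    tau_act: float = 0.010             # s
    tau_deact: float = 0.040           # s

    def __post_init__(self):
        for f in ("specific_tension", "density", "tau_act", "tau_deact"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


@dataclass
class MetabolicCoefficients:
    """Bhargava-style heat-rate coefficients (W/kg unless noted)."""
    activation_rate: float = 40.0      # W/kg, x activation
    maintenance_rate: float = 74.0     # W/kg, x activation x g(l~)
    shortening_frac: float = 0.25      # x F x shortening velocity
    basal: float = 0.0                 # W, per muscle


@dataclass
class MuscleSignals:
    excitation: float
    activation: float
    mtu_length: float       # m
    mtu_velocity: float     # m/s (positive = lengthening)
    force: float            # N

    def __post_init__(self):
        if not (0.0 <= self.excitation <= 1.0 and 0.0 <= self.activation <= 1.0):
            raise ValueError("excitation/activation must lie in [0, 1]")
        if self.force < 0:
            raise ValueError("muscle force must be non-negative")


def activation_step(u: float, a: float, dt: float,
                    constants: MuscleConstants | None = None) -> float:
    """First-order activation dynamics, exact exponential update.

    da/dt = (u - a)/tau with tau = tau_act when u > a else tau_deact.
    """
    c = constants or MuscleConstants()
    tau = c.tau_act if u > a else c.tau_deact
    a_new = u + (a - u) * np.exp(-dt / tau)
    return float(min(1.0, max(0.0, a_new)))


def force_length(l_norm):
    """Gaussian active force-length curve; f_L(1) = 1 exactly."""
    w = HILL_CURVES["fl_width"]
    return np.exp(-(((np.asarray(l_norm) - 1.0) / w) ** 2))


def force_velocity(v_norm):
    """Hill hyperbola (concentric) with eccentric plateau; f_V(0) = 1 exactly."""
    v = np.asarray(v_norm, dtype=float)
    a_f = HILL_CURVES["hill_shape"]
    plateau = HILL_CURVES["ecc_plateau"]
    rate = HILL_CURVES["ecc_rate"]
    conc = np.where(v <= -1.0, 0.0, (1.0 + v) / (1.0 - v / a_f))
    ecc = 1.0 + (plateau - 1.0) * (1.0 - np.exp(-rate * np.maximum(v, 0.0)))
    return np.where(v < 0.0, conc, ecc)


def force_passive(l_norm):
    """Exponential passive force-length, engaging only above optimal length."""
    ln = np.asarray(l_norm, dtype=float)
    kpe = HILL_CURVES["pas_kpe"]
    e0 = HILL_CURVES["pas_e0"]
    out = (np.exp(kpe * np.maximum(ln - 1.0, 0.0) / e0) - 1.0) / (np.exp(kpe) - 1.0)
    return np.where(ln > 1.0, out, 0.0)


def mtu_force(mdef: MuscleDef, L: float, v: float, a: float) -> float:
    """Rigid-tendon Hill MTU force F(a, L, v); guaranteed >= 0."""
    if L <= 0:
        raise ValueError("MTU length must be positive")
    F, _, _, _, _, _ = _kernel.hill_force(mdef.f_max, mdef.l_opt, mdef.l_slack,
                                          mdef.v_max, a, L, v,
                                          hill_params_array())
    return float(F)


def muscle_mass(mdef: MuscleDef, constants: MuscleConstants | None = None) -> float:
    """Muscle mass in kg from f_max / specific tension x density x l_opt.

    f_max [N] / sigma [N/cm^2] gives PCSA [cm^2]; times l_opt [cm] gives
    volume [cm^3]; times density [g/cm^3] gives grams.
    """
    c = constants or MuscleConstants()
    pcsa_cm2 = mdef.f_max / c.specific_tension
    volume_cm3 = pcsa_cm2 * (mdef.l_opt * 100.0)
    return volume_cm3 * c.density / 1000.0


def _maintenance_fl(l_norm: float) -> float:
    """Piecewise maintenance-heat length dependence (Bhargava-style)."""
    if l_norm <= 0.5:
        return 0.5
    if l_norm <= 1.0:
        return 1.0
    if l_norm <= 1.5:
        return -2.0 * l_norm + 3.0
    return 0.0


def metabolic_rates(signals: MuscleSignals, mdef: MuscleDef,
                    constants: MuscleConstants | None = None,
                    coefficients: MetabolicCoefficients | None = None):
    """Per-muscle metabolic power split (Adot, Mdot, Sdot, Wdot), all in W, >= 0.

    Under the rigid tendon the fiber velocity equals the MTU velocity and the
    fiber force equals the MTU force.
    """
    c = constants or MuscleConstants()
    k = coefficients or MetabolicCoefficients()
    m = muscle_mass(mdef, c)
    lf = max(signals.mtu_length - mdef.l_slack,
             HILL_CURVES["fiber_floor"] * mdef.l_opt)
    l_norm = lf / mdef.l_opt
    v_fiber = signals.mtu_velocity

    Adot = m * k.activation_rate * signals.activation + k.basal
    Mdot = m * k.maintenance_rate * _maintenance_fl(l_norm) * signals.activation
    Sdot = k.shortening_frac * signals.force * max(0.0, -v_fiber)
    Wdot = max(0.0, -signals.force * v_fiber)
    return Adot, Mdot, Sdot, Wdot
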