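"""Hunt-Crossley compliant contact with regularized Coulomb friction.

Feet meet the ground plane and the buttocks meet the finite chair box
through contact spheres.  The normal law is F = k * d^p * (1 + 1.5 c dd),
clamped non-negative (never adhesive), with d the penetration depth and dd
its rate.  Friction is a tanh-regularized Coulomb law so stiction is smooth
around zero slip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ContactSphere", "ContactSurface", "normal_force", "friction_force",
    "chair_contact", "FRICTION_V_REG",
]

#: slip-velocity scale (m/s) of the tanh friction regularization
FRICTION_V_REG = 0.008


@dataclass
class ContactSphere:
    segment: str
    offset: tuple            # m, in segment frame
    radius: float            # m
    stiffness: float         # N/m^p
    exponent: float = 1.5
    damping: float = 1.0     # s/m (Hunt-Crossley dissipation)
    friction_mu: float = 0.9
    target: str = "ground"   # "ground" or "chair"
    leg: str | None = None   # "left"/"right" for foot spheres

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError(f"{self.segment} sphere: radius must be > 0")
        if self.stiffness <= 0:
            raise ValueError(f"{self.segment} sphere: stiffness must be > 0")
        if self.target not in ("ground", "chair"):
            raise ValueError("target must be 'ground' or 'chair'")


@dataclass
class ContactSurface:
    kind: str                    # "ground_plane" or "chair_box"
    seat_height: float = 0.46    # m (chair box top)
    x_range: tuple = (-0.35, 0.08)   # m, chair box extents (finite: buttocks clear it)
    ground_y: float = 0.0
    enabled: bool = True

    def __post_init__(self):
        if self.kind not in ("ground_plane", "chair_box"):
            raise ValueError("kind must be ground_plane or chair_box")
        if self.kind == "chair_box" and not self.x_range[0] < self.x_range[1]:
            raise ValueError("chair box needs finite, ordered x extents")


def normal_force(penetration: float, penetration_rate: float,
                 sphere: ContactSphere) -> float:
    """Hunt-Crossley normal force; 0 for non-penetrating, never negative."""
    if penetration <= 0.0:
        return 0.0
    f = (sphere.stiffness * penetration ** sphere.exponent
         * (1.0 + 1.5 * sphere.damping * penetration_rate))
    return float(max(0.0, f))


def friction_force(normal: float, slip_velocity: float, mu: float,
                   v_reg: float = FRICTION_V_REG) -> float:
    """Regularized Coulomb friction opposing slip; |f| <= mu * normal."""
    if normal < 0:
        raise ValueError("normal force must be non-negative")
    return float(-mu * normal * np.tanh(slip_velocity / v_reg))


def chair_contact(model, state):
    """Evaluate all chair-sphere forces at one state.

    Returns ``(per_sphere, total_seat_normal)`` where per_sphere maps sphere
    index -> (fx, fy).  Total seat load is identically 0 once every buttock
    sphere clears the box, which is what defines seat-off downstream.
    """
    from .model_core import compile_model, _sphere_forces_at_state

    arrays = compile_model(model) if not hasattr(model, "sp_body") else model
    forces, normals = _sphere_forces_at_state(arrays, state.q, state.qd)
    per_sphere = {}
    total = 0.0
    for s in range(arrays.ns):
        if arrays.sp_target[s] == 1:
            per_sphere[s] = (forces[s, 0], forces[s, 1])
            total += normals[s]
    return per_sphere, float(total)
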