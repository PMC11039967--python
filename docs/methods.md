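# Methods

## Model

The plant is a planar (sagittal; x forward, y up) rigid-body tree: pelvis
connected to the ground by a 3-dof planar free joint, pin joints at both
hips, knees and ankles, and 1-dof lumbar and thoracic joints — 11 degrees
of freedom. Segment masses, centers of mass and inertias follow standard
anthropometric (Winter-style) tables scaled to 1.80 m and 75 kg; arm and
head mass is folded into the torso segment, as usual for planar models.
All angles are CCW-positive, which makes anterior pelvis tilt and
lumbar/thoracic flexion *negative*; this is the only sign convention
consistent with the study's printed joint-range limits (pelvis tilt
−50°..+30°, lumbar −50°..0°). Reported trunk flexion is the negated sum of
pelvis tilt, lumbar and thoracic angles, so forward lean prints positive.

Dynamics use a planar recursive Newton–Euler inverse-dynamics pass; mass
matrix columns come from unit accelerations (exact for trees), and
M(q)·q̈ = Q − bias is solved each step. Prescribed (locked) coordinates
are removed from the system before solving, which is how the static test
scenes are posed. Integration is fixed-step semi-implicit Euler, dt =
0.5 ms by default (1 ms in the desk preset), with output sampling at
100 Hz. A rollout is flagged failed — not raised — when the pelvis drops
below 0.4 m or any generalized velocity exceeds 50 rad/s.

### Muscles

Twenty Hill-type muscle-tendon units, ten per leg: ILPSO, GMAX, HAM, BFSH,
RF, VAS, GASM, GASL, SOL, TA. The roster reaches ten by splitting the
gastrocnemius into its medial and lateral heads; the common planar gait
sets stop at nine. The tendon is rigid (fiber length = L − l_slack);
active force-length is a Gaussian of width 0.45, force-velocity a Hill
hyperbola (shape 0.25) with an eccentric plateau at 1.4·f_max, and the
passive curve is exponential above optimal length — all constants in
`muscle.HILL_CURVES`. Activation follows first-order dynamics with
τ_act = 10 ms, τ_deact = 40 ms, integrated with the exact exponential
update.

Paths are piecewise-linear via-point chains in segment frames, with
pulley-style via points at the pelvic brim (ILPSO) and around the knee
(patellar mechanism for VAS/RF), so moment arms remain physiological from
deep seated flexion (knee ≈ −110°) to upright standing. Moment arms are
identically −∂L/∂q of the path geometry, so the moment-arm/length-gradient
consistency property holds by construction and is verified against finite
differences in the tests.

Maximum isometric forces are in the range of the published planar
lower-limb models, with two deliberate increases: VAS 6000 N and GMAX
3000 N. The source models' vasti are notoriously weak for a healthy adult
(the cited source itself flags this), and with the published values the
planar model cannot arrest the trunk's momentum when rising at desk-scale
budgets. Tendon slack lengths are calibrated so every MTU sits at optimal
fiber length in a deep reference pose (hip 0.9 rad, knee −0.9 rad), which
places the extensors on a strong part of their force-length curve where
the task needs them; the gastrocnemii get 2 cm extra slack so the deep
squat start (deep knee flexion + dorsiflexion) does not passively lift the
heels.

Muscle mass is f_max divided by the specific tension (25 N/cm²) times
density (1.0597 g/cm³) times optimal fiber length; scaling f_max scales
mass linearly, which couples the weakness conditions to the metabolic
cost. Metabolic power is a Bhargava-family decomposition: activation heat
40 W/kg·a, maintenance heat 74 W/kg·a·g(l̃) with the standard piecewise
length dependence, shortening heat 0.25·F·max(0, −v_fiber), and positive
mechanical work max(0, −F·v_fiber); every term is non-negative.

### Contact

Hunt–Crossley spheres against the ground plane and the finite chair box:
F = k·δ^1.5·(1 + 1.5·c·δ̇), clamped non-negative. Two spheres per foot
(heel and forefoot, mimicking a toe-roll), two buttock spheres on the
pelvis against the chair box (seat pan at 0.46 m, finite extents so the
buttocks clear it at seat-off — which is exactly how seat-off is
detected). Ground stiffness 5·10⁶, chair 2·10⁵ N/m^1.5, damping 1 s/m.
Friction is Coulomb with tanh regularization over an 8 mm/s slip scale;
coefficients 1.3 (ground) and 0.8 (chair). These friction settings are
deliberately at the grippy end: with soft regularization or low μ the feet
and pelvis creep during the slow weight shift that precedes seat-off, and
standing up becomes dynamically impossible at any gain setting. The
static-balance property (settled contact forces sum to body weight within
1%) pins the overall contact calibration.

## Controller

Two sequential standing states followed by a gait state; the transition
times t_state2 and t_gait are free parameters. Per muscle (gains shared
bilaterally):

u = clip[0,1]( K_C + K_L+·max(0, L̃(t−d) − l_o) + K_F+·F̃(t−d)
− K_F−·F̃_antagonist(t−d) + K_p·(θ(t−d) − θ_o) + K_v·θ̇(t−d) )

with L̃ normalized by optimal fiber length, F̃ by maximum isometric force,
and θ the pelvis tilt. Neural latencies are 10 ms (hip muscles), 20 ms
(knee), 35 ms (ankle) and 5 ms for the vestibular channel — monotone with
conduction path length. Antagonist wiring: ILPSO↔GMAX, VAS↔HAM, BFSH→VAS,
RF→HAM, TA↔SOL, GAS→TA. The vestibular channel feeds the hip and
trunk-spanning muscles *and* VAS, SOL and TA: slaving knee extension to
forward pitch and giving the ankle an upright balance strategy turned out
to be necessary for any standing solution to exist in this plant; this is
a deliberate widening of the usual hip-centric wiring. Lumbar and
thoracic joints carry PD torque feedback (setpoint, stiffness, damping per
state) in place of trunk muscles.

The gait controller is a per-leg finite-state reflex machine with five
phases (early stance, late stance, liftoff, swing, landing) and
phase-gated K_C/K_L/K_F reflexes plus stance-phase vestibular feedback.
Stance is detected when a leg carries at least the stance-load-threshold
fraction of body weight (a free parameter); early→late stance triggers
when the pelvis passes the stance ankle, late→liftoff when the
contralateral leg is loaded, liftoff→swing on unloading, swing→landing
when the foot travels 0.15 m ahead of the pelvis, landing→early stance on
loading.

The full parameter vector holds 430 scalars (two standing states, the
schedule, and the gait block), each with bounds and an initial step size of
10% of its box. The desk preset freezes the gait block at the hand-tuned
baseline and optimizes the 145 standing/schedule entries.

### Baseline strategy

The optimization seed is a hand-tuned "stoop" rise: state 1 slowly folds
the trunk far forward over anchored feet (soft lumbar PD, hamstring and
tibialis tone holding the feet) until the whole-body center of mass
travels over the base of support; state 2 extends knees and hips through
length-feedback servos that fade as the joints straighten, with
plantarflexor push and vestibular balance. Seated posture starts upright
(pelvis 0.53 m, feet 0.20 m ahead of the pelvis, knees ≈ −111°). The
baseline reliably reaches seat-off and full standing height and produces
gait-initiation events, but its first steps are rudimentary; the study's
reported movements are always the CMA-ES-polished solutions, warm-started
along each condition chain.

## Objective

Hard task measures are summed penalties that reach exactly zero on a
satisfying movement: squared shortfall of the average gait-phase velocity
below 0.8 m/s (gait phase = first heel strike to the end of the rollout);
time-integrated excursions (deg·s) beyond the joint ranges; the
time-integral of the knee limit force (500-stiffness spring outside
[−120°, +10°]); time-integrated head acceleration above 1 m/s²; and, in
pain conditions, ∫max(0, stepping-knee load − threshold·BW) dt in N·s.
Two shaping terms keep the optimizer oriented before any rollout succeeds:
a no-gait penalty with height/progress shaping when no heel strike exists,
and a seat-off penalty when the chair never unloads (without it, desk-scale
optimization discovers chair-skimming shuffles that score well while never
standing — an artifact of short horizons). Failed rollouts cost a 10⁴
floor plus shaping, strictly above any successful rollout.

The effort estimate is J = ω_mb·J_mb + ω_act·J_act + ω_T·J_T with
ω_mb = 0.01, ω_act = 0.1, ω_T = 0.0003. J_mb integrates whole-body
metabolic power, normalized by body mass over the stand-up phase and by
mass·distance (a transport cost) over the gait phase; J_act integrates
summed cubed activations; J_T integrates squared lumbar and thoracic
torques (the proxy for absent trunk muscles).

Joint loads are resultant bone-on-bone forces on the distal segment:
subtree inertial-minus-gravity forces, minus external contact on the
subtree, minus the pull of every muscle segment crossing into the subtree
— expressed in units of body weight (735.75 N).

## Optimization

CMA-ES ((μ/μ_w, λ) with rank-1 and rank-μ covariance updates) in
normalized coordinates: each free parameter maps to [0, 1] over its box and
one global step size σ applies; σ₀ = 0.03–0.05. Bounds are honored by
projection. Population 10; stopping on a generation cap or 200 stagnant
generations. Runs are deterministic given the seed. Independent restarts
keep the best result; condition chains warm-start each condition from the
previous (milder) condition's best solution, and an infeasible condition
(best solution never achieves seat-off) is flagged `no_solution` while the
chain continues from the last feasible parameters.

## Study conditions and problem sizes

Neutral; bilateral VAS weakness at scales 0.8, 0.7, 0.6, 0.5, 0.4 (force
and muscle mass scaled together); stepping-knee (left) pain thresholds 4,
3, 2 BW. The desk preset — 2.5 s horizon, 1 ms step, population 10, 30
generations per condition, gait block frozen — runs the whole study in a
few minutes on one CPU and is the problem size used by the acceptance
script; the test suite uses 12 generations per condition. A full-scale
preset (5 s, 0.5 ms, thousands of generations, all 430 parameters free) is
provided but takes hours per condition.

## What the synthetic setup does and does not show

Everything here is generated: the model record, the toy oracle scenes, and
the reference activation envelopes (smooth seeded basis functions used
only as plot overlays and labeled synthetic — they are not experimental
sEMG). Desk-scale results are *directional*: they test whether weakness
raises trunk flexion/VAS drive/ankle loads and whether knee unloading
slows the movement without raising trunk flexion, under heavily truncated
optimization. They do not reproduce converged full-scale magnitudes, and
the first steps of the desk-scale movements are rudimentary, so
gait-phase quantities (velocity, cadence) are not meaningful at this
scale. Condition-to-condition monotonicity of the optimized sweeps is
seed-sensitive at this budget: with ~150 free parameters and a few
hundred rollouts per condition, CMA-ES can switch movement strategy
between adjacent chain conditions, and peak activations often saturate,
hiding "reduced drive" effects. The contrasts that are robust across
seeds are the ones the un-optimized condition sweep already shows
(weakness conditions flex the trunk more than neutral and fail to rise at
severe scales; the pain cost monotonically lowers the stepping-knee
load), and the full-scale preset exists precisely because converged
magnitudes need hours per condition. Other known limitations: planar dynamics (no lateral trunk lean or
arm support), rigid tendons, no pennation or fatigue, a single chair
geometry, simplified buttock/chair contact with no thigh support, and a
lumped head-arms-torso segment.

## Numerical choices

Contact events use a 5 N force threshold with 50 ms debounce (compliant
contact never reaches exactly zero); seat-unloading onset is the first
drop below 95% of the settled chair load; movement onset is the first
0.5° trunk-angle deviation. Muscle fiber length is floored at 1% of
optimal under the rigid tendon. The controller's internal signal buffers
are pre-filled with their t = 0 values (no startup transient), while the
public `delayed()` helper zero-pads before t = 0. Schedules sampled with
t_gait ≤ t_state2 are repaired to t_gait = t_state2 + 50 ms before
rollout.
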