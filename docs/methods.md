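# Methods

This note records the models, defaults and numerical choices behind
`gaitload`, what the synthetic data do and do not emulate, and the known
limitations. Units follow the field's conventions: angles in degrees,
forces in N, moments in N·m, stresses in MPa, connector stiffnesses in
N/mm and N·m/degree.

## Synthetic gait generator

The generator produces the *statistical structure* a strength-sensitivity
analysis needs, not a forward simulation of walking.

* **Cohort.** Mass and height are truncated normals (±3 SD) with means/SDs
  of 76.3 ± 8.6 kg and 1.777 ± 0.037 m (adult males, age 29). Body-fat
  fraction comes from a standard adult linear regression,
  BF% = 1.20·BMI + 0.23·age − 10.8·(male) − 5.4, clamped to (0.03, 0.6).
  Segment lengths are fixed stature fractions (thigh 0.245, shank 0.246,
  foot 0.152).
* **Phase grid.** Stance only (heel strike → toe-off), normalized to
  0–100% with 101 samples. Kinematics and GRF share this single grid; the
  original acquisition-rate distinction (marker vs force-plate sampling)
  collapses after normalization. Swing is never generated.
* **Waveforms.** Joint angles are sums of Gaussians shaped to textbook
  stance curves (early knee-flexion wave, hip flexion→extension, ankle
  rocker). The vertical GRF is a double-peaked template whose stance
  average is normalized to exactly one body weight; peaks land near
  1.1–1.3 BW. AP shear is a braking/propulsion wave of ±0.12 BW.
  Waveform templates scale with the *style-mean* speed rather than the
  trial's speed draw, so with all noise terms zeroed, two trials of one
  style differ only in their speed value (a determinism contract used in
  the tests).
* **Styles.** Toe-out/toe-in add ±(10 ± 2)° foot-progression angle; wide
  adds +(0.10 ± 0.02) m step width. Style offsets are drawn once per
  participant (a person's "their toe-out") and small per-trial jitter
  (0.5°, 4 mm) plus smooth low-amplitude waveform noise differentiate the
  five trials. Offset SDs are chosen so the per-participant style
  orderings (toe-out FPA > normal > toe-in; wide step width > normal)
  hold for every trial, which the invariant tests assert. The CoP path
  runs along the foot's long axis, so toe-out shifts late-stance CoP
  laterally — the classical lever-arm route by which toe-out lowers the
  knee adduction moment. Wide stance points the GRF medially and reduces
  hip adduction slightly.
* **Speeds.** Per-style truncated normals with the means/SDs listed in the
  README; these reproduce the expected ordering (normal fastest) and the
  session-level speed table.
* **Seeding.** Hierarchical: master seed → participant stream → (style,
  trial) streams via NumPy `SeedSequence` spawn keys, so any subset of the
  design regenerates independently and byte-identically.

What the generator does *not* emulate: marker trajectories and inverse
kinematics, force-plate noise and filtering artefacts, inter-joint
coordination variability, fatigue, or pathological gait. Passing tests
therefore demonstrate the pipeline's mechanics and statistics on clean,
well-structured inputs — not robustness to real laboratory data.

## Musculoskeletal model

A minimal planar-pair lower limb: hip 3 DoF (flexion, adduction, internal
rotation), knee 1 DoF hinge, ankle 2 DoF (plantarflexion, inversion).
Nineteen muscle-tendon units cover all groups with constant moment arms
(optional cosine modulation by joint angle is off by default); reference
isometric strengths are order-of-magnitude physiological (vasti
1.8–2.5 kN, soleus 3.5 kN, gastrocnemius 1.8 kN, gluteus medius 1.8 kN)
and live in the roster table, not in any publication. Strength enters
*only* as the normalizer N_i of the recruitment criterion: no activation
dynamics, tendon compliance, or force–length–velocity behaviour.

Couplings that carry the strength-sensitivity mechanics are retained
deliberately:

* gastrocnemius is biarticular (plantarflexion + knee flexion) and nearly
  axial at the knee (compression fraction 0.95), so its push-off force
  loads the tibiofemoral joint;
* rectus femoris is biarticular (hip flexion + knee extension);
* hamstrings extend the hip and flex the knee with an oblique line of
  action (compression fraction 0.60);
* gluteus maximus carries a small abduction arm, so weakened abductors
  recruit it, whose extension moment then demands more hip-flexor
  (rectus femoris, iliopsoas) activity — the compensation chain that
  raises knee compression under hip-abductor weakening;
* deep plantarflexors (tibialis posterior, peroneus longus) give the
  optimizer somewhere to shift plantarflexion duty when
  gastrocnemius/soleus are weakened, which is what lowers knee compression
  under ankle-extensor weakening;
* tensor fasciae latae carries a small frontal-plane arm at the knee
  (iliotibial-band abduction support), so its force modulates the applied
  adduction moment across strength conditions.

Scaling: segment lengths follow the participant's segment lengths, segment
masses scale with body mass, and strengths scale with lean mass to the 2/3
power (cross-sectional-area scaling), lean mass = mass·(1 − fat fraction).
The reference is 75 kg, 1.75 m, 20% fat. Strength reductions multiply N_i
by (1 − fraction) for the published group memberships (quadriceps;
gluteus medius/minimus + TFL; gastrocnemius + soleus) and touch nothing
else — in particular not segment masses, matching the idea that only the
models' strengths, not the motion, change.

## Inverse dynamics

Quasi-static, bottom-up (foot → shank → thigh), solved as two planar
problems (sagittal, frontal) sharing the vertical force; the transverse
hip-rotation demand is a configurable fraction (default 0.1) of the
frontal moment. Limb posture is reconstructed from the angle waveforms
with a foot-flat + heel-rise surrogate: the shank tilts forward by the
dorsiflexion angle plus a heel-rise term proportional to the anterior CoP
excursion (4 rad/m, capped at 0.6 rad), and the thigh is oriented by knee
flexion. The posture sets lever arms only. An `inertial` mode adds
segment d'Alembert terms finite-differenced on the phase grid (central
differences scaled by stance duration, itself derived from the trial's
speed via stride length = 0.8·stature and a 0.62 stance fraction);
quasi-static is the study default because stance-phase inertial terms are
second order for the sensitivity statistics computed here, and the
inertial path exists for the property suite (it reduces exactly to the
quasi-static answer at zero velocity). All trials are compared on the
0–100% grid regardless of their physical stance time.

## Recruitment solver

Minimize Σ(f_i/N_i)^p subject to C f = r, f ≥ 0, with p = 3 for all study
runs (the order is generic so the p → ∞ min-max limit can be tested). In
activation coordinates a = f/N the problem is strictly convex on the
feasible slice, so the minimizer is unique and no tie-breaking arises.

The production path maximizes the smooth concave dual
q(λ) = λᵀr − Σ(p−1)(max(s_i,0)/p)^{p/(p−1)}, s = (C·N)ᵀλ, by damped
Newton with a line search that accepts either a dual increase or a clear
contraction of the feasibility gradient (the latter matters in the last
digits, where dual-value comparisons drown in rounding). The primal is
recovered in closed form, making stationarity and complementarity exact;
the reported KKT residual is the primal-feasibility defect plus an
explicit certificate (least-squares multipliers on the active set,
non-negativity of the inactive multipliers). A primal SLSQP fallback, run
in units of the typical activation so a^p neither under- nor overflows,
covers high orders (p > 8) and the rare geometries where the dual Newton
stalls. Default tolerance 1e-8; traces warm-start each sample from the
previous sample's multipliers.

There are no reserve actuators: an unreachable moment raises an
`InsufficientStrengthError` naming the worst row, because strength is the
experimental variable and silent torque reserves would mask exactly the
effect under study. Upper bounds f_i ≤ N_i are *not* imposed (the
formulation constrains only f ≥ 0); activations may exceed one and are
flagged.

## Knee loading and contact

The twelve per-sample inputs are assembled as: axial force =
intersegmental (along-shank) compression + Σ knee-crossing muscle forces ×
compression fractions; AP shear likewise through signed shear fractions;
the applied frontal moment = external knee adduction moment − frontal-arm
contributions of knee-crossing muscles; the patellofemoral force = the
quadriceps resultant through a flexion-dependent pulley ratio (0.7 at 20°
rising linearly to 1.0 at 60°). Patellofemoral loads are computed and
reported but no patellar contact is solved; the analyzed outcomes are
tibial. Each style × condition cell averages its five trials' traces
pointwise before the single contact solve (16 solves per participant).

Contact is a rigid femur with two quadratic condylar surfaces (AP radius
0.08 m, ML radius 0.04 m, posterior rollback 0.15 mm/deg of flexion) on
two 8×8-element, 20×15 mm plateaus 40 mm apart, 3 mm cartilage thickness.
Element pressure is k_e·penetration with
k_e = E(1−ν)/[(1+ν)(1−2ν)t_e], ν = 0.42, and an effective modulus of
4 MPa by default — a configuration value in the instantaneous-cartilage
range chosen to place stance stresses in the physiological few-MPa band;
the biphasic column provides a calibration route (below) but is not the
default source. Pose: flexion prescribed, internal-external rotation held
by its connector at the linearized equilibrium, four free DoFs
(penetration, AP, ML, ab-adduction tilt).

Numerics. The equilibrium is solved nested: an inner 2×2 damped Newton
keeps vertical force and tilt moment balanced exactly while an outer
Newton (finite-difference Jacobian, scipy `hybr`/bracketed-root fallbacks)
finds the tangential pose — separating the stiff foundation directions
from the soft connector directions. The contact law is softplus-smoothed
with a 0.2 µm width (negligible against 0.1–1 mm physiological
penetrations) so marginal contact keeps the residual differentiable;
reported stresses are hard-zeroed outside the penetration set. Converged
samples balance to ~1e-9 relative; anything worse than 0.1% raises.

Two load-envelope truncations handle physically unreachable demands at
near-zero axial load: a frontal-moment demand beyond the tipping envelope
(pressure centroid past ~0.85 of the compartment half-spacing) and a
tangential force beyond the plateau's restoring capacity are truncated to
the attainable value and flagged per sample (`moment_clipped`,
`force_clipped`), the excess being attributed to unmodeled soft tissue.
In practice this touches only the first/last stance samples, where
stresses are negligible.

The **key simplification** of the whole artifact: superficial maximum
principal stress is surrogated by the contact-pressure magnitude. In
compressive contact the superficial compressive principal stress tracks
pressure, but no tensile stresses, fibril effects, or through-thickness
fields exist here; compartment-level summaries and their *relative*
changes are the meaningful outputs, not pointwise stress values. The
upper-quartile summary takes, per compartment and sample, the mean of the
top ceil(0.25·n) stresses among contacting elements (elements at zero
pressure are not part of the contact area); the per-compartment base was
chosen because results are reported per compartment.

## Biphasic cartilage column

Linear biphasic theory in confined compression: ∂p/∂t = H_A k ∂²p/∂z² + σ̇
with a drained loaded surface and an impermeable base, solved by
Crank–Nicolson (unconditionally stable, second order; the explicit-scheme
step bound quoted for such problems is not needed and not enforced).
Defaults H_A = 0.5 MPa, k = 2e-15 m⁴/(N·s), 3 mm, 100 nodes — general
cartilage-literature values. Verification: the step-load settlement
matches the classical eigen-series to L2 < 1e-3, the drained limit is
σ₀h/H_A, fluid efflux equals settlement (incompressible constituents),
and halving the grid changes nothing at the 0.5% level.

`effective_foundation_modulus` returns σ/ε at the end of a stress ramp;
by linearity the ratio is amplitude-independent. At gait timescales
(~1e-4 of the 9000 s consolidation time) confined compression yields
~40×H_A ≈ 20 MPa: an overestimate of the in-situ foundation stiffness,
because confined compression forbids the lateral fluid escape and matrix
bulging present under an indenting condyle. That mismatch is why the
contact default (4 MPa) is a configuration value rather than the
calibration output; the calibration route remains available and tested.

## Statistics

%Change uses the printed absolute-value form, so it is non-negative and
the PP difference is a plain subtraction (the separate "absolute value"
phrasing in the accompanying text is redundant given the definition and
is implemented as written). Samples with reference stress below 0.01 MPa
are masked (NaN), not divided. Signed variants are kept alongside for
direction-of-effect statements. Cohort curves are pointwise means with
t-based 95% CIs across participants (consistent with cross-participant
shading); peak comparisons use each participant's maximum of the
upper-quartile summary over stance, per compartment, compared by paired
t-tests (differences taken reduced − reference, so t > 0 means the
reduced-strength peak is higher). The walking-speed comparison is a
classical one-way repeated-measures ANOVA with Bonferroni-corrected
pairwise post hocs; no sphericity correction is applied, and the
degenerate all-equal case returns F = 0 by convention. α = 0.05
throughout. Statistical-parametric-mapping waveform comparisons are out
of scope; pointwise curves plus peak tests cover the package's claims.

## Problem sizes and determinism

The default study is the full 7 × 4 × 5 design with four strength
conditions: 560 recruitment traces (56,560 instant solves), 448 contact
solves of 101 samples each; it completes in roughly two minutes on one
CPU, and the test suite runs it twice to assert byte-identical output
trees. Example scripts use 2–3 participants to stay interactive. All
randomness flows from one master seed through named sub-streams; results
files are written with fixed float formats and no timestamps, so a rerun
is a byte-identical tree.

## Limitations

* Direction and approximate magnitude of *relative* changes are the
  designed outputs; absolute stresses depend on configuration values
  (foundation modulus, plateau geometry) and should not be read as
  participant predictions. No published per-participant magnitudes are
  reproduced, since the underlying motion data are not available.
* The planar-pair anatomy, constant arms, and the two-planar dynamics are
  strong simplifications; conclusions that hinge on anatomical detail
  (e.g. per-vastus load shares) are outside the model's scope.
* Kinematics and GRFs are held fixed across strength conditions — the
  sensitivity isolates the recruitment/contact pathway and ignores the
  gait adaptations a genuinely weak person would make.
* The elastic foundation has no menisci, ligament bundles, fluid
  pressurization, or transient poroelasticity; the biphasic column is 1-D
  and strain-independent.
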