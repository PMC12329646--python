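"""Simplified lower-limb musculoskeletal model.

The anatomy is a minimal planar-pair surrogate: each joint degree of freedom
is spanned by at least one agonist and one antagonist, with constant moment
arms (optionally cosine-modulated by joint angle). Hip: 3 DoF (flexion,
adduction, internal rotation); knee: 1 DoF hinge (extension-positive row);
ankle: 2 DoF (plantarflexion, inversion). Muscle strength enters only as the
maximum isometric force N_i that normalizes the recruitment criterion.

Biarticular couplings that matter for the strength-sensitivity mechanics are
kept: gastrocnemius (ankle plantarflexion + knee flexion, knee-compressing),
rectus femoris (hip flexion + knee extension, knee-compressing), hamstrings
(hip extension + knee flexion, knee-compressing), and a small gluteus maximus
abduction component so that weakened hip abductors recruit the extensors.

Default isometric strengths are order-of-magnitude physiological values
(e.g. vasti 1.8-2.5 kN, soleus 3.5 kN); no study-specific values exist.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass

import numpy as np

from .config import MUSCLE_GROUPS, ModelConfig
from .errors import ConfigurationError, InvalidModelError
from .synthetic import Participant

#: Joint-DoF order used everywhere (rows of the recruitment matrix).
#: Sign conventions (internal moments): hip flexion +, hip adduction +,
#: hip internal rotation +, knee extension +, ankle plantarflexion +,
#: ankle inversion +.
DOFS = ("hip_flex", "hip_add", "hip_rot", "knee", "ankle_pf", "ankle_inv")


@dataclass
class MuscleTendonUnit:
    """One Hill-type-strength actuator.

    ``moment_arms_m`` maps DoF name -> signed arm (m) in the DOFS convention.
    ``compression_fraction`` is the share of the muscle's force transmitted as
    tibiofemoral axial compression (cos of an effective line-of-action angle);
    ``shear_fraction`` the signed anteroposterior share (+ posterior).
    ``knee_abduction_arm_m`` is a frontal-plane arm at the knee for units
    whose tension unloads the medial compartment (e.g. the iliotibial band of
    tensor fasciae latae); it is not a recruitment row.
    """

    name: str
    group: str
    isometric_strength_n: float
    moment_arms_m: dict[str, float]
    crosses_knee: bool = False
    compression_fraction: float = 0.0
    shear_fraction: float = 0.0
    knee_abduction_arm_m: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in MUSCLE_GROUPS:
            raise InvalidModelError(f"unknown muscle group '{self.group}'")
        if not self.isometric_strength_n > 0:
            raise InvalidModelError(
                f"{self.name}: isometric strength must be > 0")
        if not self.moment_arms_m:
            raise InvalidModelError(f"{self.name}: must actuate >= 1 DoF")
        for dof, arm in self.moment_arms_m.items():
            if dof not in DOFS:
                raise InvalidModelError(f"{self.name}: unknown DoF '{dof}'")
            if abs(arm) > 0.15:
                raise InvalidModelError(
                    f"{self.name}: |moment arm| {abs(arm):.3f} m exceeds 0.15 m")


@dataclass
class Segment:
    length_m: float
    mass_kg: float
    com_fraction: float  # COM position from the proximal end

    @property
    def moment_of_inertia(self) -> float:
        # Slender-rod approximation about the COM.
        return self.mass_kg * self.length_m ** 2 / 12.0


@dataclass
class MusculoskeletalModel:
    """Scaled segments, joints, and the muscle roster for one participant."""

    participant_id: str
    mass_kg: float
    height_m: float
    segments: dict[str, Segment]
    muscles: list[MuscleTendonUnit]
    hip_lateral_offset_m: float = 0.09
    ankle_height_m: float = 0.07
    arm_cosine_modulation: bool = False
    arm_modulation_amplitude: float = 0.15
    transverse_moment_fraction: float = 0.1

    def muscle_names(self) -> list[str]:
        return [m.name for m in self.muscles]

    def strengths(self) -> np.ndarray:
        return np.array([m.isometric_strength_n for m in self.muscles])

    def moment_arm(self, muscle: MuscleTendonUnit, dof: str,
                   angle_deg: float = 0.0) -> float:
        """Signed arm of ``muscle`` about ``dof``, optionally modulated as
        arm * (1 + amplitude*(cos(angle) - 1)) so the arm shrinks smoothly
        away from the neutral posture."""
        arm = muscle.moment_arms_m.get(dof, 0.0)
        if arm and self.arm_cosine_modulation:
            arm *= 1.0 + self.arm_modulation_amplitude * (
                math.cos(math.radians(angle_deg)) - 1.0)
        return arm


_DEFAULT_ROSTER: list[dict] = [
    # Knee extensors (quadriceps); rectus femoris is biarticular.
    dict(name="rectus_femoris", group="knee_extensor", N=1200.0,
         arms={"knee": 0.045, "hip_flex": 0.035}, crosses_knee=True,
         compression=0.90, shear=-0.10),
    dict(name="vastus_lateralis", group="knee_extensor", N=2500.0,
         arms={"knee": 0.045}, crosses_knee=True, compression=0.90,
         shear=-0.10),
    dict(name="vastus_medialis", group="knee_extensor", N=2200.0,
         arms={"knee": 0.042}, crosses_knee=True, compression=0.90,
         shear=-0.10),
    dict(name="vastus_intermedius", group="knee_extensor", N=1800.0,
         arms={"knee": 0.040}, crosses_knee=True, compression=0.90,
         shear=-0.10),
    # Knee flexors / hip extensors (hamstrings), oblique line of action.
    dict(name="biceps_femoris", group="knee_flexor", N=1500.0,
         arms={"knee": -0.035, "hip_flex": -0.060}, crosses_knee=True,
         compression=0.60, shear=0.15),
    dict(name="semitendinosus", group="knee_flexor", N=1000.0,
         arms={"knee": -0.040, "hip_flex": -0.055}, crosses_knee=True,
         compression=0.60, shear=0.15, knee_abd_arm=0.010),
    # Hip abductors.
    dict(name="gluteus_medius", group="hip_abductor", N=1800.0,
         arms={"hip_add": -0.055, "hip_rot": 0.010}),
    dict(name="gluteus_minimus", group="hip_abductor", N=700.0,
         arms={"hip_add": -0.045}),
    dict(name="tensor_fasciae_latae", group="hip_abductor", N=400.0,
         arms={"hip_add": -0.040, "hip_flex": 0.020}, knee_abd_arm=0.015),
    # Hip adductors.
    dict(name="adductor_magnus", group="hip_adductor", N=1500.0,
         arms={"hip_add": 0.050, "hip_flex": -0.020}),
    dict(name="adductor_longus", group="hip_adductor", N=800.0,
         arms={"hip_add": 0.045, "hip_flex": 0.020}),
    # Ankle extensors (plantarflexors); gastrocnemius is biarticular and
    # nearly axial at the knee.
    dict(name="gastrocnemius", group="ankle_extensor", N=1800.0,
         arms={"ankle_pf": 0.050, "knee": -0.020}, crosses_knee=True,
         compression=0.95, shear=0.10),
    dict(name="soleus", group="ankle_extensor", N=3500.0,
         arms={"ankle_pf": 0.045}),
    # Secondary plantarflexors that also control inversion/eversion.
    dict(name="tibialis_posterior", group="ankle_extensor_aux", N=1400.0,
         arms={"ankle_pf": 0.025, "ankle_inv": 0.020}),
    dict(name="peroneus_longus", group="ankle_extensor_aux", N=1000.0,
         arms={"ankle_pf": 0.030, "ankle_inv": -0.020}),
    # Dorsiflexor.
    dict(name="tibialis_anterior", group="ankle_dorsiflexor", N=1200.0,
         arms={"ankle_pf": -0.040, "ankle_inv": 0.010}),
    # Hip flexor / extensor pair and rotation stabilizers.
    dict(name="iliopsoas", group="hip_flexor", N=2500.0,
         arms={"hip_flex": 0.050, "hip_rot": 0.008}),
    dict(name="gluteus_maximus", group="hip_extensor", N=2500.0,
         arms={"hip_flex": -0.060, "hip_add": -0.015, "hip_rot": -0.012}),
    dict(name="piriformis", group="hip_extensor", N=500.0,
         arms={"hip_rot": -0.020, "hip_add": -0.010}),
]

# "ankle_extensor_aux" is roster shorthand for deep plantarflexors that are
# NOT part of the reducible ankle-extensor group (the study group is
# gastrocnemius + soleus only); they are stored under group "ankle_extensor"
# with a separate membership flag.
_STUDY_GROUPS = {
    "knee_extensor": {"rectus_femoris", "vastus_lateralis", "vastus_medialis",
                      "vastus_intermedius"},
    "hip_abductor": {"gluteus_medius", "gluteus_minimus",
                     "tensor_fasciae_latae"},
    "ankle_extensor": {"gastrocnemius", "soleus"},
}


def group_members(model: MusculoskeletalModel, group: str) -> list[str]:
    """Names of the units a strength reduction of ``group`` applies to.

    For the three study groups this is the published muscle list; for other
    groups it is every unit labelled with that group.
    """
    if group in _STUDY_GROUPS:
        return [m.name for m in model.muscles if m.name in _STUDY_GROUPS[group]]
    return [m.name for m in model.muscles if m.group == group]


def default_reference_model(cfg: ModelConfig | None = None) -> MusculoskeletalModel:
    """The unscaled reference model (reference mass/height/fat fraction)."""
    cfg = cfg or ModelConfig()
    h = cfg.reference_height_m
    m = cfg.reference_mass_kg
    segments = {
        "thigh": Segment(0.245 * h, cfg.thigh_mass_fraction * m, cfg.com_fraction),
        "shank": Segment(0.246 * h, cfg.shank_mass_fraction * m, cfg.com_fraction),
        "foot": Segment(0.152 * h, cfg.foot_mass_fraction * m, 0.5),
    }
    muscles = []
    for spec in _DEFAULT_ROSTER:
        group = spec["group"]
        if group == "ankle_extensor_aux":
            group = "ankle_extensor"
        muscles.append(MuscleTendonUnit(
            name=spec["name"], group=group,
            isometric_strength_n=spec["N"], moment_arms_m=dict(spec["arms"]),
            crosses_knee=spec.get("crosses_knee", False),
            compression_fraction=spec.get("compression", 0.0),
            shear_fraction=spec.get("shear", 0.0),
            knee_abduction_arm_m=spec.get("knee_abd_arm", 0.0)))
    model = MusculoskeletalModel(
        participant_id="reference", mass_kg=m, height_m=h,
        segments=segments, muscles=muscles,
        hip_lateral_offset_m=cfg.hip_lateral_offset_m,
        ankle_height_m=cfg.ankle_height_fraction * h,
        arm_cosine_modulation=cfg.arm_cosine_modulation,
        arm_modulation_amplitude=cfg.arm_modulation_amplitude,
        transverse_moment_fraction=cfg.transverse_moment_fraction)
    check_bidirectional_actuation(model)
    return model


def check_bidirectional_actuation(model: MusculoskeletalModel) -> None:
    """Every DoF must have at least one positive and one negative arm."""
    for dof in DOFS:
        arms = [mu.moment_arms_m.get(dof, 0.0) for mu in model.muscles]
        if not (any(a > 0 for a in arms) and any(a < 0 for a in arms)):
            raise InvalidModelError(
                f"DoF '{dof}' lacks bidirectional actuation")


def scale_model(reference: MusculoskeletalModel, participant: Participant,
                reference_fat_fraction: float = 0.20) -> MusculoskeletalModel:
    """Scale the reference model to a participant.

    Segment lengths follow the participant's segment lengths, masses scale
    with body mass, and isometric strengths scale with lean mass to the 2/3
    power (cross-sectional-area scaling): N_i' = N_i * (L_p / L_ref)^(2/3),
    lean mass = mass * (1 - fat fraction).
    """
    lean_ref = reference.mass_kg * (1.0 - reference_fat_fraction)
    lean_p = participant.mass_kg * (1.0 - participant.fat_fraction)
    if lean_ref <= 0 or lean_p <= 0:
        raise InvalidModelError("non-positive lean mass in scaling")
    mass_ratio = participant.mass_kg / reference.mass_kg
    strength_factor = (lean_p / lean_ref) ** (2.0 / 3.0)
    if not (mass_ratio > 0 and strength_factor > 0):
        raise InvalidModelError("non-positive scaling factor")

    scaled = copy.deepcopy(reference)
    scaled.participant_id = participant.id
    scaled.mass_kg = participant.mass_kg
    scaled.height_m = participant.height_m
    for name, seg in scaled.segments.items():
        seg.length_m = participant.segment_lengths_m[name]
        seg.mass_kg = seg.mass_kg * mass_ratio
    scaled.ankle_height_m = (reference.ankle_height_m / reference.height_m
                             * participant.height_m)
    for mu in scaled.muscles:
        mu.isometric_strength_n *= strength_factor
    return scaled


def reduce_strength(model: MusculoskeletalModel, group: str,
                    fraction: float) -> MusculoskeletalModel:
    """Return a copy with every unit of ``group`` weakened by ``fraction``.

    fraction in [0, 1): the new strength is N_i * (1 - fraction). The input
    model is not modified.
    """
    if not (0.0 <= fraction < 1.0):
        raise ConfigurationError(f"fraction {fraction} outside [0, 1)")
    members = set(group_members(model, group))
    if not members:
        raise ConfigurationError(f"group '{group}' has no members in the roster")
    out = copy.deepcopy(model)
    for mu in out.muscles:
        if mu.name in members:
            mu.isometric_strength_n *= (1.0 - fraction)
    check_bidirectional_actuation(out)
    return out


#: Condition labels in study order; the first is the unmodified reference.
CONDITIONS = ("reference", "knee_extensor", "hip_abductor", "ankle_extensor")


def build_strength_conditions(model: MusculoskeletalModel,
                              fraction: float = 0.40,
                              groups: tuple[str, ...] = CONDITIONS[1:],
                              ) -> dict[str, MusculoskeletalModel]:
    """The four study conditions: reference plus one weakened group each."""
    out = {"reference": model}
    for g in groups:
        out[g] = reduce_strength(model, g, fraction)
    return out
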