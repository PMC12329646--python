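"""Seeded synthetic stance-phase gait trials for four walking styles.

The generator emulates the statistical structure of a gait-lab session:
a cohort of adult males (mass 76.3 +/- 8.6 kg, stature 1.777 +/- 0.037 m),
four gait styles (normal, toe-out, toe-in, wide stance) at the per-style
self-selected speeds, five trials per style, and smooth stance-phase
(heel-strike to toe-off) joint-angle and ground-reaction-force waveforms on a
0-100% phase grid. It produces joint angles directly (no marker-level
simulation) and a double-peaked vertical GRF scaled to body weight.

Laboratory frame: x anterior (walking direction), y up, z lateral.
Angles in degrees, forces in N, centre of pressure in metres relative to the
ankle joint's ground projection.

Seeding is hierarchical (master seed -> participant -> style -> trial) so any
subset of the cohort regenerates independently and reproducibly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import STYLES, CohortConfig, GeneratorConfig
from .errors import ConfigurationError, OutOfRangeError

TRIAL_COLUMNS = ["phase", "hip_flex", "hip_add", "hip_rot", "knee_flex",
                 "ankle_pf", "ankle_inv", "grf_x", "grf_y", "grf_z",
                 "cop_x", "cop_z"]

_G = 9.81


@dataclass
class Participant:
    """Anthropometrics of one synthetic participant."""

    id: str
    mass_kg: float
    height_m: float
    bmi: float
    fat_fraction: float
    segment_lengths_m: dict[str, float]

    def __post_init__(self) -> None:
        if not (self.mass_kg > 0 and self.height_m > 0):
            raise ConfigurationError("mass and height must be positive")
        if not (0.03 < self.fat_fraction < 0.6):
            raise ConfigurationError(
                f"fat_fraction {self.fat_fraction:.4f} outside (0.03, 0.6)")
        if any(v <= 0 for v in self.segment_lengths_m.values()):
            raise ConfigurationError("segment lengths must be positive")
        if sum(self.segment_lengths_m.values()) >= self.height_m:
            raise ConfigurationError("segment lengths must sum to < height")


@dataclass
class GaitTrial:
    """One stance-phase trial of one participant.

    All waveforms are sampled on ``phase`` (percent of stance, 0 -> 100).
    ``foot_progression_angle_deg`` is positive for toe-out.
    """

    participant_id: str
    style: str
    trial_index: int
    phase: np.ndarray
    joint_angles: dict[str, np.ndarray]  # hip_flex/hip_add/hip_rot/knee_flex/ankle_pf/ankle_inv, deg
    grf: np.ndarray                      # (n, 3) N, columns x/y/z
    cop: np.ndarray                      # (n, 2) m, columns x/z
    foot_progression_angle_deg: float
    step_width_m: float
    speed_m_s: float
    seed: int
    body_weight_n: float = field(default=0.0)

    @property
    def n_samples(self) -> int:
        return self.phase.size


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      n_sd: float) -> float:
    """Draw from N(mean, sd) truncated at +/- n_sd standard deviations."""
    if not np.isfinite(mean) or not np.isfinite(sd) or sd < 0:
        raise ConfigurationError("distribution parameters must be finite, sd >= 0")
    if sd == 0:
        return mean
    while True:
        z = rng.standard_normal()
        if abs(z) <= n_sd:
            return mean + sd * z


def estimate_fat_fraction(bmi: float, cohort: CohortConfig | None = None) -> float:
    """Body-fat fraction from BMI via a linear adult-male regression.

    BF% = slope*BMI + age_slope*age + sex_offset, clamped to
    (fat_floor, fat_ceiling). Monotonically increasing in BMI (slope > 0).
    """
    cohort = cohort or CohortConfig()
    if not (10.0 <= bmi <= 60.0):
        raise OutOfRangeError(f"bmi {bmi} outside [10, 60]")
    pct = (cohort.fat_bmi_slope * bmi + cohort.fat_age_slope * cohort.age_yr
           + cohort.fat_sex_offset)
    frac = pct / 100.0
    return float(min(max(frac, cohort.fat_floor), cohort.fat_ceiling))


def sample_participant(cohort: CohortConfig, seed, pid: str = "P01") -> Participant:
    """Draw one participant from truncated-normal mass/height distributions."""
    for v in (cohort.mass_mean_kg, cohort.mass_sd_kg,
              cohort.height_mean_m, cohort.height_sd_m):
        if not np.isfinite(v):
            raise ConfigurationError("non-finite cohort distribution parameter")
    if cohort.mass_mean_kg <= 0 or cohort.height_mean_m <= 0:
        raise ConfigurationError("cohort means must be positive")
    if cohort.mass_sd_kg < 0 or cohort.height_sd_m < 0:
        raise ConfigurationError("cohort SDs must be non-negative")
    rng = np.random.default_rng(seed)
    mass = _truncated_normal(rng, cohort.mass_mean_kg, cohort.mass_sd_kg,
                             cohort.truncation_sd)
    height = _truncated_normal(rng, cohort.height_mean_m, cohort.height_sd_m,
                               cohort.truncation_sd)
    bmi = mass / height ** 2
    fat = estimate_fat_fraction(bmi, cohort)
    segs = {"thigh": cohort.thigh_fraction * height,
            "shank": cohort.shank_fraction * height,
            "foot": cohort.foot_fraction * height}
    return Participant(id=pid, mass_kg=mass, height_m=height, bmi=bmi,
                       fat_fraction=fat, segment_lengths_m=segs)


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _bump(s: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-(((s - center) / width) ** 2))


def _smooth_noise(rng: np.random.Generator, s: np.ndarray, amplitude: float,
                  n_bumps: int = 6) -> np.ndarray:
    """Low-amplitude smooth noise: a sum of random Gaussian bumps."""
    out = np.zeros_like(s)
    centers = rng.uniform(0.0, 1.0, n_bumps)
    amps = rng.standard_normal(n_bumps)
    for c, a in zip(centers, amps):
        out += a * _bump(s, c, 0.12)
    return amplitude * out


def _angle_templates(s: np.ndarray, speed: float) -> dict[str, np.ndarray]:
    """Smooth stance-phase joint-angle templates (degrees).

    Shapes follow textbook gait curves: early knee-flexion wave then push-off
    flexion; hip moving from flexion into extension; ankle rocking from
    slight plantarflexion through mid-stance dorsiflexion to push-off
    plantarflexion. Peak sizes scale weakly with walking speed.
    """
    v = speed / 1.16
    knee = (8.0 + 12.0 * v * _bump(s, 0.15, 0.10)
            + 35.0 * _bump(s, 0.98, 0.14))
    hip_flex = (-8.0 + 36.0 * _bump(s, 0.03, 0.45)
                + 8.0 * _bump(s, 1.0, 0.15))
    hip_add = 5.0 * _bump(s, 0.30, 0.30) + 1.0
    hip_rot = 3.0 * _bump(s, 0.5, 0.35)
    ankle_pf = (5.0 * _bump(s, 0.04, 0.08) - 12.0 * _bump(s, 0.50, 0.30)
                + 22.0 * v * _bump(s, 0.98, 0.10))
    ankle_inv = 2.0 + 3.0 * np.sin(np.pi * s)
    return {"knee_flex": knee, "hip_flex": hip_flex, "hip_add": hip_add,
            "hip_rot": hip_rot, "ankle_pf": ankle_pf, "ankle_inv": ankle_inv}


def _vertical_grf_shape(s: np.ndarray, speed: float) -> np.ndarray:
    """Unnormalized double-peaked vertical GRF shape, zero at both ends."""
    v = speed / 1.16
    env = np.sin(np.pi * np.clip(s, 0.0, 1.0)) ** 0.35
    shape = (1.0 + 0.28 * v * _bump(s, 0.25, 0.11)
             + 0.25 * v * _bump(s, 0.78, 0.11)
             - 0.18 * _bump(s, 0.51, 0.13))
    return env * shape


def _style_draws(style: str, gen: GeneratorConfig,
                 participant_rng: np.random.Generator) -> tuple[float, float]:
    """Per-participant style offsets: (FPA offset deg, step-width offset m)."""
    tr = gen.offset_truncation_sd
    if style == "toe_out":
        return (_truncated_normal(participant_rng, gen.fpa_offset_mean_deg,
                                  gen.fpa_offset_sd_deg, tr), 0.0)
    if style == "toe_in":
        return (-_truncated_normal(participant_rng, gen.fpa_offset_mean_deg,
                                   gen.fpa_offset_sd_deg, tr), 0.0)
    if style == "wide":
        return (0.0, _truncated_normal(participant_rng,
                                       gen.step_width_offset_mean_m,
                                       gen.step_width_offset_sd_m, tr))
    if style == "normal":
        return (0.0, 0.0)
    raise ConfigurationError(f"unknown gait style '{style}'")


def generate_trial(participant: Participant, style: str, trial_index: int,
                   gen: GeneratorConfig, seed) -> GaitTrial:
    """Generate one stance-phase trial.

    ``seed`` may be an int or a sequence (hierarchical seeding). The
    per-participant style offset is drawn from a sub-stream that depends only
    on (participant seed material, style), so all five trials of a style share
    one offset; per-trial jitter and smooth waveform noise differentiate them.
    """
    if style not in STYLES:
        raise ConfigurationError(f"unknown gait style '{style}'")
    base = np.random.SeedSequence(_as_entropy(seed))
    # Offset stream keyed by style only (not trial), so trials share offsets.
    style_idx = STYLES.index(style)
    offset_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=base.entropy, spawn_key=(style_idx,)))
    trial_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=base.entropy,
                               spawn_key=(style_idx, 1000 + trial_index)))

    fpa_offset, sw_offset = _style_draws(style, gen, offset_rng)

    speed = _truncated_normal(trial_rng, gen.speed_mean[style],
                              gen.speed_sd[style], gen.truncation_sd)
    fpa = (gen.fpa_normal_deg + fpa_offset
           + _truncated_normal(trial_rng, 0.0, gen.fpa_trial_sd_deg,
                               gen.truncation_sd))
    step_width = (gen.step_width_mean_m + sw_offset
                  + _truncated_normal(trial_rng, 0.0, gen.step_width_trial_sd_m,
                                      gen.truncation_sd))

    n = gen.n_phase
    phase = np.linspace(0.0, 100.0, n)
    s = phase / 100.0
    bw = participant.mass_kg * _G

    # Templates scale with the style's mean speed (not the trial's draw), so
    # the speed draw leaves the waveforms untouched: with zero noise, trials
    # of a style differ only in their speed value.
    style_speed = gen.speed_mean[style]
    angles = _angle_templates(s, style_speed)
    for name in angles:
        angles[name] = angles[name] + _smooth_noise(
            trial_rng, s, gen.angle_noise_deg)
    # Wider stance slightly reduces hip adduction (leg more vertical).
    leg = (participant.segment_lengths_m["thigh"]
           + participant.segment_lengths_m["shank"])
    angles["hip_add"] = angles["hip_add"] - 0.5 * math.degrees(
        math.asin(min(max(sw_offset, -leg), leg) / leg))
    angles["knee_flex"] = np.clip(angles["knee_flex"], 0.0, 90.0)

    # Vertical GRF: shape normalized so the stance-average equals body weight,
    # then endpoint-zero noise is superimposed.
    raw = _vertical_grf_shape(s, style_speed)
    raw = raw * (1.0 + _smooth_noise(trial_rng, s, gen.grf_noise_rel)
                 * np.sin(np.pi * s))
    grf_y = bw * raw / np.trapezoid(raw, s)
    grf_y = np.clip(grf_y, 0.0, None)
    grf_y[0] = 0.0
    grf_y[-1] = 0.0

    env = np.sin(np.pi * s)
    grf_x = bw * 0.12 * (-np.sin(2.0 * np.pi * s)) * env ** 0.5
    grf_z = bw * 0.04 * env
    # Wider stance points the GRF more medially (toward the midline).
    grf_z = grf_z - bw * 0.8 * sw_offset * env

    # Centre of pressure progresses heel -> toe along the foot's long axis;
    # the foot axis is rotated by the foot progression angle, so toe-out
    # shifts the late-stance CoP laterally.
    foot_len = participant.segment_lengths_m["foot"]
    u = foot_len * (-0.30 + 0.85 * _smoothstep(s))
    fpa_rad = math.radians(fpa)
    cop_x = math.cos(fpa_rad) * u + _smooth_noise(trial_rng, s, gen.cop_noise_m)
    cop_z = math.sin(fpa_rad) * u + _smooth_noise(trial_rng, s, gen.cop_noise_m)
    cop = np.column_stack([cop_x, cop_z])

    stored_seed = int(base.entropy if isinstance(base.entropy, int)
                      else base.entropy[0]) & 0x7FFFFFFF
    return GaitTrial(
        participant_id=participant.id, style=style, trial_index=trial_index,
        phase=phase, joint_angles=angles,
        grf=np.column_stack([grf_x, grf_y, grf_z]), cop=cop,
        foot_progression_angle_deg=fpa, step_width_m=step_width,
        speed_m_s=speed, seed=stored_seed, body_weight_n=bw)


def _as_entropy(seed) -> int | tuple[int, ...]:
    if isinstance(seed, (int, np.integer)):
        return int(seed)
    return tuple(int(x) for x in seed)


def participant_seed(master_seed: int, p_index: int) -> tuple[int, int, int]:
    """Deterministic participant-level seed material."""
    return (int(master_seed), 7919, int(p_index))


def trial_seed(master_seed: int, p_index: int) -> tuple[int, int, int]:
    """Seed material for a participant's trial generator (style/trial streams
    are derived inside :func:`generate_trial` via spawn keys)."""
    return (int(master_seed), 104729, int(p_index))


def generate_cohort(n_participants: int, n_trials: int, styles: list[str],
                    seed: int,
                    cohort: CohortConfig | None = None,
                    gen: GeneratorConfig | None = None,
                    ) -> tuple[list[Participant], list[GaitTrial]]:
    """Generate the full factorial design: participants x styles x trials."""
    if n_participants < 1 or n_trials < 1:
        raise ConfigurationError("n_participants and n_trials must be >= 1")
    cohort = cohort or CohortConfig()
    gen = gen or GeneratorConfig()
    participants: list[Participant] = []
    trials: list[GaitTrial] = []
    for p in range(n_participants):
        part = sample_participant(cohort, participant_seed(seed, p),
                                  pid=f"P{p + 1:02d}")
        participants.append(part)
        tseed = trial_seed(seed, p)
        for style in styles:
            for t in range(n_trials):
                trials.append(generate_trial(part, style, t, gen, tseed))
    return participants, trials


# ---------------------------------------------------------------------------
# Serialization

def trial_to_frame(trial: GaitTrial) -> pd.DataFrame:
    data = {
        "phase": trial.phase,
        "hip_flex": trial.joint_angles["hip_flex"],
        "hip_add": trial.joint_angles["hip_add"],
        "hip_rot": trial.joint_angles["hip_rot"],
        "knee_flex": trial.joint_angles["knee_flex"],
        "ankle_pf": trial.joint_angles["ankle_pf"],
        "ankle_inv": trial.joint_angles["ankle_inv"],
        "grf_x": trial.grf[:, 0], "grf_y": trial.grf[:, 1],
        "grf_z": trial.grf[:, 2],
        "cop_x": trial.cop[:, 0], "cop_z": trial.cop[:, 1],
    }
    return pd.DataFrame(data, columns=TRIAL_COLUMNS)


def write_trial(trial: GaitTrial, path: str | Path,
                participant: Participant | None = None) -> None:
    """Write one trial as CSV plus a YAML metadata sidecar."""
    path = Path(path)
    trial_to_frame(trial).to_csv(path, index=False, float_format="%.17g")
    meta = {
        "participant_id": trial.participant_id, "style": trial.style,
        "trial_index": trial.trial_index,
        "foot_progression_angle_deg": float(trial.foot_progression_angle_deg),
        "step_width_m": float(trial.step_width_m),
        "speed_m_s": float(trial.speed_m_s), "seed": int(trial.seed),
        "body_weight_n": float(trial.body_weight_n),
    }
    if participant is not None:
        meta["anthropometrics"] = {
            "mass_kg": float(participant.mass_kg),
            "height_m": float(participant.height_m),
            "bmi": float(participant.bmi),
            "fat_fraction": float(participant.fat_fraction),
        }
    path.with_suffix(".meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def read_trial(path: str | Path) -> GaitTrial:
    """Read a trial CSV (+ sidecar) written by :func:`write_trial`."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"trial file missing columns {missing}")
    meta = yaml.safe_load(path.with_suffix(".meta.yaml").read_text())
    angles = {k: df[k].to_numpy() for k in
              ("hip_flex", "hip_add", "hip_rot", "knee_flex",
               "ankle_pf", "ankle_inv")}
    return GaitTrial(
        participant_id=meta["participant_id"], style=meta["style"],
        trial_index=int(meta["trial_index"]),
        phase=df["phase"].to_numpy(), joint_angles=angles,
        grf=df[["grf_x", "grf_y", "grf_z"]].to_numpy(),
        cop=df[["cop_x", "cop_z"]].to_numpy(),
        foot_progression_angle_deg=float(meta["foot_progression_angle_deg"]),
        step_width_m=float(meta["step_width_m"]),
        speed_m_s=float(meta["speed_m_s"]), seed=int(meta["seed"]),
        body_weight_n=float(meta["body_weight_n"]))


def check_trial_invariants(trial: GaitTrial) -> None:
    """Assert the structural invariants every generated trial must satisfy."""
    ph = trial.phase
    if not (np.all(np.diff(ph) > 0) and ph[0] == 0.0 and ph[-1] == 100.0):
        raise AssertionError("phase grid must increase strictly from 0 to 100")
    fy = trial.grf[:, 1]
    if not (np.all(fy >= 0) and fy[0] == 0 and fy[-1] == 0):
        raise AssertionError("vertical GRF must be >= 0 and 0 at endpoints")
    kf = trial.joint_angles["knee_flex"]
    if not (np.all(kf >= 0) and np.all(kf <= 90)):
        raise AssertionError("knee flexion must stay within [0, 90] deg")
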