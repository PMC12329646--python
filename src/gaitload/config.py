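"""Study configuration: defaults, validation, YAML round-trip, hashing.

Every tunable of the pipeline lives here in one nested dataclass tree.
Defaults marked "cohort/speed" reproduce the study conditions (participant
anthropometrics, per-style walking speeds, the 40% strength reduction, the
connector stiffnesses); the remaining defaults are the package's own
configuration choices and are documented in ``docs/methods.md``.

Serialization is strict: unknown keys are rejected with the offending key
named, and ``load_config(save_config(cfg)) == cfg``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigurationError

#: Gait styles in study order.
STYLES = ("normal", "toe_out", "toe_in", "wide")

#: Muscle groups eligible for strength reduction.
MUSCLE_GROUPS = (
    "knee_extensor", "knee_flexor", "hip_abductor", "hip_adductor",
    "ankle_extensor", "ankle_dorsiflexor", "hip_flexor", "hip_extensor",
)


@dataclass
class CohortConfig:
    """Anthropometric sampling distributions for the synthetic cohort.

    Mass/height means and SDs are the study cohort statistics
    (76.3 ± 8.6 kg, 1.777 ± 0.037 m, age 29); the fat-fraction regression is
    an adult body-fat equation BF% = slope·BMI + age_slope·age + sex_offset
    (male offset −10.8 − 5.4 = −16.2), clamped to (floor, ceiling).
    """

    mass_mean_kg: float = 76.3
    mass_sd_kg: float = 8.6
    height_mean_m: float = 1.777
    height_sd_m: float = 0.037
    age_yr: float = 29.0
    fat_bmi_slope: float = 1.20
    fat_age_slope: float = 0.23
    fat_sex_offset: float = -16.2
    fat_floor: float = 0.03
    fat_ceiling: float = 0.60
    truncation_sd: float = 3.0
    # Segment lengths as fractions of stature (thigh/shank from standard
    # anthropometric tables, foot = foot length).
    thigh_fraction: float = 0.245
    shank_fraction: float = 0.246
    foot_fraction: float = 0.152


@dataclass
class GeneratorConfig:
    """Stance-phase waveform generator parameters.

    Speeds are the per-style means/SDs of the study (m/s); style offsets are
    configuration (the magnitudes participants achieved are not published).
    The foot-progression-angle (FPA) and step-width style offsets are drawn
    once per participant; per-trial jitter and smooth waveform noise make the
    five trials of a style differ.
    """

    n_phase: int = 101
    speed_mean: dict[str, float] = field(default_factory=lambda: {
        "normal": 1.16, "toe_out": 1.05, "toe_in": 1.04, "wide": 1.09})
    speed_sd: dict[str, float] = field(default_factory=lambda: {
        "normal": 0.14, "toe_out": 0.11, "toe_in": 0.12, "wide": 0.13})
    fpa_normal_deg: float = 5.0
    fpa_offset_mean_deg: float = 10.0
    fpa_offset_sd_deg: float = 2.0
    fpa_trial_sd_deg: float = 0.5
    step_width_mean_m: float = 0.10
    step_width_offset_mean_m: float = 0.10
    step_width_offset_sd_m: float = 0.02
    step_width_trial_sd_m: float = 0.004
    angle_noise_deg: float = 1.5
    grf_noise_rel: float = 0.015
    cop_noise_m: float = 0.002
    stance_fraction: float = 0.62
    stride_length_factor: float = 0.80  # stride length = factor * height
    truncation_sd: float = 3.0
    offset_truncation_sd: float = 3.0


@dataclass
class ModelConfig:
    """Reference musculoskeletal model parameters (non-paper defaults)."""

    reference_mass_kg: float = 75.0
    reference_height_m: float = 1.75
    reference_fat_fraction: float = 0.20
    hip_lateral_offset_m: float = 0.09
    ankle_height_fraction: float = 0.039  # of stature
    thigh_mass_fraction: float = 0.100
    shank_mass_fraction: float = 0.0465
    foot_mass_fraction: float = 0.0145
    com_fraction: float = 0.433  # segment COM position from proximal end
    arm_cosine_modulation: bool = False
    arm_modulation_amplitude: float = 0.15
    transverse_moment_fraction: float = 0.1


@dataclass
class RecruitmentConfig:
    """Static-optimization settings: polynomial order p and tolerances."""

    power: float = 3.0
    tol: float = 1e-8
    max_iter: int = 200


@dataclass
class ConnectorConfig:
    """Connector restraints on secondary knee kinematics.

    Units follow the study text exactly: translations N/mm, rotations
    N·m/degree. Defaults 0.5 / 1.2 / 0.2 / 0.9.
    """

    tf_translation_n_per_mm: float = 0.5
    tf_rotation_nm_per_deg: float = 1.2
    patellar_translation_n_per_mm: float = 0.2
    patellar_rotation_nm_per_deg: float = 0.9


@dataclass
class ContactConfig:
    """Elastic-foundation tibial-plateau contact surrogate parameters."""

    elements_per_side: int = 8
    plateau_length_m: float = 0.020  # anteroposterior extent per compartment
    plateau_width_m: float = 0.015   # mediolateral extent per compartment
    intercondylar_spacing_m: float = 0.040
    thickness_m: float = 0.003
    poisson_ratio: float = 0.42
    effective_modulus_pa: float = 4.0e6
    condyle_radius_ap_m: float = 0.08
    condyle_radius_ml_m: float = 0.04
    rollback_m_per_deg: float = 1.5e-4
    pulley_ratio_20deg: float = 0.7
    pulley_ratio_60deg: float = 1.0
    connectors: ConnectorConfig = field(default_factory=ConnectorConfig)
    newton_max_iter: int = 100
    newton_tol_rel: float = 1e-9


@dataclass
class CartilageConfig:
    """1-D biphasic column defaults (general cartilage literature values,
    not study values): aggregate modulus H_A, permeability k, thickness."""

    thickness_m: float = 0.003
    aggregate_modulus_pa: float = 0.5e6
    permeability_m4_per_ns: float = 2.0e-15
    n_nodes: int = 100


@dataclass
class StudyConfig:
    """Top-level study configuration (the full 7 x 4 x 5 design)."""

    n_participants: int = 7
    n_trials: int = 5
    styles: list[str] = field(default_factory=lambda: list(STYLES))
    reduced_groups: list[str] = field(default_factory=lambda: [
        "knee_extensor", "hip_abductor", "ankle_extensor"])
    strength_reduction: float = 0.40
    master_seed: int = 1
    late_stance_window: list[float] = field(default_factory=lambda: [70.0, 90.0])
    ref_stress_floor_mpa: float = 0.01
    cohort: CohortConfig = field(default_factory=CohortConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    recruitment: RecruitmentConfig = field(default_factory=RecruitmentConfig)
    contact: ContactConfig = field(default_factory=ContactConfig)
    cartilage: CartilageConfig = field(default_factory=CartilageConfig)


def _from_dict(cls: type, data: dict[str, Any], path: str = "") -> Any:
    """Build a dataclass from a nested dict, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ConfigurationError(f"expected a mapping at '{path or cls.__name__}'")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        key = sorted(unknown)[0]
        raise ConfigurationError(
            f"unknown configuration key '{path + key}'")
    kwargs: dict[str, Any] = {}
    for name, f in known.items():
        if name not in data:
            continue
        value = data[name]
        ftype = f.type if isinstance(f.type, type) else None
        if ftype is None and is_dataclass(_resolve_type(f)):
            ftype = _resolve_type(f)
        if ftype is not None and is_dataclass(ftype):
            kwargs[name] = _from_dict(ftype, value, path + name + ".")
        else:
            kwargs[name] = value
    return cls(**kwargs)


_NESTED = {
    "cohort": CohortConfig, "generator": GeneratorConfig,
    "model": ModelConfig, "recruitment": RecruitmentConfig,
    "contact": ContactConfig, "cartilage": CartilageConfig,
    "connectors": ConnectorConfig,
}


def _resolve_type(f: dataclasses.Field) -> type | None:
    return _NESTED.get(f.name)


def validate_config(cfg: StudyConfig) -> StudyConfig:
    """Check cross-field invariants; return the config unchanged if valid."""
    if not (0.0 <= cfg.strength_reduction < 1.0):
        raise ConfigurationError(
            f"strength_reduction must be in [0, 1), got {cfg.strength_reduction}")
    if cfg.n_participants < 1 or cfg.n_trials < 1:
        raise ConfigurationError("n_participants and n_trials must be >= 1")
    for s in cfg.styles:
        if s not in STYLES:
            raise ConfigurationError(f"unknown gait style '{s}'")
    for g in cfg.reduced_groups:
        if g not in MUSCLE_GROUPS:
            raise ConfigurationError(f"unknown muscle group '{g}'")
    for name, val in (("mass_mean_kg", cfg.cohort.mass_mean_kg),
                      ("height_mean_m", cfg.cohort.height_mean_m)):
        if not (val > 0) or not _finite(val):
            raise ConfigurationError(f"cohort.{name} must be finite and > 0")
    for name, val in (("mass_sd_kg", cfg.cohort.mass_sd_kg),
                      ("height_sd_m", cfg.cohort.height_sd_m)):
        if val < 0 or not _finite(val):
            raise ConfigurationError(f"cohort.{name} must be finite and >= 0")
    if cfg.generator.n_phase < 3:
        raise ConfigurationError("generator.n_phase must be >= 3")
    con = cfg.contact.connectors
    for name in ("tf_translation_n_per_mm", "tf_rotation_nm_per_deg",
                 "patellar_translation_n_per_mm", "patellar_rotation_nm_per_deg"):
        if getattr(con, name) < 0:
            raise ConfigurationError(f"contact.connectors.{name} must be >= 0")
    if cfg.contact.elements_per_side ** 2 < 64:
        raise ConfigurationError("contact grid must have >= 64 elements per compartment")
    if cfg.cartilage.n_nodes < 20:
        raise ConfigurationError("cartilage.n_nodes must be >= 20")
    return cfg


def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


def config_from_dict(data: dict[str, Any] | None) -> StudyConfig:
    """Build and validate a StudyConfig from a (possibly empty) mapping."""
    cfg = _from_dict(StudyConfig, data or {})
    return validate_config(cfg)


def config_to_dict(cfg: StudyConfig) -> dict[str, Any]:
    return dataclasses.asdict(cfg)


def load_config(path: str | Path) -> StudyConfig:
    """Load a YAML config file; an empty file yields full defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    return config_from_dict(data)


def save_config(cfg: StudyConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))


def config_hash(cfg: StudyConfig) -> str:
    """SHA-256 of the canonical JSON form; changes iff the config changes."""
    blob = json.dumps(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
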