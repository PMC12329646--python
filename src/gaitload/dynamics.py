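"""Net joint moments and intersegmental forces over the stance phase.

A bottom-up (foot -> shank -> thigh) quasi-static Newton-Euler recursion on a
planar-pair decomposition: the sagittal and frontal planes are solved as two
planar problems sharing the vertical force, and the transverse (hip rotation)
moment is a configurable fraction of the frontal moment. An ``inertial`` mode
adds segment inertial terms finite-differenced from the generated waveforms;
quasi-static is the study default (stance-phase inertial contributions are
second order for the sensitivity statistics computed here).

Limb posture is reconstructed from the joint-angle waveforms with a foot-flat
plus heel-rise model: the shank tilts forward by the dorsiflexion angle, a
smooth heel-rise ramp carries the shank over the forefoot in late stance, and
the thigh is oriented by the knee flexion angle. The posture only sets lever
arms; no marker data are involved.

Internal-moment sign conventions follow :data:`gaitload.model.DOFS`:
hip flexion +, hip adduction +, hip internal rotation +, knee extension +,
ankle plantarflexion +, ankle inversion +.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .model import DOFS, MusculoskeletalModel
from .synthetic import GaitTrial

_G = 9.81
_STEP_WIDTH_REF = 0.10
_HEEL_RISE_PER_M = 4.0      # rad of shank rotation per m of anterior CoP
_HEEL_RISE_CAP_RAD = 0.6


@dataclass
class NetLoads:
    """Inverse-dynamics output on the trial's phase grid.

    ``moments`` is (n, 6) in DOFS order: the internal net moments the muscles
    must produce (the recruitment right-hand side). ``knee_adduction_ext`` is
    the external frontal-plane knee moment, adduction-positive (the classical
    knee adduction moment); it is not a recruitment row (the knee is a 1-DoF
    hinge) but is carried to the contact stage. Intersegmental forces are the
    forces transmitted to the distal segment at each joint, lab frame
    (x anterior, y up, z lateral). ``knee_compression`` is the positive
    axial (along-shank) component of the knee intersegmental force.
    """

    phase: np.ndarray
    moments: np.ndarray
    knee_adduction_ext: np.ndarray
    intersegmental: dict[str, np.ndarray]
    knee_compression: np.ndarray
    stance_duration_s: float
    mode: str

    @property
    def n_samples(self) -> int:
        return self.phase.size


def _posture(trial: GaitTrial, model: MusculoskeletalModel):
    """Joint centre and segment-COM positions per sample (lab frame)."""
    s = trial.phase / 100.0
    L_shank = model.segments["shank"].length_m
    L_thigh = model.segments["thigh"].length_m
    L_foot = model.segments["foot"].length_m
    h_ankle = model.ankle_height_m

    pf = np.radians(trial.joint_angles["ankle_pf"])
    knee_flex = np.radians(trial.joint_angles["knee_flex"])
    # Heel rise: the shank rotates forward over the forefoot as the centre
    # of pressure progresses toward the toes (data-driven, so a static trial
    # with a centred CoP stays a vertical chain).
    heel_rise = np.clip(_HEEL_RISE_PER_M * np.clip(trial.cop[:, 0], 0.0, None),
                        0.0, _HEEL_RISE_CAP_RAD)
    phi_shank = -pf + heel_rise           # forward tilt from vertical
    phi_thigh = phi_shank - knee_flex

    n = s.size
    ankle = np.zeros((n, 3))
    ankle[:, 1] = h_ankle
    knee = ankle + L_shank * np.column_stack(
        [np.sin(phi_shank), np.cos(phi_shank), np.zeros(n)])
    hip = knee + L_thigh * np.column_stack(
        [np.sin(phi_thigh), np.cos(phi_thigh), np.zeros(n)])

    # Frontal offsets: the hip sits lateral to the foot; a wider stance
    # brings the hip medially relative to the stance foot.
    hip_z = (model.hip_lateral_offset_m
             - 0.5 * (trial.step_width_m - _STEP_WIDTH_REF))
    hip[:, 2] = hip_z
    frac = L_shank / (L_shank + L_thigh)
    knee[:, 2] = frac * hip_z

    com_f = model.segments["foot"].com_fraction
    com_frac = model.segments["shank"].com_fraction
    foot_com = ankle.copy()
    foot_com[:, 0] += com_f * 0.5 * L_foot
    foot_com[:, 1] = h_ankle / 2.0
    shank_com = knee + com_frac * (ankle - knee)
    thigh_com = hip + model.segments["thigh"].com_fraction * (knee - hip)

    angles = {"foot": np.zeros(n), "shank": phi_shank, "thigh": phi_thigh}
    return ({"ankle": ankle, "knee": knee, "hip": hip},
            {"foot": foot_com, "shank": shank_com, "thigh": thigh_com},
            angles)


def _sagittal_moment(r: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Geometric sagittal scalar: positive rotates +x toward +y."""
    return r[:, 0] * f[:, 1] - r[:, 1] * f[:, 0]


def _frontal_adduction(r: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Adduction-positive frontal scalar (torque about +x anterior axis)."""
    return r[:, 1] * f[:, 2] - r[:, 2] * f[:, 1]


_DISTAL = {"ankle": ("foot",), "knee": ("foot", "shank"),
           "hip": ("foot", "shank", "thigh")}


def stance_duration(trial: GaitTrial, model: MusculoskeletalModel,
                    stance_fraction: float = 0.62,
                    stride_length_factor: float = 0.80) -> float:
    """Stance time from the trial's speed: stride length is a fixed fraction
    of stature, stance a fixed fraction of the stride."""
    stride_length = stride_length_factor * model.height_m
    stride_time = stride_length / max(trial.speed_m_s, 1e-6)
    return stance_fraction * stride_time


def inverse_dynamics(trial: GaitTrial, model: MusculoskeletalModel,
                     mode: str = "quasi_static") -> NetLoads:
    """Compute net joint moments and intersegmental forces for one trial."""
    if mode not in ("quasi_static", "inertial"):
        raise InvalidInputError(f"unknown mode '{mode}'")
    ph = trial.phase
    if ph.ndim != 1 or ph.size < 3 or not np.all(np.diff(ph) > 0):
        raise InvalidInputError("trial phase grid must be strictly increasing")
    for name, arr in trial.joint_angles.items():
        if arr.shape != ph.shape:
            raise InvalidInputError(f"joint angle '{name}' does not match the "
                                    "phase grid")
    if trial.grf.shape[0] != ph.size or trial.cop.shape[0] != ph.size:
        raise InvalidInputError("GRF/CoP grids do not match the phase grid")

    n = ph.size
    joints, coms, seg_angles = _posture(trial, model)
    grf = trial.grf
    cop = np.column_stack([trial.cop[:, 0],
                           np.zeros(n),
                           trial.cop[:, 1]])

    T = stance_duration(trial, model)
    masses = {name: model.segments[name].mass_kg for name in
              ("foot", "shank", "thigh")}

    # Inertial terms (d'Alembert forces at the COMs and rotary torques).
    inert_force = {k: np.zeros((n, 3)) for k in masses}
    inert_torque = {k: np.zeros(n) for k in masses}
    if mode == "inertial":
        t = (ph / 100.0) * T
        for name in masses:
            acc = np.gradient(np.gradient(coms[name], t, axis=0), t, axis=0)
            inert_force[name] = -masses[name] * acc
            alpha = np.gradient(np.gradient(seg_angles[name], t), t)
            inert_torque[name] = -model.segments[name].moment_of_inertia * alpha

    gravity = {name: np.tile([0.0, -masses[name] * _G, 0.0], (n, 1))
               for name in masses}

    sag_ext = {}
    add_ext = {}
    for joint, pos in joints.items():
        s_ext = _sagittal_moment(cop - pos, grf)
        a_ext = _frontal_adduction(cop - pos, grf)
        for seg in _DISTAL[joint]:
            r = coms[seg] - pos
            s_ext = s_ext + _sagittal_moment(r, gravity[seg])
            a_ext = a_ext + _frontal_adduction(r, gravity[seg])
            if mode == "inertial":
                s_ext = s_ext + _sagittal_moment(r, inert_force[seg])
                a_ext = a_ext + _frontal_adduction(r, inert_force[seg])
                s_ext = s_ext + inert_torque[seg]
        sag_ext[joint] = s_ext
        add_ext[joint] = a_ext

    moments = np.zeros((n, len(DOFS)))
    moments[:, DOFS.index("hip_flex")] = -sag_ext["hip"]
    moments[:, DOFS.index("hip_add")] = -add_ext["hip"]
    moments[:, DOFS.index("hip_rot")] = (model.transverse_moment_fraction
                                         * -add_ext["hip"])
    moments[:, DOFS.index("knee")] = -sag_ext["knee"]
    moments[:, DOFS.index("ankle_pf")] = sag_ext["ankle"]
    moments[:, DOFS.index("ankle_inv")] = -add_ext["ankle"]

    # Intersegmental force transmitted at each joint (on the distal segment).
    inter = {}
    for joint in joints:
        total = grf.copy()
        for seg in _DISTAL[joint]:
            total = total + gravity[seg]
            if mode == "inertial":
                total = total + inert_force[seg]
        inter[joint] = -total

    # Axial (along-shank) compression at the knee, positive in compression.
    shank_axis = joints["ankle"] - joints["knee"]
    shank_axis = shank_axis / np.linalg.norm(shank_axis, axis=1, keepdims=True)
    knee_comp = np.einsum("ij,ij->i", inter["knee"], shank_axis)
    knee_comp = np.clip(knee_comp, 0.0, None)

    if not np.all(np.isfinite(moments)):
        raise InvalidInputError("non-finite net moments")
    return NetLoads(phase=ph.copy(), moments=moments,
                    knee_adduction_ext=add_ext["knee"],
                    intersegmental=inter, knee_compression=knee_comp,
                    stance_duration_s=T, mode=mode)


def netloads_to_frame(loads: NetLoads):
    """Tidy DataFrame mirroring the trial CSV layout (one column per DoF)."""
    import pandas as pd
    data = {"phase": loads.phase}
    for i, dof in enumerate(DOFS):
        data[f"moment_{dof}"] = loads.moments[:, i]
    data["knee_adduction_ext"] = loads.knee_adduction_ext
    for joint, f in loads.intersegmental.items():
        for k, ax in enumerate("xyz"):
            data[f"force_{joint}_{ax}"] = f[:, k]
    return pd.DataFrame(data)
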