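"""Full-study orchestration: cohort -> dynamics -> recruitment -> contact ->
sensitivity statistics.

The default design mirrors the study: 7 participants x 4 gait styles x
5 trials, four strength conditions per participant (reference plus a uniform
40% isometric-strength reduction of the knee extensors, hip abductors, or
ankle extensors). Per participant and style the five trials' knee-load
traces are averaged per condition, one contact solve is run per
(style, condition) cell (16 per participant), and the upper-quartile stress
summaries feed the %Change / PP_Difference statistics, cohort aggregation
and the paired tests.

Everything is deterministic given (config, master seed): re-running writes
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import model as mdl
from .config import StudyConfig, config_hash
from .contact import (ConnectorSet, KneeLoadTrace, assemble_knee_loads,
                      average_traces, build_plateau_geometry, solve_contact,
                      upper_quartile_summary, COMPARTMENTS)
from .dynamics import inverse_dynamics
from .errors import GaitLoadError
from .recruitment import solve_trace
from .stats import (cohort_aggregate, paired_t, percent_change, pp_difference,
                    rm_anova_bonferroni, signed_percent_change)
from .synthetic import (GaitTrial, Participant, generate_trial,
                        participant_seed, sample_participant, trial_seed)

REFERENCE = "reference"


@dataclass
class StudyResult:
    """All study outputs, as tidy DataFrames plus raw summary arrays."""

    config: StudyConfig
    participants: list[Participant]
    phase: np.ndarray
    #: {participant_id: {style: {condition: (n_samples, 2) upper-quartile MPa}}}
    summaries: dict[str, dict[str, dict[str, np.ndarray]]]
    speeds: pd.DataFrame
    stress: pd.DataFrame
    change: pd.DataFrame
    pp: pd.DataFrame
    cohort_change: pd.DataFrame
    cohort_pp: pd.DataFrame
    peaks: pd.DataFrame
    peak_tests: pd.DataFrame
    speed_anova: dict
    failures: list[dict] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def late_stance_direction(self) -> pd.DataFrame:
        """Per-participant mean signed late-stance medial stress change (%)
        for each reduced-strength condition, averaged over all gait styles.

        The sign structure expected from the mechanics: negative for reduced
        ankle-extensor strength (less gastrocnemius push-off compression),
        positive for reduced hip-abductor strength (extensor/flexor
        compensation raises joint compression).
        """
        lo, hi = self.config.late_stance_window
        win = (self.phase >= lo) & (self.phase <= hi)
        rows = []
        med = COMPARTMENTS.index("medial")
        for part in self.participants:
            per_style = self.summaries.get(part.id, {})
            for cond in self.config.reduced_groups:
                vals = []
                for style, conds in per_style.items():
                    if REFERENCE not in conds or cond not in conds:
                        continue
                    ref = conds[REFERENCE][:, med]
                    red = conds[cond][:, med]
                    sc = signed_percent_change(
                        red, ref, floor=self.config.ref_stress_floor_mpa)
                    vals.append(np.nanmean(sc[win]))
                if vals:
                    rows.append({"participant": part.id, "condition": cond,
                                 "mean_signed_change_pct": float(np.mean(vals))})
        return pd.DataFrame(rows)


def _participant_pipeline(cfg: StudyConfig, p_index: int,
                          failures: list[dict]):
    """Everything for one participant; returns (participant, speeds rows,
    summaries dict)."""
    part = sample_participant(cfg.cohort, participant_seed(cfg.master_seed,
                                                           p_index),
                              pid=f"P{p_index + 1:02d}")
    reference = mdl.scale_model(
        mdl.default_reference_model(cfg.model), part,
        reference_fat_fraction=cfg.model.reference_fat_fraction)
    conditions = mdl.build_strength_conditions(
        reference, fraction=cfg.strength_reduction,
        groups=tuple(cfg.reduced_groups))

    geometry = build_plateau_geometry(cfg.contact)
    connectors = ConnectorSet.from_config(cfg.contact.connectors)
    tseed = trial_seed(cfg.master_seed, p_index)

    speed_rows = []
    summaries: dict[str, dict[str, np.ndarray]] = {}
    for style in cfg.styles:
        trials: list[GaitTrial] = []
        for t in range(cfg.n_trials):
            trial = generate_trial(part, style, t, cfg.generator, tseed)
            trials.append(trial)
            speed_rows.append({"participant": part.id, "style": style,
                               "trial": t, "speed_m_s": trial.speed_m_s})
        loads = [inverse_dynamics(tr, reference) for tr in trials]
        for cond_name, cond_model in conditions.items():
            try:
                traces: list[KneeLoadTrace] = []
                for tr, ld in zip(trials, loads):
                    forces = solve_trace(ld, cond_model,
                                         tol=cfg.recruitment.tol,
                                         power=cfg.recruitment.power,
                                         joint_angles=tr.joint_angles)
                    traces.append(assemble_knee_loads(
                        tr, ld, forces, cond_model, condition=cond_name,
                        cfg=cfg.contact))
                mean_trace = average_traces(traces)
                stress_field = solve_contact(
                    mean_trace, geometry, connectors,
                    max_iter=cfg.contact.newton_max_iter,
                    tol_rel=cfg.contact.newton_tol_rel)
                summary = upper_quartile_summary(stress_field)
                summaries.setdefault(style, {})[cond_name] = \
                    summary.upper_quartile_mpa
            except GaitLoadError as err:
                failures.append({"participant": part.id, "style": style,
                                 "condition": cond_name,
                                 "error": type(err).__name__,
                                 "message": str(err)})
    return part, speed_rows, summaries


def run_study(cfg: StudyConfig) -> StudyResult:
    """Run the complete sensitivity study defined by ``cfg``."""
    failures: list[dict] = []
    participants: list[Participant] = []
    all_speed_rows: list[dict] = []
    summaries: dict[str, dict[str, dict[str, np.ndarray]]] = {}
    phase = np.linspace(0.0, 100.0, cfg.generator.n_phase)

    for p in range(cfg.n_participants):
        part, speed_rows, summ = _participant_pipeline(cfg, p, failures)
        participants.append(part)
        all_speed_rows.extend(speed_rows)
        summaries[part.id] = summ

    speeds = pd.DataFrame(all_speed_rows)

    stress_rows = []
    change_rows = []
    peak_rows = []
    floor = cfg.ref_stress_floor_mpa
    for pid, per_style in summaries.items():
        for style, conds in per_style.items():
            for cond, uq in conds.items():
                for c, comp in enumerate(COMPARTMENTS):
                    k = int(np.argmax(uq[:, c]))
                    peak_rows.append({
                        "participant": pid, "style": style, "condition": cond,
                        "compartment": comp,
                        "peak_mpa": float(uq[k, c]),
                        "peak_phase": float(phase[k])})
                    for i in range(phase.size):
                        stress_rows.append({
                            "participant": pid, "style": style,
                            "condition": cond, "compartment": comp,
                            "phase": float(phase[i]),
                            "stress_mpa": float(uq[i, c])})
            if REFERENCE not in conds:
                continue
            ref = conds[REFERENCE]
            for cond in cfg.reduced_groups:
                if cond not in conds:
                    continue
                for c, comp in enumerate(COMPARTMENTS):
                    pc = percent_change(conds[cond][:, c], ref[:, c], floor)
                    sc = signed_percent_change(conds[cond][:, c], ref[:, c],
                                               floor)
                    for i in range(phase.size):
                        change_rows.append({
                            "participant": pid, "style": style,
                            "condition": cond, "compartment": comp,
                            "phase": float(phase[i]),
                            "pct_change": float(pc[i]),
                            "signed_change": float(sc[i])})
    stress = pd.DataFrame(stress_rows)
    change = pd.DataFrame(change_rows)

    # PP_Difference: modified-gait change minus normal-gait change.
    modified_styles = [s for s in cfg.styles if s != "normal"]
    pp = pd.DataFrame()
    if "normal" in cfg.styles and not change.empty:
        key = ["participant", "condition", "compartment", "phase"]
        normal = (change[change["style"] == "normal"][key + ["pct_change"]]
                  .rename(columns={"pct_change": "normal_change"}))
        modified = change[change["style"].isin(modified_styles)]
        if not modified.empty:
            merged = modified.merge(normal, on=key, how="inner")
            merged["pp_difference"] = pp_difference(
                merged["pct_change"].to_numpy(),
                merged["normal_change"].to_numpy())
            pp = merged[["participant", "style", "condition", "compartment",
                         "phase", "pp_difference"]].copy()

    cohort_change = _cohort_curves(change, "pct_change",
                                   ["style", "condition", "compartment"])
    cohort_pp = _cohort_curves(pp, "pp_difference",
                               ["style", "condition", "compartment"])

    peaks = pd.DataFrame(peak_rows)
    peak_tests = _peak_tests(peaks, cfg)
    speed_anova = _speed_anova(speeds, cfg)

    manifest = {
        "config_hash": config_hash(cfg),
        "master_seed": int(cfg.master_seed),
        "participant_seeds": {f"P{p + 1:02d}": list(participant_seed(
            cfg.master_seed, p)) for p in range(cfg.n_participants)},
        "n_failures": len(failures),
        "failures": failures,
    }
    return StudyResult(config=cfg, participants=participants, phase=phase,
                       summaries=summaries, speeds=speeds, stress=stress,
                       change=change, pp=pp, cohort_change=cohort_change,
                       cohort_pp=cohort_pp, peaks=peaks,
                       peak_tests=peak_tests, speed_anova=speed_anova,
                       failures=failures, manifest=manifest)


def _cohort_curves(df: pd.DataFrame, value: str,
                   keys: list[str]) -> pd.DataFrame:
    rows = []
    if df.empty:
        return pd.DataFrame(rows)
    for group_key, sub in df.groupby(keys):
        piv = sub.pivot_table(index="participant", columns="phase",
                              values=value)
        if piv.shape[0] < 2:
            continue
        agg = cohort_aggregate(piv.to_numpy())
        for i, ph in enumerate(piv.columns):
            rows.append(dict(zip(keys, group_key)) | {
                "phase": float(ph), "mean": float(agg.mean[i]),
                "ci_low": float(agg.ci_low[i]),
                "ci_high": float(agg.ci_high[i]), "n": agg.n})
    return pd.DataFrame(rows)


def _peak_tests(peaks: pd.DataFrame, cfg: StudyConfig) -> pd.DataFrame:
    """Paired t-tests: per style and compartment, reference peak stress vs
    each reduced-strength condition's peak stress across participants."""
    rows = []
    if peaks.empty:
        return pd.DataFrame(rows)
    for (style, comp), sub in peaks.groupby(["style", "compartment"]):
        piv = sub.pivot_table(index="participant", columns="condition",
                              values="peak_mpa")
        if REFERENCE not in piv.columns or piv.shape[0] < 2:
            continue
        for cond in cfg.reduced_groups:
            if cond not in piv.columns:
                continue
            res = paired_t(piv[REFERENCE].to_numpy(), piv[cond].to_numpy())
            rows.append({"style": style, "compartment": comp,
                         "condition": cond, "t": res.t, "df": res.df,
                         "p": res.p, "significant": res.significant})
    return pd.DataFrame(rows)


def _speed_anova(speeds: pd.DataFrame, cfg: StudyConfig) -> dict:
    """RM-ANOVA across styles on per-participant mean walking speeds."""
    piv = speeds.pivot_table(index="participant", columns="style",
                             values="speed_m_s")
    styles = [s for s in cfg.styles if s in piv.columns]
    piv = piv[styles]
    if piv.shape[0] < 2 or piv.shape[1] < 2:
        return {}
    res = rm_anova_bonferroni(piv.to_numpy())
    pairs = {f"{styles[i]}_vs_{styles[j]}": p
             for (i, j), p in res.pairwise.items()}
    return {"F": res.F, "df_num": res.df_num, "df_den": res.df_den,
            "p": res.p, "pairwise_bonferroni": pairs,
            "significant": res.significant}


def speed_table(speeds: pd.DataFrame) -> pd.DataFrame:
    """Max/min/mean +/- SD of walking speed per style (the session's speed
    summary table layout)."""
    rows = []
    for style, sub in speeds.groupby("style", sort=False):
        v = sub["speed_m_s"]
        rows.append({"style": style, "max_m_s": v.max(), "min_m_s": v.min(),
                     "mean_m_s": v.mean(), "sd_m_s": v.std(ddof=1)})
    return pd.DataFrame(rows)
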