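"""Generate a synthetic gait session and summarize it.

Builds a small cohort walking in all four styles, prints the per-style
walking-speed table (max/min/mean +/- SD, the usual gait-lab session
summary) and basic waveform facts for one trial. Foot progression angle
(FPA) is positive for toe-out; vertical GRF is normalized so its stance
average equals body weight.
"""

import numpy as np

import gaitload as gl

participants, trials = gl.generate_cohort(
    n_participants=3, n_trials=5, styles=list(gl.STYLES), seed=1)

rows = [{"style": t.style, "speed_m_s": t.speed_m_s} for t in trials]
import pandas as pd  # noqa: E402

speeds = pd.DataFrame([{"participant": t.participant_id, "style": t.style,
                        "trial": t.trial_index, "speed_m_s": t.speed_m_s}
                       for t in trials])
print(gl.speed_table(speeds).round(3).to_string(index=False))

trial = trials[0]
p = participants[0]
print(f"\n{p.id}: mass {p.mass_kg:.1f} kg, height {p.height_m:.3f} m, "
      f"body fat {100 * p.fat_fraction:.1f}%")
print(f"trial ({trial.style}): speed {trial.speed_m_s:.2f} m/s, "
      f"FPA {trial.foot_progression_angle_deg:+.1f} deg, "
      f"step width {trial.step_width_m:.3f} m")
peak_grf = trial.grf[:, 1].max() / trial.body_weight_n
mean_grf = np.trapezoid(trial.grf[:, 1], trial.phase / 100) / trial.body_weight_n
print(f"vertical GRF: peak {peak_grf:.2f} BW, stance mean {mean_grf:.2f} BW "
      "(double-peaked, zero at heel strike and toe-off)")
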