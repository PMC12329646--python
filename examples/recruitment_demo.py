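"""Cubic-criterion muscle recruitment: closed form and a stance solve.

First solves the textbook two-parallel-muscle problem, where minimizing
sum (f_i/N_i)^3 under f_1 + f_2 = r makes forces split in proportion to
N_i^(3/2). Then runs static optimization along a full synthetic stance
phase and shows how a 40% ankle-extensor weakening redistributes forces:
the weakened gastrocnemius/soleus lose force to the deep plantarflexors,
which lowers the knee compression they generate at push-off.
"""

import numpy as np

import gaitload as gl
from gaitload.recruitment import RecruitmentProblem

# Closed form: arms 1 and 1, strengths 1000 and 500 N, demand 300 N.m.
N = np.array([1000.0, 500.0])
problem = RecruitmentProblem(C=np.array([[1.0, 1.0]]), r=np.array([300.0]),
                             N=N, dof_names=("joint",),
                             require_bidirectional=False)
sol = gl.solve_recruitment(problem)
share = N ** 1.5 / np.sum(N ** 1.5)
print("two-muscle split: solver", np.round(sol.f, 3),
      "N, closed form", np.round(300.0 * share, 3), "N")

# Stance-phase recruitment for one synthetic trial.
participant = gl.sample_participant(gl.CohortConfig(), 1)
trial = gl.generate_trial(participant, "normal", 0, gl.GeneratorConfig(), 42)
model = gl.scale_model(gl.default_reference_model(), participant)
loads = gl.inverse_dynamics(trial, model)

reference = gl.solve_trace(loads, model)
weakened = gl.solve_trace(loads, gl.reduce_strength(model, "ankle_extensor",
                                                    0.40))
j = reference.muscle_names.index("gastrocnemius")
k = int(np.argmax(reference.forces[:, j]))
print(f"gastrocnemius peak force at {trial.phase[k]:.0f}% stance: "
      f"{reference.forces[k, j]:.0f} N (reference) -> "
      f"{weakened.forces[k, j]:.0f} N (ankle extensors -40%)")
print(f"gastrocnemius peak activation: {reference.activations[:, j].max():.2f}"
      f" -> {weakened.activations[:, j].max():.2f}"
      " (force falls, activation rises: the muscle is weaker)")
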