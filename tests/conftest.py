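import numpy as np
import pytest

import gaitload as gl


@pytest.fixture(scope="session")
def cohort_cfg():
    return gl.CohortConfig()


@pytest.fixture(scope="session")
def gen_cfg():
    return gl.GeneratorConfig()


@pytest.fixture(scope="session")
def participant(cohort_cfg):
    return gl.sample_participant(cohort_cfg, 1, pid="P01")


@pytest.fixture(scope="session")
def reference_model():
    return gl.default_reference_model()


@pytest.fixture(scope="session")
def scaled_model(reference_model, participant):
    return gl.scale_model(reference_model, participant)


@pytest.fixture(scope="session")
def normal_trial(participant, gen_cfg):
    return gl.generate_trial(participant, "normal", 0, gen_cfg, 42)


@pytest.fixture(scope="session")
def trial_loads(normal_trial, scaled_model):
    return gl.inverse_dynamics(normal_trial, scaled_model)


@pytest.fixture(scope="session")
def trial_forces(trial_loads, scaled_model):
    return gl.solve_trace(trial_loads, scaled_model)


@pytest.fixture(scope="session")
def knee_trace(normal_trial, trial_loads, trial_forces, scaled_model):
    return gl.assemble_knee_loads(normal_trial, trial_loads, trial_forces,
                                  scaled_model)


def make_flat_trace(P=2000.0, M_abd=0.0, F_ap=0.0, F_ml=0.0, n=3,
                    flexion=0.0):
    """A constant-load KneeLoadTrace for contact-solver tests."""
    return gl.KneeLoadTrace(
        participant_id="toy", style="normal", condition="reference",
        phase=np.linspace(0.0, 100.0, n),
        knee_flexion_deg=np.full(n, float(flexion)),
        tf_force=np.column_stack([np.full(n, float(F_ap)),
                                  np.full(n, -float(P)),
                                  np.full(n, float(F_ml))]),
        tf_abduction_moment=np.full(n, float(M_abd)),
        tf_rotation_moment=np.zeros(n),
        pf_force=np.zeros((n, 3)), pf_moment=np.zeros((n, 3)))
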