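"""Knee loading assembly and elastic-foundation contact solve."""

import copy
import math

import numpy as np
import pytest
import yaml

import gaitload as gl
from gaitload.config import ContactConfig
from gaitload.contact import (_contact_state, _jacobian, _residual,
                              build_plateau_geometry)
from gaitload.errors import InvalidInputError
from conftest import make_flat_trace


@pytest.fixture(scope="module")
def geometry():
    return build_plateau_geometry()


@pytest.fixture(scope="module")
def connectors():
    return gl.ConnectorSet()


def total_force_n(field, sample):
    return float((field.stress_mpa[sample] * 1e6
                  * field.geometry.area_m2).sum())


class TestConnectors:
    def test_defaults_match_the_study_values_exactly(self, connectors):
        assert connectors.tf_translation_stiffness_n_per_mm == 0.5
        assert connectors.tf_rotation_stiffness_nm_per_deg == 1.2
        assert connectors.patellar_translation_stiffness_n_per_mm == 0.2
        assert connectors.patellar_rotation_stiffness_nm_per_deg == 0.9

    def test_defaults_serialize_exactly_in_config(self, tmp_path):
        cfg = gl.StudyConfig()
        path = tmp_path / "cfg.yaml"
        gl.save_config(cfg, path)
        data = yaml.safe_load(path.read_text())
        con = data["contact"]["connectors"]
        assert con["tf_translation_n_per_mm"] == 0.5
        assert con["tf_rotation_nm_per_deg"] == 1.2
        assert con["patellar_translation_n_per_mm"] == 0.2
        assert con["patellar_rotation_nm_per_deg"] == 0.9

    def test_unit_conversions(self, connectors):
        assert connectors.tf_translation_n_per_m == 500.0
        assert connectors.tf_rotation_nm_per_rad == pytest.approx(
            1.2 * 180.0 / math.pi)


class TestGeometry:
    def test_element_count_and_areas(self, geometry):
        assert geometry.n_elements == 64
        assert np.all(geometry.area_m2 > 0)
        total = geometry.area_m2.sum()
        assert total == pytest.approx(2 * 0.020 * 0.015, rel=1e-12)

    def test_compartments_do_not_overlap(self, geometry):
        assert geometry.z_m[0].max() < geometry.z_m[1].min()

    def test_foundation_stiffness_formula(self, geometry):
        cfg = ContactConfig()
        nu = cfg.poisson_ratio
        expected = (cfg.effective_modulus_pa * (1 - nu)
                    / ((1 + nu) * (1 - 2 * nu) * cfg.thickness_m))
        assert geometry.k_foundation[0, 0] == pytest.approx(expected)


class TestSolverInternals:
    def test_analytic_jacobian_matches_finite_differences(self, geometry):
        loads = (800.0, 50.0, 20.0, 10.0)
        u = np.array([3e-4, 1e-4, -5e-5, 2e-3])
        R, p, act, gx, gz, dpdd = _residual(u, loads, geometry, 1e-3,
                                            500.0, 500.0)
        J = _jacobian(u, p, act, gx, gz, dpdd, geometry, 500.0, 500.0)
        Jfd = np.zeros((4, 4))
        eps = 1e-9
        for j in range(4):
            up, um = u.copy(), u.copy()
            up[j] += eps
            um[j] -= eps
            Rp = _residual(up, loads, geometry, 1e-3, 500.0, 500.0)[0]
            Rm = _residual(um, loads, geometry, 1e-3, 500.0, 500.0)[0]
            Jfd[:, j] = (Rp - Rm) / (2 * eps)
        np.testing.assert_allclose(J, Jfd, rtol=2e-5, atol=1e-3)


class TestContactSolve:
    def test_symmetric_axial_load_gives_mirror_fields(self, geometry,
                                                      connectors):
        trace = make_flat_trace(P=2000.0)
        field = gl.solve_contact(trace, geometry, connectors)
        med = field.stress_mpa[1, 0].reshape(8, 8)
        lat = field.stress_mpa[1, 1].reshape(8, 8)
        np.testing.assert_allclose(med, lat[:, ::-1], rtol=0, atol=1e-9)
        assert total_force_n(field, 1) == pytest.approx(2000.0, rel=1e-3)

    def test_equilibrium_closes_for_gait_like_loads(self, knee_trace,
                                                    geometry, connectors):
        field = gl.solve_contact(knee_trace, geometry, connectors)
        assert np.all(field.equilibrium_residual <= 1e-3)
        # Recompute vertical balance from the reported stresses directly
        # (samples whose moment demand was truncated still balance force).
        P = knee_trace.axial_compression
        for i in range(field.phase.size):
            if P[i] < 500.0:
                continue
            assert total_force_n(field, i) == pytest.approx(P[i], rel=2e-3)

    def test_zero_load_gives_zero_field_and_pose(self, geometry, connectors):
        trace = make_flat_trace(P=0.0)
        field = gl.solve_contact(trace, geometry, connectors)
        assert np.all(field.stress_mpa == 0.0)
        assert np.all(field.pose == 0.0)

    def test_tensile_load_is_total_liftoff_not_an_error(self, geometry,
                                                        connectors):
        trace = make_flat_trace(P=-500.0)
        field = gl.solve_contact(trace, geometry, connectors)
        assert np.all(field.stress_mpa == 0.0)

    def test_stiff_foundation_split_approaches_two_point_support(self):
        cfg = ContactConfig(effective_modulus_pa=2e9)
        geom = build_plateau_geometry(cfg)
        F, M = 2000.0, 12.0
        trace = make_flat_trace(P=F, M_abd=-M)  # abduction=-M => adduction=M
        field = gl.solve_contact(trace, geom, gl.ConnectorSet())
        d = geom.intercondylar_spacing_m
        med = total_force_n_comp(field, 1, 0)
        lat = total_force_n_comp(field, 1, 1)
        assert med == pytest.approx(F / 2 + M / d, rel=0.05)
        assert lat == pytest.approx(F / 2 - M / d, rel=0.05)

    def test_medial_share_monotone_in_adduction_moment(self, geometry,
                                                       connectors):
        shares = []
        for M in np.linspace(-20.0, 20.0, 21):
            trace = make_flat_trace(P=1500.0, M_abd=-M, n=3)
            field = gl.solve_contact(trace, geometry, connectors)
            med = total_force_n_comp(field, 1, 0)
            lat = total_force_n_comp(field, 1, 1)
            shares.append(med / (med + lat))
        diffs = np.diff(shares)
        assert np.all(diffs >= -1e-9)
        assert shares[-1] > shares[0]

    def test_connectors_only_restrain_ap_translation(self, geometry):
        # Zero restraint gives the largest AP excursion; stiffening the
        # connector by decades shrinks it monotonically.
        trace = make_flat_trace(P=1500.0, F_ap=80.0)
        excursions = []
        for stiff in (0.0, 50.0, 500.0, 5000.0):
            field = gl.solve_contact(
                trace, geometry, gl.ConnectorSet(stiff, 1.2, 0.2, 0.9))
            excursions.append(abs(field.pose[1, 1]))
        assert all(a >= b - 1e-12
                   for a, b in zip(excursions, excursions[1:]))

    def test_mesh_refinement_changes_summary_by_under_two_percent(self):
        coarse = build_plateau_geometry(ContactConfig(elements_per_side=8))
        fine = build_plateau_geometry(ContactConfig(elements_per_side=16))
        trace = make_flat_trace(P=2500.0, M_abd=-15.0, F_ap=40.0, flexion=20.0)
        uq_c = gl.upper_quartile_summary(
            gl.solve_contact(trace, coarse, gl.ConnectorSet()))
        uq_f = gl.upper_quartile_summary(
            gl.solve_contact(trace, fine, gl.ConnectorSet()))
        for c in range(2):
            a = uq_c.upper_quartile_mpa[1, c]
            b = uq_f.upper_quartile_mpa[1, c]
            assert abs(a - b) / b < 0.02


def total_force_n_comp(field, sample, comp):
    return float((field.stress_mpa[sample, comp] * 1e6
                  * field.geometry.area_m2[comp]).sum())


class TestUpperQuartile:
    def test_uniform_stress_returns_itself(self, geometry):
        field = gl.StressField(
            phase=np.array([0.0]),
            stress_mpa=np.full((1, 2, 64), 3.5),
            contact_mask=np.ones((1, 2, 64), dtype=bool),
            pose=np.zeros((1, 5)),
            equilibrium_residual=np.zeros(1), geometry=geometry)
        summ = gl.upper_quartile_summary(field)
        np.testing.assert_allclose(summ.upper_quartile_mpa, 3.5)

    def test_eight_elements_ranked_one_to_eight(self, geometry):
        stress = np.zeros((1, 2, 64))
        mask = np.zeros((1, 2, 64), dtype=bool)
        stress[0, 0, :8] = np.arange(1.0, 9.0)
        mask[0, 0, :8] = True
        field = gl.StressField(phase=np.array([0.0]), stress_mpa=stress,
                               contact_mask=mask, pose=np.zeros((1, 5)),
                               equilibrium_residual=np.zeros(1),
                               geometry=geometry)
        summ = gl.upper_quartile_summary(field)
        assert summ.upper_quartile_mpa[0, 0] == pytest.approx(7.5)  # {8,7}
        assert summ.upper_quartile_mpa[0, 1] == 0.0
        assert summ.empty_contact[0, 1]

    def test_zero_pressure_elements_excluded_from_quartile_base(self,
                                                                geometry):
        stress = np.zeros((1, 2, 64))
        mask = np.zeros((1, 2, 64), dtype=bool)
        stress[0, 0, :4] = [2.0, 4.0, 6.0, 8.0]
        mask[0, 0, :4] = True  # 60 zero-pressure elements are not contact
        field = gl.StressField(phase=np.array([0.0]), stress_mpa=stress,
                               contact_mask=mask, pose=np.zeros((1, 5)),
                               equilibrium_residual=np.zeros(1),
                               geometry=geometry)
        summ = gl.upper_quartile_summary(field)
        assert summ.upper_quartile_mpa[0, 0] == pytest.approx(8.0)


class TestLoadAssembly:
    def test_added_quadriceps_force_raises_axial_by_compression_fraction(
            self, normal_trial, trial_loads, trial_forces, scaled_model):
        model = copy.deepcopy(scaled_model)
        j = model.muscle_names().index("vastus_lateralis")
        model.muscles[j].compression_fraction = 1.0
        forces = copy.deepcopy(trial_forces)
        base = gl.assemble_knee_loads(normal_trial, trial_loads, forces,
                                      model)
        forces.forces[:, j] += 1000.0
        boosted = gl.assemble_knee_loads(normal_trial, trial_loads, forces,
                                         model)
        np.testing.assert_allclose(
            boosted.axial_compression - base.axial_compression, 1000.0,
            rtol=1e-9)

    def test_zero_muscle_forces_leave_gravity_term_only(self, normal_trial,
                                                        trial_loads,
                                                        trial_forces,
                                                        scaled_model):
        forces = copy.deepcopy(trial_forces)
        forces.forces[:] = 0.0
        trace = gl.assemble_knee_loads(normal_trial, trial_loads, forces,
                                       scaled_model)
        np.testing.assert_allclose(trace.axial_compression,
                                   trial_loads.knee_compression, rtol=1e-12)

    def test_axial_waveform_is_double_peaked(self, participant, gen_cfg,
                                             scaled_model):
        from scipy.signal import find_peaks
        for seed in range(1, 8):
            trial = gl.generate_trial(participant, "normal", 0, gen_cfg, seed)
            loads = gl.inverse_dynamics(trial, scaled_model)
            forces = gl.solve_trace(loads, scaled_model)
            trace = gl.assemble_knee_loads(trial, loads, forces, scaled_model)
            peaks, _ = find_peaks(trace.axial_compression,
                                  prominence=0.1 * trial.body_weight_n)
            assert len(peaks) >= 2

    def test_missing_force_sample_raises_with_index(self, normal_trial,
                                                    trial_loads,
                                                    trial_forces,
                                                    scaled_model):
        forces = copy.deepcopy(trial_forces)
        forces.forces[17] = np.nan
        with pytest.raises(InvalidInputError, match="17"):
            gl.assemble_knee_loads(normal_trial, trial_loads, forces,
                                   scaled_model)


class TestAveraging:
    def _traces(self, participant, gen_cfg, scaled_model, n=5):
        out = []
        for i in range(n):
            trial = gl.generate_trial(participant, "normal", i, gen_cfg,
                                      (123, i))
            loads = gl.inverse_dynamics(trial, scaled_model)
            forces = gl.solve_trace(loads, scaled_model)
            out.append(gl.assemble_knee_loads(trial, loads, forces,
                                              scaled_model))
        return out

    def test_identical_traces_average_to_themselves(self, knee_trace):
        avg = gl.average_traces([knee_trace, copy.deepcopy(knee_trace)])
        np.testing.assert_allclose(avg.tf_force, knee_trace.tf_force)

    def test_pointwise_mean(self, knee_trace):
        a = copy.deepcopy(knee_trace)
        b = copy.deepcopy(knee_trace)
        b.tf_force = -a.tf_force + 2.0 * 7.0
        avg = gl.average_traces([a, b])
        np.testing.assert_allclose(avg.tf_force, 7.0, rtol=0, atol=1e-9)

    def test_mixed_styles_rejected(self, knee_trace):
        other = copy.deepcopy(knee_trace)
        other.style = "toe_in"
        with pytest.raises(InvalidInputError):
            gl.average_traces([knee_trace, other])

    def test_mean_of_five_trials_has_smaller_variance_at_first_peak(
            self, participant, gen_cfg, scaled_model):
        traces = self._traces(participant, gen_cfg, scaled_model)
        k = int(np.argmax(traces[0].axial_compression[:60]))
        vals = np.array([t.axial_compression[k] for t in traces])
        avg = gl.average_traces(traces)
        # Sample-mean property: the mean lies strictly inside the spread.
        assert vals.min() < avg.axial_compression[k] < vals.max()
        assert vals.std(ddof=1) > 0
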