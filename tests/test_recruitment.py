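"""Static-optimization recruitment: closed forms, grid oracle, KKT, limits."""

import itertools

import numpy as np
import pytest

import gaitload as gl
from gaitload.errors import InsufficientStrengthError, InvalidModelError
from gaitload.recruitment import RecruitmentProblem


def toy_problem(C, r, N):
    return RecruitmentProblem(C=np.atleast_2d(np.asarray(C, dtype=float)),
                              r=np.atleast_1d(np.asarray(r, dtype=float)),
                              N=np.asarray(N, dtype=float),
                              dof_names=tuple(f"row{i}" for i in
                                              range(np.atleast_2d(C).shape[0])),
                              require_bidirectional=False)


def grid_search_oracle(C, r, N, power=3.0, step=0.1, fmax=None):
    """Exhaustive 0.1 N grid search for small problems.

    For every facet of the non-negativity boundary (every subset of muscles
    pinned to zero), free muscles enumerate a grid while a dependent block
    is solved exactly from the equality constraints; infeasible candidates
    are discarded and the best feasible objective wins. Fully independent
    of the production solver.
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    r = np.atleast_1d(np.asarray(r, dtype=float))
    N = np.asarray(N, dtype=float)
    m, n = C.shape
    if fmax is None:
        fmax = 1.5 * np.abs(r).max() / np.abs(C[np.abs(C) > 1e-12]).min()
    grid = np.arange(0.0, fmax + step, step)

    best = None
    best_obj = np.inf
    for mask_bits in range(2 ** n):
        pinned = [i for i in range(n) if mask_bits >> i & 1]
        alive = [i for i in range(n) if i not in pinned]
        if len(alive) < m:
            continue
        # Choose the best-conditioned dependent block among the alive
        # muscles (a near-singular block would blow up the grid resolution).
        dep, det_best = None, 1e-8
        for cand in itertools.combinations(alive, m):
            det = abs(np.linalg.det(C[:, cand]))
            if det > det_best:
                dep, det_best = cand, det
        if dep is None:
            continue
        free = [i for i in alive if i not in dep]
        Binv = np.linalg.inv(C[:, dep])
        if free:
            meshes = np.meshgrid(*([grid] * len(free)), indexing="ij")
            f_free = np.stack([mm.ravel() for mm in meshes], axis=1)
        else:
            f_free = np.zeros((1, 0))
        rhs = r[None, :] - f_free @ C[:, free].T
        f_dep = rhs @ Binv.T
        ok = np.all(f_dep >= -1e-9, axis=1)
        if not np.any(ok):
            continue
        f_all = np.zeros((int(ok.sum()), n))
        f_all[:, free] = f_free[ok]
        f_all[:, dep] = np.clip(f_dep[ok], 0.0, None)
        obj = np.sum((f_all / N[None, :]) ** power, axis=1)
        k = int(np.argmin(obj))
        if obj[k] < best_obj:
            best_obj = obj[k]
            best = f_all[k]
    return best


def random_small_problem(rng):
    """A random feasible problem with <= 3 muscles and <= 2 constraints."""
    n = int(rng.integers(2, 4))
    m = int(rng.integers(1, min(n, 3)))
    while True:
        C = rng.uniform(-1.0, 1.0, size=(m, n))
        C[np.abs(C) < 0.2] = 0.3 * np.sign(rng.standard_normal())
        B = C[:, n - m:]
        if (np.linalg.matrix_rank(B) == m
                and np.linalg.cond(B) < 4.0):
            break
    N = rng.uniform(50.0, 400.0, size=n)
    f_star = rng.uniform(0.0, 40.0, size=n)
    r = C @ f_star
    return toy_problem(C, r, N)


class TestAssembly:
    def test_dimensions_match_roster(self, trial_loads, scaled_model):
        prob = gl.assemble_problem(trial_loads, scaled_model, 50)
        assert prob.C.shape == (6, len(scaled_model.muscles))
        prob.validate()

    def test_non_actuating_muscle_has_zero_entry(self, trial_loads,
                                                 scaled_model):
        prob = gl.assemble_problem(trial_loads, scaled_model, 10)
        j = scaled_model.muscle_names().index("soleus")
        assert prob.C[gl.DOFS.index("knee"), j] == 0.0

    def test_biarticular_gastrocnemius_spans_two_rows(self, trial_loads,
                                                      scaled_model):
        prob = gl.assemble_problem(trial_loads, scaled_model, 10)
        j = scaled_model.muscle_names().index("gastrocnemius")
        assert prob.C[gl.DOFS.index("ankle_pf"), j] > 0
        assert prob.C[gl.DOFS.index("knee"), j] < 0


class TestClosedForms:
    def test_single_muscle_forced_solution(self):
        sol = gl.solve_recruitment(toy_problem([[1.0]], [100.0], [1000.0]))
        assert sol.f[0] == pytest.approx(100.0, rel=1e-9)
        assert sol.activations[0] == pytest.approx(0.1, rel=1e-9)
        assert sol.objective == pytest.approx(1e-3, rel=1e-9)

    def test_parallel_pair_splits_by_strength_to_three_halves(self):
        # Stationarity 3 f^2/N^3 = lambda => f_i proportional to N_i^(3/2).
        N = np.array([1000.0, 500.0])
        sol = gl.solve_recruitment(toy_problem([[1.0, 1.0]], [300.0], N))
        share = N ** 1.5 / np.sum(N ** 1.5)
        np.testing.assert_allclose(sol.f, 300.0 * share, rtol=1e-6)
        oracle = grid_search_oracle([[1.0, 1.0]], np.array([300.0]), N,
                                    fmax=320.0)
        np.testing.assert_allclose(sol.f, oracle, atol=0.2)

    def test_zero_demand_gives_zero_forces(self):
        sol = gl.solve_recruitment(toy_problem([[1.0, -1.0]], [0.0],
                                               [800.0, 800.0]))
        np.testing.assert_array_equal(sol.f, 0.0)
        assert sol.objective == 0.0

    def test_weakening_shifts_load_and_conserves_total(self):
        N = np.array([1000.0, 1000.0])
        base = gl.solve_recruitment(toy_problem([[1.0, 1.0]], [300.0], N))
        weak = gl.solve_recruitment(toy_problem([[1.0, 1.0]], [300.0],
                                                N * [0.6, 1.0]))
        assert weak.f[0] < base.f[0]
        assert weak.f[1] > base.f[1]
        assert weak.f.sum() == pytest.approx(300.0, rel=1e-9)


class TestInvariances:
    def test_forces_scale_linearly_with_demand(self, trial_loads,
                                               scaled_model):
        prob = gl.assemble_problem(trial_loads, scaled_model, 40)
        sol1 = gl.solve_recruitment(prob)
        prob2 = gl.assemble_problem(trial_loads, scaled_model, 40)
        prob2.r = 2.0 * prob2.r
        sol2 = gl.solve_recruitment(prob2)
        np.testing.assert_allclose(sol2.f, 2.0 * sol1.f, rtol=1e-5,
                                   atol=1e-6)

    def test_forces_invariant_under_uniform_strength_scaling(
            self, trial_loads, scaled_model):
        prob = gl.assemble_problem(trial_loads, scaled_model, 40)
        sol1 = gl.solve_recruitment(prob)
        prob2 = gl.assemble_problem(trial_loads, scaled_model, 40)
        prob2.N = 3.0 * prob2.N
        sol2 = gl.solve_recruitment(prob2)
        np.testing.assert_allclose(sol2.f, sol1.f, rtol=1e-5, atol=1e-6)

    def test_kkt_residuals_small_on_random_problems(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            prob = random_small_problem(rng)
            sol = gl.solve_recruitment(prob)
            assert sol.kkt_residual <= 1e-6
            assert np.all(sol.f >= 0.0)

    def test_grid_search_oracle_agreement(self):
        rng = np.random.default_rng(12)
        checked = 0
        while checked < 40:
            prob = random_small_problem(rng)
            oracle = grid_search_oracle(prob.C, prob.r, prob.N, fmax=120.0)
            if oracle is None:
                continue
            sol = gl.solve_recruitment(prob)
            np.testing.assert_allclose(sol.f, oracle, atol=0.2)
            checked += 1


class TestLimitsAndErrors:
    def test_high_order_approaches_min_max_recruitment(self):
        # As p grows the polynomial criterion approaches min-max loading:
        # activations equalize across parallel muscles of unequal strength.
        N = np.array([1000.0, 400.0])
        sol = gl.solve_recruitment(toy_problem([[1.0, 1.0]], [300.0], N),
                                   power=41.0)
        assert abs(sol.activations[0] - sol.activations[1]) < 0.01

    def test_infeasible_demand_raises_with_row_index(self):
        prob = toy_problem([[1.0, 0.5]], [-50.0], [1000.0, 1000.0])
        with pytest.raises(InsufficientStrengthError) as err:
            gl.solve_recruitment(prob)
        assert err.value.row == 0

    def test_rank_deficient_matrix_rejected(self):
        C = np.array([[1.0, -1.0], [2.0, -2.0]])
        prob = toy_problem(C, [10.0, 20.0], [500.0, 500.0])
        with pytest.raises(InvalidModelError):
            prob.validate()

    def test_unidirectional_row_rejected_for_full_models(self):
        prob = RecruitmentProblem(C=np.array([[1.0, 0.5]]),
                                  r=np.array([10.0]),
                                  N=np.array([100.0, 100.0]),
                                  dof_names=("row0",))
        with pytest.raises(InvalidModelError):
            prob.validate()


class TestTraceSolving:
    def test_constant_loads_give_constant_solutions(self, trial_loads,
                                                    scaled_model):
        import copy
        loads = copy.deepcopy(trial_loads)
        loads.moments = np.tile(loads.moments[50], (loads.n_samples, 1))
        trace = gl.solve_trace(loads, scaled_model)
        spread = trace.forces.max(axis=0) - trace.forces.min(axis=0)
        assert np.max(spread) < 1e-3

    def test_full_trace_feasible_with_reference_strengths(self, trial_forces):
        assert not trial_forces.failures
        assert np.nanmax(trial_forces.kkt_residual) <= 1e-6

    def test_rectus_femoris_activation_rises_with_weak_abductors(
            self, trial_loads, scaled_model):
        # The compensation behind the reported activation shifts: weakened
        # hip abductors recruit hip flexors (rectus femoris among them).
        weak = gl.reduce_strength(scaled_model, "hip_abductor", 0.40)
        base = gl.solve_trace(trial_loads, scaled_model)
        mod = gl.solve_trace(trial_loads, weak)
        j = base.muscle_names.index("rectus_femoris")
        base_peak = base.activations[:, j].max()
        mod_peak = mod.activations[:, j].max()
        assert mod_peak >= base_peak - 1e-9

    def test_failed_samples_are_recorded_with_nan_rows(self, trial_loads,
                                                       scaled_model,
                                                       monkeypatch):
        import gaitload.recruitment as rec
        real = rec.solve_recruitment
        calls = {"k": -1}

        def flaky(problem, **kwargs):
            calls["k"] += 1
            if calls["k"] == 3:
                raise InsufficientStrengthError("forced", row=1)
            return real(problem, **kwargs)

        monkeypatch.setattr(rec, "solve_recruitment", flaky)
        trace = rec.solve_trace(trial_loads, scaled_model, on_error="record")
        assert trace.failures == {3: "insufficient-strength"}
        assert np.all(np.isnan(trace.forces[3]))
        assert np.all(np.isfinite(trace.forces[4]))

    def test_failure_propagates_with_sample_index_by_default(
            self, trial_loads, scaled_model, monkeypatch):
        import gaitload.recruitment as rec
        real = rec.solve_recruitment
        calls = {"k": -1}

        def flaky(problem, **kwargs):
            calls["k"] += 1
            if calls["k"] == 5:
                raise InsufficientStrengthError("forced", row=2)
            return real(problem, **kwargs)

        monkeypatch.setattr(rec, "solve_recruitment", flaky)
        with pytest.raises(InsufficientStrengthError) as err:
            rec.solve_trace(trial_loads, scaled_model)
        assert err.value.sample == 5
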