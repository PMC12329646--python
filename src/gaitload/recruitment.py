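"""Static-optimization muscle recruitment with a polynomial criterion.

At each stance-phase sample the muscle forces solve

    minimize   G(f) = sum_i (f_i / N_i)^p        (p = 3 for study runs)
    subject to C f = r,   f_i >= 0,

where C holds the signed moment arms (one moment-balance row per joint DoF),
r the net joint moments from inverse dynamics, and N_i the isometric
strengths. In the activation coordinates a_i = f_i/N_i the objective is
strictly convex on the feasible slice, so the minimizer is unique.

The solver maximizes the smooth concave dual

    q(lam) = lam.r - sum_i (p-1) * (max(s_i, 0)/p)^(p/(p-1)),   s = (C N)^T lam,

by damped Newton iteration; the primal is recovered in closed form,
a_i = (max(s_i,0)/p)^(1/(p-1)). Stationarity and complementarity are then
exact by construction, and the reported KKT residual is the remaining
primal-feasibility defect. No reserve actuators exist: if the demanded
moment is unreachable with non-negative forces the solve raises
InsufficientStrengthError naming the worst row, because strength is the
experimental variable here and silent torque reserves would mask it.

Upper bounds f_i <= N_i are deliberately NOT imposed; activations may exceed
one and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import NetLoads
from .errors import InsufficientStrengthError, InvalidModelError
from .model import DOFS, MusculoskeletalModel


@dataclass
class RecruitmentProblem:
    """One instant's moment-balance problem. ``C`` is (n_dof, n_muscles)."""

    C: np.ndarray
    r: np.ndarray
    N: np.ndarray
    dof_names: tuple[str, ...] = DOFS
    #: Full models must actuate every row in both directions; hand-built toy
    #: problems (e.g. two parallel agonists) may turn the check off.
    require_bidirectional: bool = True

    @property
    def n_muscles(self) -> int:
        return self.C.shape[1]

    def validate(self) -> None:
        if self.C.shape != (self.r.size, self.N.size):
            raise InvalidModelError("inconsistent problem dimensions")
        if np.any(self.N <= 0):
            raise InvalidModelError("isometric strengths must be positive")
        if self.require_bidirectional:
            for i in range(self.C.shape[0]):
                row = self.C[i]
                if not (np.any(row > 0) and np.any(row < 0)):
                    raise InvalidModelError(
                        f"row {i} ('{self.dof_names[i]}') lacks bidirectional "
                        "actuation")
        if np.linalg.matrix_rank(self.C) < self.C.shape[0]:
            raise InvalidModelError("constraint matrix is row-rank deficient")


@dataclass
class MuscleForceSolution:
    """Forces, activations, objective value and KKT certificate."""

    f: np.ndarray
    activations: np.ndarray
    objective: float
    kkt_residual: float
    dual: np.ndarray = field(repr=False, default=None)

    @property
    def overloaded(self) -> np.ndarray:
        """Mask of muscles recruited beyond their isometric strength."""
        return self.activations > 1.0


def assemble_problem(loads: NetLoads, model: MusculoskeletalModel,
                     sample_index: int,
                     joint_angles: dict[str, np.ndarray] | None = None,
                     ) -> RecruitmentProblem:
    """Build the moment-balance problem at one phase sample.

    ``joint_angles`` (the trial's waveforms) are only needed when the model's
    cosine arm modulation is enabled; constant arms are the default.
    """
    n = loads.n_samples
    if not (0 <= sample_index < n):
        raise InvalidModelError(f"sample_index {sample_index} outside grid")
    C = _arm_matrix(model, joint_angles, sample_index)
    r = loads.moments[sample_index].copy()
    N = model.strengths()
    problem = RecruitmentProblem(C=C, r=r, N=N)
    problem.validate()
    return problem


_ANGLE_KEY = {"hip_flex": "hip_flex", "hip_add": "hip_add",
              "hip_rot": "hip_rot", "knee": "knee_flex",
              "ankle_pf": "ankle_pf", "ankle_inv": "ankle_inv"}


def _arm_matrix(model: MusculoskeletalModel,
                joint_angles: dict[str, np.ndarray] | None,
                sample_index: int) -> np.ndarray:
    C = np.zeros((len(DOFS), len(model.muscles)))
    for j, mu in enumerate(model.muscles):
        for i, dof in enumerate(DOFS):
            angle = 0.0
            if model.arm_cosine_modulation and joint_angles is not None:
                angle = float(joint_angles[_ANGLE_KEY[dof]][sample_index])
            C[i, j] = model.moment_arm(mu, dof, angle)
    return C


def _dual_newton(Chat: np.ndarray, r: np.ndarray, p: float, tol: float,
                 max_iter: int, lam0: np.ndarray | None):
    """Maximize the dual; return (a, lam, feasibility residual)."""
    m = r.size
    scale = 1.0 + np.linalg.norm(r)
    expo = 1.0 / (p - 1.0)

    def primal(lam):
        s = Chat.T @ lam
        a = np.where(s > 0.0, (np.maximum(s, 0.0) / p) ** expo, 0.0)
        return s, a

    def qval(lam, s):
        pos = np.maximum(s, 0.0)
        return lam @ r - np.sum((p - 1.0) * (pos / p) ** (p / (p - 1.0)))

    lam = np.zeros(m) if lam0 is None else lam0.copy()
    if lam0 is None and np.any(r):
        # Warm start from a least-squares primal guess mapped through the
        # stationarity condition s_i = p * a_i^(p-1).
        a_ls, *_ = np.linalg.lstsq(Chat, r, rcond=None)
        s_target = p * np.maximum(a_ls, 1e-9) ** (p - 1.0)
        lam, *_ = np.linalg.lstsq(Chat.T, s_target, rcond=None)

    s, a = primal(lam)
    q = qval(lam, s)
    mu_reg = 1e-12
    for _ in range(max_iter):
        grad = r - Chat @ a
        gnorm = np.linalg.norm(grad)
        if gnorm <= tol * scale:
            return a, lam, gnorm / scale
        active = s > 0.0
        if np.any(active):
            d = np.zeros_like(a)
            d[active] = a[active] / ((p - 1.0) * s[active])
            H = (Chat * d) @ Chat.T
        else:
            H = np.zeros((m, m))
        trace = np.trace(H)
        reg = mu_reg * max(trace, 1.0)
        try:
            step = np.linalg.solve(H + reg * np.eye(m), grad)
        except np.linalg.LinAlgError:
            step = grad
        # Backtracking line search: accept on dual increase or, near the
        # optimum (where the dual value comparison drowns in rounding), on
        # a clear contraction of the feasibility gradient.
        t = 1.0
        improved = False
        for _ls in range(60):
            lam_new = lam + t * step
            s_new, a_new = primal(lam_new)
            q_new = qval(lam_new, s_new)
            g_new = np.linalg.norm(r - Chat @ a_new)
            if q_new > q + 1e-14 * abs(q) or g_new < 0.7 * gnorm:
                lam, s, a, q = lam_new, s_new, a_new, q_new
                improved = True
                break
            t *= 0.5
        if improved:
            mu_reg = max(mu_reg * 0.3, 1e-14)
        else:
            # Try a pure (scaled) gradient step before declaring failure.
            t = 1.0 / max(np.linalg.norm(grad), 1.0)
            advanced = False
            for _ls in range(60):
                lam_new = lam + t * grad
                s_new, a_new = primal(lam_new)
                q_new = qval(lam_new, s_new)
                if q_new > q:
                    lam, s, a, q = lam_new, s_new, a_new, q_new
                    advanced = True
                    break
                t *= 0.5
            if not advanced:
                break
            mu_reg = min(mu_reg * 10.0, 1e-6)
        if np.linalg.norm(lam) > 1e12 * scale:
            break
    grad = r - Chat @ a
    return a, lam, np.linalg.norm(grad) / scale


def _primal_slsqp(Chat: np.ndarray, r: np.ndarray, p: float):
    """Primal fallback: sequential quadratic programming on the activation
    coordinates. Used for high polynomial orders (where the dual map is
    badly conditioned) and for geometries where the dual Newton stalls."""
    from scipy.optimize import minimize
    n = Chat.shape[1]
    a0, *_ = np.linalg.lstsq(Chat, r, rcond=None)
    a0 = np.clip(a0, 1e-6, None)
    # Optimize in units of the typical activation so a^p neither under- nor
    # overflows at high polynomial order.
    c = max(float(np.abs(a0).max()), 1e-12)
    Cb = Chat * c
    b0 = a0 / c
    res = minimize(lambda b: float(np.sum(b ** p)), b0,
                   jac=lambda b: p * b ** (p - 1.0),
                   bounds=[(0.0, None)] * n,
                   constraints=[{"type": "eq",
                                 "fun": lambda b: Cb @ b - r,
                                 "jac": lambda b: Cb}],
                   method="SLSQP",
                   options={"maxiter": 500, "ftol": 1e-16})
    return np.clip(res.x, 0.0, None) * c


def _kkt_certificate(Chat: np.ndarray, r: np.ndarray, a: np.ndarray,
                     p: float) -> float:
    """Normalized maximum of the feasibility, stationarity and
    complementarity defects of a candidate activation vector."""
    feas = np.linalg.norm(Chat @ a - r) / (1.0 + np.linalg.norm(r))
    grad = p * a ** (p - 1.0)
    active = a > 1e-9 * max(a.max(initial=0.0), 1.0)
    scale = 1.0 + np.abs(grad).max(initial=0.0)
    if np.any(active):
        lam, *_ = np.linalg.lstsq(Chat[:, active].T, grad[active], rcond=None)
    else:
        lam = np.zeros(r.size)
    s = Chat.T @ lam
    stat = (np.abs(grad - s)[active].max(initial=0.0) / scale
            if np.any(active) else 0.0)
    # Inactive muscles need non-negative multipliers: grad_i - s_i >= 0.
    comp = np.clip(s - grad, 0.0, None)[~active].max(initial=0.0) / scale
    return float(max(feas, stat, comp))


def solve_recruitment(problem: RecruitmentProblem, tol: float = 1e-8,
                      power: float = 3.0, max_iter: int = 200,
                      warm_dual: np.ndarray | None = None,
                      ) -> MuscleForceSolution:
    """Solve one recruitment problem to the unique polynomial-criterion
    minimizer; raises :class:`InsufficientStrengthError` if infeasible."""
    problem.validate()
    r = problem.r
    if not np.any(r):
        zeros = np.zeros(problem.n_muscles)
        return MuscleForceSolution(f=zeros, activations=zeros.copy(),
                                   objective=0.0, kkt_residual=0.0,
                                   dual=np.zeros(r.size))
    Chat = problem.C * problem.N  # column scaling: activation coordinates
    threshold = max(tol * 100.0, 1e-6)
    lam = np.zeros(r.size)
    res = np.inf
    a = np.zeros(problem.n_muscles)
    if power <= 8.0:
        a, lam, res = _dual_newton(Chat, r, power, tol, max_iter, warm_dual)
    if res > threshold:
        a_p = _primal_slsqp(Chat, r, power)
        res_p = _kkt_certificate(Chat, r, a_p, power)
        if res_p < res:
            a, res = a_p, res_p
    if res > threshold:
        row = int(np.argmax(np.abs(r - Chat @ a)))
        raise InsufficientStrengthError(
            f"recruitment infeasible or unconverged (residual {res:.3e}); "
            f"worst row {row} ('{problem.dof_names[row]}')", row=row)
    f = problem.N * a
    return MuscleForceSolution(
        f=f, activations=a, objective=float(np.sum(a ** power)),
        kkt_residual=float(res), dual=lam)


@dataclass
class RecruitmentTrace:
    """Per-sample solutions over the stance phase."""

    phase: np.ndarray
    forces: np.ndarray        # (n_samples, n_muscles)
    activations: np.ndarray
    objective: np.ndarray
    kkt_residual: np.ndarray
    muscle_names: list[str]
    failures: dict[int, str] = field(default_factory=dict)


def solve_trace(loads: NetLoads, model: MusculoskeletalModel,
                tol: float = 1e-8, power: float = 3.0,
                joint_angles: dict[str, np.ndarray] | None = None,
                on_error: str = "raise") -> RecruitmentTrace:
    """Solve every sample of a trace, warm-starting each from the previous.

    ``on_error='record'`` stores failures per sample (NaN rows) instead of
    raising; the default propagates InsufficientStrengthError with the
    failing sample index attached.
    """
    n = loads.n_samples
    names = model.muscle_names()
    n_m = len(names)
    forces = np.zeros((n, n_m))
    acts = np.zeros((n, n_m))
    objective = np.zeros(n)
    kkt = np.zeros(n)
    failures: dict[int, str] = {}

    static_arms = not model.arm_cosine_modulation
    C0 = _arm_matrix(model, joint_angles, 0)
    N = model.strengths()
    warm = None
    for k in range(n):
        C = C0 if static_arms else _arm_matrix(model, joint_angles, k)
        problem = RecruitmentProblem(C=C, r=loads.moments[k].copy(), N=N)
        try:
            sol = solve_recruitment(problem, tol=tol, power=power,
                                    warm_dual=warm)
        except InsufficientStrengthError as err:
            if on_error == "raise":
                err.sample = k
                raise
            failures[k] = "insufficient-strength"
            forces[k] = np.nan
            acts[k] = np.nan
            objective[k] = np.nan
            kkt[k] = np.nan
            warm = None
            continue
        forces[k] = sol.f
        acts[k] = sol.activations
        objective[k] = sol.objective
        kkt[k] = sol.kkt_residual
        warm = sol.dual
    return RecruitmentTrace(phase=loads.phase.copy(), forces=forces,
                            activations=acts, objective=objective,
                            kkt_residual=kkt, muscle_names=names,
                            failures=failures)


def trace_to_frame(trace: RecruitmentTrace, kind: str = "force"):
    """Force or activation trace as a DataFrame (one column per muscle)."""
    import pandas as pd
    data = trace.forces if kind == "force" else trace.activations
    df = pd.DataFrame(data, columns=trace.muscle_names)
    df.insert(0, "phase", trace.phase)
    return df
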