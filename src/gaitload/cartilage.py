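"""One-dimensional biphasic (linear poroelastic) cartilage column.

Confined compression of a fluid-saturated solid matrix: the excess pore
pressure obeys the consolidation equation

    dp/dt = c_v d2p/dz2 + dsigma/dt,      c_v = H_A * k,

with a permeable loaded surface (p = 0 at z = 0), an impermeable rigid base
(dp/dz = 0 at z = h), aggregate modulus H_A and permeability k. Surface
settlement is w(t) = (1/H_A) * int (sigma - p) dz; at t -> infinity the load
is fully drained and w -> sigma*h/H_A.

The solver is a Crank-Nicolson finite-difference scheme (unconditionally
stable, second order in dz and dt). ``consolidation_series_settlement`` is
the classical single-series closed form used as the independent verification
route; the finite-difference path never calls it.

This module serves two roles: verifying consolidation physics against the
closed form, and supplying a rate-dependent effective foundation modulus
(stress/strain at the end of a loading ramp) to the contact surrogate.
Fibril reinforcement and intrinsic viscoelasticity are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .errors import ConfigurationError, NumericalError


@dataclass
class BiphasicColumn:
    """Material column: thickness (m), H_A (Pa), k (m^4/(N s)), grid size."""

    thickness_m: float = 0.003
    aggregate_modulus_pa: float = 0.5e6
    permeability_m4_per_ns: float = 2.0e-15
    n_nodes: int = 100

    def __post_init__(self) -> None:
        if min(self.thickness_m, self.aggregate_modulus_pa,
               self.permeability_m4_per_ns) <= 0:
            raise ConfigurationError("all physical parameters must be > 0")
        if self.n_nodes < 20:
            raise ConfigurationError("n_nodes must be >= 20")

    @property
    def consolidation_coefficient(self) -> float:
        """c_v = H_A * k (m^2/s)."""
        return self.aggregate_modulus_pa * self.permeability_m4_per_ns

    @property
    def characteristic_time_s(self) -> float:
        """t* = h^2 / (H_A k), the consolidation time scale."""
        return self.thickness_m ** 2 / self.consolidation_coefficient


@dataclass
class ConsolidationResult:
    """Time series of surface settlement and final pore-pressure profile."""

    time_s: np.ndarray
    settlement_m: np.ndarray          # positive into the column
    pressure_pa: np.ndarray           # (n_times, n_nodes) profiles
    applied_stress_pa: np.ndarray
    z_m: np.ndarray
    fluid_efflux_m: np.ndarray        # cumulative fluid volume per unit area


def simulate_consolidation(column: BiphasicColumn, duration_s: float,
                           dt_s: float, sigma0_pa: float = 1.0,
                           ramp_time_s: float = 0.0) -> ConsolidationResult:
    """Integrate a ramp-hold surface traction: sigma rises linearly to
    ``sigma0_pa`` over ``ramp_time_s`` and is then held."""
    if duration_s <= 0 or dt_s <= 0:
        raise ConfigurationError("duration and dt must be positive")
    n = column.n_nodes
    h = column.thickness_m
    z = np.linspace(0.0, h, n)
    dz = z[1] - z[0]
    cv = column.consolidation_coefficient
    r = cv * dt_s / dz ** 2

    n_steps = int(round(duration_s / dt_s))
    times = dt_s * np.arange(n_steps + 1)
    if ramp_time_s > 0:
        sigma = sigma0_pa * np.clip(times / ramp_time_s, 0.0, 1.0)
    else:
        sigma = np.full_like(times, sigma0_pa)
        sigma[0] = 0.0

    # Crank-Nicolson: (I - r/2 L) p_new = (I + r/2 L) p_old + dsigma,
    # with p(0)=0 (drained surface) and a mirrored node at the base.
    lower = np.zeros(n)
    diag = np.zeros(n)
    upper = np.zeros(n)
    diag[0] = 1.0                        # Dirichlet surface row
    diag[1:] = 1.0 + r
    lower[1:-1] = -r / 2.0
    lower[-1] = -r                       # base: mirrored neighbour
    upper[2:] = -r / 2.0
    ab = np.vstack([np.concatenate([[0.0], upper[1:]]),
                    diag,
                    np.concatenate([lower[1:], [0.0]])])

    p = np.zeros(n)
    profiles = np.zeros((n_steps + 1, n))
    settlement = np.zeros(n_steps + 1)
    efflux = np.zeros(n_steps + 1)

    def _settle(pp: np.ndarray, sig: float) -> float:
        return float(np.trapezoid(sig - pp, z) / column.aggregate_modulus_pa)

    def _surface_flux(pp: np.ndarray) -> float:
        # Darcy velocity out of the surface: k * dp/dz at z=0 (2nd order).
        dpdz = (-3.0 * pp[0] + 4.0 * pp[1] - pp[2]) / (2.0 * dz)
        return column.permeability_m4_per_ns * dpdz

    flux_prev = _surface_flux(p)
    for step in range(1, n_steps + 1):
        rhs = np.empty(n)
        rhs[0] = 0.0
        interior = p[1:-1]
        rhs[1:-1] = (interior
                     + (r / 2.0) * (p[2:] - 2.0 * interior + p[:-2])
                     + (sigma[step] - sigma[step - 1]))
        rhs[-1] = (p[-1] + r * (p[-2] - p[-1])
                   + (sigma[step] - sigma[step - 1]))
        p = solve_banded((1, 1), ab, rhs)
        if not np.all(np.isfinite(p)):
            raise NumericalError(
                f"non-finite pore pressure at step {step} (dt={dt_s}, dz={dz})")
        profiles[step] = p
        settlement[step] = _settle(p, sigma[step])
        flux = _surface_flux(p)
        efflux[step] = efflux[step - 1] + 0.5 * dt_s * (flux + flux_prev)
        flux_prev = flux
    return ConsolidationResult(time_s=times, settlement_m=settlement,
                               pressure_pa=profiles,
                               applied_stress_pa=sigma, z_m=z,
                               fluid_efflux_m=efflux)


def consolidation_series_settlement(T: np.ndarray, n_terms: int = 200) -> np.ndarray:
    """Classical closed-form degree of consolidation U(T) for a step load:

        U(T) = 1 - sum_m 2/M^2 exp(-M^2 T),   M = pi (2m+1) / 2,

    with T = c_v t / h^2. U multiplies the drained settlement sigma*h/H_A.
    """
    T = np.asarray(T, dtype=float)
    m = np.arange(n_terms)
    M = np.pi * (2.0 * m + 1.0) / 2.0
    terms = (2.0 / M ** 2)[None, :] * np.exp(-np.outer(T, M ** 2))
    return 1.0 - terms.sum(axis=1)


def effective_foundation_modulus(column: BiphasicColumn,
                                 loading_timescale_s: float,
                                 n_steps: int = 400) -> float:
    """Apparent stiffness sigma/epsilon at the end of a stress ramp of the
    given duration (strain amplitude is immaterial: the model is linear, so
    the ratio at 10% strain equals the ratio at unit stress).

    Bounded below by the drained aggregate modulus H_A (timescale >> t*) and
    rising toward the undrained short-time stiffness as the timescale shrinks.
    """
    if loading_timescale_s <= 0:
        raise ConfigurationError("loading_timescale must be > 0")
    dt = loading_timescale_s / n_steps
    res = simulate_consolidation(column, duration_s=loading_timescale_s,
                                 dt_s=dt, sigma0_pa=1.0,
                                 ramp_time_s=loading_timescale_s)
    strain = res.settlement_m[-1] / column.thickness_m
    if strain <= 0:
        raise NumericalError("non-positive strain at ramp end")
    return float(1.0 / strain)
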