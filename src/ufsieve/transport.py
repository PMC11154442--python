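"""Solution-friction transport equations for solute rejection in ultrafiltration.

The model pictures steady-state solute transport through two layers in
series: a concentration-polarization film on the retentate side (advection
toward the membrane balanced by back-diffusion) and the active layer of the
membrane itself (hindered advection and diffusion inside the pores, with a
partition jump at each pore mouth).  Integrating the flux equation across
each layer gives closed-form expressions in terms of two Peclet numbers,

    Pe_d = v_w / k_dbl      (polarization layer)
    Pe_m = v_w / k_m        (membrane active layer)

and a sieving coefficient sigma = 1 - K_c * Phi, where Phi is the
partition coefficient at the pore entrance and K_c the advective hindrance
factor.  The observed rejection R_obs = 1 - c_permeate / c_retentate then
follows from these three lumped parameters alone.

This module provides those closed forms, the steric (Ferry) and
Boltzmann-weighted (Smith-Deen) partition coefficients, and an independent
numerical boundary-value solver (:func:`solve_profile_numeric`) that
integrates the layer ODEs directly and serves as the verification oracle
for the algebra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "TransportParameters",
    "MicroscopicParameters",
    "ConcentrationProfile",
    "PartitionInputs",
    "UnphysicalValueWarning",
    "DiffusionLimitWarning",
    "peclet_membrane",
    "peclet_polarization",
    "sieving_coefficient",
    "ferry_partition",
    "smith_deen_partition",
    "rejection_general",
    "rejection_advection",
    "solute_flux_membrane",
    "solute_flux_polarization",
    "observed_rejection",
    "solve_profile_numeric",
]

# exp(-x) underflows to exactly 0 past this point; the rejection formulas
# then take their analytic limits rather than producing 0/0.
_EXP_UNDERFLOW = 709.0


class UnphysicalValueWarning(UserWarning):
    """A formula was evaluated outside its physical domain (value still returned)."""


class DiffusionLimitWarning(UserWarning):
    """A flux expression was evaluated at Pe = 0 and replaced by its diffusive limit."""


@dataclass(frozen=True)
class TransportParameters:
    """Lumped parameters that fully determine predicted rejection.

    Parameters
    ----------
    sigma : float
        Sieving coefficient (dimensionless); the rejection limit at
        vanishing flux.
    k_dbl : float
        Mass-transfer coefficient of the polarization layer, m/s.
    k_m : float, optional
        Mass-transfer coefficient inside the membrane, m/s.  ``None``
        selects the advection-dominated model (no pore diffusion).
    """

    sigma: float
    k_dbl: float
    k_m: Optional[float] = None

    def __post_init__(self) -> None:
        if self.k_dbl <= 0:
            raise ValueError(f"k_dbl must be positive, got {self.k_dbl}")
        if self.k_m is not None and self.k_m <= 0:
            raise ValueError(f"k_m must be positive when present, got {self.k_m}")

    def validate_physical(self) -> None:
        """Raise if sigma lies outside [0, 1] (strict physical-bounds mode)."""
        if not 0.0 <= self.sigma <= 1.0:
            raise ValueError(f"sigma={self.sigma} outside [0, 1]")


@dataclass(frozen=True)
class MicroscopicParameters:
    """Pore-scale quantities consumed by the numerical profile solver.

    K_f is the solute-wall friction factor (0 = no transport, 1 = no
    friction); K_c and K_d are the hindrance factors for advection and
    diffusion; D_m and D_i the pore and bulk diffusivities; delta_mem and
    delta_pol the active-layer and polarization-layer thicknesses; phi the
    partition coefficient at the pore mouths.
    """

    K_c: float
    K_d: float
    D_m: float
    D_i: float
    delta_mem: float
    delta_pol: float
    phi: float
    K_f: float = 1.0

    def __post_init__(self) -> None:
        for name in ("K_c", "K_d", "D_m", "D_i", "delta_mem", "delta_pol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.phi < 0:
            raise ValueError("phi must be >= 0")
        if not 0.0 <= self.K_f <= 1.0:
            raise ValueError("K_f must lie in [0, 1]")

    @property
    def sigma(self) -> float:
        """Implied sieving coefficient 1 - K_c * phi."""
        return 1.0 - self.K_c * self.phi

    def k_dbl(self) -> float:
        """Polarization-layer mass-transfer coefficient D_i / delta_pol."""
        return self.D_i / self.delta_pol

    def k_m(self) -> float:
        """Membrane mass-transfer coefficient K_d * D_m / (K_c * delta_mem)."""
        return self.K_d * self.D_m / (self.K_c * self.delta_mem)


@dataclass(frozen=True)
class ConcentrationProfile:
    """Steady-state concentrations through both layers plus the fluxes.

    All concentrations share one (arbitrary) unit; ``J_i = v_w * c_p`` holds
    at steady state.
    """

    c_b: float
    c_m: float
    c_x0: float
    c_xdx: float
    c_p: float
    J_i: float
    v_w: float
    flux_imbalance: float = 0.0
    iterations: int = 0

    @property
    def rejection(self) -> float:
        """Observed rejection 1 - c_p / c_b."""
        return 1.0 - self.c_p / self.c_b


@dataclass(frozen=True)
class PartitionInputs:
    """Inputs to the Smith-Deen partition coefficient."""

    r_s: float
    r_p: float
    E_T: float
    kT: float

    def __post_init__(self) -> None:
        if self.r_p <= 0:
            raise ValueError("pore radius r_p must be positive")
        if self.r_s < 0:
            raise ValueError("solute radius r_s must be non-negative")
        if self.kT <= 0:
            raise ValueError("thermal energy kT must be positive")


def peclet_membrane(v_w, k_m):
    """Membrane Peclet number Pe_m = v_w / k_m.

    Ratio of advective to diffusive transport inside the pores; Pe_m >> 1
    means pore diffusion is negligible.
    """
    v_w = np.asarray(v_w, dtype=float)
    if np.any(np.asarray(k_m) <= 0):
        raise ValueError("k_m must be positive")
    if np.any(v_w < 0):
        raise ValueError("v_w must be non-negative")
    out = v_w / k_m
    return float(out) if out.ndim == 0 else out


def peclet_polarization(v_w, k_dbl):
    """Polarization-layer Peclet number Pe_d = v_w / k_dbl."""
    v_w = np.asarray(v_w, dtype=float)
    if np.any(np.asarray(k_dbl) <= 0):
        raise ValueError("k_dbl must be positive")
    if np.any(v_w < 0):
        raise ValueError("v_w must be non-negative")
    out = v_w / k_dbl
    return float(out) if out.ndim == 0 else out


def sieving_coefficient(K_c: float, phi: float) -> float:
    """Sieving coefficient sigma = 1 - K_c * phi.

    Warns (but still returns the algebraic value) when K_c * phi > 1, which
    would imply negative sigma — advection into the pore faster than in free
    solution combined with favourable partitioning.
    """
    if K_c < 0 or phi < 0:
        raise ValueError("K_c and phi must be non-negative")
    sigma = 1.0 - K_c * phi
    if sigma < 0:
        warnings.warn(
            f"K_c*phi = {K_c * phi:g} > 1 gives negative sieving coefficient",
            UnphysicalValueWarning,
            stacklevel=2,
        )
    return sigma


def ferry_partition(r_s: float, r_p: float) -> float:
    """Steric partition coefficient (1 - r_s/r_p)^2 (Ferry equation).

    Returns 0 for r_s >= r_p: a solute as large as the pore cannot enter,
    and the squared form would spuriously rise again past r_s = 2 r_p.
    """
    if r_s < 0 or r_p <= 0:
        raise ValueError("radii must satisfy r_s >= 0, r_p > 0")
    if r_s >= r_p:
        return 0.0
    return (1.0 - r_s / r_p) ** 2


def smith_deen_partition(p: PartitionInputs) -> float:
    """Partition coefficient with an interaction-energy Boltzmann factor.

    Phi = (1 - r_s/r_p)^2 * exp(-E_T / kT); reduces to the Ferry equation
    when the solute-membrane interaction energy E_T is zero.  E_T > 0 is
    net repulsion (lower partitioning), E_T < 0 net attraction.
    """
    steric = ferry_partition(p.r_s, p.r_p)
    if np.isposinf(p.E_T):
        return 0.0
    return steric * float(np.exp(-p.E_T / p.kT))


def _check_sigma(sigma, strict: bool) -> None:
    s = np.asarray(sigma, dtype=float)
    if np.any(s < 0) or np.any(s > 1):
        if strict:
            raise ValueError(f"sigma outside [0, 1]: {sigma}")
        warnings.warn(
            "sigma outside [0, 1]; returning the algebraic value",
            UnphysicalValueWarning,
            stacklevel=3,
        )


def rejection_general(sigma, pe_d, pe_m, *, strict: bool = False):
    """Observed rejection with polarization and pore diffusion.

    R_obs = 1 - (1-sigma) / [(1-sigma) + exp(-Pe_d)*(1 - exp(-Pe_m))*sigma]

    The exp(-Pe_m) term carries the diffusive leak through the membrane:
    Pe_m -> 0 gives R_obs = 0 (diffusion equilibrates permeate with
    retentate), Pe_m -> infinity recovers :func:`rejection_advection`.
    Stable for Peclet numbers far past exp-underflow (exp(-pe) is taken as
    exactly 0 beyond 709 and the analytic limits apply).

    Accepts scalars or numpy arrays (broadcast).
    """
    _check_sigma(sigma, strict)
    sigma, pe_d, pe_m = np.broadcast_arrays(
        np.asarray(sigma, dtype=float),
        np.asarray(pe_d, dtype=float),
        np.asarray(pe_m, dtype=float),
    )
    if np.any(pe_d < 0) or np.any(pe_m < 0):
        raise ValueError("Peclet numbers must be non-negative")
    exp_d = np.where(pe_d > _EXP_UNDERFLOW, 0.0, np.exp(-np.minimum(pe_d, _EXP_UNDERFLOW)))
    # 1 - exp(-pe_m), accurate near pe_m = 0
    leak = np.where(pe_m > _EXP_UNDERFLOW, 1.0, -np.expm1(-np.minimum(pe_m, _EXP_UNDERFLOW)))
    num = 1.0 - sigma
    den = num + exp_d * leak * sigma
    with np.errstate(divide="ignore", invalid="ignore"):
        r = 1.0 - num / den
    # den == 0 only when sigma == 1 and (exp_d == 0 or leak == 0):
    # sigma = 1 rejects fully unless the membrane is purely diffusive
    # (pe_m = 0), which passes everything.
    r = np.where(den == 0.0, np.where(pe_m == 0.0, 0.0, 1.0), r)
    r = np.where(pe_m == 0.0, 0.0, r)
    return float(r) if r.ndim == 0 else r


def rejection_advection(sigma, pe_d, *, strict: bool = False):
    """Observed rejection when pore transport is purely advective.

    R_obs = 1 - (1-sigma) / [(1-sigma) + exp(-Pe_d)*sigma]

    Limit of :func:`rejection_general` as Pe_m -> infinity; at vanishing
    flux (Pe_d -> 0) R_obs -> sigma, which is why the sieving coefficient
    is the low-flux rejection plateau.
    """
    _check_sigma(sigma, strict)
    sigma, pe_d = np.broadcast_arrays(
        np.asarray(sigma, dtype=float), np.asarray(pe_d, dtype=float)
    )
    if np.any(pe_d < 0):
        raise ValueError("Peclet numbers must be non-negative")
    exp_d = np.where(pe_d > _EXP_UNDERFLOW, 0.0, np.exp(-np.minimum(pe_d, _EXP_UNDERFLOW)))
    num = 1.0 - sigma
    den = num + exp_d * sigma
    with np.errstate(divide="ignore", invalid="ignore"):
        r = 1.0 - num / den
    r = np.where(den == 0.0, 1.0, r)  # sigma == 1, exp_d == 0
    return float(r) if r.ndim == 0 else r


def solute_flux_membrane(c_m, c_p, v_w, K_c, phi, pe_m):
    """Integrated solute flux across the membrane active layer.

    J_i = K_c*Phi*v_w * (c_p*exp(-Pe_m) - c_m) / (exp(-Pe_m) - 1)

    Positive toward the permeate (c_m > c_p regime).  The expression is
    singular at Pe_m = 0 (pure diffusion: the flux then depends on k_m,
    which the arguments no longer determine); that case is flagged and the
    advective-scale limit is returned.
    """
    if pe_m < 0:
        raise ValueError("pe_m must be non-negative")
    if pe_m == 0.0:
        warnings.warn(
            "solute_flux_membrane is singular at Pe_m = 0; returning the "
            "pure-diffusion limit K_c*phi*(v_w/pe_m)*(c_m - c_p) -> inf "
            "unless c_m == c_p",
            DiffusionLimitWarning,
            stacklevel=2,
        )
        if c_m == c_p:
            return 0.0
        return float(np.sign(c_m - c_p) * np.inf) * K_c * phi
    if pe_m > _EXP_UNDERFLOW:
        return K_c * phi * v_w * c_m
    e = np.exp(-pe_m)
    return K_c * phi * v_w * (c_p * e - c_m) / (e - 1.0)


def solute_flux_polarization(c_b, c_m, v_w, pe_d):
    """Integrated solute flux across the concentration-polarization layer.

    J_i = v_w * (c_m*exp(-Pe_d) - c_b) / (exp(-Pe_d) - 1)

    With c_b = c_m the layer carries pure advection, J_i = v_w * c_b.
    Singular at Pe_d = 0 (flagged; same caveat as
    :func:`solute_flux_membrane`).
    """
    if pe_d < 0:
        raise ValueError("pe_d must be non-negative")
    if pe_d == 0.0:
        warnings.warn(
            "solute_flux_polarization is singular at Pe_d = 0; pure "
            "diffusion limit (v_w/pe_d)*(c_m - c_b) -> inf unless c_m == c_b",
            DiffusionLimitWarning,
            stacklevel=2,
        )
        if c_m == c_b:
            return 0.0
        return float(np.sign(c_m - c_b) * np.inf)
    if pe_d > _EXP_UNDERFLOW:
        return v_w * c_m
    e = np.exp(-pe_d)
    return v_w * (c_m * e - c_b) / (e - 1.0)


def observed_rejection(c_retentate, c_permeate):
    """Observed rejection R_obs = 1 - c_permeate / c_retentate.

    Both concentrations in the same units.  A permeate richer than the
    retentate yields a negative rejection, returned with a warning.
    """
    c_ret = np.asarray(c_retentate, dtype=float)
    c_per = np.asarray(c_permeate, dtype=float)
    if np.any(c_ret <= 0):
        raise ValueError("retentate concentration must be positive")
    if np.any(c_per < 0):
        raise ValueError("permeate concentration must be non-negative")
    r = 1.0 - c_per / c_ret
    if np.any(r < 0):
        warnings.warn(
            "permeate concentration exceeds retentate; negative rejection",
            UnphysicalValueWarning,
            stacklevel=2,
        )
    return float(r) if r.ndim == 0 else r


class ProfileConvergenceError(RuntimeError):
    """The boundary-value iteration failed to reach the flux tolerance."""


def _integrate_layer(c_start: float, J: float, v: float, D: float, length: float,
                     rtol: float) -> float:
    """Integrate dc/dx = (v*c - J)/D from 0 to `length`; return c(length).

    The steady advection-diffusion balance in either layer, written with x
    increasing from retentate to permeate and positive flux toward the
    permeate.
    """
    sol = solve_ivp(
        lambda x, c: (v * c - J) / D,
        (0.0, length),
        [c_start],
        method="RK45",
        rtol=rtol,
        atol=1e-14 * max(abs(c_start), abs(J / v) if v else 1.0, 1e-30),
        dense_output=False,
    )
    if not sol.success:
        raise ProfileConvergenceError(f"layer integration failed: {sol.message}")
    return float(sol.y[0, -1])


def solve_profile_numeric(
    mp: MicroscopicParameters,
    v_w: float,
    c_b: float,
    *,
    tol: float = 1e-10,
    max_iter: int = 200,
    ode_rtol: float = 1e-12,
) -> ConcentrationProfile:
    """Solve the two-layer steady-state transport problem numerically.

    Shoots on the permeate concentration c_p: for a trial c_p the uniform
    steady flux is J = v_w * c_p, the polarization-layer ODE (friction-free,
    bulk diffusivity) is integrated from c_b across delta_pol to get the
    wall concentration c_m, the partition jump Phi is applied at the pore
    entrance, the hindered ODE is integrated across delta_mem, and the exit
    concentration is compared with the partition condition Phi * c_p.  The
    mismatch is affine in c_p, so a secant step lands on the root; the
    iteration then polishes until the flux computed independently from the
    closed-form layer expressions is uniform to relative tolerance `tol`.

    This solver shares no algebra with :func:`rejection_general`; it is the
    independent oracle for the closed forms.
    """
    if v_w <= 0 or c_b <= 0:
        raise ValueError("v_w and c_b must be positive")

    if mp.phi == 0.0:
        # total exclusion: no solute crosses
        c_m = _solve_cm_no_flux(mp, v_w, c_b, ode_rtol)
        return ConcentrationProfile(
            c_b=c_b, c_m=c_m, c_x0=0.0, c_xdx=0.0, c_p=0.0, J_i=0.0, v_w=v_w,
            flux_imbalance=0.0, iterations=0,
        )

    D_mem_eff = mp.K_d * mp.D_m  # hindered diffusivity inside the pores

    def exit_mismatch(c_p: float) -> tuple[float, float, float]:
        J = v_w * c_p
        c_m = _integrate_layer(c_b, J, v_w, mp.D_i, mp.delta_pol, ode_rtol)
        c_x0 = mp.phi * c_m
        # inside the pore the advective velocity is hindered by K_c
        c_xdx = _integrate_layer(c_x0, J, mp.K_c * v_w, D_mem_eff, mp.delta_mem,
                                 ode_rtol)
        return c_xdx - mp.phi * c_p, c_m, c_xdx

    # mismatch is affine in c_p: two evaluations determine the root
    g0, _, _ = exit_mismatch(0.0)
    g1, _, _ = exit_mismatch(c_b)
    denom = g1 - g0
    if denom == 0.0:
        raise ProfileConvergenceError("degenerate shooting function")
    c_p = -g0 * c_b / denom

    scale = max(abs(v_w * c_b), 1e-300)
    last_imbalance = np.inf
    for iteration in range(1, max_iter + 1):
        g, c_m, c_xdx = exit_mismatch(c_p)
        c_x0 = mp.phi * c_m
        J = v_w * c_p
        # independent flux checks from the closed-form layer expressions
        pe_d = v_w * mp.delta_pol / mp.D_i
        pe_m = mp.K_c * v_w * mp.delta_mem / D_mem_eff
        J_pol = solute_flux_polarization(c_b, c_m, v_w, pe_d)
        J_mem = solute_flux_membrane(c_m, c_p, v_w, mp.K_c, mp.phi, pe_m)
        last_imbalance = max(abs(J_pol - J), abs(J_mem - J)) / scale
        if abs(g) <= tol * max(c_b, 1e-300) and last_imbalance <= max(tol, 10 * ode_rtol):
            return ConcentrationProfile(
                c_b=c_b, c_m=c_m, c_x0=c_x0, c_xdx=c_xdx, c_p=c_p, J_i=J,
                v_w=v_w, flux_imbalance=last_imbalance, iterations=iteration,
            )
        # secant refinement against the affine mismatch
        g_hi, _, _ = exit_mismatch(c_p + 0.5 * c_b)
        slope = (g_hi - g) / (0.5 * c_b)
        if slope == 0.0:
            break
        c_p = c_p - g / slope
    raise ProfileConvergenceError(
        f"no convergence after {max_iter} iterations "
        f"(flux imbalance {last_imbalance:.3e})"
    )


def _solve_cm_no_flux(mp: MicroscopicParameters, v_w: float, c_b: float,
                      ode_rtol: float) -> float:
    """Wall concentration when J = 0 (total exclusion): pure exponential film."""
    return _integrate_layer(c_b, 0.0, v_w, mp.D_i, mp.delta_pol, ode_rtol)
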