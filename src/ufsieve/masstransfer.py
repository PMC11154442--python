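"""Dimensionless groups and Sherwood correlations for crossflow channels.

The polarization-layer mass-transfer coefficient k_dbl of a spiral-wound
(spacer-filled) module is conventionally estimated from a Sherwood power
law Sh = A * Re^m * Sc^n, with Sh = k_dbl * d_h / D and the hydraulic
diameter of a spacer-filled channel

    d_h = 4 * eps / (2/h + (1 - eps) * S_v,p)

Five literature correlations are provided, with their exponents exactly as
published (note the Graetz-Leveque dialect uses 0.33 rather than 1/3, and
Bandini-Morelli exactly 1/3; a switch normalises all cube-root exponents to
1/3).  Applicability ranges are advisory: correlations derived for
turbulent salt-solution NF/RO channels are known to underestimate k_dbl
for protein ultrafiltration (Sc > 10^4, strong permeation "suction"), so
out-of-range use warns rather than errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "ModuleGeometry",
    "SolutionProperties",
    "CORRELATIONS",
    "ApplicabilityWarning",
    "hydraulic_diameter",
    "reynolds",
    "schmidt",
    "sherwood",
    "kdbl_from_sherwood",
    "kdbl_estimate",
]


class ApplicabilityWarning(UserWarning):
    """A correlation is being used outside its published flow regime."""


@dataclass(frozen=True)
class ModuleGeometry:
    """Spacer-filled channel geometry of a spiral-wound module.

    h: channel (spacer) height [m]; eps: spacer porosity (1 = open
    channel); S_vp: specific surface of the spacer [1/m]; L: channel
    length [m], needed only by entrance-region (Graetz-Leveque) laws.
    """

    h: float
    eps: float = 1.0
    S_vp: float = 0.0
    L: float = 1.0

    def __post_init__(self) -> None:
        if self.h <= 0 or self.L <= 0:
            raise ValueError("h and L must be positive")
        if not 0.0 < self.eps <= 1.0:
            raise ValueError("spacer porosity eps must lie in (0, 1]")
        if self.S_vp < 0:
            raise ValueError("S_vp must be non-negative")

    @property
    def d_h(self) -> float:
        return hydraulic_diameter(self)


@dataclass(frozen=True)
class SolutionProperties:
    """Fluid properties and crossflow velocity feeding Re and Sc.

    rho [kg/m^3], eta [Pa s], D bulk solute diffusivity [m^2/s],
    v_r crossflow velocity [m/s].
    """

    rho: float
    eta: float
    D: float
    v_r: float

    def __post_init__(self) -> None:
        for name in ("rho", "eta", "D", "v_r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def hydraulic_diameter(g: ModuleGeometry) -> float:
    """Hydraulic diameter 4*eps / (2/h + (1-eps)*S_vp) of a spacer-filled channel.

    Reduces to 2h for an empty channel (eps = 1)."""
    return 4.0 * g.eps / (2.0 / g.h + (1.0 - g.eps) * g.S_vp)


def reynolds(sp: SolutionProperties, d_h: float) -> float:
    """Reynolds number rho * v_r * d_h / eta."""
    if d_h <= 0:
        raise ValueError("d_h must be positive")
    return sp.rho * sp.v_r * d_h / sp.eta


def schmidt(sp: SolutionProperties) -> float:
    """Schmidt number eta / (rho * D)."""
    return sp.eta / (sp.rho * sp.D)


# name -> (A, m, n, uses_length, (Re_lo, Re_hi) advisory range)
_CORRELATION_TABLE = {
    "schock_miquel": (0.065, 0.875, 0.25, False, (100.0, 1000.0)),
    "graetz_leveque": (1.86, 0.33, 0.33, True, (0.0, 2100.0)),
    "harriot_hamilton": (0.0096, 0.91, 0.35, False, (2100.0, float("inf"))),
    "bandini_morelli": (0.016, 0.8, 1.0 / 3.0, False, (2100.0, float("inf"))),
    "shi": (0.075, 0.61, 0.33, False, (0.0, float("inf"))),
}

CORRELATIONS = tuple(_CORRELATION_TABLE)


def sherwood(
    correlation: str,
    Re: float,
    Sc: float,
    d_h: Optional[float] = None,
    L: Optional[float] = None,
    *,
    third_exponents: bool = False,
) -> float:
    """Evaluate a named Sherwood correlation A * Re^m * Sc^n.

    Parameters
    ----------
    correlation : str
        One of ``CORRELATIONS``.
    Re, Sc : float
        Reynolds and Schmidt numbers.
    d_h, L : float, optional
        Hydraulic diameter and channel length; required only by
        ``graetz_leveque``, whose law carries an extra (d_h/L)^0.33.
    third_exponents : bool
        Replace every printed 0.33 (or 0.35-adjacent cube root) exponent
        that is nominally a cube root with exactly 1/3.  Default keeps the
        published dialects bit-for-bit.
    """
    if correlation not in _CORRELATION_TABLE:
        raise ValueError(
            f"unknown correlation {correlation!r}; choose from {CORRELATIONS}"
        )
    if Re < 0 or Sc < 0:
        raise ValueError("Re and Sc must be non-negative")
    A, m, n, uses_length, (re_lo, re_hi) = _CORRELATION_TABLE[correlation]
    if third_exponents and abs(n - 0.33) < 1e-9:
        n = 1.0 / 3.0
    sh = A * Re**m * Sc**n
    if uses_length:
        if d_h is None or L is None:
            raise ValueError("graetz_leveque requires d_h and L")
        exp_geom = 1.0 / 3.0 if third_exponents else 0.33
        sh *= (d_h / L) ** exp_geom
    if Re > 0 and not re_lo <= Re <= re_hi:
        warnings.warn(
            f"{correlation}: Re = {Re:g} outside the published range "
            f"[{re_lo:g}, {re_hi:g}]",
            ApplicabilityWarning,
            stacklevel=2,
        )
    return sh


def kdbl_from_sherwood(Sh: float, D: float, d_h: float) -> float:
    """Mass-transfer coefficient k_dbl = Sh * D / d_h."""
    if Sh < 0 or D <= 0 or d_h <= 0:
        raise ValueError("require Sh >= 0, D > 0, d_h > 0")
    return Sh * D / d_h


def kdbl_estimate(
    correlation: str,
    geometry: ModuleGeometry,
    solution: SolutionProperties,
    *,
    third_exponents: bool = False,
) -> dict:
    """One-call estimate: d_h, Re, Sc, Sh and k_dbl for a named correlation."""
    d_h = hydraulic_diameter(geometry)
    Re = reynolds(solution, d_h)
    Sc = schmidt(solution)
    Sh = sherwood(correlation, Re, Sc, d_h=d_h, L=geometry.L,
                  third_exponents=third_exponents)
    return {
        "correlation": correlation,
        "d_h": d_h,
        "Re": Re,
        "Sc": Sc,
        "Sh": Sh,
        "k_dbl": kdbl_from_sherwood(Sh, solution.D, d_h),
    }


def default_solution_properties(v_r: float = 0.167) -> SolutionProperties:
    """Dilute aqueous BSA solution at 25 degC.

    rho = 997 kg/m^3 and eta = 0.89 mPa s are standard water values at
    25 degC and D = 6.0e-11 m^2/s a literature BSA diffusivity; they are
    package defaults for convenience, not measured properties of any
    particular rig.
    """
    return SolutionProperties(rho=997.0, eta=0.89e-3, D=6.0e-11, v_r=v_r)
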