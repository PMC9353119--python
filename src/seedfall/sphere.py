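"""Theoretical terminal velocity of a smooth sphere in air.

Used to validate video-based terminal-velocity estimates against first
principles: for a sphere of diameter ``d`` and density ``rho_s`` falling in
air, terminal velocity satisfies the force balance

    Cd(Re) * (pi d^2 / 8) * rho_a * Vt^2  =  (pi d^3 / 6) * (rho_s - rho_a) * g

with the Reynolds number Re = rho_a * Vt * d / mu coupling the drag
coefficient to the unknown Vt.  The fixed point is found with a bracketing
root finder.  The drag correlation is pluggable; the default is the
Clift-Gauvin fit to the standard drag curve for smooth spheres, valid from
the Stokes regime up to Re ~ 2e5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .physics import STANDARD_GRAVITY

__all__ = [
    "SphereSpec",
    "AirProperties",
    "SphereVtResult",
    "drag_coefficient",
    "theoretical_Vt",
]

#: Available drag-coefficient correlations.
CD_MODELS = ("clift-gauvin", "schiller-naumann", "constant")


@dataclass(frozen=True)
class SphereSpec:
    """A smooth sphere: diameter ``d`` (m) and material density ``rho_s`` (kg/m^3)."""

    d: float
    rho_s: float

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise ValueError("sphere diameter must be positive")
        if not self.rho_s > 0:
            raise ValueError("sphere density must be positive")


@dataclass(frozen=True)
class AirProperties:
    """Ambient air: density (kg/m^3) and dynamic viscosity (Pa s).

    Defaults are sea-level values at 20 degC.
    """

    rho_a: float = 1.204
    mu: float = 1.825e-5

    def __post_init__(self) -> None:
        if not (self.rho_a > 0 and self.mu > 0):
            raise ValueError("air density and viscosity must be positive")


@dataclass(frozen=True)
class SphereVtResult:
    """Converged terminal velocity with its Reynolds number and drag coefficient."""

    Vt: float
    Re: float
    Cd: float
    residual: float  # |drag - submerged weight| / weight


def drag_coefficient(Re, model: str = "clift-gauvin", constant: float = 0.44):
    """Drag coefficient of a smooth sphere at Reynolds number ``Re``.

    ``clift-gauvin`` (default): Cd = (24/Re)(1 + 0.15 Re^0.687)
    + 0.42 / (1 + 42500 Re^-1.16), a standard-drag-curve fit good to a few
    percent over 0 < Re < 2e5 and reducing to Stokes' law (24/Re) at small Re.
    ``schiller-naumann``: the same viscous branch without the Newton plateau
    term (valid Re < ~800).  ``constant``: Cd fixed at ``constant``.
    """
    Re = np.asarray(Re, dtype=float)
    if np.any(Re <= 0):
        raise ValueError("Reynolds number must be positive")
    if model == "clift-gauvin":
        cd = 24.0 / Re * (1.0 + 0.15 * Re**0.687) + 0.42 / (1.0 + 42500.0 * Re**-1.16)
    elif model == "schiller-naumann":
        cd = 24.0 / Re * (1.0 + 0.15 * Re**0.687)
    elif model == "constant":
        cd = np.full_like(Re, float(constant))
    else:
        raise ValueError(f"unknown drag model {model!r}; choose from {CD_MODELS}")
    return cd if cd.ndim else float(cd)


def theoretical_Vt(
    sphere: SphereSpec,
    air: AirProperties = AirProperties(),
    g: float = STANDARD_GRAVITY,
    cd_model: str = "clift-gauvin",
    cd_constant: float = 0.44,
    tol: float = 1e-8,
) -> SphereVtResult:
    """Terminal velocity of a sphere, solving the Vt <-> Re coupling.

    Finds the root of the force balance
    ``Vt - sqrt((4/3) g d (rho_s - rho_a) / (Cd(Re(Vt)) rho_a))``
    by bracketing; buoyancy enters through the density difference (negligible
    for dense materials, a ~0.1% effect already at rho_s = 500 kg/m^3, but
    physically correct for light foams).

    Returns the converged Vt together with the Reynolds number, the drag
    coefficient at convergence, and the relative force-balance residual.
    """
    if sphere.rho_s <= air.rho_a:
        raise ValueError(
            f"sphere density ({sphere.rho_s} kg/m^3) must exceed air density "
            f"({air.rho_a} kg/m^3) for the sphere to fall"
        )

    d, rho_s, rho_a, mu = sphere.d, sphere.rho_s, air.rho_a, air.mu

    def balance_speed(v: float) -> float:
        # Vt implied by the force balance at the drag coefficient of speed v
        Re = rho_a * v * d / mu
        cd = drag_coefficient(Re, model=cd_model, constant=cd_constant)
        return float(np.sqrt(4.0 * g * d * (rho_s - rho_a) / (3.0 * cd * rho_a)))

    def f(v: float) -> float:
        return v - balance_speed(v)

    # Bracket: start from the constant-Cd Newton estimate and expand.
    v_hi = balance_speed(max(balance_speed(1.0), 1e-12))
    lo, hi = 1e-12, max(v_hi, 1e-6)
    for _ in range(200):
        if f(hi) >= 0:
            break
        hi *= 2.0
    else:
        raise RuntimeError(
            f"terminal-velocity solver failed to bracket a root "
            f"(d={d}, rho_s={rho_s}; last bracket [{lo}, {hi}])"
        )
    Vt = brentq(f, lo, hi, xtol=tol)

    Re = rho_a * Vt * d / mu
    Cd = float(drag_coefficient(Re, model=cd_model, constant=cd_constant))
    weight = np.pi * d**3 / 6.0 * (rho_s - rho_a) * g
    drag = Cd * np.pi * d**2 / 8.0 * rho_a * Vt**2
    residual = abs(drag - weight) / weight
    if residual > 1e-6:
        raise RuntimeError(
            f"terminal-velocity solver did not converge: relative force "
            f"residual {residual:.3e} (Vt={Vt:.6g}, Re={Re:.6g})"
        )
    return SphereVtResult(Vt=float(Vt), Re=float(Re), Cd=Cd, residual=float(residual))
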