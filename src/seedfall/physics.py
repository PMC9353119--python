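"""Closed-form kinematics of vertical free fall with quadratic air resistance.

A falling body whose drag grows with the square of its speed (a sphere at
Reynolds number > 10) obeys

    dv/dt = g (1 - v**2 / Vt**2),        v(0) = 0,

where ``Vt`` is the terminal velocity at which drag balances weight.  The
solution has the closed forms

    v(t) = Vt * tanh(g t / Vt)
    z(t) = z0 - (Vt**2 / g) * log(cosh(g t / Vt))

with ``z`` the metric vertical position (increasing upward; the seed falls so
``z`` decreases from the release position ``z0``).  This module houses those
kinematics and the derived quantities used to reason about seed acceleration:
the fall distance needed to approach terminal velocity, its inverse, and the
relaxation timescale ``tau = Vt / g``.

All quantities are SI (metres, seconds, m/s, m/s^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

STANDARD_GRAVITY = 9.81  # m/s^2

__all__ = [
    "STANDARD_GRAVITY",
    "FallModel",
    "log_cosh",
    "predict_position",
    "predict_velocity",
    "distance_to_velocity_fraction",
    "velocity_fraction_at_distance",
    "relaxation_time",
]


def log_cosh(u):
    """Overflow-safe ``log(cosh(u))``.

    Uses ``log(cosh(u)) = logaddexp(u, -u) - log 2``, which is exact in
    floating point and never overflows (``cosh(u)`` itself overflows for
    ``|u| > ~710``, easily reached for slow seeds over long times).
    """
    u = np.asarray(u, dtype=float)
    return np.logaddexp(u, -u) - np.log(2.0)


@dataclass(frozen=True)
class FallModel:
    """Free-fall-with-drag model parameters.

    Parameters
    ----------
    Vt : float
        Terminal velocity in m/s; must be positive.
    z0 : float
        Vertical position at t = 0 (release / recording start), in metres.
    g : float
        Gravitational acceleration in m/s^2 (default 9.81).
    """

    Vt: float
    z0: float = 0.0
    g: float = STANDARD_GRAVITY

    def __post_init__(self) -> None:
        if not self.Vt > 0:
            raise ValueError(f"terminal velocity must be positive, got {self.Vt}")
        if not self.g > 0:
            raise ValueError(f"gravitational acceleration must be positive, got {self.g}")

    def position(self, t):
        return predict_position(self, t)

    def velocity(self, t):
        return predict_velocity(self, t)


def _check_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return t


def predict_position(model: FallModel, t):
    """Vertical position z(t) = z0 - (Vt^2/g) * log cosh(g t / Vt).

    Vectorised over ``t``; raises ``ValueError`` for negative times.
    """
    t = _check_time(t)
    u = model.g * t / model.Vt
    z = model.z0 - (model.Vt**2 / model.g) * log_cosh(u)
    return z if z.ndim else float(z)


def predict_velocity(model: FallModel, t):
    """Falling speed v(t) = Vt * tanh(g t / Vt); 0 <= v < Vt, v(0) = 0."""
    t = _check_time(t)
    v = model.Vt * np.tanh(model.g * t / model.Vt)
    return v if v.ndim else float(v)


def distance_to_velocity_fraction(Vt: float, fraction: float, g: float = STANDARD_GRAVITY) -> float:
    """Fall distance from rest at which speed first equals ``fraction * Vt``.

    Solving v(t) = fraction * Vt gives g t / Vt = atanh(fraction), so the
    distance fallen is (Vt^2 / g) * log cosh(atanh(fraction)).  A seed never
    attains its terminal velocity exactly, hence ``fraction`` must lie in
    (0, 1); e.g. reaching 99% of Vt = 6.4 m/s requires a fall of ~8.2 m.
    """
    if not Vt > 0:
        raise ValueError("Vt must be positive")
    if not 0 < fraction < 1:
        raise ValueError(
            f"fraction must lie strictly between 0 and 1 (terminal velocity is "
            f"approached asymptotically, never attained); got {fraction}"
        )
    u = np.arctanh(fraction)
    return float(Vt**2 / g * log_cosh(u))


def velocity_fraction_at_distance(Vt: float, distance: float, g: float = STANDARD_GRAVITY) -> float:
    """Fraction of Vt attained after falling ``distance`` metres from rest.

    Inverse of :func:`distance_to_velocity_fraction`:
    fraction = tanh(arccosh(exp(distance * g / Vt^2))).
    """
    if not Vt > 0:
        raise ValueError("Vt must be positive")
    if distance < 0:
        raise ValueError("distance must be non-negative")
    if distance == 0:
        return 0.0
    u = distance * g / Vt**2
    # tanh(arccosh(e^u)) = sqrt(1 - e^(-2u)), stable for large u
    return float(np.sqrt(-np.expm1(-2.0 * u)))


def relaxation_time(Vt: float, g: float = STANDARD_GRAVITY) -> float:
    """Lagrangian relaxation timescale tau = Vt / g.

    The characteristic time over which a particle with quadratic drag adjusts
    its velocity toward equilibrium; seeds with large tau respond sluggishly
    to gravity and to changes in wind speed.
    """
    if not Vt > 0:
        raise ValueError("Vt must be positive")
    if not g > 0:
        raise ValueError("g must be positive")
    return Vt / g
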