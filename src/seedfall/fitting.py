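"""Nonlinear least-squares estimation of terminal velocity from a trajectory.

Only the vertical coordinate enters the fit: the model
z(t) = z0 - (Vt^2/g) * log cosh(g t / Vt) is fitted to the observed (t, z)
series over the two parameters (Vt, z0), with Vt constrained positive.  The
time origin is the recording clock (the camera starts when the release flap
opens), so v(0) = 0 holds by construction and no time-offset parameter is
needed.

Model adequacy is judged in velocity space: the observed average velocity
over each inter-frame interval, (z_i - z_{i+1}) / dt, is compared with the
model's average velocity over the same interval (finite difference of the
predicted positions — with this convention a noise-free model trajectory has
exactly zero error).  The root mean squared error of these interval
velocities summarises the discrepancy; the unaggregated differences, plotted
against time, show which phase of the fall the model misses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

from .physics import STANDARD_GRAVITY, FallModel, log_cosh, predict_position
from .tracking import Trajectory3D

__all__ = ["FallFit", "fit_fall_model", "velocity_rmse", "velocity_differences"]


@dataclass(frozen=True)
class FallFit:
    """A fitted fall model with its goodness-of-fit diagnostics."""

    model: FallModel
    r_squared: float
    velocity_rmse: float
    n_frames: int
    residuals: np.ndarray  # observed - predicted position, m
    converged: bool
    n_iterations: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "Vt": self.model.Vt,
                    "z0": self.model.z0,
                    "g": self.model.g,
                    "r_squared": self.r_squared,
                    "velocity_rmse": self.velocity_rmse,
                    "n_frames": self.n_frames,
                    "converged": self.converged,
                    "n_iterations": self.n_iterations,
                },
                indent=2,
            )
        )


def _model_z(t: np.ndarray, Vt: float, z0: float, g: float) -> np.ndarray:
    u = g * t / Vt
    return z0 - (Vt**2 / g) * log_cosh(u)


def _start_values(t: np.ndarray, z: np.ndarray, g: float) -> tuple[float, float]:
    # z0: first observed position plus the drop a freely-falling (drag-free)
    # seed would have accumulated by the first observed frame time.
    z0 = float(z[0] + 0.5 * g * t[0] ** 2)
    # Vt: the seed is closest to terminal speed at the end of the window.
    k = min(3, len(t) - 1)
    v_late = (z[-1 - k] - z[-1]) / (t[-1] - t[-1 - k])
    return max(float(v_late), 0.1), z0


def fit_fall_model(traj: Trajectory3D, g: float = STANDARD_GRAVITY) -> FallFit:
    """Estimate (Vt, z0) by nonlinear least squares on the vertical positions.

    Uses bounded least squares with the analytic Jacobian
    (d z/d Vt = -(2 Vt/g) log cosh(u) + t tanh(u) with u = g t / Vt;
    d z/d z0 = 1).  Raises on an upward-moving series ("not a falling
    trajectory") or failure to converge.
    """
    t = np.asarray(traj.t, dtype=float)
    z = np.asarray(traj.z, dtype=float)
    if len(t) < 5:
        raise ValueError(f"need at least 5 frames to fit, got {len(t)}")
    if np.ptp(z) == 0:
        raise ValueError("z is constant; nothing to fit")
    if z[-1] > z[0]:
        raise ValueError("not a falling trajectory: z increases over the observation window")

    def residuals(theta: np.ndarray) -> np.ndarray:
        Vt, z0 = theta
        return z - _model_z(t, Vt, z0, g)

    def jacobian(theta: np.ndarray) -> np.ndarray:
        Vt, _ = theta
        u = g * t / Vt
        # residual = z - model, so J = -d(model)/d(theta)
        dz_dVt = -(2.0 * Vt / g) * log_cosh(u) + t * np.tanh(u)
        J = np.empty((len(t), 2))
        J[:, 0] = -dz_dVt
        J[:, 1] = -1.0
        return J

    x0 = np.asarray(_start_values(t, z, g))
    result = least_squares(
        residuals,
        x0,
        jac=jacobian,
        bounds=([1e-6, -np.inf], [np.inf, np.inf]),
        xtol=1e-10,
        ftol=1e-12,
        gtol=1e-12,
    )
    if not result.success:
        raise RuntimeError(
            f"terminal-velocity fit did not converge: {result.message} "
            f"(status {result.status}, {result.nfev} evaluations, x={result.x})"
        )

    Vt, z0 = result.x
    model = FallModel(Vt=float(Vt), z0=float(z0), g=g)
    resid = residuals(result.x)
    sst = float(np.sum((z - z.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0
    fit = FallFit(
        model=model,
        r_squared=r2,
        velocity_rmse=np.nan,
        n_frames=len(t),
        residuals=resid,
        converged=True,
        n_iterations=int(result.nfev),
    )
    return FallFit(
        model=model,
        r_squared=r2,
        velocity_rmse=velocity_rmse(traj, fit),
        n_frames=len(t),
        residuals=resid,
        converged=True,
        n_iterations=int(result.nfev),
    )


def _interval_velocities(traj: Trajectory3D, fit: FallFit):
    t = np.asarray(traj.t, dtype=float)
    z = np.asarray(traj.z, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 frames to compute interval velocities")
    dt = np.diff(t)
    observed = (z[:-1] - z[1:]) / dt  # falling speed, positive downward
    z_pred = predict_position(fit.model, t)
    predicted = (z_pred[:-1] - z_pred[1:]) / dt
    t_mid = 0.5 * (t[:-1] + t[1:])
    return t_mid, observed, predicted


def velocity_rmse(traj: Trajectory3D, fit: FallFit) -> float:
    """RMSE between observed and model interval-average falling velocities (m/s)."""
    _, observed, predicted = _interval_velocities(traj, fit)
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


def velocity_differences(traj: Trajectory3D, fit: FallFit):
    """Per-interval (t_mid, observed - predicted velocity) diagnostic series.

    The root mean square of the returned differences equals
    :func:`velocity_rmse`; systematic late-time structure indicates model
    violations (e.g. lift from rotation) rather than measurement noise.
    """
    t_mid, observed, predicted = _interval_velocities(traj, fit)
    return t_mid, observed - predicted
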