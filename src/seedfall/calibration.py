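"""Conversion functions mapping image coordinates to 3D metric coordinates.

A seed appears twice in each frame: directly (image coordinates ``x_d``,
``z_d``, in px) and via the mirror (``y_m``, ``z_m``).  Three linear models
with interaction convert these four pixel coordinates into metric space:

    x = a0 + a1*x_d + a2*y_m + a3*x_d*y_m
    y = b0 + b1*x_d + b2*y_m + b3*x_d*y_m
    z = c0 + c1*z_d + c2*z_m + c3*z_d*z_m

The horizontal maps use only the two horizontal image coordinates and the
vertical map only the two vertical ones.  The coefficients are fitted by
ordinary least squares to observations of marked grid locations with known
3D positions (a calibration board photographed at several placements inside
the falling corridor).  The interaction term absorbs the perspective
coupling between the two views; no explicit camera model is required, which
is precisely what makes the single-camera-plus-mirror design calibratable
with a sheet of grid paper.

Pixel origin is the image top-left (columns increase rightward, rows
downward); the fitted signs of the vertical coefficients convert rows to
upward metric z, so no hard-coded axis flip exists anywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationObservation",
    "ConversionModel",
    "fit_conversion",
    "image_to_world",
    "read_calibration_csv",
    "write_calibration_csv",
]

#: canonical CSV column order for calibration tables
CALIBRATION_COLUMNS = ["true_x", "true_y", "true_z", "x_d", "z_d", "y_m", "z_m"]


@dataclass(frozen=True)
class CalibrationObservation:
    """One marked grid location: its metric 3D position and its two image positions.

    ``true_x, true_y, true_z`` in metres; ``x_d, z_d`` (direct view) and
    ``y_m, z_m`` (mirror view) in pixels.
    """

    true_x: float
    true_y: float
    true_z: float
    x_d: float
    z_d: float
    y_m: float
    z_m: float


@dataclass(frozen=True)
class ConversionModel:
    """Fitted coefficients of the three image-to-world linear maps.

    Each coefficient vector is ordered (intercept, first coordinate, second
    coordinate, interaction): ``coef_x``/``coef_y`` over (1, x_d, y_m,
    x_d*y_m) and ``coef_z`` over (1, z_d, z_m, z_d*z_m).  ``r_squared`` holds
    the in-sample R^2 of each map, and ``pixel_bounds`` the calibrated pixel
    ranges per image coordinate (used to flag extrapolation).
    """

    coef_x: np.ndarray
    coef_y: np.ndarray
    coef_z: np.ndarray
    r_squared: dict  # {"x": .., "y": .., "z": ..}
    n_obs: int
    pixel_bounds: dict  # {"x_d": (lo, hi), ...}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "model": "linear-with-interaction",
            "coef_x": list(map(float, self.coef_x)),
            "coef_y": list(map(float, self.coef_y)),
            "coef_z": list(map(float, self.coef_z)),
            "r_squared": {k: float(v) for k, v in self.r_squared.items()},
            "n_obs": int(self.n_obs),
            "pixel_bounds": {k: [float(v[0]), float(v[1])] for k, v in self.pixel_bounds.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ConversionModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            coef_x=np.asarray(payload["coef_x"], dtype=float),
            coef_y=np.asarray(payload["coef_y"], dtype=float),
            coef_z=np.asarray(payload["coef_z"], dtype=float),
            r_squared=payload["r_squared"],
            n_obs=payload["n_obs"],
            pixel_bounds={k: tuple(v) for k, v in payload["pixel_bounds"].items()},
        )


def _design(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(a), a, b, a * b])


def _ols(X: np.ndarray, y: np.ndarray, name: str, predictors: tuple[str, str]):
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient calibration design for the {name} map: the image "
            f"coordinates {predictors} do not span enough distinct values "
            f"(rank {rank} < 4); spread the calibration marks over the corridor"
        )
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0
    return coef, r2


def _as_table(observations) -> pd.DataFrame:
    if isinstance(observations, pd.DataFrame):
        df = observations
    else:
        df = pd.DataFrame([vars(o) if not isinstance(o, dict) else o for o in observations])
    missing = [c for c in CALIBRATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"calibration table is missing columns {missing}")
    return df


def fit_conversion(observations: Sequence[CalibrationObservation] | pd.DataFrame) -> ConversionModel:
    """Fit the three conversion maps by ordinary least squares.

    Requires at least 8 observations whose image coordinates are not
    collinear (each 4-coefficient map needs a full-rank design).  Returns the
    fitted :class:`ConversionModel` with per-coordinate R^2.
    """
    df = _as_table(observations)
    if len(df) < 8:
        raise ValueError(f"need at least 8 calibration observations, got {len(df)}")

    x_d = df["x_d"].to_numpy(float)
    z_d = df["z_d"].to_numpy(float)
    y_m = df["y_m"].to_numpy(float)
    z_m = df["z_m"].to_numpy(float)

    Xh = _design(x_d, y_m)
    Xv = _design(z_d, z_m)
    coef_x, r2_x = _ols(Xh, df["true_x"].to_numpy(float), "x", ("x_d", "y_m"))
    coef_y, r2_y = _ols(Xh, df["true_y"].to_numpy(float), "y", ("x_d", "y_m"))
    coef_z, r2_z = _ols(Xv, df["true_z"].to_numpy(float), "z", ("z_d", "z_m"))

    bounds = {
        name: (float(v.min()), float(v.max()))
        for name, v in (("x_d", x_d), ("z_d", z_d), ("y_m", y_m), ("z_m", z_m))
    }
    return ConversionModel(
        coef_x=coef_x,
        coef_y=coef_y,
        coef_z=coef_z,
        r_squared={"x": r2_x, "y": r2_y, "z": r2_z},
        n_obs=len(df),
        pixel_bounds=bounds,
    )


def image_to_world(model: ConversionModel, x_d, z_d, y_m, z_m):
    """Apply the fitted conversion maps to image coordinates.

    Vectorised; returns ``(x, y, z, extrapolated)`` where ``extrapolated`` is
    a boolean flag (per element) marking inputs outside the calibrated pixel
    ranges.  Extrapolation is permitted — the linear maps remain defined —
    but accuracy is only guaranteed inside the calibrated volume.
    """
    x_d = np.asarray(x_d, dtype=float)
    z_d = np.asarray(z_d, dtype=float)
    y_m = np.asarray(y_m, dtype=float)
    z_m = np.asarray(z_m, dtype=float)

    Xh = _design(x_d.ravel(), y_m.ravel())
    Xv = _design(z_d.ravel(), z_m.ravel())
    x = (Xh @ model.coef_x).reshape(x_d.shape)
    y = (Xh @ model.coef_y).reshape(x_d.shape)
    z = (Xv @ model.coef_z).reshape(z_d.shape)

    extrapolated = np.zeros(x_d.shape, dtype=bool)
    for name, v in (("x_d", x_d), ("z_d", z_d), ("y_m", y_m), ("z_m", z_m)):
        lo, hi = model.pixel_bounds[name]
        extrapolated |= (v < lo) | (v > hi)

    if x.ndim == 0:
        return float(x), float(y), float(z), bool(extrapolated)
    return x, y, z, extrapolated


def read_calibration_csv(path: str | Path) -> pd.DataFrame:
    """Read a calibration table (columns true_x, true_y, true_z, x_d, z_d, y_m, z_m)."""
    return _as_table(pd.read_csv(path))


def write_calibration_csv(observations, path: str | Path) -> None:
    _as_table(observations)[CALIBRATION_COLUMNS].to_csv(path, index=False)
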