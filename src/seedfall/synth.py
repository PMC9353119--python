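"""Synthetic data standing in for the drop-test apparatus.

The measurement rig is a backlit falling corridor (0.25 x 0.25 x 0.33 m)
filmed by a single high-speed camera 0.58 m from the corridor center, with a
mirror on the adjacent side giving a second, perpendicular-ish view of the
seed in the same frame (1920 x 1200 px, up to 150 fps).  This module
emulates every data product of that rig so the full analysis chain can be
exercised and validated without hardware:

* ground-truth falling trajectories from the drag kinematics;
* their projection into direct + mirror image coordinates through a pinhole
  model of the camera-and-mirror geometry;
* rendered frame stacks (dark seed blob on a bright background, first frame
  seed-free) for the detector;
* calibration-board designs (35 grid marks imaged at 5 x 5 board
  placements) for the conversion-model fit;
* replicated terminal-velocity datasets with prescribed species / seed /
  residual variance components for the repeatability statistics.

World coordinates: origin at the corridor center horizontally, z measured
upward from the corridor floor; the camera looks along +y, the mirror's
virtual camera along -x (the mirror sits at 62 degrees to the camera plane,
which makes the reflected view close to perpendicular; the residual
obliquity is exactly what the fitted conversion functions absorb on the
real rig, so the perpendicular approximation is the default and the virtual
view angle is configurable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import CALIBRATION_COLUMNS
from .detection import FrameStack
from .physics import STANDARD_GRAVITY, FallModel, predict_position
from .tracking import Trajectory3D

__all__ = [
    "ApparatusGeometry",
    "NoiseModel",
    "simulate_trajectory",
    "project",
    "render_frames",
    "generate_calibration",
    "simulate_vt_dataset",
]


@dataclass(frozen=True)
class ApparatusGeometry:
    """Geometry of the corridor, camera and mirror.

    corridor : (width x, depth y, height z) of the measurement volume, m.
    camera_distance : lens to corridor center along the optical axis, m.
    mirror_path : effective optical path camera -> mirror -> corridor
        center, m.  Longer than ``camera_distance`` because the mirror view
        is folded; sets the mirror view's (smaller) magnification.
    mirror_angle_deg : physical mirror angle from the camera plane, deg.
    mirror_view_angle_deg : horizontal angle between the direct optical axis
        and the mirror's virtual viewing axis; 90 is the perpendicular
        approximation.
    frame_size : (width, height) px.  fps : frames per second.
    fill_fraction : fraction of each half-frame the corridor spans at its
        nearest face; fixes the focal length.
    projection : "pinhole" (perspective) or "orthographic" (constant
        magnification at the center depth; makes the conversion maps exactly
        linear — useful as a degenerate test case).
    """

    corridor: tuple[float, float, float] = (0.25, 0.25, 0.33)
    camera_distance: float = 0.58
    mirror_path: float = 0.81
    mirror_angle_deg: float = 62.0
    mirror_view_angle_deg: float = 90.0
    frame_size: tuple[int, int] = (1920, 1200)
    fps: float = 130.0
    fill_fraction: float = 0.85
    projection: str = "pinhole"

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.corridor):
            raise ValueError("corridor dimensions must be positive")
        if self.camera_distance <= 0 or self.mirror_path <= 0 or self.fps <= 0:
            raise ValueError("camera distance, mirror path and fps must be positive")
        if not 0 < self.mirror_angle_deg < 90:
            raise ValueError("mirror angle must lie in (0, 90) degrees")
        if self.projection not in ("pinhole", "orthographic"):
            raise ValueError("projection must be 'pinhole' or 'orthographic'")

    # -- derived quantities -------------------------------------------------

    @property
    def z_center(self) -> float:
        return self.corridor[2] / 2.0

    @property
    def split_col(self) -> float:
        """Column separating the direct (left) from the mirror (right) half."""
        return self.frame_size[0] / 2.0

    @property
    def principal_points(self) -> dict:
        """Principal point (col, row) of each view in full-frame coordinates."""
        w, h = self.frame_size
        return {"direct": (w / 4.0, h / 2.0), "mirror": (3.0 * w / 4.0, h / 2.0)}

    @property
    def focal_px(self) -> float:
        """Focal length in px so the corridor fills ``fill_fraction`` of a half-frame."""
        cx, cy, cz = self.corridor
        w, h = self.frame_size
        half_w = w / 2.0
        near_d = self.camera_distance - cy / 2.0
        near_m = self.mirror_path - cx / 2.0
        candidates = [
            half_w * near_d / cx,
            h * near_d / cz,
            half_w * near_m / cy,
            h * near_m / cz,
        ]
        return self.fill_fraction * min(candidates)

    def contains(self, x, y, z) -> np.ndarray:
        cx, cy, cz = self.corridor
        return (
            (np.abs(np.asarray(x)) <= cx / 2.0)
            & (np.abs(np.asarray(y)) <= cy / 2.0)
            & (np.asarray(z) >= 0.0)
            & (np.asarray(z) <= cz)
        )


@dataclass(frozen=True)
class NoiseModel:
    """Imaging imperfections applied when projecting / rendering.

    jitter_px : sd of Gaussian jitter on each projected image coordinate.
    blob_radius_px : rendered seed radius.
    contrast : intensity drop of the blob below the background (0-255).
    pixel_noise_sd : sd of Gaussian gray-level noise per pixel.
    dropout_prob : probability that a frame renders without the seed.
    background_level : backlit background intensity (0-255).
    """

    jitter_px: float = 0.3
    blob_radius_px: float = 8.0
    contrast: float = 180.0
    pixel_noise_sd: float = 2.0
    dropout_prob: float = 0.0
    background_level: float = 230.0

    def __post_init__(self) -> None:
        if self.jitter_px < 0 or self.pixel_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if not 0 <= self.dropout_prob <= 1:
            raise ValueError("dropout probability must lie in [0, 1]")


# ---------------------------------------------------------------------------
# trajectory simulation
# ---------------------------------------------------------------------------


def simulate_trajectory(
    Vt: float,
    z0: float,
    geometry: ApparatusGeometry = ApparatusGeometry(),
    duration: float | None = None,
    g: float = STANDARD_GRAVITY,
    x0: float = 0.0,
    y0: float = 0.0,
    lateral_drift_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Trajectory3D:
    """Ground-truth trajectory of a seed released at height ``z0`` at t = 0.

    Samples the drag kinematics at the frame rate and keeps the frames during
    which the seed is inside the corridor (0 <= z <= corridor height); the
    frame index stays on the recording clock, with frame 0 at release.
    Lateral position is constant by default; ``lateral_drift_sd`` (m per
    sqrt(frame)) adds a smooth random walk in x and y.
    """
    model = FallModel(Vt=Vt, z0=z0, g=g)
    cz = geometry.corridor[2]
    if duration is not None and duration <= 0:
        raise ValueError("duration must be positive (zero-length recording requested)")
    if duration is None:
        # analytic time to reach the corridor floor, plus one frame of slack
        duration = _time_to_position(model, 0.0) + 1.0 / geometry.fps

    n = int(math.floor(duration * geometry.fps)) + 1
    frame_index = np.arange(n)
    t = frame_index / geometry.fps
    z = predict_position(model, t)

    if lateral_drift_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        x = x0 + np.cumsum(rng.normal(0.0, lateral_drift_sd, n))
        y = y0 + np.cumsum(rng.normal(0.0, lateral_drift_sd, n))
    else:
        x = np.full(n, float(x0))
        y = np.full(n, float(y0))

    inside = (z <= cz) & (z >= 0.0)
    if not inside.any():
        raise ValueError(
            f"seed never enters the corridor within {duration:.3g} s "
            f"(release height {z0} m, corridor top {cz} m)"
        )
    return Trajectory3D(
        frame_index=frame_index[inside],
        t=t[inside],
        x=x[inside],
        y=y[inside],
        z=z[inside],
    )


def _time_to_position(model: FallModel, z_target: float) -> float:
    """Invert z(t) for the time at which the model first reaches ``z_target``."""
    drop = model.z0 - z_target
    if drop < 0:
        raise ValueError("target position lies above the release height")
    # log cosh(u) = drop * g / Vt^2  ->  u = arccosh(exp(...))
    u = math.acosh(math.exp(min(drop * model.g / model.Vt**2, 700.0)))
    return u * model.Vt / model.g


# ---------------------------------------------------------------------------
# forward projection (camera + mirror)
# ---------------------------------------------------------------------------


def _project_points(geometry: ApparatusGeometry, x, y, z) -> pd.DataFrame:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    f = geometry.focal_px
    zc = geometry.z_center
    pp = geometry.principal_points

    # direct view: optical axis +y, depth measured from the lens
    depth_d = geometry.camera_distance + y
    if np.any(depth_d <= 0):
        raise ValueError("position behind the camera (non-positive direct-view depth)")

    # mirror view: virtual camera along -x (rotated by mirror_view_angle from
    # the direct axis); depth along the virtual axis, lateral coordinate is
    # the in-plane perpendicular component
    theta = math.radians(geometry.mirror_view_angle_deg)
    depth_m = geometry.mirror_path - (x * math.sin(theta) + y * math.cos(theta))
    lateral_m = y * math.sin(theta) - x * math.cos(theta)
    if np.any(depth_m <= 0):
        raise ValueError("position behind the mirror's virtual camera")

    if geometry.projection == "orthographic":
        depth_d = np.full_like(depth_d, geometry.camera_distance)
        depth_m = np.full_like(depth_m, geometry.mirror_path)

    x_d = pp["direct"][0] + f * x / depth_d
    z_d = pp["direct"][1] - f * (z - zc) / depth_d
    y_m = pp["mirror"][0] + f * lateral_m / depth_m
    z_m = pp["mirror"][1] - f * (z - zc) / depth_m
    return pd.DataFrame({"x_d": x_d, "z_d": z_d, "y_m": y_m, "z_m": z_m})


def project(
    traj: Trajectory3D,
    geometry: ApparatusGeometry = ApparatusGeometry(),
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Project a trajectory into per-frame image coordinates.

    Returns a table (frame_index, x_d, z_d, y_m, z_m) in full-frame pixel
    coordinates (direct view in the left half, mirror view in the right).
    Optional Gaussian jitter (``noise.jitter_px``) models centroid noise.
    """
    coords = _project_points(geometry, traj.x, traj.y, traj.z)
    coords.insert(0, "frame_index", traj.frame_index)
    if noise is not None and noise.jitter_px > 0:
        if rng is None:
            rng = np.random.default_rng()
        for c in ("x_d", "z_d", "y_m", "z_m"):
            coords[c] = coords[c] + rng.normal(0.0, noise.jitter_px, len(coords))
    return coords


# ---------------------------------------------------------------------------
# frame rendering
# ---------------------------------------------------------------------------


def _draw_blob(frame: np.ndarray, col: float, row: float, radius: float, contrast: float) -> None:
    """Darken an anti-aliased disk in place (soft 1-px edge for subpixel centroids)."""
    h, w = frame.shape
    r_out = int(math.ceil(radius)) + 2
    c0, c1 = int(math.floor(col)) - r_out, int(math.floor(col)) + r_out + 1
    r0, r1 = int(math.floor(row)) - r_out, int(math.floor(row)) + r_out + 1
    c0c, c1c = max(c0, 0), min(c1, w)
    r0c, r1c = max(r0, 0), min(r1, h)
    if c0c >= c1c or r0c >= r1c:
        return
    cols = np.arange(c0c, c1c)
    rows = np.arange(r0c, r1c)
    dist = np.hypot(cols[None, :] - col, rows[:, None] - row)
    coverage = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    patch = frame[r0c:r1c, c0c:c1c]
    patch -= contrast * coverage


def render_frames(
    projected: pd.DataFrame,
    geometry: ApparatusGeometry = ApparatusGeometry(),
    noise: NoiseModel = NoiseModel(),
    rng: np.random.Generator | None = None,
) -> FrameStack:
    """Render a frame stack from projected coordinates.

    Frame 0 is always seed-free (the background the detector subtracts);
    frames 1..max(frame_index) carry the seed blob in both halves when the
    seed is present in that frame.  Blobs falling (partly) outside the frame
    are clipped.
    """
    if rng is None:
        rng = np.random.default_rng()
    w, h = geometry.frame_size
    n_frames = int(projected["frame_index"].max()) + 1 if len(projected) else 1
    by_frame = {int(r.frame_index): r for r in projected.itertuples(index=False)}

    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    for idx in range(n_frames):
        frame = np.full((h, w), noise.background_level, dtype=np.float32)
        if noise.pixel_noise_sd > 0:
            frame += noise.pixel_noise_sd * rng.standard_normal((h, w), dtype=np.float32)
        row = by_frame.get(idx)
        if idx > 0 and row is not None and rng.random() >= noise.dropout_prob:
            _draw_blob(frame, row.x_d, row.z_d, noise.blob_radius_px, noise.contrast)
            _draw_blob(frame, row.y_m, row.z_m, noise.blob_radius_px, noise.contrast)
        frames[idx] = np.clip(frame, 0, 255).astype(np.uint8)
    return FrameStack(frames=frames, fps=geometry.fps)


# ---------------------------------------------------------------------------
# calibration design
# ---------------------------------------------------------------------------


def generate_calibration(
    geometry: ApparatusGeometry = ApparatusGeometry(),
    n_marks: tuple[int, int] = (7, 5),
    n_placements: tuple[int, int] = (5, 5),
    board_size: tuple[float, float] = (0.12, 0.28),
    parallel_span: float = 0.06,
    depth_span: float = 0.12,
    jitter_px: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Synthetic calibration table mimicking the grid-board protocol.

    A board parallel to the camera plane carries ``n_marks`` = (cols x rows)
    grid marks spanning ``board_size`` (m) in x and z.  It is photographed at
    ``n_placements`` = (parallel, perpendicular) positions: shifted parallel
    to the camera plane over ``parallel_span`` m, and placed at depths
    spanning ``depth_span`` m along the optical axis.  Default: 35 marks x 25
    placements = 875 observations covering the measurement volume — the full
    corridor height and the central horizontal column that seeds released
    through the 10-cm drop tube actually traverse, with margin.

    Returns a table with the canonical calibration columns; optional pixel
    jitter models mark-extraction noise.
    """
    mx, mz = n_marks
    px, py = n_placements

    mark_x = np.linspace(-board_size[0] / 2.0, board_size[0] / 2.0, mx)
    mark_z = geometry.z_center + np.linspace(-board_size[1] / 2.0, board_size[1] / 2.0, mz)
    offs_x = np.linspace(-parallel_span / 2.0, parallel_span / 2.0, px) if px > 1 else np.zeros(1)
    depth_y = np.linspace(-depth_span / 2.0, depth_span / 2.0, py) if py > 1 else np.zeros(1)

    X, Z, OX, DY = np.meshgrid(mark_x, mark_z, offs_x, depth_y, indexing="ij")
    x = (X + OX).ravel()
    y = np.broadcast_to(DY, X.shape).ravel().copy()
    z = Z.ravel()

    coords = _project_points(geometry, x, y, z)
    if jitter_px > 0:
        if rng is None:
            rng = np.random.default_rng()
        for c in ("x_d", "z_d", "y_m", "z_m"):
            coords[c] = coords[c] + rng.normal(0.0, jitter_px, len(coords))

    table = pd.DataFrame({"true_x": x, "true_y": y, "true_z": z})
    table = pd.concat([table, coords], axis=1)
    return table[CALIBRATION_COLUMNS]


# ---------------------------------------------------------------------------
# replicated Vt datasets
# ---------------------------------------------------------------------------


def simulate_vt_dataset(
    n_species: int = 5,
    n_seeds: int = 10,
    n_replicates: int = 4,
    var_species: float = 0.984,
    var_seed: float = 0.010,
    var_resid: float = 0.006,
    grand_mean_log: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Replicated terminal-velocity measurements with nested random effects.

    log Vt = grand mean + species effect + seed-within-species effect +
    residual, each Gaussian with the given variances (natural-log scale),
    then exponentiated.  The defaults match the study design the
    repeatability analysis targets: 5 species x 10 seeds x 4 replicate drops,
    with species differences dominating (variance fractions
    98.4 : 1.0 : 0.6 percent of a unit total log-variance).
    """
    if min(n_species, n_seeds, n_replicates) < 1:
        raise ValueError("design dimensions must be at least 1")
    if min(var_species, var_seed, var_resid) < 0:
        raise ValueError("variance components must be non-negative")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    rows = []
    for i in range(n_species):
        sp_eff = rng.normal(0.0, math.sqrt(var_species))
        for j in range(n_seeds):
            seed_eff = rng.normal(0.0, math.sqrt(var_seed))
            for k in range(n_replicates):
                logv = grand_mean_log + sp_eff + seed_eff + rng.normal(0.0, math.sqrt(var_resid))
                rows.append(
                    {
                        "species": f"sp{i + 1:02d}",
                        "seed": f"seed{j + 1:02d}",
                        "replicate": k + 1,
                        "Vt": math.exp(logv),
                    }
                )
    return pd.DataFrame(rows)
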