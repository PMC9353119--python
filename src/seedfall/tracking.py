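"""Cleaning of per-frame object tables into a single 3D seed trajectory.

The raw object table from detection contains the seed in both frame halves,
plus dust, reflections and artefacts at the corridor edges.  Four cleaning
steps isolate the seed:

1. drop objects whose centroid lies within ``edge_margin`` px of the frame
   bounds (edge artefacts from the corridor walls);
2. per frame and per half, keep only the largest-area object;
3. a frame holds a *putative seed* iff it has an object in both halves whose
   vertical (row) coordinates agree to within ``z_match_tol`` px — the two
   views see the same seed at the same height;
4. the longest run of consecutive putative-seed frames is the trajectory
   (earliest run wins ties).

The surviving (x_d, z_d, y_m, z_m) quadruples are then pushed through the
fitted conversion model to give the metric trajectory (t, x, y, z) with
t = frame_index / fps on the recording clock: the camera starts with the
release flap, so t = 0 is the moment the seed is dropped and v(0) = 0 is
physically meaningful for the fall-model fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import ConversionModel, image_to_world
from .detection import FrameObject

__all__ = [
    "CleaningConfig",
    "PairedObservations",
    "Trajectory3D",
    "clean_and_pair",
    "reconstruct",
]

TRAJECTORY_COLUMNS = ["frame_index", "t", "x", "y", "z"]


@dataclass(frozen=True)
class CleaningConfig:
    """Thresholds of the four-step cleaning.

    edge_margin : px; objects this close to a frame edge are discarded.
    z_match_tol : px; maximum |z_d - z_m| for the direct/mirror pair to count
        as one seed (inclusive).  The two views magnify differently (the
        mirror's optical path is longer), so the same seed's vertical
        coordinates legitimately diverge as it moves away from mid-height;
        the default covers that divergence over the whole corridor for the
        default geometry while still rejecting clutter at a different height.
    min_frames : shortest acceptable trajectory, in frames.
    frame_shape : (height, width) px of the frame, for the edge test.
    """

    edge_margin: float = 5.0
    z_match_tol: float = 280.0
    min_frames: int = 10
    frame_shape: tuple[int, int] = (1200, 1920)


@dataclass(frozen=True)
class PairedObservations:
    """Per-frame matched direct/mirror image coordinates for one seed run."""

    frame_index: np.ndarray  # consecutive ints
    x_d: np.ndarray
    z_d: np.ndarray
    y_m: np.ndarray
    z_m: np.ndarray


@dataclass(frozen=True)
class Trajectory3D:
    """Reconstructed metric trajectory: t (s), x, y, z (m) per retained frame."""

    frame_index: np.ndarray
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_index": self.frame_index,
                "t": self.t,
                "x": self.x,
                "y": self.y,
                "z": self.z,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory3D":
        df = pd.read_csv(path)
        missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trajectory table is missing columns {missing}")
        return cls(
            frame_index=df["frame_index"].to_numpy(int),
            t=df["t"].to_numpy(float),
            x=df["x"].to_numpy(float),
            y=df["y"].to_numpy(float),
            z=df["z"].to_numpy(float),
        )


def clean_and_pair(
    objects: Sequence[FrameObject], config: CleaningConfig = CleaningConfig()
) -> PairedObservations:
    """Apply the four cleaning steps; return matched per-frame coordinates.

    Raises ``ValueError`` if no putative-seed frame exists or the longest run
    is shorter than ``config.min_frames``.
    """
    H, W = config.frame_shape
    m = config.edge_margin

    # step 1: edge removal
    kept = [
        o
        for o in objects
        if m <= o.col < W - m and m <= o.row < H - m
    ]

    # step 2: largest object per (frame, half); ties -> first in input order
    best: dict[tuple[int, str], FrameObject] = {}
    for o in kept:
        key = (o.frame_index, o.half)
        if key not in best or o.area > best[key].area:
            best[key] = o

    # step 3: direct/mirror vertical agreement (inclusive tolerance)
    putative: dict[int, tuple[FrameObject, FrameObject]] = {}
    for fi in sorted({k[0] for k in best}):
        d = best.get((fi, "direct"))
        mi = best.get((fi, "mirror"))
        if d is not None and mi is not None and abs(d.row - mi.row) <= config.z_match_tol:
            putative[fi] = (d, mi)

    if not putative:
        raise ValueError("no trajectory found: no frame contains a matched direct/mirror pair")

    # step 4: longest consecutive run, earliest on ties
    frames = sorted(putative)
    best_start = best_len = 0
    start = 0
    for i in range(1, len(frames) + 1):
        if i == len(frames) or frames[i] != frames[i - 1] + 1:
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = i
    run = frames[best_start : best_start + best_len]

    if best_len < config.min_frames:
        raise ValueError(
            f"trajectory too short to fit: longest run has {best_len} frames "
            f"(< {config.min_frames})"
        )

    d_objs = [putative[f][0] for f in run]
    m_objs = [putative[f][1] for f in run]
    return PairedObservations(
        frame_index=np.asarray(run, dtype=int),
        x_d=np.asarray([o.col for o in d_objs]),
        z_d=np.asarray([o.row for o in d_objs]),
        y_m=np.asarray([o.col for o in m_objs]),
        z_m=np.asarray([o.row for o in m_objs]),
    )


def reconstruct(
    paired: PairedObservations, model: ConversionModel, fps: float
) -> Trajectory3D:
    """Convert paired image coordinates to a metric 3D trajectory.

    Time is the recording clock: t = frame_index / fps, frame 0 at flap
    opening.  The conversion model supplies metric x, y, z per frame.
    """
    if not fps > 0:
        raise ValueError("fps must be positive")
    x, y, z, _ = image_to_world(model, paired.x_d, paired.z_d, paired.y_m, paired.z_m)
    t = paired.frame_index / fps
    return Trajectory3D(frame_index=paired.frame_index.copy(), t=t, x=x, y=y, z=z)
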