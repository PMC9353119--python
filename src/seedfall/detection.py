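"""Object detection in backlit frame stacks.

The apparatus films a dark seed against a bright, backlit background.  The
analysis mirrors the classic ImageJ recipe in four steps:

1. invert every frame (seed becomes bright on dark);
2. subtract the first, seed-free frame (removes the static background);
3. binarise the differential image at a fixed absolute threshold;
4. for every connected component above a minimum size, measure the centroid,
   area and circularity (4*pi*area / perimeter^2, ImageJ convention with the
   Crofton perimeter estimate, clamped to 1).

Each detected object is assigned to the *direct* or *mirror* half of the
frame by a configured vertical split column, since both views of the seed
share one sensor.

The canonical input is a directory of PNG/TIFF frames in lexicographic
(= temporal) order plus a frame rate; this keeps the core free of video
codec dependencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import regionprops

__all__ = [
    "FrameStack",
    "FrameObject",
    "DetectionConfig",
    "detect_objects",
    "objects_to_table",
    "table_to_objects",
    "load_frame_stack",
]

OBJECT_COLUMNS = ["frame_index", "half", "col", "row", "area", "circularity"]


@dataclass
class FrameStack:
    """An ordered stack of same-shape grayscale frames with a frame rate.

    ``frames`` is a (n_frames, H, W) uint8 array (intensities 0-255);
    ``fps`` the recording rate in frames per second.  Frame index 0 is the
    start of recording (the flap opening), which anchors the time origin of
    the trajectory fit.
    """

    frames: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be a (n, H, W) stack, got shape {self.frames.shape}")
        if not self.fps > 0:
            raise ValueError("fps must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class FrameObject:
    """One detected object in one half of one frame."""

    frame_index: int
    half: str  # "direct" | "mirror"
    col: float
    row: float
    area: float  # px^2
    circularity: float  # in (0, 1]


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds of the four-step detection.

    threshold : absolute binarisation level on the background-subtracted
        image (0-255 scale).  The original ImageJ workflow leaves this to
        ImageJ defaults; here it is explicit.
    min_size : smallest reported component area in px^2.
    split_col : column separating the direct (left) from the mirror (right)
        half of the frame; ``None`` means the frame midline.
    """

    threshold: float = 25.0
    min_size: float = 10.0
    split_col: float | None = None


def detect_objects(stack: FrameStack, config: DetectionConfig = DetectionConfig()) -> list[FrameObject]:
    """Run the four-step detection over a frame stack.

    The first frame must be seed-free: it is the background that step 2
    subtracts.  Returns one :class:`FrameObject` per above-threshold
    connected component (8-connectivity) per frame, for frames 1..n-1.
    """
    if len(stack) < 2:
        raise ValueError("frame stack needs at least 2 frames (background + data)")
    split = config.split_col if config.split_col is not None else stack.shape[1] / 2.0

    # steps 1-2 combined: (255 - frame) - (255 - background) = background - frame
    background = stack.frames[0].astype(np.int16)
    structure = np.ones((3, 3), dtype=int)  # 8-connectivity

    objects: list[FrameObject] = []
    for idx in range(1, len(stack)):
        diff = background - stack.frames[idx].astype(np.int16)
        binary = diff > config.threshold
        labels, n = ndimage.label(binary, structure=structure)
        if n == 0:
            continue
        for prop in regionprops(labels):
            if prop.area < config.min_size:
                continue
            row, col = prop.centroid
            perim = prop.perimeter_crofton
            circ = 4.0 * np.pi * prop.area / perim**2 if perim > 0 else 1.0
            objects.append(
                FrameObject(
                    frame_index=idx,
                    half="direct" if col < split else "mirror",
                    col=float(col),
                    row=float(row),
                    area=float(prop.area),
                    circularity=float(min(circ, 1.0)),
                )
            )

    _warn_if_background_contaminated(stack, config, structure)
    return objects


def _warn_if_background_contaminated(
    stack: FrameStack, config: DetectionConfig, structure: np.ndarray
) -> None:
    """Warn when the supposed seed-free background frame itself contains objects.

    Detected by thresholding the background against the stack's median frame;
    an object there silently corrupts every differential image.
    """
    if len(stack) < 3:
        return
    # median over a handful of sampled frames is enough to expose a static
    # object in the background frame without touching the whole stack
    sample_idx = np.unique(np.linspace(1, len(stack) - 1, 5).astype(int))
    median = np.median(stack.frames[sample_idx].astype(np.int16), axis=0)
    diff = median - stack.frames[0].astype(np.int16)
    labels, n = ndimage.label(diff > config.threshold, structure=structure)
    if n == 0:
        return
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    if np.any(np.asarray(areas) >= config.min_size):
        warnings.warn(
            "background (first) frame appears to contain an object above the "
            "size threshold; detections may be corrupted",
            stacklevel=3,
        )


def objects_to_table(objects: Iterable[FrameObject]) -> pd.DataFrame:
    """Object list -> tidy table (frame_index, half, col, row, area, circularity)."""
    rows = [vars(o) for o in objects]
    if not rows:
        return pd.DataFrame(columns=OBJECT_COLUMNS)
    return pd.DataFrame(rows)[OBJECT_COLUMNS]


def table_to_objects(table: pd.DataFrame) -> list[FrameObject]:
    return [
        FrameObject(
            frame_index=int(r.frame_index),
            half=str(r.half),
            col=float(r.col),
            row=float(r.row),
            area=float(r.area),
            circularity=float(r.circularity),
        )
        for r in table.itertuples(index=False)
    ]


def load_frame_stack(directory: str | Path, fps: float, pattern: str = "*.png") -> FrameStack:
    """Load a directory of image frames (lexicographic order = time order)."""
    import imageio.v3 as iio

    paths = sorted(Path(directory).glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no frames matching {pattern!r} in {directory}")
    frames = np.stack([np.asarray(iio.imread(p)) for p in paths])
    if frames.ndim == 4:  # RGB(A) -> grayscale by channel mean
        frames = frames[..., :3].mean(axis=-1).astype(np.uint8)
    return FrameStack(frames=frames, fps=fps)
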