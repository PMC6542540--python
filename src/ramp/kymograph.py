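"""Kymographs from path-straightened movies and segment speed measurement.

A 1-px-wide (or width-averaged) line is traced from the soma toward an axon
or dendrite tip, each frame is resampled along that path at unit arc-length
steps (bilinear interpolation), and the per-frame lines are stacked into a
distance × time image — the kymograph. Moving particles appear as sloped
streaks: with the soma at column 0, motion toward the tip (increasing
distance) is anterograde and motion toward the soma retrograde. Speeds come
from user- or generator-annotated segment endpoints, exactly as manual
kymograph reading does: |Δdistance| in μm over Δtime in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from ramp.core_io import Image, ImageStack

__all__ = [
    "Kymograph",
    "TrackSegment",
    "straighten",
    "build_kymograph",
    "segment_speed",
]

#: Below this absolute speed (μm/s) a segment counts as a stationary focus.
STATIONARY_THRESHOLD_UM_S = 0.05


@dataclass(frozen=True)
class Kymograph:
    """Time (rows) × path distance (cols) intensity; soma end at column 0."""

    array: np.ndarray
    pixel_size: float  # μm per path step (= 1 px of the source image)
    frame_interval: float  # s

    def __post_init__(self) -> None:
        arr = np.asarray(self.array, dtype=float)
        if arr.ndim != 2:
            raise ValueError("kymograph must be 2-D")
        object.__setattr__(self, "array", arr)

    @property
    def n_frames(self) -> int:
        return self.array.shape[0]

    @property
    def path_length_px(self) -> int:
        return self.array.shape[1]


@dataclass(frozen=True)
class TrackSegment:
    """One annotated line on a kymograph converted to physical units."""

    t0: float  # s
    d0: float  # μm
    t1: float
    d1: float
    direction: Literal["anterograde", "retrograde", "stationary"]
    speed: float  # μm/s

    def __post_init__(self) -> None:
        if not self.t1 > self.t0:
            raise ValueError("t1 must be after t0")
        if self.speed < 0:
            raise ValueError("speed must be >= 0")


def _resample_path(polyline: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-arc-length sample points and unit normals along a polyline."""
    pts = np.atleast_2d(np.asarray(polyline, dtype=float))
    if pts.shape[0] < 2:
        raise ValueError("polyline needs at least 2 points")
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    if seg_len.sum() == 0:
        raise ValueError("zero-length path")
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = arc[-1]
    n_steps = int(math.ceil(total)) + 1
    s = np.linspace(0.0, total, n_steps)
    rows = np.interp(s, arc, pts[:, 0])
    cols = np.interp(s, arc, pts[:, 1])
    # tangents by central differences → normals for width averaging
    dr = np.gradient(rows)
    dc = np.gradient(cols)
    norm = np.hypot(dr, dc)
    norm[norm == 0] = 1.0
    normals = np.column_stack([-dc / norm, dr / norm])
    return np.column_stack([rows, cols]), normals


def straighten(
    stack: ImageStack,
    polyline: Sequence[Sequence[float]],
    width_px: int = 1,
) -> np.ndarray:
    """Resample each frame along the path at unit arc-length steps.

    Intensity is bilinearly interpolated; for ``width_px`` > 1 the value at
    each step is the mean over perpendicular offsets spanning the width.
    Returns an array of shape (n_frames, path_length_px).
    """
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    centers, normals = _resample_path(np.asarray(polyline, dtype=float))
    h, w = stack.shape
    if (
        centers[:, 0].min() < -0.5
        or centers[:, 0].max() > h - 0.5
        or centers[:, 1].min() < -0.5
        or centers[:, 1].max() > w - 0.5
    ):
        raise ValueError("polyline outside image bounds")
    offsets = np.arange(width_px) - (width_px - 1) / 2.0
    out = np.empty((len(stack), centers.shape[0]))
    for k, frame in enumerate(stack.frames):
        acc = np.zeros(centers.shape[0])
        for off in offsets:
            coords = centers + off * normals
            acc += ndimage.map_coordinates(
                frame.pixels, [coords[:, 0], coords[:, 1]], order=1, mode="nearest"
            )
        out[k] = acc / width_px
    return out


def build_kymograph(
    straightened: np.ndarray,
    pixel_size: float,
    frame_interval: float,
) -> Kymograph:
    """Stack straightened lines into a time × distance image.

    Row k is the width-averaged line of frame k; the distance axis runs
    soma → tip, inherited from the polyline orientation.
    """
    arr = np.asarray(straightened, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need a straightened stack with at least 2 frames")
    return Kymograph(arr, pixel_size, frame_interval)


def segment_speed(
    t0_frame: float,
    d0_px: float,
    t1_frame: float,
    d1_px: float,
    pixel_size: float,
    frame_interval: float,
    stationary_threshold: float = STATIONARY_THRESHOLD_UM_S,
) -> TrackSegment:
    """Speed and direction of one annotated kymograph segment.

    speed = |Δd|·pixel_size / (Δframes·frame_interval); direction follows
    the slope sign (toward the tip, i.e. increasing distance, = anterograde)
    unless |speed| falls below ``stationary_threshold``.
    """
    if not t1_frame > t0_frame:
        raise ValueError("segment must move forward in time")
    dt = (t1_frame - t0_frame) * frame_interval
    dd_um = (d1_px - d0_px) * pixel_size
    speed = abs(dd_um) / dt
    if speed < stationary_threshold:
        direction = "stationary"
        speed_out = speed
    elif dd_um > 0:
        direction = "anterograde"
        speed_out = speed
    else:
        direction = "retrograde"
        speed_out = speed
    return TrackSegment(
        t0=t0_frame * frame_interval,
        d0=d0_px * pixel_size,
        t1=t1_frame * frame_interval,
        d1=d1_px * pixel_size,
        direction=direction,
        speed=speed_out,
    )
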