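"""Core containers and I/O: images, stacks, cell geometry, TIFF and config.

Conventions used package-wide:

- Coordinates are 0-based ``(row, col)`` and pixel-centered; all distances are
  measured between pixel centers.
- ``pixel_size`` (μm/px) and ``frame_interval`` (s) are carried on the
  containers and come from a sidecar config rather than TIFF tags, because
  acquisition-metadata dialects vary between microscopes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import tifffile
import yaml
from scipy import ndimage

__all__ = [
    "Image",
    "ImageStack",
    "CellGeometry",
    "read_stack",
    "write_stack",
    "read_mask",
    "max_project",
    "apply_mask",
    "load_config",
]


@dataclass(frozen=True)
class Image:
    """A single-channel fluorescence image.

    Parameters
    ----------
    pixels : ndarray
        2-D grid of finite, nonnegative intensities.
    pixel_size : float
        Physical size of one pixel in μm. Must be positive.
    """

    pixels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels must be finite")
        if np.any(px < 0):
            raise ValueError("pixels must be nonnegative")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def total_intensity(self) -> float:
        return float(self.pixels.sum())


@dataclass(frozen=True)
class ImageStack:
    """An ordered time series of same-shape images.

    ``frame_interval`` is the time between consecutive frames in seconds.
    """

    frames: tuple[Image, ...]
    frame_interval: float = 60.0

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        if len(frames) == 0:
            raise ValueError("stack needs at least one frame")
        shape = frames[0].shape
        psz = frames[0].pixel_size
        for f in frames:
            if f.shape != shape:
                raise ValueError(f"frame shape {f.shape} != {shape}")
            if f.pixel_size != psz:
                raise ValueError("frames disagree on pixel_size")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> Image:
        return self.frames[i]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    @property
    def pixel_size(self) -> float:
        return self.frames[0].pixel_size

    def times_minutes(self) -> np.ndarray:
        """Frame acquisition times in minutes, frame 0 at t = 0."""
        return np.arange(len(self)) * self.frame_interval / 60.0

    def as_array(self) -> np.ndarray:
        return np.stack([f.pixels for f in self.frames])


@dataclass(frozen=True)
class CellGeometry:
    """Per-cell geometry anchoring the normalized radial coordinate.

    ``center`` is the nucleus center in ``(row, col)`` pixels; ``r_max`` is
    the distance from the center to the farthest mask pixel, so that
    normalized radius = distance / r_max maps the cell border to 1.
    """

    center: tuple[float, float]
    cell_mask: np.ndarray
    r_max: float = field(default=0.0)

    def __post_init__(self) -> None:
        mask = np.asarray(self.cell_mask, dtype=bool)
        if mask.ndim != 2 or not mask.any():
            raise ValueError("cell_mask must be a nonempty 2-D boolean grid")
        _, n_comp = ndimage.label(mask)
        if n_comp != 1:
            raise ValueError(f"cell_mask must be one connected component, got {n_comp}")
        r, c = self.center
        ri, ci = int(round(r)), int(round(c))
        if not (0 <= ri < mask.shape[0] and 0 <= ci < mask.shape[1]) or not mask[ri, ci]:
            raise ValueError("center must lie inside cell_mask")
        object.__setattr__(self, "cell_mask", mask)
        if self.r_max <= 0:  # compute from the mask unless the caller overrides
            object.__setattr__(self, "r_max", self._mask_r_max())
        elif not self.r_max > 0:
            raise ValueError("r_max must be > 0")

    def _mask_r_max(self) -> float:
        rows, cols = np.nonzero(self.cell_mask)
        d = np.hypot(rows - self.center[0], cols - self.center[1])
        return float(d.max())

    def radii(self) -> np.ndarray:
        """Center-to-pixel distance (px) for the whole grid."""
        rr, cc = np.indices(self.cell_mask.shape)
        return np.hypot(rr - self.center[0], cc - self.center[1])


# ---------------------------------------------------------------------------
# TIFF I/O


def read_stack(
    path: str | Path,
    pixel_size: float = 1.0,
    frame_interval: float = 60.0,
) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF as an :class:`ImageStack`.

    Pages are kept in storage order. ``pixel_size`` and ``frame_interval``
    are supplied by the caller (typically from config) because they are not
    parsed from TIFF tags.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        shapes = {p.shape for p in tf.pages}
        if len(shapes) > 1:
            raise ValueError(f"TIFF pages have ragged shapes: {sorted(shapes)}")
        data = tf.asarray()
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"expected a 2-D or 3-D grayscale TIFF, got shape {data.shape}")
    if data.shape[0] == 0:
        raise ValueError("TIFF has zero pages")
    frames = tuple(Image(np.asarray(p, dtype=float), pixel_size) for p in data)
    return ImageStack(frames, frame_interval)


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a stack as a multi-page float32 TIFF (lossless for our data)."""
    tifffile.imwrite(Path(path), stack.as_array().astype(np.float32))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a cell mask from TIFF or PNG; any nonzero pixel is inside."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        data = tifffile.imread(path)
    else:
        from imageio.v3 import imread

        data = imread(path)
    if data.ndim == 3:  # RGB(A) PNG → any channel nonzero
        data = data.max(axis=-1)
    return np.asarray(data) != 0


# ---------------------------------------------------------------------------
# Operations


def max_project(zstack: ImageStack) -> Image:
    """Maximum-intensity projection over the stack axis."""
    return Image(zstack.as_array().max(axis=0), zstack.pixel_size)


def apply_mask(image: Image, geometry: CellGeometry) -> Image:
    """Zero all intensity outside the cell mask (isolates one cell)."""
    if image.shape != geometry.cell_mask.shape:
        raise ValueError(
            f"image shape {image.shape} != mask shape {geometry.cell_mask.shape}"
        )
    return Image(np.where(geometry.cell_mask, image.pixels, 0.0), image.pixel_size)


# ---------------------------------------------------------------------------
# Config

_CONFIG_DEFAULTS: dict = {
    "pixel_size_um": 1.0,
    "frame_interval_s": 60.0,
    "nucleus_center": None,  # (row, col) in px
    "f_grid": [round(f, 2) for f in np.arange(0.05, 1.0001, 0.05)],
    "seed": 0,
}


def load_config(path: str | Path | None = None, **overrides) -> dict:
    """Load a YAML/JSON analysis config, filling defaults for absent keys.

    Recognized keys: ``pixel_size_um``, ``frame_interval_s``,
    ``nucleus_center``, ``f_grid``, ``seed``. Unknown keys raise, catching
    typos early.
    """
    cfg = dict(_CONFIG_DEFAULTS)
    if path is not None:
        path = Path(path)
        text = path.read_text()
        loaded = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        unknown = set(loaded) - set(_CONFIG_DEFAULTS)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(loaded)
    unknown = set(overrides) - set(_CONFIG_DEFAULTS)
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(overrides)
    if not cfg["pixel_size_um"] > 0:
        raise ValueError("pixel_size_um must be > 0")
    if not cfg["frame_interval_s"] > 0:
        raise ValueError("frame_interval_s must be > 0")
    fg = np.asarray(cfg["f_grid"], dtype=float)
    if fg.size == 0 or np.any(fg <= 0) or np.any(fg > 1):
        raise ValueError("f_grid values must lie in (0, 1]")
    return cfg
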