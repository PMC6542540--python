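"""Synthetic microscopy data with known ground truth.

Generates the inputs every analysis stage needs: cell geometries with a
nucleus, point-like organelle fields drawn from known radial distributions,
recovery movies that relax exponentially between two distributions, movies of
particles translating at constant speed, and populations of round or
elongated binary shapes.

Radial mixture families (normalized radius r = distance / r_max in [0, 1]):

- ``perinuclear``: Beta(1, c) — density monotonically decreasing in r,
  mimicking organelles clustered around the nucleus;
- ``peripheral``: Beta(c, 1) — density increasing in r, mimicking clustering
  at the cell border;
- ``uniform``: area-uniform over the mask (radial CDF r² on a disk).

The concentration parameter c sharpens clustering. All generators are pure
functions of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage.draw import disk as draw_disk

from ramp.core_io import CellGeometry, Image, ImageStack

__all__ = [
    "MixtureComponent",
    "DistributionSpec",
    "PointSet",
    "make_geometry",
    "sample_positions",
    "render_image",
    "make_recovery_movie",
    "make_motion_movie",
    "make_shape_population",
    "PERIPHERAL",
    "PERINUCLEAR",
    "STEADY_STATE",
]

ComponentKind = Literal["perinuclear", "peripheral", "uniform"]


@dataclass(frozen=True)
class MixtureComponent:
    kind: ComponentKind
    weight: float
    concentration: float = 4.0

    def __post_init__(self) -> None:
        if self.kind not in ("perinuclear", "peripheral", "uniform"):
            raise ValueError(f"unknown component kind {self.kind!r}")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")

    def radial_cdf(self, r: np.ndarray) -> np.ndarray:
        """Analytic CDF of the normalized radius for this component."""
        r = np.asarray(r, dtype=float)
        if self.kind == "perinuclear":
            return stats.beta.cdf(r, 1.0, self.concentration)
        if self.kind == "peripheral":
            return stats.beta.cdf(r, self.concentration, 1.0)
        return np.clip(r, 0, 1) ** 2  # area-uniform

    def sample_radii(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "perinuclear":
            return rng.beta(1.0, self.concentration, size=n)
        if self.kind == "peripheral":
            return rng.beta(self.concentration, 1.0, size=n)
        return np.sqrt(rng.random(n))


@dataclass(frozen=True)
class DistributionSpec:
    """Recipe for one synthetic organelle field."""

    components: tuple[MixtureComponent, ...]
    n_organelles: int = 300
    intensity_per_organelle: float = 1000.0
    psf_sigma: float = 2.0
    poisson_scale: float = 0.0  # 0 disables shot noise
    gaussian_sd: float = 0.0  # additive read noise, 0 disables

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        if not comps:
            raise ValueError("spec needs at least one component")
        total = sum(c.weight for c in comps)
        if not math.isclose(total, 1.0, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError(f"component weights must sum to 1, got {total}")
        if self.n_organelles < 0:
            raise ValueError("n_organelles must be >= 0")
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be >= 0")
        object.__setattr__(self, "components", comps)

    def radial_cdf(self, r: np.ndarray) -> np.ndarray:
        out = np.zeros_like(np.asarray(r, dtype=float))
        for c in self.components:
            out = out + c.weight * c.radial_cdf(r)
        return out

    def with_weights(self, weights: Sequence[float]) -> "DistributionSpec":
        comps = tuple(
            MixtureComponent(c.kind, w, c.concentration)
            for c, w in zip(self.components, weights)
        )
        return DistributionSpec(
            comps,
            self.n_organelles,
            self.intensity_per_organelle,
            self.psf_sigma,
            self.poisson_scale,
            self.gaussian_sd,
        )


def _single(kind: ComponentKind, concentration: float = 4.0) -> DistributionSpec:
    return DistributionSpec((MixtureComponent(kind, 1.0, concentration),))


#: Tight accumulation at the cell border (motor-driven peripheral clustering).
PERIPHERAL = _single("peripheral", 8.0)
#: Clustering around the nucleus: the cluster rings the nucleus rather than
#: collapsing to the geometric center, so the radial density is broader than
#: the peripheral case (median normalized radius ≈ 0.3).
PERINUCLEAR = _single("perinuclear", 2.0)
#: Default steady-state: mostly perinuclear with a diffuse uniform pool.
STEADY_STATE = DistributionSpec(
    (
        MixtureComponent("perinuclear", 0.6, 2.0),
        MixtureComponent("uniform", 0.4),
    )
)


@dataclass(frozen=True)
class PointSet:
    """Organelle positions inside a cell mask with their normalized radii."""

    positions: np.ndarray  # (n, 2) float (row, col)
    normalized_radii: np.ndarray  # (n,) in [0, 1]

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if pos.size == 0:
            pos = pos.reshape(0, 2)
        nr = np.asarray(self.normalized_radii, dtype=float)
        if pos.shape[0] != nr.shape[0]:
            raise ValueError("positions and normalized_radii disagree in length")
        if nr.size and (nr.min() < 0 or nr.max() > 1):
            raise ValueError("normalized radii must lie in [0, 1]")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "normalized_radii", nr)

    def __len__(self) -> int:
        return self.positions.shape[0]


# ---------------------------------------------------------------------------
# Geometry


def make_geometry(
    shape: Literal["circle", "ellipse", "blob"] = "circle",
    cell_radius: float = 100.0,
    nucleus_radius: float = 20.0,
    seed: int = 0,
    aspect: float = 0.5,
    pad: int = 4,
) -> CellGeometry:
    """Build a synthetic cell mask with the nucleus at its center.

    ``circle`` gives a disk of radius ``cell_radius``; ``ellipse`` an ellipse
    with semi-axes (cell_radius, aspect·cell_radius); ``blob`` a smooth
    star-convex outline whose radius fluctuates around ``cell_radius`` (seeded
    low-order Fourier modes). The nucleus is only an annotation (its center);
    the mask covers the whole cell including the nucleus.
    """
    if not 0 < nucleus_radius < cell_radius:
        raise ValueError("need 0 < nucleus_radius < cell_radius")
    n = int(math.ceil(cell_radius)) + pad
    size = 2 * n + 1
    center = (float(n), float(n))
    rr, cc = np.indices((size, size))
    dy, dx = rr - n, cc - n
    if shape == "circle":
        mask = dy**2 + dx**2 <= cell_radius**2
    elif shape == "ellipse":
        mask = (dy / (aspect * cell_radius)) ** 2 + (dx / cell_radius) ** 2 <= 1.0
    elif shape == "blob":
        rng = np.random.default_rng(seed)
        n_modes = 4
        amp = rng.uniform(-0.12, 0.12, size=n_modes)
        phase = rng.uniform(0, 2 * np.pi, size=n_modes)
        theta = np.arctan2(dy, dx)
        wobble = sum(
            a * np.cos((k + 2) * theta + p) for k, (a, p) in enumerate(zip(amp, phase))
        )
        radius = cell_radius * (1.0 + wobble) * (1.0 - pad / (2.0 * size))
        mask = np.hypot(dy, dx) <= radius
    else:
        raise ValueError(f"unknown shape {shape!r}")
    return CellGeometry(center=center, cell_mask=mask)


# ---------------------------------------------------------------------------
# Point sampling and rendering


def sample_positions(
    geometry: CellGeometry,
    spec: DistributionSpec,
    seed: int = 0,
    max_tries: int = 200,
) -> PointSet:
    """Draw organelle positions from the spec's radial mixture, inside the mask.

    Radii follow the mixture's analytic distribution; angles are uniform.
    Points falling outside the mask (non-circular geometries, discretization
    at the border) are rejected and redrawn, so for non-circular masks the
    realized radial law is the mixture conditioned on mask membership.
    """
    n = spec.n_organelles
    if n == 0:
        return PointSet(np.empty((0, 2)), np.empty(0))
    rng = np.random.default_rng(seed)
    weights = np.array([c.weight for c in spec.components])
    mask = geometry.cell_mask
    cy, cx = geometry.center
    accepted_pos: list[np.ndarray] = []
    accepted_r: list[np.ndarray] = []
    remaining = n
    tries = 0
    while remaining > 0:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n} points in the mask after {max_tries} rounds"
            )
        tries += 1
        comp_idx = rng.choice(len(weights), size=remaining, p=weights)
        radii = np.empty(remaining)
        for i, comp in enumerate(spec.components):
            sel = comp_idx == i
            if sel.any():
                radii[sel] = comp.sample_radii(int(sel.sum()), rng)
        theta = rng.uniform(0, 2 * np.pi, size=remaining)
        rows = cy + radii * geometry.r_max * np.sin(theta)
        cols = cx + radii * geometry.r_max * np.cos(theta)
        ri = np.clip(np.round(rows).astype(int), 0, mask.shape[0] - 1)
        ci = np.clip(np.round(cols).astype(int), 0, mask.shape[1] - 1)
        inside = mask[ri, ci] & (radii <= 1.0)
        accepted_pos.append(np.column_stack([rows[inside], cols[inside]]))
        accepted_r.append(radii[inside])
        remaining -= int(inside.sum())
    positions = np.concatenate(accepted_pos)[:n]
    radii = np.concatenate(accepted_r)[:n]
    return PointSet(positions, radii)


def _stamp_gaussian(
    canvas: np.ndarray, row: float, col: float, total: float, sigma: float
) -> None:
    """Deposit an integrated 2-D Gaussian spot (exact per-pixel integrals)."""
    if sigma == 0:
        r = min(max(int(round(row)), 0), canvas.shape[0] - 1)
        c = min(max(int(round(col)), 0), canvas.shape[1] - 1)
        canvas[r, c] += total
        return
    half = int(math.ceil(4 * sigma)) + 1
    r0 = max(int(math.floor(row)) - half, 0)
    r1 = min(int(math.floor(row)) + half + 1, canvas.shape[0])
    c0 = max(int(math.floor(col)) - half, 0)
    c1 = min(int(math.floor(col)) + half + 1, canvas.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    # pixel i covers [i-0.5, i+0.5); integrate the Gaussian over each pixel
    edges_r = np.arange(r0, r1 + 1) - 0.5
    edges_c = np.arange(c0, c1 + 1) - 0.5
    cdf_r = stats.norm.cdf(edges_r, loc=row, scale=sigma)
    cdf_c = stats.norm.cdf(edges_c, loc=col, scale=sigma)
    canvas[r0:r1, c0:c1] += total * np.outer(np.diff(cdf_r), np.diff(cdf_c))


def render_image(
    points: PointSet,
    geometry: CellGeometry,
    spec: DistributionSpec,
    seed: int = 0,
    pixel_size: float = 1.0,
) -> Image:
    """Render a point field as a diffraction-blurred, optionally noisy image.

    Each point deposits ``intensity_per_organelle`` total counts as a Gaussian
    spot of width ``psf_sigma``. Shot noise (Poisson on photon counts scaled
    by ``poisson_scale``) and additive Gaussian read noise follow; everything
    outside the cell mask is zeroed.
    """
    canvas = np.zeros(geometry.cell_mask.shape)
    for (r, c) in points.positions:
        _stamp_gaussian(canvas, r, c, spec.intensity_per_organelle, spec.psf_sigma)
    rng = np.random.default_rng(seed)
    if spec.poisson_scale > 0:
        canvas = rng.poisson(canvas * spec.poisson_scale) / spec.poisson_scale
    if spec.gaussian_sd > 0:
        canvas = canvas + rng.normal(0, spec.gaussian_sd, size=canvas.shape)
    canvas = np.clip(canvas, 0, None)
    canvas[~geometry.cell_mask] = 0.0
    return Image(canvas, pixel_size)


# ---------------------------------------------------------------------------
# Movies


def make_recovery_movie(
    spec_start: DistributionSpec,
    spec_end: DistributionSpec,
    tau_min: float,
    times: Sequence[float],
    geometry: CellGeometry,
    seed: int = 0,
    pixel_size: float = 1.0,
) -> ImageStack:
    """Movie of an organelle field relaxing exponentially between two states.

    At time t (minutes) the field is a mixture with weight exp(−t/τ) on
    ``spec_start`` and 1 − exp(−t/τ) on ``spec_end``; positions are sampled
    fresh each frame (the downstream statistic is distributional, so no
    per-organelle tracking is needed). ``times`` must be evenly spaced so the
    result maps onto a fixed frame interval.
    """
    if not tau_min > 0:
        raise ValueError("tau_min must be > 0")
    times = np.asarray(times, dtype=float)
    if times.size < 1 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if times.size > 1:
        dts = np.diff(times)
        if not np.allclose(dts, dts[0]):
            raise ValueError("times must be evenly spaced")
        frame_interval = float(dts[0]) * 60.0
    else:
        frame_interval = 60.0
    ss = np.random.SeedSequence(seed)
    frame_seeds = ss.generate_state(2 * times.size)
    frames = []
    for k, t in enumerate(times):
        w = math.exp(-t / tau_min)
        comps = tuple(
            MixtureComponent(c.kind, c.weight * w, c.concentration)
            for c in spec_start.components
        ) + tuple(
            MixtureComponent(c.kind, c.weight * (1.0 - w), c.concentration)
            for c in spec_end.components
        )
        mixed = DistributionSpec(
            comps,
            spec_start.n_organelles,
            spec_start.intensity_per_organelle,
            spec_start.psf_sigma,
            spec_start.poisson_scale,
            spec_start.gaussian_sd,
        )
        pts = sample_positions(geometry, mixed, seed=int(frame_seeds[2 * k]))
        frames.append(
            render_image(pts, geometry, mixed, seed=int(frame_seeds[2 * k + 1]), pixel_size=pixel_size)
        )
    return ImageStack(tuple(frames), frame_interval)


def make_motion_movie(
    speeds: float | Sequence[float],
    path_length: float,
    pixel_size: float,
    frame_interval: float,
    n_frames: int,
    seed: int = 0,
    psf_sigma: float = 1.5,
    intensity: float = 1000.0,
    height: int = 15,
) -> tuple[ImageStack, pd.DataFrame]:
    """Movie of point particles translating along a straight horizontal path.

    ``speeds`` is one signed speed (μm/s) or a sequence, one spot per entry;
    positive moves toward increasing column (away from the origin at column
    0), negative toward it. Spots start at the end of the path they move away
    from. Returns the stack and a ground-truth table with one row per spot
    and frame (spot, frame, time_s, distance_um, col_px) plus a ``truncated``
    column flagging spots that leave the field before the last frame.
    """
    speeds_arr = np.atleast_1d(np.asarray(speeds, dtype=float))
    n_cols = int(math.ceil(path_length / pixel_size)) + 1
    row = height / 2.0
    records = []
    frames = []
    for k in range(n_frames):
        canvas = np.zeros((height, n_cols))
        t = k * frame_interval
        for s_idx, v in enumerate(speeds_arr):
            start_um = 0.0 if v >= 0 else path_length
            d_um = start_um + v * t
            col = d_um / pixel_size
            on_path = 0 <= d_um <= path_length
            if on_path:
                _stamp_gaussian(canvas, row, col, intensity, psf_sigma)
            records.append(
                dict(
                    spot=s_idx,
                    frame=k,
                    time_s=t,
                    distance_um=d_um,
                    col_px=col,
                    on_path=on_path,
                )
            )
        frames.append(Image(canvas, pixel_size))
    truth = pd.DataFrame.from_records(records)
    truncated = ~truth.groupby("spot")["on_path"].all()
    truth["truncated"] = truth["spot"].map(truncated)
    return ImageStack(tuple(frames), frame_interval), truth


# ---------------------------------------------------------------------------
# Shape populations


def make_shape_population(
    n: int,
    kind: Literal["round", "elongated"],
    size_range: tuple[float, float] = (8.0, 16.0),
    seed: int = 0,
    image_size: int = 512,
    intensity: float = 200.0,
    max_tries: int = 2000,
    pixel_size: float = 1.0,
) -> tuple[Image, pd.DataFrame]:
    """Binary-shape population image with per-object ground truth.

    ``round`` places non-overlapping disks with radius in ``size_range``;
    ``elongated`` places capsules (rectangle with semicircular caps) with
    half-width in ``size_range``/2 and aspect ratio drawn in [2, 5]. The
    ground-truth table lists per-object area, axes and perimeter (analytic,
    in px / px²).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    canvas = np.zeros((image_size, image_size))
    placed: list[dict] = []
    tries = 0
    while len(placed) < n:
        if tries >= max_tries:
            raise RuntimeError(f"could not place {n} non-overlapping objects")
        tries += 1
        if kind == "round":
            radius = rng.uniform(*size_range)
            major = minor = 2 * radius
            angle = 0.0
            clearance = radius
        elif kind == "elongated":
            minor = rng.uniform(*size_range)
            ar = rng.uniform(2.0, 5.0)
            major = ar * minor
            radius = minor / 2.0
            angle = rng.uniform(0, np.pi)
            clearance = major / 2.0
        else:
            raise ValueError(f"unknown kind {kind!r}")
        margin = clearance + 3
        cy = rng.uniform(margin, image_size - margin)
        cx = rng.uniform(margin, image_size - margin)
        too_close = any(
            np.hypot(cy - p["row"], cx - p["col"]) < clearance + p["clearance"] + 3
            for p in placed
        )
        if too_close:
            continue
        if kind == "round":
            rr, cc = draw_disk((cy, cx), radius, shape=canvas.shape)
            canvas[rr, cc] = intensity
            area = np.pi * radius**2
            perimeter = 2 * np.pi * radius
        else:
            _draw_capsule(canvas, cy, cx, major, minor, angle, intensity)
            body = major - minor  # straight-segment length
            area = body * minor + np.pi * radius**2
            perimeter = 2 * body + 2 * np.pi * radius
        placed.append(
            dict(
                row=cy,
                col=cx,
                major_px=major,
                minor_px=minor,
                angle=angle,
                area_px2=area,
                perimeter_px=perimeter,
                clearance=clearance,
            )
        )
    truth = pd.DataFrame(placed).drop(columns=["clearance"]) if placed else pd.DataFrame(
        columns=["row", "col", "major_px", "minor_px", "angle", "area_px2", "perimeter_px"]
    )
    return Image(canvas, pixel_size), truth


def _draw_capsule(
    canvas: np.ndarray,
    cy: float,
    cx: float,
    major: float,
    minor: float,
    angle: float,
    value: float,
) -> None:
    """Rasterize a capsule: points within minor/2 of the central segment."""
    half_body = (major - minor) / 2.0
    r = minor / 2.0
    ux, uy = np.cos(angle), np.sin(angle)
    half = int(math.ceil(major / 2.0)) + 2
    r0, r1 = max(int(cy) - half, 0), min(int(cy) + half + 1, canvas.shape[0])
    c0, c1 = max(int(cx) - half, 0), min(int(cx) + half + 1, canvas.shape[1])
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    dy, dx = rr - cy, cc - cx
    t = np.clip(dx * ux + dy * uy, -half_body, half_body)
    dist = np.hypot(dx - t * ux, dy - t * uy)
    canvas[r0:r1, c0:c1][dist <= r] = value
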