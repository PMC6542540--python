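"""Radial intensity profiles and the fractional-distance statistic d_f.

The dispersion readout works on one masked cell at a time: integrate the
fluorescence in 1-px-wide annuli around the nucleus center, normalize radius
so that the farthest mask pixel maps to 1, and report d_f — the minimal
normalized radius whose enclosed annuli contain a fraction f of the cell's
total intensity. Peripheral clustering pushes d_f toward 1, perinuclear
clustering pulls it toward the nucleus radius over r_max.

Note the profile stores *integrated* (summed) intensity per annulus, not the
per-annulus mean that radial-profile plugins usually report: d_f is defined
through cumulative fractions of the total fluorescence, so the bins must add
up to the cell's total intensity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from ramp.core_io import CellGeometry, Image, ImageStack, apply_mask

__all__ = [
    "RadialProfile",
    "FractionalDistance",
    "RecoveryCurve",
    "radial_profile",
    "fractional_distance",
    "select_f",
    "recovery_curve",
    "aggregate_curves",
    "distribution_boxstats",
    "fit_exponential",
    "ExponentialFit",
]


@dataclass(frozen=True)
class RadialProfile:
    """Integrated intensity per annulus, on normalized radius in [0, 1].

    ``bin_edges`` has length n_bins + 1, starts at 0 and ends at 1; the
    physical bin width is r_max / n_bins ≈ 1 px.
    """

    bin_edges: np.ndarray
    integrated_intensity: np.ndarray
    r_max: float

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        vals = np.asarray(self.integrated_intensity, dtype=float)
        if edges.ndim != 1 or edges.size != vals.size + 1:
            raise ValueError("bin_edges must have one more entry than intensities")
        if not (math.isclose(edges[0], 0.0) and math.isclose(edges[-1], 1.0)):
            raise ValueError("bin edges must span [0, 1]")
        widths = np.diff(edges)
        if not np.allclose(widths, widths[0]):
            raise ValueError("bins must have equal width")
        if np.any(vals < 0):
            raise ValueError("intensities must be >= 0")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "integrated_intensity", vals)

    @property
    def total(self) -> float:
        return float(self.integrated_intensity.sum())

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass(frozen=True)
class FractionalDistance:
    """d_f: minimal normalized radius containing fraction f of total intensity."""

    f: float
    d_f: float

    def __post_init__(self) -> None:
        if not 0 < self.f <= 1:
            raise ValueError("f must lie in (0, 1]")
        if not 0 <= self.d_f <= 1:
            raise ValueError("d_f must lie in [0, 1]")


@dataclass(frozen=True)
class RecoveryCurve:
    """d_f versus time for one cell's movie; t = 0 at the perturbation."""

    times: np.ndarray  # minutes
    values: np.ndarray  # d_f per frame
    f: float
    cell_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size != v.size or t.size == 0:
            raise ValueError("times and values must be nonempty and equal-length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("d_f values must lie in [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


def radial_profile(image: Image, geometry: CellGeometry) -> RadialProfile:
    """Bin a masked cell's intensity into 1-px annuli around the center.

    Each in-mask pixel contributes its full intensity to the annulus
    containing its center-to-center distance; the bins exactly partition
    [0, r_max], so the profile sums to the masked image total.
    """
    masked = apply_mask(image, geometry)
    rows, cols = np.nonzero(geometry.cell_mask)
    dist = np.hypot(rows - geometry.center[0], cols - geometry.center[1])
    n_bins = max(int(math.ceil(geometry.r_max)), 1)
    weights = masked.pixels[rows, cols]
    counts, edges_px = np.histogram(
        dist, bins=n_bins, range=(0.0, geometry.r_max), weights=weights
    )
    total = float(weights.sum())
    if total == 0:
        warnings.warn("radial_profile: zero total in-mask intensity", stacklevel=2)
    return RadialProfile(edges_px / geometry.r_max, counts, geometry.r_max)


def fractional_distance(profile: RadialProfile, f: float) -> FractionalDistance:
    """Smallest normalized radius whose annuli hold a fraction f of the total.

    Reported at the upper edge of the first bin where the cumulative
    intensity reaches f·total, so the stated fraction is fully contained.
    """
    if not 0 < f <= 1:
        raise ValueError("f must lie in (0, 1]")
    total = profile.total
    if total <= 0:
        raise ValueError("fractional distance undefined for zero total intensity")
    cum = np.cumsum(profile.integrated_intensity)
    # tolerate roundoff at f = 1
    idx = int(np.searchsorted(cum, f * total - 1e-9 * total, side="left"))
    idx = min(idx, cum.size - 1)
    return FractionalDistance(f, float(profile.bin_edges[idx + 1]))


def select_f(
    curves_start: np.ndarray,
    curves_end: np.ndarray,
    f_grid: np.ndarray,
) -> float:
    """Pick the intensity fraction maximizing start/end contrast.

    ``curves_start`` and ``curves_end`` are (n_cells, n_f) arrays of per-cell
    d_f evaluated on the shared ``f_grid`` at the initial and final states.
    Returns the grid point with the largest |mean difference|; ties break
    toward larger f (keeping more of the signal). A zero maximum difference
    is degenerate and warns.
    """
    start = np.atleast_2d(np.asarray(curves_start, dtype=float))
    end = np.atleast_2d(np.asarray(curves_end, dtype=float))
    f_grid = np.asarray(f_grid, dtype=float)
    if start.size == 0 or end.size == 0:
        raise ValueError("need at least one cell per condition")
    if start.shape[1] != f_grid.size or end.shape[1] != f_grid.size:
        raise ValueError("curves and f_grid disagree in length")
    diff = np.abs(start.mean(axis=0) - end.mean(axis=0))
    best = diff.max()
    if best == 0:
        warnings.warn("select_f: start and end indistinguishable at every f", stacklevel=2)
    # last index attaining the max → largest f on a sorted grid
    idx = int(np.nonzero(diff == best)[0][-1])
    return float(f_grid[idx])


def recovery_curve(
    stack: ImageStack,
    geometry: CellGeometry,
    f: float,
    cell_id: str = "",
    t0_min: float = 0.0,
) -> RecoveryCurve:
    """Per-frame d_f for one cell's movie; times in minutes from t0."""
    times = stack.times_minutes() + t0_min
    values = []
    for k, frame in enumerate(stack.frames):
        prof = radial_profile(frame, geometry)
        if prof.total <= 0:
            raise ValueError(f"frame {k} has zero in-mask intensity")
        values.append(fractional_distance(prof, f).d_f)
    return RecoveryCurve(times, np.asarray(values), f, cell_id)


def aggregate_curves(
    curves: list[RecoveryCurve],
    time_grid: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Pointwise mean and SD over cells, with n per time point.

    Curves on different time offsets are resampled onto the common grid by
    linear interpolation (no extrapolation: points outside a curve's span do
    not count toward its n).
    """
    if not curves:
        raise ValueError("need at least one curve")
    if time_grid is None:
        time_grid = curves[0].times
    time_grid = np.asarray(time_grid, dtype=float)
    rows = np.full((len(curves), time_grid.size), np.nan)
    for i, c in enumerate(curves):
        inside = (time_grid >= c.times[0]) & (time_grid <= c.times[-1])
        rows[i, inside] = np.interp(time_grid[inside], c.times, c.values)
    n = np.sum(~np.isnan(rows), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean = np.nanmean(rows, axis=0)
        sd = np.where(n > 1, np.nanstd(rows, axis=0, ddof=1), 0.0)
    return {"times": time_grid, "mean": mean, "sd": sd, "n": n}


def distribution_boxstats(values) -> dict[str, float]:
    """Five-number summary (min, Q1, median, Q3, max) over per-cell d_f values.

    Quartiles use linear interpolation between order statistics (the
    inclusive convention).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    return {
        "min": float(v.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(v.max()),
    }


@dataclass(frozen=True)
class ExponentialFit:
    """Result of fitting y(t) = y_inf + (y0 − y_inf)·exp(−k·t)."""

    k: float  # rate, 1/min
    y0: float
    y_inf: float
    r_squared: float
    degenerate: bool = False

    @property
    def tau(self) -> float:
        """Time constant 1/k (min); inf for a degenerate (flat) fit."""
        return 1.0 / self.k if self.k > 0 else math.inf

    @property
    def amplitude(self) -> float:
        return self.y0 - self.y_inf


def fit_exponential(times, values) -> ExponentialFit:
    """Least-squares single-exponential relaxation fit.

    A constant (or near-constant) series cannot identify a rate; it returns
    k = 0 with the ``degenerate`` flag set.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 time points")
    span = y.max() - y.min()
    if span < 1e-12:
        return ExponentialFit(0.0, float(y[0]), float(y[0]), 1.0, degenerate=True)

    def model(tt, y_inf, amp, k):
        return y_inf + amp * np.exp(-k * tt)

    t_scale = max(t[-1] - t[0], 1e-9)
    p0 = (float(y[-1]), float(y[0] - y[-1]), 2.0 / t_scale)
    try:
        popt, _ = curve_fit(
            model,
            t,
            y,
            p0=p0,
            bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError:
        return ExponentialFit(0.0, float(y[0]), float(y.mean()), 0.0, degenerate=True)
    y_inf, amp, k = popt
    resid = y - model(t, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ExponentialFit(float(k), float(y_inf + amp), float(y_inf), r2)
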