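"""Radial profiles, the fractional-distance statistic and recovery curves."""

import numpy as np
import pytest

from ramp import synthetic as syn
from ramp.core_io import Image, ImageStack
from ramp.radial import (
    aggregate_curves,
    distribution_boxstats,
    fit_exponential,
    fractional_distance,
    radial_profile,
    recovery_curve,
    RecoveryCurve,
    select_f,
)


def unbinned_d_f(image, geometry, f):
    """Brute-force oracle: sort in-mask pixels by exact center distance and
    find the minimal normalized distance reaching the fraction f of the
    total intensity."""
    rows, cols = np.nonzero(geometry.cell_mask)
    dist = np.hypot(rows - geometry.center[0], cols - geometry.center[1])
    vals = image.pixels[rows, cols]
    order = np.argsort(dist)
    cum = np.cumsum(vals[order])
    idx = np.searchsorted(cum, f * cum[-1] - 1e-9 * cum[-1])
    return dist[order][min(idx, len(cum) - 1)] / geometry.r_max


class TestRadialProfile:
    def test_single_pixel_lands_in_its_annulus(self, circle_geometry):
        px = np.zeros(circle_geometry.cell_mask.shape)
        r0, c0 = circle_geometry.center
        px[int(r0), int(c0) + 37] = 5.0  # distance exactly 37 px
        prof = radial_profile(Image(px), circle_geometry)
        nonzero = np.nonzero(prof.integrated_intensity)[0]
        assert len(nonzero) == 1
        lo, hi = prof.bin_edges[nonzero[0]], prof.bin_edges[nonzero[0] + 1]
        assert lo <= 37.0 / circle_geometry.r_max < hi

    def test_constant_disk_matches_annulus_pixel_counts(self, circle_geometry):
        prof = radial_profile(Image(np.ones(circle_geometry.cell_mask.shape)), circle_geometry)
        rows, cols = np.nonzero(circle_geometry.cell_mask)
        dist = np.hypot(rows - circle_geometry.center[0], cols - circle_geometry.center[1])
        counts, _ = np.histogram(dist, bins=len(prof.integrated_intensity),
                                 range=(0, circle_geometry.r_max))
        np.testing.assert_array_equal(prof.integrated_intensity, counts)

    def test_conserves_total_intensity(self, circle_geometry, rng):
        img = Image(rng.random(circle_geometry.cell_mask.shape))
        prof = radial_profile(img, circle_geometry)
        masked_sum = img.pixels[circle_geometry.cell_mask].sum()
        assert prof.total == pytest.approx(masked_sum)

    def test_zero_intensity_flagged(self, circle_geometry):
        with pytest.warns(UserWarning, match="zero total"):
            radial_profile(Image(np.zeros(circle_geometry.cell_mask.shape)), circle_geometry)


class TestFractionalDistance:
    def test_point_mass_every_f(self, circle_geometry):
        px = np.zeros(circle_geometry.cell_mask.shape)
        r0, c0 = circle_geometry.center
        px[int(r0), int(c0) + 50] = 1.0  # normalized radius 0.50
        prof = radial_profile(Image(px), circle_geometry)
        for f in (0.1, 0.5, 0.99, 1.0):
            d = fractional_distance(prof, f).d_f
            assert 0.50 <= d <= 0.50 + prof.bin_width + 1e-12

    def test_f_one_is_outermost_nonzero_bin(self, circle_geometry, rng):
        pts = syn.sample_positions(circle_geometry, syn.STEADY_STATE, seed=0)
        img = syn.render_image(pts, circle_geometry, syn.STEADY_STATE, seed=0)
        prof = radial_profile(img, circle_geometry)
        nz = np.nonzero(prof.integrated_intensity)[0]
        assert fractional_distance(prof, 1.0).d_f == pytest.approx(
            prof.bin_edges[nz[-1] + 1]
        )

    def test_matches_unbinned_oracle(self, circle_geometry):
        """Binned d_f equals the pixel-sorted quantile within one bin width."""
        for seed in range(10):
            pts = syn.sample_positions(circle_geometry, syn.STEADY_STATE, seed=seed)
            img = syn.render_image(pts, circle_geometry, syn.STEADY_STATE, seed=seed)
            prof = radial_profile(img, circle_geometry)
            for f in (0.25, 0.5, 0.75, 0.95):
                got = fractional_distance(prof, f).d_f
                want = unbinned_d_f(img, circle_geometry, f)
                assert abs(got - want) <= prof.bin_width + 1e-12

    def test_nondecreasing_in_f(self, circle_geometry):
        pts = syn.sample_positions(circle_geometry, syn.STEADY_STATE, seed=7)
        img = syn.render_image(pts, circle_geometry, syn.STEADY_STATE, seed=7)
        prof = radial_profile(img, circle_geometry)
        fs = np.linspace(0.01, 1.0, 200)
        ds = [fractional_distance(prof, f).d_f for f in fs]
        assert np.all(np.diff(ds) >= 0)

    def test_scaling_and_rotation_invariance(self, circle_geometry):
        pts = syn.sample_positions(circle_geometry, syn.STEADY_STATE, seed=3)
        img = syn.render_image(pts, circle_geometry, syn.STEADY_STATE, seed=3)
        prof = radial_profile(img, circle_geometry)
        scaled = radial_profile(Image(img.pixels * 37.5), circle_geometry)
        rotated = radial_profile(Image(np.rot90(img.pixels)), circle_geometry)
        for f in (0.3, 0.75, 0.95):
            d = fractional_distance(prof, f).d_f
            assert fractional_distance(scaled, f).d_f == pytest.approx(d)
            assert abs(fractional_distance(rotated, f).d_f - d) <= prof.bin_width + 1e-12

    def test_zero_total_raises(self, circle_geometry):
        with pytest.warns(UserWarning):
            prof = radial_profile(
                Image(np.zeros(circle_geometry.cell_mask.shape)), circle_geometry
            )
        with pytest.raises(ValueError):
            fractional_distance(prof, 0.5)


class TestSelectF:
    def _step_curves(self, masses, radii, f_grid):
        """d_f curves of a discrete intensity distribution (analytic)."""
        order = np.argsort(radii)
        cum = np.cumsum(np.asarray(masses, float)[order])
        cum /= cum[-1]
        r_sorted = np.asarray(radii, float)[order]
        return np.array([[r_sorted[np.searchsorted(cum, f - 1e-12)] for f in f_grid]])

    def test_constant_objective_tie_breaks_to_largest_f(self):
        f_grid = np.array([0.25, 0.5, 0.75, 0.95])
        start = self._step_curves([1.0], [0.9], f_grid)
        end = self._step_curves([1.0], [0.3], f_grid)
        assert select_f(start, end, f_grid) == 0.95

    def test_peak_at_known_grid_point(self):
        """Two-component mixtures built so the contrast peaks at f = 0.75."""
        f_grid = np.round(np.arange(0.05, 1.0, 0.05), 2)
        # start jumps to 0.95 above f = 0.70, end jumps to 0.55 above 0.78:
        # the contrast is 0.45 only on (0.70, 0.78], which contains just 0.75
        start = self._step_curves([0.70, 0.30], [0.30, 0.95], f_grid)
        end = self._step_curves([0.78, 0.22], [0.50, 0.55], f_grid)
        diff = np.abs(start.mean(axis=0) - end.mean(axis=0))
        brute = f_grid[np.nonzero(diff == diff.max())[0][-1]]
        assert select_f(start, end, f_grid) == pytest.approx(brute)
        assert brute == pytest.approx(0.75)

    def test_identical_inputs_warn_and_return_largest(self):
        f_grid = np.array([0.25, 0.5, 0.75])
        curves = self._step_curves([1.0], [0.5], f_grid)
        with pytest.warns(UserWarning, match="indistinguishable"):
            assert select_f(curves, curves.copy(), f_grid) == 0.75

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            select_f(np.empty((0, 3)), np.empty((0, 3)), np.array([0.3, 0.5, 0.7]))


class TestRecoveryCurve:
    def test_static_movie_constant_curve(self, circle_geometry):
        pts = syn.sample_positions(circle_geometry, syn.STEADY_STATE, seed=1)
        img = syn.render_image(pts, circle_geometry, syn.STEADY_STATE, seed=1)
        stack = ImageStack((img,) * 5, frame_interval=60.0)
        curve = recovery_curve(stack, circle_geometry, f=0.75)
        assert np.ptp(curve.values) == 0.0
        np.testing.assert_allclose(curve.times, np.arange(5))

    def test_monotone_interpolation_gives_monotone_curve(self, circle_geometry):
        from scipy.stats import spearmanr

        movie = syn.make_recovery_movie(
            syn.PERINUCLEAR, syn.PERIPHERAL, tau_min=15.0,
            times=np.arange(0, 30.0, 2.0), geometry=circle_geometry, seed=6,
        )
        curve = recovery_curve(movie, circle_geometry, f=0.75)
        rho = spearmanr(curve.times, curve.values).statistic
        assert abs(rho) > 0.9

    def test_tau_recovered_from_generator_movie(self, circle_geometry):
        """Perinuclear-release movie with tau = 10 min: the fitted exponential
        time constant of d_75(t) recovers tau (mean over seeds within 20%)."""
        taus = []
        for seed in range(5):
            movie = syn.make_recovery_movie(
                syn.PERINUCLEAR, syn.STEADY_STATE, tau_min=10.0,
                times=np.arange(0, 46.0), geometry=circle_geometry, seed=seed,
            )
            curve = recovery_curve(movie, circle_geometry, f=0.75)
            taus.append(fit_exponential(curve.times, curve.values).tau)
        assert np.mean(taus) == pytest.approx(10.0, rel=0.20)


class TestAggregation:
    def test_single_curve_mean_sd(self):
        c = RecoveryCurve(np.arange(4.0), np.array([0.1, 0.2, 0.3, 0.4]), f=0.75)
        agg = aggregate_curves([c])
        np.testing.assert_array_equal(agg["mean"], c.values)
        np.testing.assert_array_equal(agg["sd"], np.zeros(4))

    def test_two_constant_curves_closed_form(self):
        t = np.arange(3.0)
        a = RecoveryCurve(t, np.full(3, 0.4), f=0.75)
        b = RecoveryCurve(t, np.full(3, 0.6), f=0.75)
        agg = aggregate_curves([a, b])
        np.testing.assert_allclose(agg["mean"], 0.5)
        np.testing.assert_allclose(agg["sd"], np.sqrt(0.02), rtol=1e-12)
        np.testing.assert_array_equal(agg["n"], [2, 2, 2])

    def test_mean_near_truth_for_many_replicates(self, rng):
        t = np.arange(10.0)
        truth = 0.5 + 0.3 * np.exp(-t / 3.0)
        curves = [
            RecoveryCurve(t, np.clip(truth + rng.normal(0, 0.05, 10), 0, 1), f=0.75)
            for _ in range(100)
        ]
        agg = aggregate_curves(curves)
        sem = agg["sd"] / np.sqrt(agg["n"])
        assert np.all(np.abs(agg["mean"] - truth) < 2.5 * sem + 1e-3)

    def test_offset_curves_resampled(self):
        a = RecoveryCurve(np.array([0.0, 2.0]), np.array([0.0, 1.0]), f=0.75)
        b = RecoveryCurve(np.array([1.0, 3.0]), np.array([0.5, 0.5]), f=0.75)
        agg = aggregate_curves([a, b], time_grid=np.array([1.0, 2.0]))
        np.testing.assert_allclose(agg["mean"], [0.5, 0.75])
        np.testing.assert_array_equal(agg["n"], [2, 2])


class TestBoxstats:
    def test_five_point_closed_form(self):
        s = distribution_boxstats([0.2, 0.4, 0.6, 0.8, 1.0])
        assert s == {"min": 0.2, "q1": 0.4, "median": 0.6, "q3": 0.8, "max": 1.0}

    def test_single_value(self):
        s = distribution_boxstats([0.42])
        assert all(v == 0.42 for v in s.values())

    def test_uniform_quartiles(self, rng):
        s = distribution_boxstats(rng.random(10_000))
        assert abs(s["q1"] - 0.25) < 0.02
        assert abs(s["median"] - 0.5) < 0.02
        assert abs(s["q3"] - 0.75) < 0.02

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            distribution_boxstats([])


class TestFitExponential:
    def test_exact_exponential_recovered(self):
        t = np.arange(0, 46.0)
        y = 0.6 + 0.35 * np.exp(-0.1 * t)
        fit = fit_exponential(t, y)
        assert fit.k == pytest.approx(0.1, abs=1e-6)
        assert fit.y_inf == pytest.approx(0.6, abs=1e-6)
        assert fit.r_squared > 0.999999

    def test_constant_series_degenerate(self):
        fit = fit_exponential(np.arange(5.0), np.full(5, 0.7))
        assert fit.degenerate and fit.k == 0.0 and fit.amplitude == 0.0

    def test_noisy_recovery_within_15_percent(self, rng):
        t = np.arange(0, 46.0)
        ks = []
        for _ in range(50):
            y = 0.6 + 0.35 * np.exp(-0.1 * t) + rng.normal(0, 0.02, t.size)
            ks.append(fit_exponential(t, y).k)
        assert np.mean(ks) == pytest.approx(0.1, rel=0.15)
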