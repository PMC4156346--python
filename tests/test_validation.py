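"""Density-profile measurement and Ripley's K randomness testing."""

import numpy as np
import pytest

from nanodot import (
    DensityFunction,
    GradientSpec,
    RasterImage,
    column_window_edges,
    crop_strip,
    csr_envelope,
    generate_ordered,
    generate_random,
    measure_density_profile,
    r_squared,
    rasterize,
    ripley_k,
    ripley_test,
)
from nanodot.validation import _k_hat
from tests.conftest import constant_density


class TestDensityProfile:
    def test_ordered_linear_fidelity(self, linear_01_30, ordered_linear_pattern):
        image = rasterize(ordered_linear_pattern, 0.02)
        edges = column_window_edges(ordered_linear_pattern, 1.0)
        profile = measure_density_profile(image, linear_01_30, edges=edges)
        assert profile.r_squared >= 0.9998

    def test_ordered_exponential_fidelity(self):
        density = DensityFunction("exponential", 0.01, 0.30, 100.0, k=3.0)
        pattern = generate_ordered(GradientSpec(100.0, 100.0, density, "ordered"))
        image = rasterize(pattern, 0.02)
        profile = measure_density_profile(
            image, density, edges=column_window_edges(pattern, 1.0)
        )
        assert profile.r_squared >= 0.9998

    def test_constant_profile_perfect_fit(self):
        # constant measured profile matching a constant reference: SS_tot is
        # zero, reported as a perfect fit rather than an indeterminate ratio
        pixels = np.zeros((50, 100), bool)
        pixels[:25, :] = True  # half covered in every window
        image = RasterImage(pixels, 0.05)
        flat = DensityFunction("custom", length=5.0, custom=lambda l: 0.5 * np.ones_like(l))
        profile = measure_density_profile(image, flat, window_length=1.0)
        np.testing.assert_allclose(profile.measured, 0.5)
        assert profile.r_squared == 1.0

    def test_window_longer_than_field_rejected(self, linear_01_30):
        image = RasterImage(np.zeros((10, 10), bool), 0.05)
        with pytest.raises(ValueError):
            measure_density_profile(image, linear_01_30, window_length=5.0)

    def test_r_squared_degenerate_mismatch(self):
        # constant measurement that misses a constant reference: no fit
        assert r_squared([0.5, 0.5], [0.7, 0.7]) == 0.0

    def test_windows_report_physical_centres(self, linear_01_30):
        image = RasterImage(np.zeros((10, 200), bool), 0.05)
        profile = measure_density_profile(image, linear_01_30, window_length=2.0)
        np.testing.assert_allclose(profile.positions, np.arange(1.0, 10.0, 2.0))


class TestRipley:
    def test_isolated_pair_zero_below_separation(self):
        pts = np.array([[2.0, 2.0], [2.0, 3.0]])  # distance 1
        est = ripley_k(pts, (0, 0, 5, 5), np.array([0.5, 0.9]))
        assert est.k.tolist() == [0.0, 0.0]

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            ripley_k(np.array([[1.0, 1.0]]), (0, 0, 2, 2), np.array([0.5]))

    def test_points_outside_region_rejected(self):
        pts = np.array([[1.0, 1.0], [3.0, 1.0]])
        with pytest.raises(ValueError):
            ripley_k(pts, (0, 0, 2, 2), np.array([0.5]))

    def test_csr_calibration_small_radii(self, rng):
        # mean K̂/(pi s²) within 10% of 1 for s << region side
        s = np.array([0.02, 0.035, 0.05])
        ratios = []
        for _ in range(100):
            pts = rng.random((200, 2))
            ratios.append(_k_hat(pts, 1.0, s) / (np.pi * s**2))
        np.testing.assert_array_less(np.abs(np.mean(ratios, axis=0) - 1.0), 0.1)

    def test_envelope_z0_collapses_to_mean(self):
        s = np.linspace(0.1, 1.0, 5)
        env = csr_envelope(0.2, 0.04, (0, 0, 10, 50), s, n_sims=5, z=0.0, seed=1)
        np.testing.assert_array_equal(env.lo, env.mean)
        np.testing.assert_array_equal(env.hi, env.mean)

    def test_envelope_tracks_theory(self):
        s = np.linspace(0.2, 1.0, 5)
        env = csr_envelope(0.2, 0.04, (0, 0, 10, 400), s, n_sims=10, seed=3)
        np.testing.assert_allclose(env.mean, np.pi * s**2, rtol=0.05)

    def test_envelope_mean_sd_scales_with_sims(self):
        # SD of the envelope mean shrinks ~1/sqrt(n_sims)
        s = np.array([0.5, 1.0])
        region = (0, 0, 10, 100)

        def mean_sd(n_sims, reps=12):
            means = [
                csr_envelope(0.2, 0.04, region, s, n_sims=n_sims, seed=100 + r).mean
                for r in range(reps)
            ]
            return np.std(means, axis=0, ddof=1)

        ratio = mean_sd(4) / mean_sd(16)
        assert 1.2 < np.median(ratio) < 3.5  # ~2 expected

    def test_envelope_contains_its_own_mean(self):
        s = np.linspace(0.1, 2.0, 10)
        env = csr_envelope(0.2, 0.04, (0, 0, 10, 100), s, n_sims=10, seed=7)
        assert np.all(env.lo <= env.mean) and np.all(env.mean <= env.hi)

    def test_own_simulations_rarely_leave_envelope(self, rng):
        # members of the envelope's own sample exceed the band <= ~5%
        s = np.linspace(0.1, 1.5, 15)
        out = tot = 0
        for _ in range(10):
            ks = np.array(
                [
                    _k_hat(
                        np.column_stack(
                            [rng.uniform(0, 10, 3000), rng.uniform(0, 100, 3000)]
                        ),
                        1000.0,
                        s,
                    )
                    for _ in range(10)
                ]
            )
            mean, sd = ks.mean(0), ks.std(0, ddof=1)
            inside = (ks >= mean - 1.96 * sd) & (ks <= mean + 1.96 * sd)
            out += (~inside).sum()
            tot += inside.size
        assert out / tot <= 0.07  # ~5% with binomial slack

    def test_independent_csr_mostly_inside(self, rng):
        s = np.linspace(0.1, 1.5, 15)
        region = (0, 0, 10, 200)
        fracs = []
        for rep in range(8):
            pts = np.column_stack(
                [rng.uniform(0, 10, 6000), rng.uniform(0, 200, 6000)]
            )
            est = ripley_test(pts, region, s, 0.04, seed=400 + rep)
            fracs.append(est.fraction_inside)
        assert np.mean(fracs) >= 0.85

    def test_discriminates_ordered_from_random(self):
        """The Fig-4 separation: a random constant-density strip stays inside
        the CSR envelope; the ordered lattice at the same density leaves it."""
        s = np.linspace(0.05, 2.0, 40)
        const = constant_density(0.20, 14.0)
        rand = generate_random(GradientSpec(100.0, 14.0, const, "random", seed=3))
        pts, region = crop_strip(rand, 2.0, 12.0)
        est_rand = ripley_test(pts, region, s, 0.04, seed=21)

        ordered = generate_ordered(
            GradientSpec(100.0, 10.0, constant_density(0.20, 10.0), "ordered")
        )
        est_ord = ripley_test(
            ordered.centers, ordered.center_bounds(), s, 0.04, seed=22
        )
        assert est_rand.fraction_inside >= 0.9
        assert est_ord.fraction_inside <= 0.5
        # the lattice has no neighbours below its pitch: K=0 where CSR grows
        assert est_ord.k[s < 0.4].max() == 0.0


class TestCropStrip:
    def test_crop_shifts_and_bounds(self, random_exponential_pattern):
        pts, region = crop_strip(random_exponential_pattern, 10.0, 20.0)
        assert region[0] == 0.0 and region[2] == 10.0
        assert pts[:, 0].min() >= 0.0 and pts[:, 0].max() < 10.0

    def test_rejects_out_of_field(self, random_exponential_pattern):
        with pytest.raises(ValueError):
            crop_strip(random_exponential_pattern, 50.0, 150.0)
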