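"""Random generator: overlap compensation, determinism, coverage oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanodot import (
    DensityFunction,
    GradientSpec,
    NanodotPattern,
    compensated_count,
    expected_coverage,
    generate_random,
    grid_threshold_pattern,
    rasterize,
)
from nanodot.randomized import seed_box
from tests.conftest import constant_density


class TestCompensatedCount:
    def test_max_density_reference_counts(self):
        # 400x1 µm² box, 200x200 nm² dots, D = 0.9999
        assert compensated_count(0.9999, 0.04, 400.0) == 92_099
        uncompensated = 0.9999 * 400.0 / 0.04
        assert round(uncompensated) == 9_999

    def test_small_density_linearises(self):
        assert compensated_count(1e-6, 0.04, 400.0) == 1

    def test_density_one_diverges(self):
        with pytest.raises(ValueError):
            compensated_count(1.0, 0.04, 400.0)
        with pytest.raises(ValueError):
            compensated_count(0.99995, 0.04, 400.0)  # above the 0.9999 cap

    @given(st.floats(0.0, 0.9999), st.floats(0.0, 0.9999))
    @settings(max_examples=200, derandomize=True)
    def test_nondecreasing_in_density(self, d1, d2):
        lo, hi = sorted((d1, d2))
        assert compensated_count(lo, 0.04, 400.0) <= compensated_count(hi, 0.04, 400.0)


class TestExpectedCoverage:
    def test_trivial_counts(self):
        assert expected_coverage(0, 0.04, 400.0) == 0.0
        assert expected_coverage(1, 0.04, 400.0) == pytest.approx(1e-4, rel=1e-12)

    def test_round_trips_printed_count(self):
        assert expected_coverage(92_099, 0.04, 400.0) == pytest.approx(0.9999, abs=5e-5)

    @given(st.floats(0.0, 0.9999))
    @settings(max_examples=200, derandomize=True)
    def test_ceil_round_trip_bracket(self, density):
        # coverage of the compensated count lies in [D, D + one-dot increment]
        n = compensated_count(density, 0.04, 400.0)
        cov = expected_coverage(n, 0.04, 400.0)
        increment = (1.0 - cov) * (0.04 / 400.0) / (1.0 - 0.04 / 400.0)
        assert density - 1e-12 <= cov <= density + increment + 1e-12


class TestGenerateRandom:
    def test_deterministic_from_seed(self, linear_01_30):
        spec = GradientSpec(100.0, 100.0, linear_01_30, "random", seed=7)
        a = generate_random(spec)
        b = generate_random(spec)
        np.testing.assert_array_equal(a.centers, b.centers)
        c = generate_random(GradientSpec(100.0, 100.0, linear_01_30, "random", seed=8))
        assert not np.array_equal(a.centers, c.centers)

    def test_dots_inside_field_and_counts_match_plan(self, random_exponential_pattern):
        pattern = random_exponential_pattern
        assert pattern.inside_field()
        assert pattern.n_dots == pattern.metadata["box_counts"].sum()

    def test_box_midpoint_density_drives_counts(self, linear_01_30):
        spec = GradientSpec(100.0, 100.0, linear_01_30, "random", seed=0)
        pattern = generate_random(spec)
        meta = pattern.metadata
        mids = 0.5 * (meta["box_edges"][:-1] + meta["box_edges"][1:])
        for mid, d, n in zip(mids, meta["box_densities"], meta["box_counts"]):
            assert d == pytest.approx(linear_01_30(mid), abs=1e-12)
            assert n == compensated_count(d, 0.04, 100.0 * 1.0)

    def test_truncated_final_box_uses_actual_area(self):
        density = constant_density(0.2, 10.5)
        spec = GradientSpec(100.0, 10.5, density, "random", box_width=1.0, seed=1)
        pattern = generate_random(spec)
        edges = pattern.metadata["box_edges"]
        assert edges[-1] == pytest.approx(10.5)
        assert edges[-1] - edges[-2] == pytest.approx(0.5)
        assert pattern.metadata["box_counts"][-1] == compensated_count(
            0.2, 0.04, 100.0 * 0.5
        )

    def test_narrow_box_rejected(self, linear_01_30):
        with pytest.raises(ValueError):
            GradientSpec(100.0, 100.0, linear_01_30, "random", box_width=0.1)

    @pytest.mark.parametrize("target", [0.1, 0.5, 0.9])
    def test_union_coverage_matches_target(self, target):
        """Monte-Carlo validation of the overlap compensation: the realised
        union coverage of compensated seeding in a periodic 400x1 µm² box
        equals the programmed density within 3 standard errors."""
        n = compensated_count(target, 0.04, 400.0)
        exact = expected_coverage(n, 0.04, 400.0)  # target + ceil remainder
        covs = []
        for seed in range(20):
            rng = np.random.default_rng(900 + seed)
            pts = seed_box(target, 0.04, (0.0, 0.0, 1.0, 400.0), rng)
            pattern = NanodotPattern(pts, 0.2, 400.0, 1.0)
            img = rasterize(pattern, 0.01, wrap_x=True, wrap_y=True)
            covs.append(img.coverage())
        mean = np.mean(covs)
        se = np.std(covs, ddof=1) / np.sqrt(len(covs))
        assert abs(mean - exact) < 3 * se


class TestGridThreshold:
    def test_empty_and_full_fields(self):
        base = dict(width=10.0, length=10.0, algorithm="grid_threshold", seed=0)
        zero = DensityFunction("custom", length=10.0, custom=np.zeros_like)
        empty = grid_threshold_pattern(GradientSpec(density=zero, **base))
        assert empty.n_dots == 0
        one = DensityFunction("custom", length=10.0, custom=np.ones_like)
        full = grid_threshold_pattern(GradientSpec(density=one, **base))
        # every cell on (up to the 1e-4 density cap on a 2500-cell grid)
        assert full.n_dots >= 0.998 * 50 * 50

    def test_on_fraction_binomial(self):
        # 2000x2000 cells at D=0.3: on-fraction within 3 binomial SD
        spec = GradientSpec(
            400.0, 400.0, constant_density(0.3, 400.0), "grid_threshold", seed=11
        )
        pattern = grid_threshold_pattern(spec)
        n_cells = 2000 * 2000
        frac = pattern.n_dots / n_cells
        assert abs(frac - 0.3) < 3 * np.sqrt(0.3 * 0.7 / n_cells)

    def test_dots_on_grid(self):
        spec = GradientSpec(
            4.0, 4.0, constant_density(0.5, 4.0), "grid_threshold", seed=2
        )
        pattern = grid_threshold_pattern(spec)
        # centres at (i + 0.5) * dot_edge
        frac = (pattern.centers / 0.2 - 0.5) % 1.0
        np.testing.assert_allclose(frac, 0.0, atol=1e-9)
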