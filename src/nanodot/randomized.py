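"""Random DNG generation with analytic overlap compensation.

Randomly seeded dots overlap, so the union coverage of N dots in a box of
area A_box falls short of N*A_dot/A_box.  Treating each dot independently,
the probability that a given point is covered by one dot is
p = A_dot/A_box, so the expected union coverage of N dots is
1 - (1 - p)^N (a binomial Boolean-model result).  Solving for N gives the
compensated count

    N = ceil( ln(1 - D) / ln(1 - A_dot/A_box) )

which diverges as D -> 1; the programmed ceiling is therefore
MAX_DENSITY = 0.9999.  The gradient field is subdivided into full-width
boxes along the gradient axis; each box is seeded with the compensated
count for the density at its midpoint.

Also provided: the grid-threshold generator, where dots sit on a regular
dot-pitch grid and each cell is switched on with probability equal to the
local density (random in value, ordered in position — a halftoning-style
random grid, not a fully random pattern).
"""

from __future__ import annotations

import math

import numpy as np

from .density import MAX_DENSITY
from .pattern import GradientSpec, NanodotPattern

__all__ = [
    "compensated_count",
    "expected_coverage",
    "seed_box",
    "generate_random",
    "grid_threshold_pattern",
]


def compensated_count(density: float, dot_area: float, box_area: float) -> int:
    """Dots needed so the expected union coverage of a box equals ``density``.

    Rounded up, so the expected coverage never undershoots the target.
    """
    if density < 0:
        raise ValueError("density must be non-negative")
    if density >= 1:
        raise ValueError("the required count diverges as density -> 1")
    if density > MAX_DENSITY:
        raise ValueError(f"density capped at {MAX_DENSITY}")
    if not 0 < dot_area < box_area:
        raise ValueError("need 0 < dot_area < box_area")
    if density == 0:
        return 0
    return math.ceil(math.log1p(-density) / math.log1p(-dot_area / box_area))


def expected_coverage(n: int, dot_area: float, box_area: float) -> float:
    """Expected union coverage fraction of ``n`` independently seeded dots."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if not 0 < dot_area < box_area:
        raise ValueError("need 0 < dot_area < box_area")
    return -math.expm1(n * math.log1p(-dot_area / box_area))


def seed_box(
    density: float,
    dot_area: float,
    bounds: tuple[float, float, float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Seed one box: compensated dot count, centres i.i.d. uniform over it.

    This is the random algorithm's primitive: with centres uniform over the
    full box, every interior point is covered by a given dot with
    probability exactly A_dot/A_box, so the expected union coverage of the
    returned dots equals ``density`` (up to the ceil rounding).  Dots may
    extend past the box bounds; on a periodic (toroidal) box the coverage
    identity is exact, which is how the compensation is validated.
    """
    x0, y0, x1, y1 = bounds
    n = compensated_count(density, dot_area, (x1 - x0) * (y1 - y0))
    return np.column_stack([rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)])


def _box_edges(length: float, box_width: float) -> np.ndarray:
    """Box boundaries along the gradient axis; last box may be truncated."""
    n_full = int(math.floor(length / box_width + 1e-9))
    edges = np.arange(n_full + 1) * box_width
    if length - edges[-1] > 1e-9:
        edges = np.append(edges, length)
    edges[-1] = length
    return edges


def generate_random(spec: GradientSpec) -> NanodotPattern:
    """Seed uniformly distributed dots box-by-box with overlap compensation.

    Dot centres are drawn uniformly over each full box, so the per-point
    coverage probability is exactly A_dot/A_box as the compensation assumes;
    dots may straddle box borders (spill between neighbouring boxes cancels
    for smooth density functions).  Only at the two outer field boundaries
    is the draw clamped inward by half a dot edge so every dot stays inside
    the field.  The layout is reproducible from ``spec.seed``.
    """
    if spec.algorithm != "random":
        raise ValueError("spec.algorithm must be 'random'")
    rng = np.random.default_rng(spec.seed)
    e = spec.dot_edge
    h = e / 2
    w, length = spec.width, spec.length
    edges = _box_edges(length, spec.box_width)

    counts: list[int] = []
    dens: list[float] = []
    chunks: list[np.ndarray] = []
    for x0, x1 in zip(edges[:-1], edges[1:]):
        a_box = w * (x1 - x0)
        d_mid = spec.density(0.5 * (x0 + x1))
        n = compensated_count(d_mid, spec.dot_area, a_box)
        counts.append(n)
        dens.append(d_mid)
        if n == 0:
            continue
        xs = rng.uniform(max(x0, h), min(x1, length - h), n)
        ys = rng.uniform(h, w - h, n)
        chunks.append(np.column_stack([xs, ys]))

    centers = np.concatenate(chunks) if chunks else np.empty((0, 2))
    meta = {
        "algorithm": "random",
        "seed": spec.seed,
        "box_edges": edges,
        "box_counts": np.array(counts),
        "box_densities": np.array(dens),
        "spec_label": spec.label,
    }
    return NanodotPattern(centers, e, w, length, meta)


def grid_threshold_pattern(spec: GradientSpec) -> NanodotPattern:
    """Random-grid (threshold) pattern: dot-pitch grid cells switched on
    with probability equal to the local density.

    A matrix of pseudo-random values is compared against the density at
    each cell's position; values below the threshold become dots.  One
    grid cell per dot, so the expected on-fraction of each constant-density
    strip equals the programmed density.
    """
    if spec.algorithm != "grid_threshold":
        raise ValueError("spec.algorithm must be 'grid_threshold'")
    rng = np.random.default_rng(spec.seed)
    e = spec.dot_edge
    nx = int(round(spec.length / e))
    ny = int(round(spec.width / e))
    xc = (np.arange(nx) + 0.5) * e
    yc = (np.arange(ny) + 0.5) * e
    thresh = spec.density(np.clip(xc, 0, spec.length))  # density per grid column
    on = rng.random((ny, nx)) < thresh[None, :]
    jj, ii = np.nonzero(on)
    centers = np.column_stack([xc[ii], yc[jj]])
    meta = {
        "algorithm": "grid_threshold",
        "seed": spec.seed,
        "grid_shape": (ny, nx),
        "spec_label": spec.label,
    }
    return NanodotPattern(centers, e, spec.width, spec.length, meta)
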