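"""Pattern validation: density-profile fidelity and Ripley's K randomness.

Density fidelity: the rendered bitmap is cut into full-width windows along
the gradient axis; the covered-pixel fraction per window ("ratio of black
to white pixels", read as black/(black+white)) is regressed against the
programmed density at the window centres, reported as
R² = 1 - SS_res/SS_tot.  The reference is the programmed curve itself, not
a refitted line.

Randomness: Ripley's K counts neighbours within radius s, normalised so a
homogeneous Poisson pattern (complete spatial randomness, CSR) has
E[K(s)] = pi s².  Because density varies along the gradient, randomness is
only assessed within constant-density strips, perpendicular to the
gradient.  Significance is judged against a Monte-Carlo envelope
(mean ± z·SD over CSR simulations of the same intensity and geometry),
which cancels edge bias by construction, so the estimator applies no
analytic edge correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .density import DensityFunction
from .raster import RasterImage

__all__ = [
    "r_squared",
    "DensityProfile",
    "measure_density_profile",
    "crop_strip",
    "RipleyEnvelope",
    "RipleyEstimate",
    "ripley_k",
    "csr_envelope",
    "ripley_test",
]


def r_squared(measured, reference) -> float:
    """Coefficient of determination of ``measured`` against ``reference``.

    SS_tot uses the measured mean.  A constant measured profile (SS_tot = 0)
    is a perfect fit iff the residuals are also zero.
    """
    m = np.asarray(measured, dtype=float)
    r = np.asarray(reference, dtype=float)
    ss_res = float(np.sum((m - r) ** 2))
    ss_tot = float(np.sum((m - m.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res < 1e-24 else 0.0
    return 1.0 - ss_res / ss_tot


@dataclass
class DensityProfile:
    """Measured vs programmed density per window along the gradient axis."""

    positions: np.ndarray  # window centres, µm
    measured: np.ndarray  # covered fraction per window
    programmed: np.ndarray  # programmed density at window centres
    r_squared: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position_um": self.positions,
                "measured_density": self.measured,
                "programmed_density": self.programmed,
            }
        )


def measure_density_profile(
    image: RasterImage,
    programmed: DensityFunction,
    window_length: float | None = 1.0,
    edges: np.ndarray | None = None,
) -> DensityProfile:
    """Measure the realised density profile of a rendered gradient.

    The image is split into full-width windows along the gradient axis —
    either fixed windows of ``window_length`` µm, or at explicit ``edges``
    (µm; e.g. :func:`nanodot.ordered.column_window_edges`, so each window
    holds whole unit cells).  Covered pixels are counted over the pixel
    columns nearest the window bounds, while the denominator is the
    physical window area, so the measurement is not biased by quantising
    window widths to whole pixels.
    """
    ny, nx = image.shape
    ps = image.pixel_size
    extent = nx * ps
    if edges is None:
        if window_length is None:
            raise ValueError("give window_length or edges")
        if window_length > extent + 1e-9:
            raise ValueError("window longer than the field")
        n_win = int(extent / window_length + 1e-9)
        edges = np.arange(n_win + 1) * window_length
    edges = np.asarray(edges, dtype=float)
    cols = np.rint(edges / ps).astype(int)
    cols = np.clip(cols, 0, nx)

    pos, meas = [], []
    for (e0, e1), (c0, c1) in zip(zip(edges[:-1], edges[1:]), zip(cols[:-1], cols[1:])):
        if c1 <= c0:
            raise ValueError("window narrower than one pixel column")
        covered = int(image.pixels[:, c0:c1].sum())
        meas.append(covered * ps / (ny * (e1 - e0)))
        pos.append((e0 + e1) / 2)
    pos = np.asarray(pos)
    meas = np.asarray(meas)
    prog = np.asarray(programmed(np.clip(pos, 0, programmed.length)), dtype=float)
    return DensityProfile(pos, meas, prog, r_squared(meas, prog))


def crop_strip(pattern, x0: float, x1: float):
    """Cut a constant-density strip out of a pattern for randomness testing.

    Returns ``(points, region)``: dot centres with gradient-axis coordinate
    in ``[x0, x1)``, shifted so the strip starts at 0, and the matching
    analysis rectangle.  Crop away from the field ends — the outermost
    half dot edge of a random pattern is a clamped placement margin whose
    locally raised intensity would bias K̂ upward.  Along the width the
    region is the dot-centre support (field shrunk by half a dot edge).
    """
    if not 0 <= x0 < x1 <= pattern.length:
        raise ValueError("strip outside the field")
    h = pattern.dot_edge / 2
    pts = pattern.centers
    sel = (pts[:, 0] >= x0) & (pts[:, 0] < x1)
    pts = pts[sel] - np.array([x0, 0.0])
    return pts, (0.0, h, x1 - x0, pattern.width - h)


# ---------------------------------------------------------------------------
# Ripley's K


@dataclass
class RipleyEnvelope:
    """Monte-Carlo CSR envelope: mean ± z·SD of K̂ over simulations."""

    s: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    n_sims: int
    z: float
    n_points: int


@dataclass
class RipleyEstimate:
    """K̂(s) with CSR reference and envelope classification."""

    s: np.ndarray
    k: np.ndarray
    theoretical: np.ndarray  # pi s^2
    n_points: int
    area: float
    intensity: float  # points per µm²
    envelope: RipleyEnvelope | None = None

    @property
    def inside(self) -> np.ndarray:
        if self.envelope is None:
            raise ValueError("no envelope attached")
        return (self.k >= self.envelope.lo) & (self.k <= self.envelope.hi)

    @property
    def fraction_inside(self) -> float:
        return float(self.inside.mean())

    def to_frame(self) -> pd.DataFrame:
        d = {"s_um": self.s, "k_hat": self.k, "pi_s2": self.theoretical}
        if self.envelope is not None:
            d["envelope_lo"] = self.envelope.lo
            d["envelope_hi"] = self.envelope.hi
        return pd.DataFrame(d)


def _k_hat(points: np.ndarray, area: float, s_grid: np.ndarray) -> np.ndarray:
    n = len(points)
    tree = cKDTree(points)
    pairs = tree.count_neighbors(tree, s_grid)  # ordered pairs incl. self
    return area * (pairs - n) / (n * (n - 1))


def ripley_k(points, region, s_grid) -> RipleyEstimate:
    """Ripley's K estimator K̂(s) = Area/(n(n-1)) * sum_{i!=j} 1[d_ij <= s].

    ``region`` is (x0, y0, x1, y1) in µm; all points must lie inside it.
    For CSR input K̂(s) ≈ pi s²; excess signals clustering, deficit
    dispersion.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 2:
        raise ValueError("need at least two points")
    x0, y0, x1, y1 = region
    if not (x1 > x0 and y1 > y0):
        raise ValueError("degenerate region")
    if (
        pts[:, 0].min() < x0 - 1e-9
        or pts[:, 0].max() > x1 + 1e-9
        or pts[:, 1].min() < y0 - 1e-9
        or pts[:, 1].max() > y1 + 1e-9
    ):
        raise ValueError("points outside region")
    s = np.asarray(s_grid, dtype=float)
    area = (x1 - x0) * (y1 - y0)
    k = _k_hat(pts, area, s)
    return RipleyEstimate(s, k, np.pi * s**2, len(pts), area, len(pts) / area)


def csr_envelope(
    density: float,
    dot_area: float,
    region,
    s_grid,
    n_sims: int = 10,
    z: float = 1.96,
    seed: int = 0,
) -> RipleyEnvelope:
    """Envelope of K̂ from CSR simulations matching a pattern's intensity.

    The simulated point count is the expected dot count of a pattern at
    ``density`` with dots of ``dot_area`` in ``region``; the default
    z = 1.96 with 10 simulations gives the 95% band used for randomness QC.
    """
    if n_sims < 2:
        raise ValueError("need at least two simulations")
    x0, y0, x1, y1 = region
    if not (x1 > x0 and y1 > y0):
        raise ValueError("degenerate region")
    area = (x1 - x0) * (y1 - y0)
    n = max(2, int(round(density * area / dot_area)))
    rng = np.random.default_rng(seed)
    s = np.asarray(s_grid, dtype=float)
    ks = np.empty((n_sims, len(s)))
    for i in range(n_sims):
        pts = np.column_stack(
            [rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)]
        )
        ks[i] = _k_hat(pts, area, s)
    mean = ks.mean(axis=0)
    sd = ks.std(axis=0, ddof=1)
    return RipleyEnvelope(s, mean, sd, mean - z * sd, mean + z * sd, n_sims, z, n)


def ripley_test(
    points,
    region,
    s_grid,
    dot_area: float,
    n_sims: int = 10,
    z: float = 1.96,
    seed: int = 0,
) -> RipleyEstimate:
    """K̂ for a point set plus a same-geometry CSR envelope.

    The envelope intensity is matched to the observed pattern
    (n points * dot_area / area).
    """
    est = ripley_k(points, region, s_grid)
    density = est.n_points * dot_area / est.area
    est.envelope = csr_envelope(density, dot_area, region, s_grid, n_sims, z, seed)
    return est
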