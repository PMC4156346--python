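"""Binary rasterisation of dot layouts and lossless raster I/O.

Rasters are boolean pixel matrices with a physical pixel size in µm/px.
Array layout: ``pixels[row, col]`` where ``col`` indexes the gradient axis
(x) and ``row`` the width axis (y), row 0 at y = 0.  Pixel centres sit at
``(index + 0.5) * pixel_size``; a pixel is covered iff its centre lies
inside any dot square (half-open on the high edge), with no anti-aliasing —
density measurement is a black/white pixel count.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .pattern import NanodotPattern

__all__ = ["RasterImage", "rasterize", "write_raster", "read_raster"]


@dataclass
class RasterImage:
    """Binary pixel grid with physical pixel size (µm/px)."""

    pixels: np.ndarray  # bool, shape (ny, nx)
    pixel_size: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def coverage(self) -> float:
        """Covered-pixel fraction of the whole image."""
        return float(self.pixels.mean())


def _ceil_div(a: float, b: float) -> int:
    return int(math.ceil(a / b - 1e-9))


def rasterize(
    pattern: NanodotPattern,
    pixel_size: float,
    *,
    wrap_x: bool = False,
    wrap_y: bool = False,
    min_resolution: float = 2.0,
) -> RasterImage:
    """Render a pattern to a binary pixel grid.

    ``pixel_size`` must give at least ``min_resolution`` pixels per dot edge
    (default 2).  ``wrap_x``/``wrap_y`` wrap dot footprints periodically
    (toroidal field) — used to measure the union coverage of a single
    seeding box as it would appear flanked by identically seeded
    neighbours, free of edge effects.
    """
    if not pixel_size > 0:
        raise ValueError("pixel_size must be positive")
    if pixel_size > pattern.dot_edge / min_resolution + 1e-12:
        raise ValueError(
            f"pixel_size {pixel_size} too coarse: need >= {min_resolution} px per dot edge"
        )
    nx = _ceil_div(pattern.length, pixel_size)
    ny = _ceil_div(pattern.width, pixel_size)
    img = np.zeros((ny, nx), dtype=bool)
    if pattern.n_dots:
        h = pattern.dot_edge / 2
        ps = pixel_size
        cx, cy = pattern.centers[:, 0], pattern.centers[:, 1]
        # pixel centre (i + 0.5) ps covered iff x0 <= centre < x1
        i0 = np.ceil((cx - h) / ps - 0.5).astype(np.int64)
        i1 = np.ceil((cx + h) / ps - 0.5).astype(np.int64) - 1
        j0 = np.ceil((cy - h) / ps - 0.5).astype(np.int64)
        j1 = np.ceil((cy + h) / ps - 0.5).astype(np.int64) - 1
        if not wrap_x:
            i0 = np.clip(i0, 0, nx - 1)
            i1 = np.clip(i1, 0, nx - 1)
        if not wrap_y:
            j0 = np.clip(j0, 0, ny - 1)
            j1 = np.clip(j1, 0, ny - 1)
        for a, b, c, d in zip(i0, i1, j0, j1):
            xi = slice(a, b + 1) if 0 <= a and b < nx else np.arange(a, b + 1) % nx
            yi = slice(c, d + 1) if 0 <= c and d < ny else np.arange(c, d + 1) % ny
            if isinstance(xi, slice) or isinstance(yi, slice):
                img[yi, xi] = True
            else:
                img[np.ix_(yi, xi)] = True
    return RasterImage(img, pixel_size)


def write_raster(image: RasterImage, path) -> None:
    """Write a raster losslessly as 8-bit grayscale PNG/BMP.

    The physical pixel size is stored in a JSON sidecar (``<path>.json``)
    so a reload reconstructs the full object.
    """
    path = Path(path)
    arr = (image.pixels.astype(np.uint8)) * 255
    Image.fromarray(arr, mode="L").save(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"pixel_size_um": image.pixel_size}))


def read_raster(path, pixel_size: float | None = None) -> RasterImage:
    """Read a raster written by :func:`write_raster` (or any gray image).

    Pixels with value > 127 are covered.  ``pixel_size`` overrides (or
    supplies, when no sidecar exists) the physical scale.
    """
    path = Path(path)
    with Image.open(path) as im:
        if im.mode not in ("1", "L"):
            raise ValueError(f"unsupported raster mode {im.mode!r} (need 1-bit or 8-bit gray)")
        arr = np.asarray(im.convert("L"))
    if pixel_size is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise ValueError("pixel_size not given and no sidecar metadata found")
        pixel_size = float(json.loads(sidecar.read_text())["pixel_size_um"])
    return RasterImage(arr > 127, pixel_size)
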