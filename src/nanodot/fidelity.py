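"""Design-vs-print quality control.

After a dot layout is fabricated and transferred (e.g. printed as
fluorescent protein), the print is imaged, thresholded to binary, and
overlaid on the design bitmap; design dots with no counterpart in the print
are counted as missing and the fraction recovered is the print fidelity.

Because real micrographs need microscopy hardware, a synthetic print
simulator is included: it drops a seeded subset of design dots, blurs with
a Gaussian point-spread function, rescales to 8-bit and adds read noise,
recording the dropped dots as ground truth so the whole QC pipeline is
testable end-to-end.  Registration between design and print is assumed
done (synthetic prints are generated pre-aligned).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .raster import RasterImage

__all__ = [
    "PrintSimulation",
    "FidelityReport",
    "simulate_print",
    "threshold_binarize",
    "overlay_count_missing",
]

#: 8-connectivity: squares touching corner-to-corner count as one spot.
_STRUCT = np.ones((3, 3), dtype=bool)


@dataclass
class PrintSimulation:
    """Synthetic print image with ground-truth dropout list."""

    image: np.ndarray  # uint8 grayscale
    pixel_size: float
    n_dots: int  # connected dots in the design
    removed: np.ndarray  # labels of the dropped dots (ground truth)
    psf_sigma: float
    noise_sd: float


@dataclass
class FidelityReport:
    """Missing-dot count from a design/print overlay."""

    considered: int
    missing: int
    min_overlap: float
    threshold_lo: int | None = None
    threshold_hi: int | None = None

    @property
    def fidelity(self) -> float:
        if self.considered == 0:
            return 1.0
        return 1.0 - self.missing / self.considered


def simulate_print(
    design: RasterImage,
    psf_sigma: float = 0.1,
    dropout_fraction: float = 0.0,
    noise_sd: float = 5.0,
    seed: int = 0,
    n_dropout: int | None = None,
) -> PrintSimulation:
    """Simulate a fluorescence image of a printed design.

    A seeded random subset of the design's connected dots is removed
    (``n_dropout`` exact count, or ``dropout_fraction`` of all dots), the
    binary image is blurred with a Gaussian PSF of width ``psf_sigma`` (µm),
    scaled to 8-bit, and Gaussian noise of ``noise_sd`` gray levels is
    added and clipped to [0, 255].
    """
    if psf_sigma < 0:
        raise ValueError("psf_sigma must be non-negative")
    if not 0.0 <= dropout_fraction < 1.0:
        raise ValueError("dropout_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    labels, n_dots = ndimage.label(design.pixels, structure=_STRUCT)
    k = n_dropout if n_dropout is not None else int(round(dropout_fraction * n_dots))
    if k > n_dots:
        raise ValueError(f"cannot drop {k} of {n_dots} dots")
    removed = np.sort(rng.choice(np.arange(1, n_dots + 1), size=k, replace=False))
    kept = design.pixels & ~np.isin(labels, removed)

    img = kept.astype(float)
    if psf_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=psf_sigma / design.pixel_size)
    img = img * 255.0
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return PrintSimulation(img, design.pixel_size, n_dots, removed, psf_sigma, noise_sd)


def threshold_binarize(image: np.ndarray, lo: int = 31, hi: int = 255,
                       pixel_size: float = 1.0) -> RasterImage:
    """Binarize a grayscale image: pixel on iff lo <= value <= hi.

    The defaults reproduce the ImageJ boundary values (31, 255) used for
    printed-IgG micrographs.
    """
    if not 0 <= lo <= hi <= 255:
        raise ValueError("need 0 <= lo <= hi <= 255")
    arr = np.asarray(image)
    return RasterImage((arr >= lo) & (arr <= hi), pixel_size)


def overlay_count_missing(
    design: RasterImage,
    print_binary: RasterImage,
    min_overlap: float = 0.25,
) -> FidelityReport:
    """Overlay a binarized print on the design and count missing dots.

    A connected design dot is missing when fewer than ``min_overlap`` of
    its pixels are covered in the print (a quantitative proxy for counting
    unmatched "yellow" dots in a two-colour merge).  Images must share
    dimensions and pixel size.
    """
    if design.shape != print_binary.shape:
        raise ValueError(f"shape mismatch: {design.shape} vs {print_binary.shape}")
    if abs(design.pixel_size - print_binary.pixel_size) > 1e-12:
        raise ValueError("pixel size mismatch")
    labels, n_dots = ndimage.label(design.pixels, structure=_STRUCT)
    if n_dots == 0:
        return FidelityReport(0, 0, min_overlap)
    idx = np.arange(1, n_dots + 1)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, idx)
    covered = ndimage.sum_labels(print_binary.pixels.astype(float), labels, idx)
    missing = int(np.count_nonzero(covered / sizes < min_overlap))
    return FidelityReport(n_dots, missing, min_overlap)
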