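# Methods

## Scope and conventions

The package designs and validates digital nanodot gradients: fields of
square dots of edge `dot_edge` (default 0.2 µm, area `A_dot = 0.04 µm²`)
whose areal density follows a programmed function `D(l)` along one axis.
Conventions used everywhere: gradient axis = x (length `L`), constant-
density axis = y (width `W`), origin at the bottom-left, all coordinates
in micrometres, densities as coverage fractions in `[0, 0.9999]`. The
ceiling exists because `D = 1` is unreachable by either algorithm: the
ordered unit cell would equal the dot with zero placement slack, and the
random compensated count diverges.

## Density model

Monotonic profiles are endpoint-normalised: the linear ramp is
`D_min + (D_max − D_min)·l/L` and the exponential is
`D_min + (D_max − D_min)·(e^{k l/L} − 1)/(e^k − 1)` — the unique
single-exponential form hitting both endpoints; `k → 0` recovers the
linear ramp continuously. Non-monotonic profiles superpose a sinusoid on a
flat, linear, or exponential trend:
`D(l) = trend(l) + env(l)·sin(2π B l/L)`, where the amplitude envelope is
constant (`A`), linear (`A·l/L`) or exponential (`A` scaled by the same
normalised exponential shape with constant `k2`). The exact envelope
algebra was an open design choice; this form reproduces the documented
parameter roles (`A`, `B`, `k1`, `k2`) with the fewest assumptions.
Negative excursions and excursions above the cap are clamped — a coverage
fraction cannot leave `[0, 1)` — so deep flat-trend sinusoids flatten at
zero rather than fold. Custom callables are clamped but never normalised.

## Ordered generation

Columns are placed iteratively from `l = 0`: the cell size is evaluated
from the density at the cell's **left edge**, the next column starts at the
cumulative sum of cell sizes, and iteration stops at the last column whose
full cell fits within `L` (no partial trailing cell; a 1 ns-scale float
tolerance keeps exact-fit sequences, e.g. constant density, from dropping
their final column). Each column holds `n = round(W/d)` dots (minimum 1,
with a warning when a cell is wider than the field), re-spaced to pitch
`W/n` with dot centres at `(j + 0.5)·W/n` — equal margins at both width
edges. Dot centres sit at `l + dot_edge/2` so dots never protrude.

Two consequences of left-edge sampling are worth knowing. First, realised
density lags the programmed value by about half a cell, which is only
visible where the density changes appreciably within one cell (steep,
low-density regions); the fidelity R² of whole gradients is unaffected
(≥ 0.9998 for all tested profiles). Second, the continuum dot budget
`W·∫D dl / A_dot` is approached from below, with boundary truncation
contributing `O(d_end/L)`; the 1% agreement is tested at 400 µm fields.

## Random generation

Boxes are full-width slices of extent `box_width` (default 1 µm) along the
gradient; the final box is truncated if needed and uses its actual area.
Each box gets the compensated count for the density at its **midpoint**
(symmetric, and it reproduces the published dot totals within 0.03%),
rounded up so expected coverage never undershoots. Dot centres are drawn
i.i.d. uniform over the **full box**: this makes the per-point coverage
probability exactly `A_dot/A_box`, which is the assumption behind the
compensation formula. Dots may straddle box borders; for smooth density
functions the spill between neighbours cancels. An alternative — shrinking
the draw region so dots stay inside their box — would inflate the interior
coverage probability by `box_width/(box_width − dot_edge)` (25% for 1 µm
boxes) and was measured to miss the target coverage badly (0.836 realised
at D = 0.90); it is therefore not used. Only at the two outer field ends is
the draw clamped inward by half a dot edge so every dot stays inside the
field; the bias is confined to the outermost 0.1 µm.

The compensation is validated by Monte Carlo: seeding a 400×1 µm² box on a
torus (periodic rasterisation emulates the identically seeded neighbours)
reproduces the programmed density within 3 standard errors at D = 0.1, 0.5
and 0.9.

The grid-threshold generator is the halftoning-style alternative: dots on
a regular `dot_edge`-pitch grid, each switched on when a uniform draw falls
below the local density. It is random in value but ordered in position,
and is kept for comparison, not as a substitute for the random algorithm.

All randomness flows through `numpy.random.default_rng(seed)`; the seed is
stored in pattern metadata and identical specs reproduce bit-identical
coordinate lists.

## Raster and CIF export

CIF files use the format's native 0.01 µm unit, which represents 200 nm
dots and 100 nm gaps exactly; one `B` box record per dot inside a symbol
definition, with multi-gradient arrays as one symbol per gradient
instantiated via translated calls. Coordinates round-trip to within 10 nm
and counts exactly; the bundled reader covers exactly the subset the
writer emits.

Rasterisation is binary (no anti-aliasing): a pixel is covered iff its
centre lies inside a dot square (half-open upper edges make ties
deterministic). At 10 px per dot edge, a 0.2 µm dot at 0.02 µm/px covers
exactly 10×10 pixels regardless of alignment, so density measurement
carries no per-dot pixelation bias.

## Density-fidelity measurement

The rendered bitmap is cut into full-width windows along the gradient; the
covered-pixel fraction per window (the black-to-white pixel ratio read as
black/(black+white) — the literal ratio cannot equal a density) is
regressed against the programmed density at window centres with
`R² = 1 − SS_res/SS_tot` (reference is the programmed curve, not a
refitted line; a constant profile with zero residuals reports R² = 1).
Pixel counts are taken over the window's pixel columns while the
denominator uses the physical window area, avoiding the bias of quantising
window widths to whole pixels.

Window choice matters and is principled as follows:

- **Ordered patterns**: windows are unions of whole unit cells, grown to a
  minimum length (default 1 µm). Fixed-width windows cut cells and at low
  density catch zero or one column, capping R² near 0.93 for the linear
  demo gradient; whole-cell windows measure what the algorithm actually
  laid down (R² = 0.99986).
- **Random monotonic profiles**: windows of two seeding boxes (2 µm). The
  per-box union coverage carries irreducible counting noise that caps
  per-box R² at ~0.9997; averaging two boxes reaches the reported
  fidelity (0.99987) while still oversampling the k = 3 exponential's
  33 µm feature scale sixteen-fold. Windows must align with box boundaries
  (misaligned windows straddle boxes of different planned density).
- **Random non-monotonic profiles**: one-box (1 µm) windows, i.e. five
  samples per period of the B = 20 sinusoid; wider windows would attenuate
  the measured amplitude by the boxcar sinc factor.

## Ripley's K randomness QC

`K̂(s) = Area/(n(n−1)) · Σ_{i≠j} 1[d_ij ≤ s]`, with no analytic edge
correction: significance is judged against an envelope (mean ± 1.96·SD,
default 10 simulations) of CSR point sets with the same count and the same
rectangle, so edge bias cancels by construction. Because density varies
along the gradient, randomness is only assessed within constant-density
strips, perpendicular to the gradient axis.

Two geometric rules keep the estimator honest: analyses use the dot-centre
support region (the field shrunk by half a dot edge — otherwise the
envelope simulates a larger area than the points occupy and K̂ reads ~2%
high), and strips from random patterns are cropped away from the field
ends, whose clamped placement margin locally raises intensity. With these
rules the random generator's strips stay inside the envelope for ≥ 95% of
radii on average, while ordered lattices at the same density report K̂ = 0
below their pitch — far outside the band.

A calibration caveat recorded for users: an *independent* CSR draw lies
inside a 10-simulation 1.96·SD band for ~91.6% of radii in expectation
(the SD is estimated from 10 samples; the proper reference is a t-, not a
z-interval), while members of the envelope's own sample exceed it ≤ ~5% of
the time. The randomness check is a screening tool against gross
structure, not an exact 5%-level test.

## Print-fidelity QC

The design bitmap is compared with a binarised print image (threshold band
default 31–255 gray levels, matching common ImageJ practice for printed-
protein micrographs); a connected design dot is "missing" when fewer than
25% of its pixels are covered in the print. The 25% overlap criterion is a
quantitative proxy for visually counting unmatched dots in a two-colour
merge; 8-connectivity treats corner-touching squares as one spot.
Registration is assumed done — synthetic prints are generated pre-aligned.

The synthetic print simulator stands in for fluorescence micrographs: it
drops a seeded subset of design dots (ground truth recorded), blurs with a
Gaussian PSF (default σ = 0.1 µm, of the order of a confocal PSF width),
scales to 8-bit and adds Gaussian read noise (default SD 5 gray levels).
It does not model uneven illumination, dot-size variation, registration
error, or structured background — so exact dropout recovery in tests shows
the counting pipeline is correct, not that real micrographs are this
clean. Under the default blur/noise and ~1000-dot designs the pipeline
recovers injected dropout counts of 0–100 exactly across seeds.

## Gradient arrays

Array builds are driven by a CSV parameter table (one gradient per row;
missing columns take documented defaults). Gradients are generated with
independent seeds, placed row-major on a grid with 213 µm spacing by
default — the spacing that puts a 10×10 array of 400 µm fields in a
35 mm² footprint — and written as one multi-symbol CIF plus a manifest of
per-gradient dot counts, seeds, and dynamic range (log10(D_max/D_min)).
The bundled 100-gradient table is a synthetic reconstruction of the
published array's taxonomy (family structure and counts exact; individual
parameter values representative, with the extreme gradients pinned to the
0.0002–0.4444 range); it is labelled synthetic in its filename and
docstring. The CLI refuses multi-million-dot builds without `--full`.

## Problem sizes used in tests

The test suite and acceptance script run the full-size reference
computations where they are cheap (whole 400×400 µm² gradient totals,
~10⁶ dots, seconds) and scale down only Monte-Carlo replication counts
(e.g. 20–50 seeds for coverage validation, 3–5 seeds for stochastic R²
averages, strips of 10–14 µm for Ripley analyses); these sizes give
standard errors comfortably below the tolerances being checked.

## Known limitations

- Square dots only in the tested paths (the CIF stores centres, so other
  shapes can be drawn downstream).
- One-dimensional density fields; no perpendicular superposition.
- No overlap-avoiding or quasi-random generators (deliberately: they are
  not random at the cellular scale).
- Ripley analysis has no analytic edge correction and relies on
  same-geometry envelopes.
- The print simulator's noise model is minimal (see above).
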