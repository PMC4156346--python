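"""Parameter tables and multi-gradient array composition.

A gradient array is driven by a CSV table with one row per gradient
(function kind, algorithm, density range and shape parameters, geometry,
seed).  Gradients are generated independently, placed on a rectangular
grid, and written as one multi-symbol CIF plus a CSV manifest of per-
gradient dot counts and seeds.

The bundled 100-gradient table (``data/gradient_array_100_synthetic.csv``)
is a synthetic reconstruction of a published 100-gradient array taxonomy:
20 ordered gradients (10 linear, 10 exponential), 10 linear + 10
exponential random twins of the same functions, 14 flat sinusoid controls,
and 46 sinusoid-on-trend gradients, spanning densities 0.0002-0.4444 over
400x400 µm² fields.  The family structure and counts are exact; individual
parameter values are representative choices, not the authors' originals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .cif import write_cif_array
from .density import DensityFunction
from .generate import generate
from .pattern import GradientSpec

__all__ = [
    "TABLE_COLUMNS",
    "load_array_table",
    "hundred_gradient_table",
    "bundled_table_path",
    "ArrayLayout",
    "build_array",
]

TABLE_COLUMNS = [
    "id",
    "kind",
    "algorithm",
    "d_min",
    "d_max",
    "k",
    "amplitude",
    "oscillations",
    "k1",
    "k2",
    "envelope",
    "width",
    "length",
    "dot_edge",
    "box_width",
    "seed",
]

_DEFAULTS = {
    "k": 0.0,
    "amplitude": 0.0,
    "oscillations": 0.0,
    "k1": 0.0,
    "k2": 0.0,
    "envelope": "constant",
    "dot_edge": 0.2,
    "box_width": 1.0,
}


def _row_to_spec(row: pd.Series, index: int) -> GradientSpec:
    def get(col, default=None):
        v = row.get(col)
        if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
            if default is None and col not in _DEFAULTS:
                raise ValueError(f"missing required column {col!r}")
            return _DEFAULTS.get(col, default) if default is None else default
        return v

    density = DensityFunction(
        kind=str(get("kind")),
        d_min=float(get("d_min")),
        d_max=float(get("d_max")),
        length=float(get("length")),
        k=float(get("k")),
        amplitude=float(get("amplitude")),
        oscillations=float(get("oscillations")),
        k1=float(get("k1")),
        k2=float(get("k2")),
        envelope=str(get("envelope")),
    )
    return GradientSpec(
        width=float(get("width")),
        length=float(get("length")),
        density=density,
        algorithm=str(get("algorithm")),
        dot_edge=float(get("dot_edge")),
        box_width=float(get("box_width")),
        seed=int(get("seed", index)),
        label=str(get("id", index)),
    )


def load_array_table(path) -> list[GradientSpec]:
    """Read a gradient parameter CSV into validated GradientSpecs.

    Malformed rows are reported together with their (1-based) row numbers;
    an empty table is an error.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"empty parameter table: {path}")
    specs: list[GradientSpec] = []
    errors: list[str] = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            specs.append(_row_to_spec(row, i))
        except (ValueError, KeyError, TypeError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValueError("invalid parameter table:\n" + "\n".join(errors))
    return specs


def hundred_gradient_table(
    width: float = 400.0, length: float = 400.0, seed0: int = 1000
) -> pd.DataFrame:
    """Build the synthetic 100-gradient parameter table (see module docs).

    Gradients 1-10 / 81-90 are the same linear functions as ordered and
    random twins (gradient 1 and 81 span the full 0.0002-0.4444 range);
    11-20 / 91-100 are exponential twins (k = 3); 21-30 are flat-trend
    sinusoid controls with linearly growing amplitude, 31-34 with constant
    amplitude; 35-36 linear trend + linear amplitude envelope; 37-40
    exponential trend + exponential envelope; 41-60 linear trend + constant
    amplitude; 61-80 exponential trend + constant amplitude.
    """
    d_mins = np.round(np.geomspace(0.0002, 0.003, 10), 6)
    d_max = 0.4444
    rows: list[dict] = []

    def add(i, kind, algorithm, d_min, d_maxv, **kw):
        row = {
            "id": i,
            "kind": kind,
            "algorithm": algorithm,
            "d_min": d_min,
            "d_max": d_maxv,
            "width": width,
            "length": length,
            "seed": seed0 + i,
            **_DEFAULTS,
            **kw,
        }
        rows.append(row)

    for j in range(10):  # 1-10 ordered linear
        add(j + 1, "linear", "ordered", d_mins[j], d_max)
    for j in range(10):  # 11-20 ordered exponential
        add(j + 11, "exponential", "ordered", d_mins[j], d_max, k=3.0)
    amps = np.round(np.linspace(0.02, 0.15, 10), 4)
    oscs = np.arange(5, 55, 5)
    for j in range(10):  # 21-30 flat controls, growing amplitude
        add(j + 21, "sinusoid_flat", "random", 0.2, 0.2,
            amplitude=amps[j], oscillations=float(oscs[j]), envelope="linear")
    for j in range(4):  # 31-34 flat controls, constant amplitude
        add(j + 31, "sinusoid_flat", "random", 0.2, 0.2,
            amplitude=0.05 + 0.03 * j, oscillations=10.0 + 10.0 * j)
    for j in range(2):  # 35-36 linear trend + linear envelope
        add(j + 35, "sinusoid_linear_trend", "random", 0.01, 0.30,
            amplitude=0.05 + 0.05 * j, oscillations=20.0, envelope="linear")
    for j in range(4):  # 37-40 exponential trend + exponential envelope
        add(j + 37, "sinusoid_exponential_trend", "random", 0.01, 0.30,
            amplitude=0.05 + 0.025 * j, oscillations=10.0 + 10.0 * j,
            k1=3.0, k2=3.0, envelope="exponential")
    amps20 = np.round(np.linspace(0.01, 0.1, 20), 4)
    oscs20 = np.tile(np.arange(10, 60, 10), 4)[:20].astype(float)
    for j in range(20):  # 41-60 linear trend + constant amplitude
        add(j + 41, "sinusoid_linear_trend", "random", 0.11, 0.30,
            amplitude=amps20[j], oscillations=oscs20[j])
    for j in range(20):  # 61-80 exponential trend + constant amplitude
        add(j + 61, "sinusoid_exponential_trend", "random", 0.11, 0.30,
            amplitude=amps20[j], oscillations=oscs20[j], k1=3.0)
    for j in range(10):  # 81-90 random linear twins of 1-10
        add(j + 81, "linear", "random", d_mins[j], d_max)
    for j in range(10):  # 91-100 random exponential twins of 11-20
        add(j + 91, "exponential", "random", d_mins[j], d_max, k=3.0)

    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def bundled_table_path() -> Path:
    """Path of the packaged synthetic 100-gradient parameter table."""
    return Path(resources.files("nanodot") / "data" / "gradient_array_100_synthetic.csv")


@dataclass
class ArrayLayout:
    """Grid placement of generated gradients."""

    placements: list  # (GradientSpec, (offset_x_um, offset_y_um))
    shape: tuple[int, int]  # rows x cols
    spacing: float  # µm between neighbouring fields
    footprint_mm2: float
    manifest: pd.DataFrame


def build_array(
    specs: list[GradientSpec],
    shape: tuple[int, int] | None = None,
    spacing: float = 213.0,
    out_cif=None,
    out_manifest=None,
) -> ArrayLayout:
    """Generate every gradient, place them on a grid, and export.

    Placement is row-major from the bottom-left; cell pitch is the largest
    field dimension plus ``spacing`` (negative spacing would overlap
    placements and is rejected).  The default 213 µm spacing puts a 10x10
    array of 400x400 µm² gradients inside a ~35 mm² footprint
    ((10*0.4 + 9*0.213 mm)² = 35.0 mm²).  Returns the
    layout with a manifest of per-gradient dot counts and seeds; optionally
    writes the combined multi-symbol CIF and the manifest CSV.
    """
    if not specs:
        raise ValueError("no gradient specs given")
    if spacing < 0:
        raise ValueError("negative spacing overlaps placements")
    n = len(specs)
    if shape is None:
        cols = int(math.ceil(math.sqrt(n)))
        shape = (int(math.ceil(n / cols)), cols)
    rows, cols = shape
    if rows * cols < n:
        raise ValueError(f"grid {rows}x{cols} too small for {n} gradients")
    pitch_x = max(s.length for s in specs) + spacing
    pitch_y = max(s.width for s in specs) + spacing

    placements = []
    records = []
    cif_placements = []
    for i, spec in enumerate(specs):
        r, c = divmod(i, cols)
        ox, oy = c * pitch_x, r * pitch_y
        pattern = generate(spec)
        placements.append((spec, (ox, oy)))
        name = f"g{spec.label or i + 1}"
        cif_placements.append((pattern, (ox, oy), name))
        records.append(
            {
                "id": spec.label or str(i + 1),
                "kind": spec.density.kind,
                "algorithm": spec.algorithm,
                "seed": spec.seed,
                "n_dots": pattern.n_dots,
                "d_min": spec.density.d_min,
                "d_max": spec.density.d_max,
                "dynamic_range_om": spec.density.dynamic_range(),
                "offset_x_um": ox,
                "offset_y_um": oy,
            }
        )
    manifest = pd.DataFrame(records)

    used_cols = min(cols, n)
    used_rows = math.ceil(n / cols)
    ext_x = (used_cols - 1) * pitch_x + max(s.length for s in specs)
    ext_y = (used_rows - 1) * pitch_y + max(s.width for s in specs)
    footprint = ext_x * ext_y / 1e6  # µm² -> mm²

    if out_cif is not None:
        write_cif_array(cif_placements, out_cif)
    if out_manifest is not None:
        manifest.to_csv(out_manifest, index=False)
    return ArrayLayout(placements, (rows, cols), spacing, footprint, manifest)
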