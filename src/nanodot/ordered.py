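"""Ordered DNG generation by the unit-cell algorithm.

Each column of dots occupies a virtual square "unit cell" whose side d is
set by the local density: d = sqrt(A_dot / D), so one dot per cell realises
coverage D exactly.  Columns are laid down iteratively along the gradient
axis, each starting where the previous cell ends (cumulative sum of cell
sizes), so the pitch tracks the density function continuously instead of in
steps.  Within a column the integer number of dots that fits the width is
re-spaced symmetrically so both margins are equal.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .pattern import GradientSpec, NanodotPattern

__all__ = ["unit_cell_dim", "generate_ordered", "column_window_edges"]


def unit_cell_dim(density: float, dot_area: float) -> float:
    """Side of the square unit cell holding one dot at coverage ``density``.

    d = sqrt(A_dot / D).  D must be positive: a density of zero would
    require an infinitely large unit cell.
    """
    if not density > 0:
        raise ValueError("density must be positive (zero needs an infinite cell)")
    if density > 1:
        raise ValueError("density cannot exceed 1")
    return math.sqrt(dot_area / density)


def generate_ordered(spec: GradientSpec) -> NanodotPattern:
    """Place columns of equally spaced dots with pitch set by D(l).

    Column i sits at the left edge l_i of its unit cell, with
    l_{i+1} = l_i + d_i and d_i = sqrt(A_dot / D(l_i)); iteration stops
    when the next full cell would not fit within the field length.  The
    column holds n_i = round(W / d_i) dots (at least one) re-spaced to
    pitch W / n_i, centred so the margins at both width edges are equal.
    """
    if spec.algorithm != "ordered":
        raise ValueError("spec.algorithm must be 'ordered'")
    density = spec.density
    w, length, a_dot = spec.width, spec.length, spec.dot_area

    col_pos: list[float] = []
    col_dim: list[float] = []
    col_n: list[int] = []
    chunks: list[np.ndarray] = []

    l = 0.0
    while True:
        d = unit_cell_dim(density(l), a_dot)
        n = round(w / d)
        if n < 1:
            warnings.warn(
                f"unit cell ({d:.3g} µm) wider than the field; "
                "placing a single centred dot",
                stacklevel=2,
            )
            n = 1
        pitch = w / n
        ys = (np.arange(n) + 0.5) * pitch
        xs = np.full(n, l + spec.dot_edge / 2)
        chunks.append(np.column_stack([xs, ys]))
        col_pos.append(l)
        col_dim.append(d)
        col_n.append(n)

        l_next = l + d
        if l_next >= length - 1e-9:
            break
        d_next = unit_cell_dim(density(min(l_next, length)), a_dot)
        if l_next + d_next > length + 1e-9:  # next full cell must fit
            break
        l = l_next

    centers = np.concatenate(chunks)
    meta = {
        "algorithm": "ordered",
        "seed": spec.seed,
        "column_positions": np.array(col_pos),
        "column_cell_dims": np.array(col_dim),
        "column_counts": np.array(col_n),
        "spec_label": spec.label,
    }
    return NanodotPattern(centers, spec.dot_edge, w, length, meta)


def column_window_edges(pattern: NanodotPattern, min_length: float = 1.0) -> np.ndarray:
    """Window edges made of whole unit cells, each window >= ``min_length`` µm.

    Density measured over a window that cuts through a unit cell is biased
    by the partial cell, so fidelity measurements group consecutive whole
    cells ("averaged over several columns") until the window is at least
    ``min_length`` long.  Returns the window boundary positions along the
    gradient axis.
    """
    pos = pattern.metadata.get("column_positions")
    dims = pattern.metadata.get("column_cell_dims")
    if pos is None or dims is None:
        raise ValueError("pattern has no column metadata (not an ordered pattern?)")
    edges = [0.0]
    i = 0
    while i < len(pos):
        j = i
        while j < len(pos):
            end = pos[j] + dims[j]
            j += 1
            if end - edges[-1] >= min_length:
                break
        edges.append(float(end))
        i = j
    return np.asarray(edges)
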