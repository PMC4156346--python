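"""Caltech Intermediate Format (CIF) export and re-import of dot layouts.

CIF is a plain-text vector format for lithography masks; storing one box
record per nanodot keeps multi-million-dot files compact and leaves the dot
shape re-definable downstream.  The native CIF unit is 0.01 µm = 10 nm,
which represents 200 nm dots and 100 nm gaps exactly; coordinates are
rounded to integer units, so positions round-trip to within 10 nm.

Writer emits CIF 2.0: one symbol definition (``DS``/``DF``) per pattern
containing ``B width height cx cy;`` records, plus top-level ``C`` calls
(with ``T`` translations for array placement).  The bundled reader parses
boxes, symbol definitions and translated calls — enough to round-trip
anything this package writes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .pattern import NanodotPattern

__all__ = ["CIF_UNIT_UM", "write_cif", "write_cif_array", "read_cif", "CifBox"]

#: micrometres per CIF integer unit (10 nm).
CIF_UNIT_UM = 0.01


@dataclass(frozen=True)
class CifBox:
    """One box record, in µm: centre (cx, cy), extents (w, h)."""

    cx: float
    cy: float
    w: float
    h: float


def _u(value_um: float) -> int:
    return int(round(value_um / CIF_UNIT_UM))


def _symbol_lines(pattern: NanodotPattern, index: int, name: str) -> list[str]:
    e = _u(pattern.dot_edge)
    lines = [f"DS {index} 1 1;", f"9 {name};", "L L1;"]
    cx = np.rint(pattern.centers[:, 0] / CIF_UNIT_UM).astype(np.int64)
    cy = np.rint(pattern.centers[:, 1] / CIF_UNIT_UM).astype(np.int64)
    lines.extend(f"B {e} {e} {x} {y};" for x, y in zip(cx, cy))
    lines.append("DF;")
    return lines


def write_cif(pattern: NanodotPattern, path, name: str = "dng") -> None:
    """Write one pattern as a single-symbol CIF 2.0 file."""
    if pattern.n_dots == 0:
        raise ValueError("refusing to write an empty symbol")
    lines = ["(CIF 2.0; 1 unit = 10 nm);"]
    lines += _symbol_lines(pattern, 1, name)
    lines += ["C 1;", "E"]
    Path(path).write_text("\n".join(lines) + "\n")


def write_cif_array(
    placements: list[tuple[NanodotPattern, tuple[float, float], str]], path
) -> None:
    """Write several patterns as one multi-symbol CIF.

    ``placements`` is a list of (pattern, (offset_x_um, offset_y_um), name);
    each pattern becomes its own symbol, instantiated once with a ``T``
    translation.
    """
    if not placements:
        raise ValueError("no placements given")
    lines = ["(CIF 2.0; 1 unit = 10 nm);"]
    for i, (pattern, _, name) in enumerate(placements, start=1):
        if pattern.n_dots == 0:
            raise ValueError(f"placement {name!r} is empty")
        lines += _symbol_lines(pattern, i, name)
    for i, (_, (ox, oy), _) in enumerate(placements, start=1):
        lines.append(f"C {i} T {_u(ox)} {_u(oy)};")
    lines.append("E")
    Path(path).write_text("\n".join(lines) + "\n")


_BOX_RE = re.compile(r"^B\s+(-?\d+)\s+(-?\d+)\s+(-?\d+)\s+(-?\d+)$")
_DS_RE = re.compile(r"^DS\s+(\d+)(?:\s+(\d+)\s+(\d+))?$")
_CALL_RE = re.compile(r"^C\s+(\d+)\s*(.*)$")
_TRANS_RE = re.compile(r"^T\s+(-?\d+)\s+(-?\d+)$")


def read_cif(path) -> list[CifBox]:
    """Parse a CIF file into the flat list of instantiated boxes (µm).

    Supports the subset this package emits: box records inside symbol
    definitions, ``9`` name and ``L`` layer commands, and top-level calls
    with optional ``T`` translations.  Anything else raises.
    """
    text = Path(path).read_text()
    text = re.sub(r"\([^)]*\)", " ", text)  # strip comments
    commands = [c.strip() for c in text.split(";")]

    symbols: dict[int, list[CifBox]] = {}
    scales: dict[int, float] = {}
    current: int | None = None
    boxes: list[CifBox] = []
    instantiated: list[CifBox] = []
    ended = False
    for cmd in commands:
        if not cmd or ended:
            if cmd and ended:
                raise ValueError("commands after E")
            continue
        if cmd == "E":
            ended = True
            continue
        if cmd.startswith("9") or cmd.startswith("L"):
            continue
        m = _DS_RE.match(cmd)
        if m:
            if current is not None:
                raise ValueError("nested DS")
            current = int(m.group(1))
            a = int(m.group(2) or 1)
            b = int(m.group(3) or 1)
            scales[current] = a / b
            boxes = []
            continue
        if cmd == "DF":
            if current is None:
                raise ValueError("DF without DS")
            symbols[current] = boxes
            current = None
            continue
        m = _BOX_RE.match(cmd)
        if m:
            if current is None:
                raise ValueError("box outside a symbol definition")
            w, h, x, y = (int(g) for g in m.groups())
            s = scales[current] * CIF_UNIT_UM
            boxes.append(CifBox(x * s, y * s, w * s, h * s))
            continue
        m = _CALL_RE.match(cmd)
        if m:
            if current is not None:
                raise ValueError("call inside a symbol definition")
            idx = int(m.group(1))
            rest = m.group(2).strip()
            dx = dy = 0.0
            if rest:
                t = _TRANS_RE.match(rest)
                if not t:
                    raise ValueError(f"unsupported transformation {rest!r}")
                dx = int(t.group(1)) * CIF_UNIT_UM
                dy = int(t.group(2)) * CIF_UNIT_UM
            if idx not in symbols:
                raise ValueError(f"call to undefined symbol {idx}")
            instantiated.extend(
                CifBox(b.cx + dx, b.cy + dy, b.w, b.h) for b in symbols[idx]
            )
            continue
        raise ValueError(f"unsupported CIF command {cmd!r}")
    if not ended:
        raise ValueError("missing E terminator")
    return instantiated
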