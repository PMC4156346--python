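"""Gradient recipes and generated nanodot layouts.

Axis convention used throughout the package: the gradient axis is x
(length ``L``, density varies along it), the constant-density axis is y
(width ``W``).  The origin is the bottom-left corner of the field and all
coordinates are in micrometres.  Dots are squares of side ``dot_edge``
identified by their centre coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .density import DensityFunction

__all__ = ["GradientSpec", "NanodotPattern", "ALGORITHMS"]

ALGORITHMS = ("ordered", "random", "grid_threshold")


@dataclass(frozen=True)
class GradientSpec:
    """Full recipe for one digital nanodot gradient.

    ``width``/``length`` are the field dimensions W x L in µm; ``dot_edge``
    is the square nanodot side (µm; 0.2 µm = the 200 nm dots used for
    e-beam patterning); ``box_width`` is the seeding-box extent along the
    gradient axis for the random algorithm.
    """

    width: float
    length: float
    density: DensityFunction
    algorithm: str = "ordered"
    dot_edge: float = 0.2
    box_width: float = 1.0
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.length > 0):
            raise ValueError("field dimensions must be positive")
        if not self.dot_edge > 0:
            raise ValueError("dot_edge must be positive")
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.algorithm == "random" and self.box_width < self.dot_edge:
            raise ValueError("box_width must be at least one dot edge")
        if abs(self.density.length - self.length) > 1e-9:
            raise ValueError(
                "density.length must equal the field length "
                f"({self.density.length} != {self.length})"
            )

    @property
    def dot_area(self) -> float:
        """Nanodot area A_dot = dot_edge**2 (µm²)."""
        return self.dot_edge * self.dot_edge


@dataclass
class NanodotPattern:
    """A generated layout: dot centres (µm), dot size and field bounds.

    ``metadata`` records provenance (algorithm, seed, planned per-column or
    per-box counts) needed for validation and manifests.
    """

    centers: np.ndarray  # shape (n, 2): columns x, y in µm
    dot_edge: float
    width: float
    length: float
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)

    @property
    def n_dots(self) -> int:
        return int(self.centers.shape[0])

    @property
    def dot_area(self) -> float:
        return self.dot_edge * self.dot_edge

    def translated(self, dx: float, dy: float) -> "NanodotPattern":
        """Return a copy shifted by (dx, dy) µm (array placement)."""
        return NanodotPattern(
            self.centers + np.array([dx, dy]),
            self.dot_edge,
            self.width,
            self.length,
            dict(self.metadata),
        )

    def center_bounds(self) -> tuple[float, float, float, float]:
        """Support rectangle of dot centres: the field shrunk by half a dot
        edge on every side.  Spatial statistics (Ripley's K) should use this
        region so the estimator's intensity matches the placement support."""
        h = self.dot_edge / 2
        return (h, h, self.length - h, self.width - h)

    def inside_field(self, tol: float = 1e-9) -> bool:
        """True if every dot lies fully inside the field bounds."""
        if self.n_dots == 0:
            return True
        h = self.dot_edge / 2 - tol
        x, y = self.centers[:, 0], self.centers[:, 1]
        return bool(
            (x >= h).all()
            and (x <= self.length - h).all()
            and (y >= h).all()
            and (y <= self.width - h).all()
        )
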