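"""Single entry point dispatching a GradientSpec to its generator."""

from __future__ import annotations

from .ordered import generate_ordered
from .pattern import GradientSpec, NanodotPattern
from .randomized import generate_random, grid_threshold_pattern

__all__ = ["generate"]

_GENERATORS = {
    "ordered": generate_ordered,
    "random": generate_random,
    "grid_threshold": grid_threshold_pattern,
}


def generate(spec: GradientSpec) -> NanodotPattern:
    """Generate the nanodot layout for ``spec`` with its chosen algorithm."""
    return _GENERATORS[spec.algorithm](spec)
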