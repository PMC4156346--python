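"""Parametric one-dimensional density profiles for digital nanodot gradients.

A digital nanodot gradient (DNG) encodes a surface-bound concentration
gradient as the areal density ``D(l)`` of fixed-size nanodots, where ``l``
is the position along the gradient axis in micrometres.  Density is a
dimensionless coverage fraction (dot area / total area).

Supported profile shapes:

``linear``
    ``D(l) = d_min + (d_max - d_min) * l / L`` — normalised so the ramp
    spans the full dynamic range over the gradient length ``L``.
``exponential``
    ``D(l) = d_min + (d_max - d_min) * (e^(k l / L) - 1) / (e^k - 1)``.
    This is the unique single-exponential form with ``D(0) = d_min`` and
    ``D(L) = d_max``; ``k`` is the (dimensionless) decay constant.  ``k = 0``
    degenerates to the linear ramp.
``sinusoid_flat`` / ``sinusoid_linear_trend`` / ``sinusoid_exponential_trend``
    A sinusoid superposed on a flat, linear, or exponential average trend:
    ``D(l) = trend(l) + envelope(l) * sin(2 pi B l / L)`` with ``B`` the
    number of oscillations over the length.  The amplitude envelope may be
    constant (``A``), linearly increasing (``A l / L``) or exponentially
    increasing (``A`` scaled by the normalised exponential shape with decay
    constant ``k2``); the exponential trend uses decay constant ``k1``.
``custom``
    Any caller-supplied mapping ``l -> D``; clamped but never normalised.

A density of exactly 1 is not realisable — the ordered algorithm would need
a unit cell the size of the dot with zero margin and the random algorithm an
infinite dot count — so every evaluation is clamped to
``[0, MAX_DENSITY] = [0, 0.9999]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "MAX_DENSITY",
    "DensityFunction",
    "eval_linear",
    "eval_exponential",
    "eval_sinusoid",
]

#: Hard ceiling on programmed density (coverage fraction).
MAX_DENSITY = 0.9999

_MONOTONIC_KINDS = frozenset({"linear", "exponential"})
_SINUSOID_KINDS = frozenset(
    {"sinusoid_flat", "sinusoid_linear_trend", "sinusoid_exponential_trend"}
)
_KINDS = _MONOTONIC_KINDS | _SINUSOID_KINDS | {"custom"}
_ENVELOPES = frozenset({"constant", "linear", "exponential"})


def _exp_shape(x: np.ndarray, k: float) -> np.ndarray:
    """Normalised exponential ramp: 0 at x=0, 1 at x=1; linear for k=0."""
    if k == 0:
        return x
    return np.expm1(k * x) / np.expm1(k)


@dataclass(frozen=True)
class DensityFunction:
    """A programmed density profile ``D(l)`` on ``l in [0, length]``.

    Parameters
    ----------
    kind
        One of ``linear``, ``exponential``, ``sinusoid_flat``,
        ``sinusoid_linear_trend``, ``sinusoid_exponential_trend``, ``custom``.
    d_min, d_max
        Density at the start / end of the gradient (coverage fractions).
        For sinusoid kinds these bound the *trend*, not the oscillation.
    length
        Gradient length L in micrometres.
    k
        Decay constant for the ``exponential`` kind.
    amplitude
        Sinusoid amplitude A (density units).
    oscillations
        Number of oscillations B over the gradient length.
    k1, k2
        Decay constants of the exponential trend and of the exponential
        amplitude envelope, respectively (sinusoid kinds).
    envelope
        Amplitude envelope shape: ``constant``, ``linear`` or ``exponential``.
    d_mean
        Mean density of the ``sinusoid_flat`` trend; defaults to
        ``(d_min + d_max) / 2``.
    custom
        Callable ``l -> D`` for the ``custom`` kind (vectorised or scalar).
    """

    kind: str = "linear"
    d_min: float = 0.01
    d_max: float = 0.30
    length: float = 100.0
    k: float = 0.0
    amplitude: float = 0.0
    oscillations: float = 0.0
    k1: float = 0.0
    k2: float = 0.0
    envelope: str = "constant"
    d_mean: float | None = None
    custom: Callable | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown density kind {self.kind!r}")
        if self.envelope not in _ENVELOPES:
            raise ValueError(f"unknown envelope {self.envelope!r}")
        if not self.length > 0:
            raise ValueError("length must be positive")
        if self.kind == "custom":
            if self.custom is None:
                raise ValueError("custom kind requires a callable")
            return
        if not (0.0 <= self.d_min <= MAX_DENSITY and 0.0 < self.d_max <= MAX_DENSITY):
            raise ValueError(
                f"densities must lie in [0, {MAX_DENSITY}]; "
                f"got d_min={self.d_min}, d_max={self.d_max}"
            )
        if self.kind in _MONOTONIC_KINDS and self.d_min > self.d_max:
            raise ValueError("monotonic kinds require d_min <= d_max")

    # -- evaluation ------------------------------------------------------

    def _trend(self, x: np.ndarray) -> np.ndarray:
        span = self.d_max - self.d_min
        if self.kind in ("linear", "sinusoid_linear_trend"):
            return self.d_min + span * x
        if self.kind == "exponential":
            return self.d_min + span * _exp_shape(x, self.k)
        if self.kind == "sinusoid_exponential_trend":
            return self.d_min + span * _exp_shape(x, self.k1)
        # sinusoid_flat
        mean = self.d_mean if self.d_mean is not None else 0.5 * (self.d_min + self.d_max)
        return np.full_like(x, mean)

    def _envelope(self, x: np.ndarray) -> np.ndarray:
        if self.envelope == "constant":
            return np.full_like(x, self.amplitude)
        if self.envelope == "linear":
            return self.amplitude * x
        return self.amplitude * _exp_shape(x, self.k2)

    def __call__(self, l) -> np.ndarray | float:
        """Evaluate D(l); ``l`` may be a scalar or array of positions (µm)."""
        arr = np.asarray(l, dtype=float)
        if np.any(arr < -1e-9) or np.any(arr > self.length + 1e-9):
            raise ValueError(f"position outside [0, {self.length}] µm")
        x = np.clip(arr / self.length, 0.0, 1.0)
        if self.kind == "custom":
            d = np.asarray(self.custom(arr), dtype=float)
        elif self.kind in _SINUSOID_KINDS:
            d = self._trend(x) + self._envelope(x) * np.sin(
                2.0 * np.pi * self.oscillations * x
            )
        else:
            d = self._trend(x)
        d = np.clip(d, 0.0, MAX_DENSITY)
        return float(d) if np.isscalar(l) or np.ndim(l) == 0 else d

    # -- derived quantities ---------------------------------------------

    def mean_density(self, n: int = 10_001) -> float:
        """Trapezoidal mean of D over [0, length] (continuum dot-budget aid)."""
        x = np.linspace(0.0, self.length, n)
        return float(np.trapezoid(self(x), x) / self.length)

    def dynamic_range(self) -> float:
        """Orders of magnitude spanned, log10(d_max / d_min)."""
        if self.d_min <= 0:
            return float("inf")
        return float(np.log10(self.d_max / self.d_min))


# Thin functional aliases mirroring the three named profile families.

def eval_linear(l, spec: DensityFunction):
    """Evaluate a linear ramp specified by ``spec`` at position(s) ``l``."""
    if spec.kind != "linear":
        spec = DensityFunction(
            kind="linear", d_min=spec.d_min, d_max=spec.d_max, length=spec.length
        )
    return spec(l)


def eval_exponential(l, spec: DensityFunction):
    """Evaluate a normalised exponential ramp at position(s) ``l``."""
    if spec.kind != "exponential":
        spec = DensityFunction(
            kind="exponential",
            d_min=spec.d_min,
            d_max=spec.d_max,
            length=spec.length,
            k=spec.k,
        )
    return spec(l)


def eval_sinusoid(l, spec: DensityFunction):
    """Evaluate a sinusoid-superposed profile at position(s) ``l``."""
    if spec.kind not in _SINUSOID_KINDS:
        raise ValueError("spec must be a sinusoid kind")
    return spec(l)
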