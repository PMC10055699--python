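"""Spectral grids and sampled spectral curves.

Everything downstream — filter transmittance, design targets, camera
spectral responses, hyperspectral band maps — lives on a
:class:`SpectralGrid` of vacuum wavelengths in nanometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpectralGrid", "SpectralCurve", "default_grid"]


@dataclass(frozen=True)
class SpectralGrid:
    """Strictly increasing vacuum wavelengths, nm."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 1:
            raise ValueError("grid needs at least one wavelength")
        if np.any(wl <= 0):
            raise ValueError("wavelengths must be positive")
        if wl.size > 1 and np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralGrid):
            return NotImplemented
        return self.wavelengths.shape == other.wavelengths.shape and bool(
            np.array_equal(self.wavelengths, other.wavelengths)
        )

    def __hash__(self) -> int:
        return hash(self.wavelengths.tobytes())

    def trapezoid_weights(self) -> np.ndarray:
        """Integration weights Δλ (trapezoid rule); all-ones for a single sample."""
        wl = self.wavelengths
        if wl.size == 1:
            return np.ones(1)
        w = np.empty_like(wl)
        w[0] = (wl[1] - wl[0]) / 2
        w[-1] = (wl[-1] - wl[-2]) / 2
        w[1:-1] = (wl[2:] - wl[:-2]) / 2
        return w


def default_grid(start: float = 400.0, stop: float = 800.0, step: float = 2.0) -> SpectralGrid:
    """Visible-range default: 400–800 nm in 2 nm steps (N = 201)."""
    n = int(round((stop - start) / step)) + 1
    return SpectralGrid(start + step * np.arange(n))


@dataclass(frozen=True)
class SpectralCurve:
    """Per-wavelength values on a grid (transmittance, response, reflectance...)."""

    grid: SpectralGrid
    values: np.ndarray
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.grid),):
            raise ValueError(
                f"curve has {v.size} values for a grid of {len(self.grid)} wavelengths"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("curve values must be finite")
        object.__setattr__(self, "values", v)

    def require_grid(self, grid: SpectralGrid) -> None:
        if self.grid != grid:
            raise ValueError("spectral grids do not match")
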