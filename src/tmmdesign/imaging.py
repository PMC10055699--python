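"""RGB image formation through a spectral filter and a camera response.

A hyperspectral radiance cube is pushed through two diagonal spectral
weights — the filter transmittance T(λ) and one camera-spectral-response
(CSR) channel per output color — and integrated over wavelength:

    RGB_c(x, y) = exposure · Σ_λ cube(x, y, λ) · T(λ) · CSR_c(λ) · Δλ

with trapezoidal Δλ weights and clipping to [0, 1] only after the
exposure scaling.  The exposure is chosen once per evaluation (so that
the 99th percentile of the *no-filter* image maps to 0.95) and held fixed
across transmittance-curve swaps, keeping swapped images radiometrically
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import SpectralCurve, SpectralGrid, default_grid
from .synthetic import Scene

__all__ = [
    "CameraSpectralResponse",
    "RGBImage",
    "resample_curve",
    "no_filter_curve",
    "default_csr",
    "auto_exposure",
    "synthesize_rgb",
]


@dataclass(frozen=True)
class CameraSpectralResponse:
    """Three nonnegative per-channel sensitivity curves on a common grid."""

    grid: SpectralGrid
    channels: np.ndarray  # (3, N)

    def __post_init__(self) -> None:
        ch = np.asarray(self.channels, dtype=float)
        if ch.shape != (3, len(self.grid)):
            raise ValueError("CSR needs exactly 3 channels on the grid")
        if np.any(ch < 0) or not np.all(np.isfinite(ch)):
            raise ValueError("CSR values must be finite and nonnegative")
        object.__setattr__(self, "channels", ch)


@dataclass(frozen=True)
class RGBImage:
    """H×W×3 image in [0, 1] after exposure normalization."""

    data: np.ndarray
    exposure: float

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3 or d.shape[2] != 3:
            raise ValueError("RGB image must be H×W×3")
        if not np.all(np.isfinite(d)):
            raise ValueError("RGB image must be finite")
        object.__setattr__(self, "data", d)


def resample_curve(curve: SpectralCurve, grid: SpectralGrid) -> SpectralCurve:
    """Linear interpolation onto ``grid`` with edge hold outside the domain.

    Values are clipped to the original curve's range so interpolation
    never manufactures out-of-range transmittance.
    """
    if curve.grid == grid:
        return curve
    v = np.interp(grid.wavelengths, curve.grid.wavelengths, curve.values)
    v = np.clip(v, curve.values.min(), curve.values.max())
    return SpectralCurve(grid, v, name=curve.name)


def no_filter_curve(grid: SpectralGrid) -> SpectralCurve:
    """All-ones transmittance: the bare-camera (no filter) baseline."""
    return SpectralCurve(grid, np.ones(len(grid)), name="no_filter")


def default_csr(grid: SpectralGrid | None = None) -> CameraSpectralResponse:
    """Smooth Gaussian-like R/G/B channels peaking near 600/540/460 nm.

    A stand-in for an untabulated machine-vision sensor response; supply a
    measured CSR to override.
    """
    grid = grid or default_grid()
    wl = grid.wavelengths
    peaks, widths = (600.0, 540.0, 460.0), (45.0, 42.0, 38.0)
    ch = np.stack([np.exp(-0.5 * ((wl - p) / w) ** 2) for p, w in zip(peaks, widths)])
    return CameraSpectralResponse(grid, ch)


def _band_integrals(
    scene: Scene, filter_curve: SpectralCurve, csr: CameraSpectralResponse
) -> np.ndarray:
    """Unscaled Σ_λ cube·T·CSR·Δλ, shape H×W×3."""
    grid = csr.grid
    if not np.array_equal(scene.band_wavelengths, grid.wavelengths):
        raise ValueError("cube bands and CSR grid do not match; resample first")
    filter_curve.require_grid(grid)
    weights = filter_curve.values * grid.trapezoid_weights()  # (N,)
    return np.einsum("hwl,cl,l->hwc", scene.cube, csr.channels, weights, optimize=True)


def auto_exposure(
    scenes: list[Scene] | Scene, csr: CameraSpectralResponse, percentile: float = 99.0, headroom: float = 0.95
) -> float:
    """Exposure scalar mapping the no-filter image's 99th percentile to 0.95."""
    if isinstance(scenes, Scene):
        scenes = [scenes]
    ones = no_filter_curve(csr.grid)
    ref = np.concatenate([_band_integrals(s, ones, csr).ravel() for s in scenes])
    level = float(np.percentile(ref, percentile))
    if level <= 0:
        raise ValueError("scene is dark everywhere; cannot set exposure")
    return headroom / level


def synthesize_rgb(
    scene: Scene,
    filter_curve: SpectralCurve,
    csr: CameraSpectralResponse,
    exposure: float,
) -> RGBImage:
    """Form the three-channel camera image seen through ``filter_curve``."""
    if exposure <= 0:
        raise ValueError("exposure must be positive")
    raw = _band_integrals(scene, filter_curve, csr)
    return RGBImage(np.clip(exposure * raw, 0.0, 1.0), exposure=float(exposure))
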