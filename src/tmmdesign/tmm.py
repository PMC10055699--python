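r"""Transfer-matrix method for lossless multilayer dielectric stacks.

A stack is modelled as an injection medium (index ``n0``, semi-infinite),
``L`` coherent inner layers with real indices and thicknesses in nm, and a
semi-infinite substrate.  For each polarization the 2×2 complex transfer
matrix of layer *j* is

    M_j = diag(e^{-i δ_j}, e^{+i δ_j}) · (1/t_j) [[1, r_j], [r_j, 1]]

with phase thickness δ_j = d_j k_j, k_j = 2π n_j cosθ_j / λ, and (r_j, t_j)
the Fresnel amplitude coefficients of the j → j+1 interface.  The injection
medium is layer 0 with zero thickness, so the ordered product
M̃ = M_0 M_1 ... M_L propagates field amplitudes from injection to
substrate, where no backward-travelling wave exists.  Amplitude
coefficients of the whole stack are r = M̃_{10}/M̃_{00}, t = 1/M̃_{00}, and
power coefficients R = |r|², T = (n_sub cosθ_sub)/(n0 cosθ0) |t|².

Because each thickness d_m enters only its own factor M_m, the exact
thickness gradient of the spectrum follows from the product rule with
prefix/suffix partial products — no autodiff framework is required.

The substrate is treated as semi-infinite: its back surface is not
modelled.  Indices are real constants (no dispersion, no absorption); the
complex arithmetic is retained throughout so absorbing indices degrade
gracefully, but only lossless stacks are tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .spectra import SpectralGrid

__all__ = [
    "LayerStack",
    "SpectralResponse",
    "TotalInternalReflectionError",
    "refraction_angles",
    "fresnel_interface",
    "layer_matrix",
    "stack_matrix",
    "stack_coefficients",
    "power_coefficients",
    "transmittance_spectrum",
    "transmittance_with_gradient",
]

Polarization = Literal["s", "p"]


class TotalInternalReflectionError(ValueError):
    """Snell's law has no real refracted angle in some layer."""


@dataclass(frozen=True)
class LayerStack:
    """Injection medium | inner layers | substrate.

    Parameters
    ----------
    n0 : real refractive index of the injection medium (≥ 1).
    layer_indices : real index of each inner layer, in propagation order.
    thicknesses : physical thickness of each inner layer, nm (≥ 0).
    n_sub : real refractive index of the semi-infinite substrate.
    """

    n0: float
    layer_indices: np.ndarray
    thicknesses: np.ndarray
    n_sub: float

    def __post_init__(self) -> None:
        idx = np.atleast_1d(np.asarray(self.layer_indices, dtype=float))
        th = np.atleast_1d(np.asarray(self.thicknesses, dtype=float))
        if idx.size == 0:
            idx = idx.reshape(0)
            th = th.reshape(0)
        if idx.shape != th.shape:
            raise ValueError("one thickness per inner layer is required")
        if self.n0 < 1 or self.n_sub < 1 or np.any(idx < 1):
            raise ValueError("refractive indices must be ≥ 1")
        if np.any(th < 0):
            raise ValueError("thicknesses must be non-negative")
        object.__setattr__(self, "layer_indices", idx)
        object.__setattr__(self, "thicknesses", th)

    @property
    def num_layers(self) -> int:
        return int(self.layer_indices.size)

    def with_thicknesses(self, thicknesses: Sequence[float]) -> "LayerStack":
        """Same materials, new design point."""
        return LayerStack(self.n0, self.layer_indices, np.asarray(thicknesses, float), self.n_sub)

    def all_indices(self) -> np.ndarray:
        """Indices of every medium: injection, inner layers, substrate."""
        return np.concatenate(([self.n0], self.layer_indices, [self.n_sub]))


@dataclass(frozen=True)
class SpectralResponse:
    """Per-wavelength power coefficients of a stack at one incidence angle."""

    grid: SpectralGrid
    T_s: np.ndarray
    T_p: np.ndarray
    R_s: np.ndarray
    R_p: np.ndarray

    @property
    def T_unpolarized(self) -> np.ndarray:
        return (self.T_s + self.T_p) / 2.0


def refraction_angles(stack: LayerStack, theta0: float) -> np.ndarray:
    """Propagation angle in every medium (injection, layers, substrate), radians.

    Snell's law conserves n·sinθ across all interfaces, so each angle
    depends only on that layer's index, not on the layers before it.
    """
    if not 0 <= theta0 < np.pi / 2:
        raise ValueError("incidence angle must be in [0, π/2)")
    n = stack.all_indices()
    sines = stack.n0 * np.sin(theta0) / n
    if np.any(sines > 1):
        bad = int(np.argmax(sines > 1))
        raise TotalInternalReflectionError(
            f"total internal reflection entering medium {bad} (n={n[bad]:g})"
        )
    return np.arcsin(sines)


def fresnel_interface(
    n_j: float, n_j1: float, theta_j: float, theta_j1: float, polarization: Polarization
) -> tuple[float, float]:
    """Fresnel amplitude coefficients (r, t) for the j → j+1 interface."""
    cj, cj1 = np.cos(theta_j), np.cos(theta_j1)
    if polarization == "s":
        denom = n_j * cj + n_j1 * cj1
        if denom == 0:
            raise ZeroDivisionError("degenerate grazing interface (zero s denominator)")
        return (n_j * cj - n_j1 * cj1) / denom, 2 * n_j * cj / denom
    if polarization == "p":
        denom = n_j1 * cj + n_j * cj1
        if denom == 0:
            raise ZeroDivisionError("degenerate grazing interface (zero p denominator)")
        return (n_j1 * cj - n_j * cj1) / denom, 2 * n_j * cj / denom
    raise ValueError(f"polarization must be 's' or 'p', got {polarization!r}")


def layer_matrix(delta_j: complex, r_interface: complex, t_interface: complex) -> np.ndarray:
    """2×2 transfer matrix: phase across the layer, then its exit interface."""
    if t_interface == 0:
        raise ZeroDivisionError("interface transmission coefficient is zero")
    phase = np.array([[np.exp(-1j * delta_j), 0], [0, np.exp(1j * delta_j)]])
    interface = np.array([[1, r_interface], [r_interface, 1]]) / t_interface
    return phase @ interface


def _stack_angles_and_fresnel(
    stack: LayerStack, theta0: float, polarization: Polarization
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Angles for every medium and per-interface (r, t) arrays."""
    angles = refraction_angles(stack, theta0)
    n = stack.all_indices()
    r = np.empty(n.size - 1)
    t = np.empty(n.size - 1)
    for j in range(n.size - 1):
        r[j], t[j] = fresnel_interface(n[j], n[j + 1], angles[j], angles[j + 1], polarization)
    return angles, r, t


def stack_matrix(
    stack: LayerStack, theta0: float, wavelength: float, polarization: Polarization
) -> np.ndarray:
    """Total transfer matrix M̃ at one wavelength.

    The injection medium is the zero-thickness layer 0, so the product
    starts with its interface factor alone.
    """
    angles, r, t = _stack_angles_and_fresnel(stack, theta0, polarization)
    m = layer_matrix(0.0, r[0], t[0])
    for j in range(stack.num_layers):
        k_j = 2 * np.pi * stack.layer_indices[j] * np.cos(angles[j + 1]) / wavelength
        delta = stack.thicknesses[j] * k_j
        m = m @ layer_matrix(delta, r[j + 1], t[j + 1])
    return m


def stack_coefficients(m: np.ndarray) -> tuple[complex, complex]:
    """Amplitude (r, t) from M̃ under the no-backward-wave substrate condition."""
    if m[0, 0] == 0:
        raise ZeroDivisionError("M[0,0] = 0: perfectly reflecting degenerate stack")
    return m[1, 0] / m[0, 0], 1.0 / m[0, 0]


def power_coefficients(
    r: complex, t: complex, stack: LayerStack, theta0: float, theta_sub: float
) -> tuple[float, float]:
    """Reflectance R = |r|² and transmittance T with the substrate flux factor."""
    R = abs(r) ** 2
    T = (stack.n_sub * np.cos(theta_sub)) / (stack.n0 * np.cos(theta0)) * abs(t) ** 2
    return float(R), float(T)


# ---------------------------------------------------------------------------
# Vectorized spectral path (the differentiable simulator core)
# ---------------------------------------------------------------------------


def _layer_matrices_batch(
    stack: LayerStack, theta0: float, grid: SpectralGrid, polarization: Polarization
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-factor matrices over the grid.

    Returns (M, k, cos_ratio): M has shape (L+1, N, 2, 2) — factor 0 is the
    injection interface, factor m ≥ 1 is phase(d_m) + exit interface of
    inner layer m; k is (L, N) phase wave-vectors ∂δ/∂d; cos_ratio is the
    scalar flux factor n_sub cosθ_sub / (n0 cosθ0).
    """
    angles, r, t = _stack_angles_and_fresnel(stack, theta0, polarization)
    wl = grid.wavelengths
    L, N = stack.num_layers, len(grid)
    M = np.empty((L + 1, N, 2, 2), dtype=complex)
    M[0] = np.array([[1, r[0]], [r[0], 1]]) / t[0]
    k = np.empty((L, N))
    for j in range(L):
        k[j] = 2 * np.pi * stack.layer_indices[j] * np.cos(angles[j + 1]) / wl
        delta = stack.thicknesses[j] * k[j]
        e_m, e_p = np.exp(-1j * delta), np.exp(1j * delta)
        inv_t = 1.0 / t[j + 1]
        M[j + 1, :, 0, 0] = e_m * inv_t
        M[j + 1, :, 0, 1] = e_m * r[j + 1] * inv_t
        M[j + 1, :, 1, 0] = e_p * r[j + 1] * inv_t
        M[j + 1, :, 1, 1] = e_p * inv_t
    cos_ratio = stack.n_sub * np.cos(angles[-1]) / (stack.n0 * np.cos(theta0))
    return M, k, float(cos_ratio)


def _polarized_RT(
    stack: LayerStack, theta0: float, grid: SpectralGrid, polarization: Polarization
) -> tuple[np.ndarray, np.ndarray]:
    M, _, cos_ratio = _layer_matrices_batch(stack, theta0, grid, polarization)
    total = M[0]
    for j in range(1, M.shape[0]):
        total = total @ M[j]
    m00, m10 = total[:, 0, 0], total[:, 1, 0]
    if np.any(m00 == 0):
        raise ZeroDivisionError("M[0,0] = 0 at some wavelength: degenerate stack")
    R = np.abs(m10 / m00) ** 2
    T = cos_ratio / np.abs(m00) ** 2
    return R, T


def transmittance_spectrum(stack: LayerStack, theta0: float, grid: SpectralGrid) -> SpectralResponse:
    """Power spectra T_s, T_p, R_s, R_p of the stack over a wavelength grid."""
    R_s, T_s = _polarized_RT(stack, theta0, grid, "s")
    R_p, T_p = _polarized_RT(stack, theta0, grid, "p")
    return SpectralResponse(grid=grid, T_s=T_s, T_p=T_p, R_s=R_s, R_p=R_p)


def transmittance_with_gradient(
    stack: LayerStack, theta0: float, grid: SpectralGrid, polarization: Polarization
) -> tuple[np.ndarray, np.ndarray]:
    """Transmittance T(λ) and its exact thickness Jacobian ∂T/∂d, shape (L, N).

    Only factor m of the matrix product depends on d_m, and
    ∂M_m/∂d_m = k_m · diag(-i, +i) · M_m, so with prefix products
    A_m = M_0…M_{m-1} and suffix products B_m = M_{m+1}…M_L the product
    rule gives ∂M̃/∂d_m = A_m (k_m D M_m) B_m.  From T = c/|M̃_00|²,
    ∂T/∂d_m = −2 T Re(∂M̃_00/∂d_m / M̃_00).
    """
    M, k, cos_ratio = _layer_matrices_batch(stack, theta0, grid, polarization)
    F, N = M.shape[0], M.shape[1]  # F = L + 1 factors
    L = F - 1
    prefix = np.empty_like(M)
    prefix[0] = M[0]
    for j in range(1, F):
        prefix[j] = prefix[j - 1] @ M[j]
    suffix = np.empty_like(M)
    suffix[F - 1] = M[F - 1]
    for j in range(F - 2, -1, -1):
        suffix[j] = M[j] @ suffix[j + 1]
    total = prefix[F - 1]
    m00 = total[:, 0, 0]
    if np.any(m00 == 0):
        raise ZeroDivisionError("M[0,0] = 0 at some wavelength: degenerate stack")
    T = cos_ratio / np.abs(m00) ** 2

    D = np.array([-1j, 1j])
    dT = np.empty((L, N))
    for m in range(1, F):
        # middle = diag(-i, i) @ (M_m @ suffix_{m+1}) = diag(-i, i) @ suffix_m
        right = suffix[m + 1] if m + 1 < F else np.broadcast_to(np.eye(2, dtype=complex), (N, 2, 2))
        mid = D[None, :, None] * (M[m] @ right)
        d_total = prefix[m - 1] @ mid
        dm00 = k[m - 1] * d_total[:, 0, 0]
        dT[m - 1] = -2.0 * T * np.real(dm00 / m00)
    return T, dT
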