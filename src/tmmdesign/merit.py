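r"""Dual-angle merit functions and thickness optimization.

The design objective compares the stack's transmittance with a target
curve simultaneously at normal (θ0) and oblique (θ1) incidence:

* ``merit1`` uses the unpolarized transmittance T = (T_s + T_p)/2 at both
  angles:  (1/N) Σ_λ [(T^θ0 − T^t)² + (T^θ1 − T^t)²].
* ``merit2`` penalizes the two oblique polarizations separately:
  (1/N) Σ_λ [(T^θ0 − T^t)² + (T_p^θ1 − T^t)² + (T_s^θ1 − T^t)²].
* ``normal_only`` keeps just the θ0 term — the classical single-angle
  design the dual-angle merits are compared against.

Thicknesses are optimized with bound-constrained L-BFGS-B (lower bound 0:
negative thicknesses are physically implausible) using the exact analytic
thickness gradient of the transfer-matrix spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence, Union

import numpy as np
from scipy.optimize import minimize

from .spectra import SpectralCurve, SpectralGrid
from .tmm import LayerStack, transmittance_spectrum, transmittance_with_gradient

__all__ = [
    "TargetCurve",
    "MeritConfig",
    "DesignResult",
    "unpolarized_T",
    "merit1",
    "merit2",
    "normal_only_merit",
    "merit_value",
    "merit_gradient",
    "optimize_thicknesses",
    "mae_curve",
    "initialize_design",
    "alternating_stack",
]

MeritVariant = Literal["merit1", "merit2", "normal_only"]
_VARIANTS = ("merit1", "merit2", "normal_only")

#: a single target used at both angles (the usual design setting), or a
#: (θ0-target, θ1-target) pair for recovery experiments with per-angle truth
TargetLike = Union["TargetCurve", tuple["TargetCurve", "TargetCurve"]]


@dataclass(frozen=True)
class TargetCurve:
    """Desired transmittance on the optimization grid, clipped to [0, 1]."""

    grid: SpectralGrid
    values: np.ndarray
    name: str = field(default="target", compare=False)

    def __post_init__(self) -> None:
        v = np.clip(np.asarray(self.values, dtype=float), 0.0, 1.0)
        if v.shape != (len(self.grid),):
            raise ValueError("target length must match its grid")
        object.__setattr__(self, "values", v)

    def as_curve(self) -> SpectralCurve:
        return SpectralCurve(self.grid, self.values, name=self.name)


@dataclass(frozen=True)
class MeritConfig:
    """Which merit to evaluate, at which pair of angles, on which grid."""

    variant: MeritVariant = "merit2"
    theta0: float = 0.0
    theta1: float = np.deg2rad(20.0)
    grid: SpectralGrid = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}")
        if self.variant != "normal_only" and self.theta0 == self.theta1:
            raise ValueError("dual-angle merits need two distinct angles")
        if self.grid is None:
            raise ValueError("a SpectralGrid is required")


def _split_target(target: TargetLike, grid: SpectralGrid) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(target, TargetCurve):
        t0 = t1 = target
    else:
        t0, t1 = target
    for t in (t0, t1):
        if t.grid != grid:
            raise ValueError("target grid does not match the merit grid")
    return t0.values, t1.values


def unpolarized_T(stack: LayerStack, theta: float, grid: SpectralGrid) -> np.ndarray:
    """Unpolarized transmittance (T_s + T_p)/2 per wavelength."""
    return transmittance_spectrum(stack, theta, grid).T_unpolarized


def _merit_terms_from_spectra(
    variant: MeritVariant,
    T0_unpol: np.ndarray,
    Ts1: np.ndarray,
    Tp1: np.ndarray,
    target0: np.ndarray,
    target1: np.ndarray,
) -> float:
    """Merit arithmetic on already-computed spectra (unit-testable in isolation)."""
    N = T0_unpol.size
    normal = np.sum((T0_unpol - target0) ** 2)
    if variant == "normal_only":
        return float(normal / N)
    if variant == "merit1":
        oblique = np.sum(((Ts1 + Tp1) / 2.0 - target1) ** 2)
    else:
        oblique = np.sum((Tp1 - target1) ** 2) + np.sum((Ts1 - target1) ** 2)
    return float((normal + oblique) / N)


def merit_value(stack: LayerStack, target: TargetLike, config: MeritConfig) -> float:
    """Evaluate the configured merit function for a stack."""
    target0, target1 = _split_target(target, config.grid)
    sr0 = transmittance_spectrum(stack, config.theta0, config.grid)
    if config.variant == "normal_only":
        return _merit_terms_from_spectra("normal_only", sr0.T_unpolarized, sr0.T_s, sr0.T_p, target0, target1)
    sr1 = transmittance_spectrum(stack, config.theta1, config.grid)
    return _merit_terms_from_spectra(config.variant, sr0.T_unpolarized, sr1.T_s, sr1.T_p, target0, target1)


def merit1(stack: LayerStack, target: TargetLike, config: MeritConfig) -> float:
    return merit_value(stack, target, MeritConfig("merit1", config.theta0, config.theta1, config.grid))


def merit2(stack: LayerStack, target: TargetLike, config: MeritConfig) -> float:
    return merit_value(stack, target, MeritConfig("merit2", config.theta0, config.theta1, config.grid))


def normal_only_merit(stack: LayerStack, target: TargetLike, config: MeritConfig) -> float:
    return merit_value(
        stack, target, MeritConfig("normal_only", config.theta0, config.theta1, config.grid)
    )


def _merit_and_gradient(
    stack: LayerStack, target: TargetLike, config: MeritConfig
) -> tuple[float, np.ndarray]:
    """Merit value and its exact gradient w.r.t. every inner-layer thickness."""
    target0, target1 = _split_target(target, config.grid)
    N = len(config.grid)
    # θ0: s and p coincide only at exactly 0; handle the general case.
    Ts0, dTs0 = transmittance_with_gradient(stack, config.theta0, config.grid, "s")
    Tp0, dTp0 = transmittance_with_gradient(stack, config.theta0, config.grid, "p")
    Tu0 = (Ts0 + Tp0) / 2.0
    dTu0 = (dTs0 + dTp0) / 2.0
    res0 = Tu0 - target0
    value = np.sum(res0**2)
    grad = dTu0 @ (2.0 * res0)
    if config.variant != "normal_only":
        Ts1, dTs1 = transmittance_with_gradient(stack, config.theta1, config.grid, "s")
        Tp1, dTp1 = transmittance_with_gradient(stack, config.theta1, config.grid, "p")
        if config.variant == "merit1":
            Tu1 = (Ts1 + Tp1) / 2.0
            res1 = Tu1 - target1
            value += np.sum(res1**2)
            grad += ((dTs1 + dTp1) / 2.0) @ (2.0 * res1)
        else:
            res_s = Ts1 - target1
            res_p = Tp1 - target1
            value += np.sum(res_s**2) + np.sum(res_p**2)
            grad += dTs1 @ (2.0 * res_s) + dTp1 @ (2.0 * res_p)
    return float(value / N), grad / N


def merit_gradient(stack: LayerStack, target: TargetLike, config: MeritConfig) -> np.ndarray:
    """Gradient of the configured merit w.r.t. the thickness vector, nm⁻¹."""
    return _merit_and_gradient(stack, target, config)[1]


@dataclass(frozen=True)
class DesignResult:
    """Outcome of one bounded quasi-Newton thickness optimization."""

    thicknesses: np.ndarray
    merit_trace: np.ndarray  # merit at the start point and each accepted iterate
    final_merit: float
    converged: bool
    seed: int
    message: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if np.any(self.thicknesses < 0):
            raise ValueError("optimized thicknesses must be non-negative")


def optimize_thicknesses(
    initial: Sequence[float],
    target: TargetLike,
    config: MeritConfig,
    stack_template: LayerStack,
    bounds: tuple[float, float] = (0.0, 1000.0),
    max_iter: int = 500,
    seed: int = 0,
    gtol: float = 1e-8,
    ftol: float = 1e-10,
    callback: Callable[[np.ndarray], None] | None = None,
) -> DesignResult:
    """Minimize the merit over layer thicknesses with L-BFGS-B.

    ``stack_template`` supplies the fixed materials (indices, injection,
    substrate); only the thickness vector moves.  Deterministic for a
    given start point; ``seed`` is recorded for provenance of seeded
    initializations.
    """
    x0 = np.asarray(initial, dtype=float)
    if x0.size != stack_template.num_layers:
        raise ValueError("initial thickness vector does not match the stack template")
    lo, hi = bounds
    if lo < 0 or hi <= lo:
        raise ValueError("bounds must satisfy 0 ≤ lo < hi")
    x0 = np.clip(x0, lo, hi)

    trace: list[float] = []

    def fun(x: np.ndarray) -> tuple[float, np.ndarray]:
        v, g = _merit_and_gradient(stack_template.with_thicknesses(x), target, config)
        if not np.isfinite(v):
            raise FloatingPointError(f"non-finite merit {v!r} during line search")
        return v, g

    def record(xk: np.ndarray) -> None:
        trace.append(fun(xk)[0])
        if callback is not None:
            callback(xk)

    trace.append(fun(x0)[0])
    res = minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(lo, hi)] * x0.size,
        callback=record,
        options={"maxiter": max_iter, "ftol": ftol, "gtol": gtol},
    )
    return DesignResult(
        thicknesses=np.asarray(res.x, dtype=float),
        merit_trace=np.asarray(trace),
        final_merit=float(res.fun),
        converged=bool(res.success),
        seed=seed,
        message=str(res.message),
    )


def mae_curve(curve_a: SpectralCurve, curve_b: SpectralCurve) -> float:
    """Mean absolute error between two curves on the same grid."""
    curve_a.require_grid(curve_b.grid)
    return float(np.mean(np.abs(curve_a.values - curve_b.values)))


def initialize_design(
    num_layers: int,
    strategy: str = "quarter_wave",
    seed: int = 0,
    *,
    indices: Sequence[float] | None = None,
    lambda_ref: float = 550.0,
    jitter_nm: float = 0.0,
    lo: float = 20.0,
    hi: float = 300.0,
) -> np.ndarray:
    """Seeded starting thicknesses.

    ``quarter_wave``: λ_ref/(4 n_j) per layer (optionally jittered
    uniformly by ±``jitter_nm``); ``uniform_random``: U[lo, hi].
    """
    rng = np.random.default_rng(seed)
    if strategy == "quarter_wave":
        if indices is None:
            indices = np.where(np.arange(num_layers) % 2 == 0, 2.3, 1.46)
        idx = np.asarray(indices, dtype=float)
        if idx.size != num_layers:
            raise ValueError("one index per layer is required")
        d = lambda_ref / (4.0 * idx)
        if jitter_nm > 0:
            d = d + rng.uniform(-jitter_nm, jitter_nm, num_layers)
        return np.clip(d, 0.0, None)
    if strategy == "uniform_random":
        return rng.uniform(lo, hi, num_layers)
    raise ValueError(f"unknown initialization strategy {strategy!r}")


def alternating_stack(
    num_layers: int = 60,
    thicknesses: Sequence[float] | None = None,
    n_hi: float = 2.3,
    n_lo: float = 1.46,
    n0: float = 1.0,
    n_sub: float = 1.52,
) -> LayerStack:
    """The Ta2O5/SiO2-on-glass stack class: {air | 2.3 | 1.46 | … | glass}."""
    indices = np.where(np.arange(num_layers) % 2 == 0, n_hi, n_lo)
    if thicknesses is None:
        thicknesses = initialize_design(num_layers, "quarter_wave", indices=indices)
    return LayerStack(n0, indices, np.asarray(thicknesses, float), n_sub)
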