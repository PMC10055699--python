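"""Synthetic inputs: target curves, known-truth stacks, near-color scenes.

The greenhouse hyperspectral dataset and the manufactured filter's target
curve this toolkit was motivated by are not publicly available, so every
pipeline input can be generated here instead: band-pass-like design
targets, seeded random stacks whose spectra serve as recoverable ground
truth, and two-class scenes of spectrally overlapping "pepper" and "leaf"
materials with ground-truth masks.  Pepper and leaf reflectances are
deliberately near-color — correlated above 0.9 on the default grid — so
the classes confuse an RGB camera while remaining separable from spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .merit import TargetCurve, alternating_stack
from .spectra import SpectralCurve, SpectralGrid, default_grid
from .tmm import LayerStack, SpectralResponse, transmittance_spectrum

__all__ = [
    "MaterialSpectrum",
    "SceneSpec",
    "Scene",
    "make_target_curve",
    "make_known_stack",
    "default_materials",
    "make_scene",
    "make_dataset",
    "default_illumination",
]


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def make_target_curve(
    kind: str,
    center: float,
    width: float,
    edge_steepness: float = 0.5,
    grid: SpectralGrid | None = None,
) -> TargetCurve:
    """Smooth logistic-edged target transmittance.

    ``bandpass``: product of a rising and a falling logistic edge at
    center ± width/2; ``notch``: its pointwise complement; ``double_band``:
    two bandpasses at center ± width (each of half width), clipped to 1.
    ``edge_steepness`` is the logistic rate in nm⁻¹.
    """
    grid = grid or default_grid()
    wl = grid.wavelengths
    if not (wl[0] <= center <= wl[-1]):
        raise ValueError("band center must lie within the grid")
    if width <= 0 or edge_steepness <= 0:
        raise ValueError("width and edge_steepness must be positive")

    def bandpass(c: float, w: float) -> np.ndarray:
        return _logistic(edge_steepness * (wl - (c - w / 2))) * _logistic(
            edge_steepness * ((c + w / 2) - wl)
        )

    if kind == "bandpass":
        v = bandpass(center, width)
    elif kind == "notch":
        v = 1.0 - bandpass(center, width)
    elif kind == "double_band":
        v = np.clip(bandpass(center - width, width / 2) + bandpass(center + width, width / 2), 0, 1)
    else:
        raise ValueError(f"unknown target kind {kind!r}")
    return TargetCurve(grid, v, name=f"{kind}_{center:g}nm")


def make_known_stack(
    num_layers: int = 10,
    seed: int = 0,
    theta1: float = np.deg2rad(20.0),
    grid: SpectralGrid | None = None,
) -> tuple[LayerStack, SpectralResponse, SpectralResponse]:
    """Seeded random alternating stack plus its spectra at 0° and θ1.

    Thicknesses are drawn uniformly from [30, 250] nm on the alternating
    high/low structure; the returned spectra are the recovery ground truth.
    """
    if num_layers < 1:
        raise ValueError("need at least one layer")
    grid = grid or default_grid()
    rng = np.random.default_rng(seed)
    stack = alternating_stack(num_layers, thicknesses=rng.uniform(30.0, 250.0, num_layers))
    return stack, transmittance_spectrum(stack, 0.0, grid), transmittance_spectrum(stack, theta1, grid)


def make_bandpass_stack(
    mirror_pairs: int = 4,
    lambda_ref: float = 550.0,
    n_hi: float = 2.3,
    n_lo: float = 1.46,
) -> LayerStack:
    """Quarter-wave Fabry–Pérot band-pass cavity centered at ``lambda_ref``.

    Two quarter-wave (HL)^m mirrors around a half-wave low-index spacer;
    its passband peak blue-shifts with incidence angle, the phenomenon the
    dual-angle merits are designed to suppress.
    """
    qw_hi, qw_lo = lambda_ref / (4 * n_hi), lambda_ref / (4 * n_lo)
    layers: list[tuple[float, float]] = []
    for _ in range(mirror_pairs):
        layers += [(n_hi, qw_hi), (n_lo, qw_lo)]
    layers[-1] = (n_lo, 2 * qw_lo)  # half-wave spacer
    for _ in range(mirror_pairs):
        layers += [(n_hi, qw_hi), (n_lo, qw_lo)]
    indices = np.array([n for n, _ in layers])
    thicknesses = np.array([d for _, d in layers])
    return LayerStack(1.0, indices, thicknesses, 1.52)


# ---------------------------------------------------------------------------
# Materials and scenes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MaterialSpectrum:
    """A class label with its reflectance curve and per-sample jitter scale."""

    class_label: str
    reflectance: SpectralCurve
    variability: float = 0.05

    def __post_init__(self) -> None:
        v = self.reflectance.values
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("reflectance must lie in [0, 1]")


def _gaussian(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def default_materials(grid: SpectralGrid | None = None) -> dict[str, MaterialSpectrum]:
    """Pepper / leaf / background reflectances.

    The two vegetation classes are built to be *camera-metameric*: the
    pepper curve is the leaf curve plus a narrow-band green-region
    perturbation chosen orthogonal (under flat illumination) to all three
    default camera response channels.  A bare RGB camera therefore cannot
    tell the classes apart by color, while a band-pass filter that cuts
    into the perturbation's lobes re-exposes the difference — the premise
    that makes a spectral filter worth designing for near-color crops.
    Correlation of the two reflectances exceeds 0.9 on the default grid.
    Background is broadband low reflectance.
    """
    from .imaging import default_csr  # deferred: imaging imports Scene from here

    grid = grid or default_grid()
    wl = grid.wavelengths
    leaf = 0.05 + 0.30 * _gaussian(wl, 556.0, 34.0) + 0.45 * _logistic(0.09 * (wl - 712.0))
    leaf = np.clip(leaf, 0, 1)

    # perturbation basis: four narrow green-region bumps; the SVD null
    # space of their channel responses is a bump mix invisible to every
    # CSR channel (3 constraints, 4 bumps -> one metameric mode)
    bumps = np.stack(
        [
            _gaussian(wl, 520.0, 14.0),
            _gaussian(wl, 545.0, 10.0),
            _gaussian(wl, 572.0, 12.0),
            _gaussian(wl, 602.0, 16.0),
        ]
    )
    csr = default_csr(grid).channels * grid.trapezoid_weights()  # (3, N)
    responses = bumps @ csr.T  # (4, 3)
    _, _, vt = np.linalg.svd(responses.T)
    delta = vt[-1] @ bumps
    delta *= 0.12 / np.max(np.abs(delta))
    if delta[np.argmin(np.abs(wl - 545.0))] < 0:
        delta = -delta  # sign convention: pepper brighter inside the passband

    pepper = np.clip(leaf + delta, 0, 1)
    background = np.full_like(wl, 0.08)
    return {
        "pepper": MaterialSpectrum("pepper", SpectralCurve(grid, pepper, "pepper"), 0.05),
        "leaf": MaterialSpectrum("leaf", SpectralCurve(grid, leaf, "leaf"), 0.05),
        "background": MaterialSpectrum(
            "background", SpectralCurve(grid, background, "background"), 0.05
        ),
    }


def default_illumination(grid: SpectralGrid | None = None, kind: str = "flat") -> SpectralCurve:
    """Flat illuminant by default; ``daylight`` is a smooth D65-like hump."""
    grid = grid or default_grid()
    wl = grid.wavelengths
    if kind == "flat":
        return SpectralCurve(grid, np.ones_like(wl), "flat")
    if kind == "daylight":
        v = 0.6 + 0.4 * _gaussian(wl, 560.0, 160.0)
        return SpectralCurve(grid, v / v.max(), "daylight")
    raise ValueError(f"unknown illumination kind {kind!r}")


@dataclass(frozen=True)
class SceneSpec:
    """Geometry and noise of one synthetic greenhouse-like scene."""

    height: int = 64
    width: int = 64
    n_peppers: int = 3
    axis_range: tuple[float, float] = (5.0, 12.0)  # ellipse semi-axes, px
    illumination: SpectralCurve | None = None
    noise_sd: float = 0.01  # additive Gaussian, fraction of peak radiance
    jitter: float = 0.05  # per-object multiplicative reflectance jitter sd
    leaf_texture: float = 0.08  # leaf-background brightness texture amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("scene dimensions must be positive")
        if self.n_peppers < 0:
            raise ValueError("n_peppers must be non-negative")
        a_min, a_max = self.axis_range
        if not 0 < a_min <= a_max:
            raise ValueError("invalid ellipse axis range")


@dataclass(frozen=True)
class Scene:
    """A hyperspectral cube with its ground-truth pepper mask."""

    cube: np.ndarray  # H×W×Λ, nonnegative relative radiance
    band_wavelengths: np.ndarray
    mask: np.ndarray  # H×W, 0 = background/leaf, 1 = pepper
    seed: int = field(default=0, compare=False)


def make_scene(
    spec: SceneSpec, materials: Mapping[str, MaterialSpectrum] | None = None
) -> Scene:
    """Ellipse-shaped peppers over a leaf-textured background.

    cube(x, y, λ) = illumination(λ) · reflectance(x, y, λ) · (1 + jitter)
    + noise, fully determined by ``spec.seed``.  Raises if an ellipse
    cannot fit inside the frame.
    """
    grid_materials = materials or default_materials()
    pepper = grid_materials["pepper"]
    leaf = grid_materials["leaf"]
    grid = pepper.reflectance.grid
    illum = spec.illumination or default_illumination(grid)
    illum.require_grid(grid)

    H, W = spec.height, spec.width
    a_min, a_max = spec.axis_range
    if spec.n_peppers > 0 and 2 * a_max >= min(H, W):
        raise ValueError("peppers cannot fit: ellipse axes too large for the frame")
    rng = np.random.default_rng(spec.seed)

    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    mask = np.zeros((H, W), dtype=np.uint8)
    gain = np.ones((H, W))
    # leaf texture: smooth low-frequency brightness modulation of the background
    if spec.leaf_texture > 0:
        fy, fx = rng.uniform(1.0, 3.0, 2)
        py, px = rng.uniform(0, 2 * np.pi, 2)
        gain += spec.leaf_texture * np.sin(2 * np.pi * fy * yy / H + py) * np.sin(
            2 * np.pi * fx * xx / W + px
        )

    for _ in range(spec.n_peppers):
        a, b = rng.uniform(a_min, a_max, 2)
        cy = rng.uniform(a_max, H - a_max)
        cx = rng.uniform(a_max, W - a_max)
        phi = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = dx * np.cos(phi) + dy * np.sin(phi)
        v = -dx * np.sin(phi) + dy * np.cos(phi)
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        mask[inside] = 1
        if spec.jitter > 0:
            gain[inside] = 1.0 + spec.jitter * rng.standard_normal()

    refl = np.where(
        mask[:, :, None] == 1, pepper.reflectance.values, leaf.reflectance.values
    )
    cube = illum.values[None, None, :] * refl * gain[:, :, None]
    if spec.noise_sd > 0:
        cube = cube + spec.noise_sd * cube.max() * rng.standard_normal(cube.shape)
    cube = np.clip(cube, 0.0, None)
    return Scene(cube=cube, band_wavelengths=grid.wavelengths.copy(), mask=mask, seed=spec.seed)


def make_dataset(
    n_scenes: int,
    spec: SceneSpec,
    split: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    materials: Mapping[str, MaterialSpectrum] | None = None,
) -> tuple[list[Scene], list[Scene], list[Scene], dict]:
    """Disjoint seeded train/val/test scene lists plus a manifest.

    Per-scene seeds are drawn from the master seed, so the whole dataset
    is a pure function of ``seed``.
    """
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    scene_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, n_scenes)]
    if len(set(scene_seeds)) != n_scenes:  # astronomically unlikely; regenerate
        scene_seeds = list(range(seed * n_scenes, (seed + 1) * n_scenes))
    scenes = [
        make_scene(
            SceneSpec(
                height=spec.height,
                width=spec.width,
                n_peppers=spec.n_peppers,
                axis_range=spec.axis_range,
                illumination=spec.illumination,
                noise_sd=spec.noise_sd,
                jitter=spec.jitter,
                leaf_texture=spec.leaf_texture,
                seed=s,
            ),
            materials,
        )
        for s in scene_seeds
    ]
    n_train = int(round(split[0] * n_scenes))
    n_val = int(round(split[1] * n_scenes))
    train = scenes[:n_train]
    val = scenes[n_train : n_train + n_val]
    test = scenes[n_train + n_val :]
    manifest = {
        "master_seed": seed,
        "n_scenes": n_scenes,
        "split": list(split),
        "scene_seeds": scene_seeds,
        "train_seeds": scene_seeds[:n_train],
        "val_seeds": scene_seeds[n_train : n_train + n_val],
        "test_seeds": scene_seeds[n_train + n_val :],
    }
    return train, val, test, manifest
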