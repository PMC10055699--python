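"""Freeze-and-swap segmentation evaluation of filter designs.

A small segmenter is trained on RGB images synthesized through one
transmittance curve, then frozen; competing curves are swapped into the
optical-filter stage and scored by mean intersection-over-union (mIoU)
under the *same* frozen network and camera response.  Only the filter
curve changes between rows of the report, so differences in mIoU isolate
the optical design.

With no deep-learning framework available, the segmenter is a pixelwise
multilayer perceptron over multi-scale Gaussian-pyramid RGB features
(per-pixel color plus smoothed context at two scales) — a deliberately
small stand-in for an encoder–decoder network.  It is seeded and fully
deterministic, and its checkpoint serializes to JSON so the frozen-weights
contract is byte-checkable.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

from .imaging import CameraSpectralResponse, RGBImage, auto_exposure, no_filter_curve, synthesize_rgb
from .merit import unpolarized_T
from .spectra import SpectralCurve, SpectralGrid
from .synthetic import Scene
from .tmm import LayerStack, transmittance_spectrum

__all__ = [
    "SegmenterConfig",
    "FrozenSegmenter",
    "SwapRecord",
    "SwapReport",
    "mean_iou",
    "extract_features",
    "train_segmenter",
    "swap_and_evaluate",
    "curves_for_design",
]

_FEATURE_SIGMAS = (2.0, 6.0)


def mean_iou(
    predictions: Sequence[np.ndarray] | np.ndarray,
    ground_truths: Sequence[np.ndarray] | np.ndarray,
    num_classes: int = 2,
) -> float:
    """Mean over classes of |P∩G| / |P∪G|, aggregated over all images.

    Classes whose union is empty in every image are left out of the mean
    rather than scored; a shape mismatch anywhere raises.
    """
    if isinstance(predictions, np.ndarray):
        predictions = [predictions]
    if isinstance(ground_truths, np.ndarray):
        ground_truths = [ground_truths]
    if len(predictions) != len(ground_truths):
        raise ValueError("need one prediction per ground truth")
    inter = np.zeros(num_classes, dtype=np.int64)
    union = np.zeros(num_classes, dtype=np.int64)
    for p, g in zip(predictions, ground_truths):
        p = np.asarray(p)
        g = np.asarray(g)
        if p.shape != g.shape:
            raise ValueError(f"prediction shape {p.shape} != ground truth shape {g.shape}")
        for c in range(num_classes):
            pc, gc = p == c, g == c
            inter[c] += np.count_nonzero(pc & gc)
            union[c] += np.count_nonzero(pc | gc)
    present = union > 0
    if not np.any(present):
        raise ValueError("no class present in predictions or ground truth")
    return float(np.mean(inter[present] / union[present]))


def extract_features(image: RGBImage) -> np.ndarray:
    """Per-pixel features: instance-normalized RGB plus smoothed context.

    Each channel plane (raw and Gaussian-smoothed at two scales) is
    standardized per image, the role instance/batch normalization plays
    in an encoder–decoder network: global radiometric shifts between
    swapped filter curves are discounted, within-image color contrast is
    kept.
    """
    planes = [image.data[:, :, c] for c in range(3)]
    for sigma in _FEATURE_SIGMAS:
        planes.extend(gaussian_filter(image.data[:, :, c], sigma) for c in range(3))
    normed = [(p - p.mean()) / (p.std() + 1e-6) for p in planes]
    return np.stack(normed, axis=-1).reshape(-1, 3 * (1 + len(_FEATURE_SIGMAS)))


@dataclass(frozen=True)
class SegmenterConfig:
    """Hyperparameters of the pixel segmenter; all runs are seeded."""

    hidden_sizes: tuple[int, ...] = (24, 12)
    max_iter: int = 60
    learning_rate: float = 1e-3
    batch_size: int = 512
    max_train_pixels: int = 60_000  # seeded subsample across the training set
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iter <= 0 or self.learning_rate <= 0 or self.batch_size <= 0:
            raise ValueError("hyperparameters must be positive")


@dataclass
class FrozenSegmenter:
    """A trained, frozen pixel segmenter with a serializable checkpoint."""

    model: MLPClassifier
    config: SegmenterConfig
    training_curve_name: str
    exposure: float
    frozen: bool = True

    def predict_mask(self, image: RGBImage) -> np.ndarray:
        h, w = image.data.shape[:2]
        proba = self.model.predict_proba(extract_features(image))[:, 1]
        return (proba >= 0.5).astype(np.uint8).reshape(h, w)

    def checkpoint_json(self) -> str:
        """Deterministic JSON serialization of all learned weights."""
        payload = {
            "hidden_sizes": list(self.config.hidden_sizes),
            "training_curve": self.training_curve_name,
            "exposure": self.exposure,
            "coefs": [c.tolist() for c in self.model.coefs_],
            "intercepts": [b.tolist() for b in self.model.intercepts_],
        }
        return json.dumps(payload, sort_keys=True)

    def checkpoint_hash(self) -> str:
        return hashlib.sha256(self.checkpoint_json().encode()).hexdigest()


@dataclass(frozen=True)
class SwapRecord:
    curve_name: str
    incidence_angle_deg: float
    polarization: str  # "s", "p" or "unpolarized"
    miou: float


@dataclass(frozen=True)
class SwapReport:
    """One mIoU row per swapped-in transmittance curve, same frozen model."""

    records: tuple[SwapRecord, ...]
    frozen_model_id: str
    dataset_hash: str = field(default="", compare=False)

    def as_rows(self) -> list[dict]:
        return [
            {
                "curve_name": r.curve_name,
                "incidence_angle_deg": r.incidence_angle_deg,
                "polarization": r.polarization,
                "miou": r.miou,
            }
            for r in self.records
        ]

    def miou_of(self, curve_name: str) -> float:
        for r in self.records:
            if r.curve_name == curve_name:
                return r.miou
        raise KeyError(curve_name)


def _training_matrix(
    scenes: Iterable[Scene],
    filter_curve: SpectralCurve,
    csr: CameraSpectralResponse,
    exposure: float,
) -> tuple[np.ndarray, np.ndarray]:
    X, y = [], []
    for scene in scenes:
        img = synthesize_rgb(scene, filter_curve, csr, exposure)
        X.append(extract_features(img))
        y.append(scene.mask.ravel())
    return np.concatenate(X), np.concatenate(y)


def train_segmenter(
    train_scenes: Sequence[Scene],
    filter_curve: SpectralCurve,
    csr: CameraSpectralResponse,
    config: SegmenterConfig = SegmenterConfig(),
) -> FrozenSegmenter:
    """Train on RGB synthesized with ``filter_curve``, then freeze.

    The exposure is set from the no-filter rendering of the training
    scenes and stored with the model so swap evaluations reuse it.
    """
    train_scenes = list(train_scenes)
    if not train_scenes:
        raise ValueError("training set is empty")
    exposure = auto_exposure(train_scenes, csr)
    X, y = _training_matrix(train_scenes, filter_curve, csr, exposure)
    if len(np.unique(y)) < 2:
        raise ValueError("training scenes contain a single class")
    if X.shape[0] > config.max_train_pixels:
        rng = np.random.default_rng(config.seed)
        pick = rng.choice(X.shape[0], config.max_train_pixels, replace=False)
        X, y = X[pick], y[pick]
    model = MLPClassifier(
        hidden_layer_sizes=config.hidden_sizes,
        activation="relu",
        solver="adam",
        learning_rate_init=config.learning_rate,
        batch_size=config.batch_size,
        max_iter=config.max_iter,
        shuffle=True,
        random_state=config.seed,
        tol=0.0,
        n_iter_no_change=config.max_iter,
    )
    with warnings.catch_warnings():
        # the iteration cap is a deliberate budget, not a convergence failure
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        model.fit(X, y)
    if not np.all(np.isfinite(model.loss_curve_)):
        raise FloatingPointError("segmenter training diverged to a non-finite loss")
    return FrozenSegmenter(
        model=model,
        config=config,
        training_curve_name=filter_curve.name or "training_curve",
        exposure=exposure,
    )


def swap_and_evaluate(
    segmenter: FrozenSegmenter,
    test_scenes: Sequence[Scene],
    curves: Mapping[str, SpectralCurve] | Sequence[SpectralCurve],
    csr: CameraSpectralResponse,
    curve_meta: Mapping[str, tuple[float, str]] | None = None,
) -> SwapReport:
    """Score each named curve's mIoU under the one frozen segmenter.

    ``curve_meta`` optionally maps curve name → (incidence angle in
    degrees, polarization tag) for the report; unknown curves get NaN
    angle and "unpolarized".
    """
    if not segmenter.frozen:
        raise ValueError("segmenter must be frozen before swap evaluation")
    if not isinstance(curves, Mapping):
        curves = {c.name or f"curve_{i}": c for i, c in enumerate(curves)}
    before = segmenter.checkpoint_json()
    records = []
    gts = [s.mask for s in test_scenes]
    for name, curve in curves.items():
        preds = [
            segmenter.predict_mask(synthesize_rgb(s, curve, csr, segmenter.exposure))
            for s in test_scenes
        ]
        angle, pol = (curve_meta or {}).get(name, (float("nan"), "unpolarized"))
        records.append(SwapRecord(name, angle, pol, mean_iou(preds, gts)))
    if segmenter.checkpoint_json() != before:
        raise RuntimeError("frozen-model contract violated: weights changed during swap")
    return SwapReport(
        records=tuple(records),
        frozen_model_id=segmenter.checkpoint_hash(),
    )


def curves_for_design(
    stack: LayerStack,
    theta1: float,
    grid: SpectralGrid,
    prefix: str = "design",
) -> tuple[dict[str, SpectralCurve], dict[str, tuple[float, str]]]:
    """The three evaluation curves of one design: 0° unpolarized, θ1 s, θ1 p."""
    deg1 = float(np.degrees(theta1))
    sr1 = transmittance_spectrum(stack, theta1, grid)
    curves = {
        f"{prefix}_0deg": SpectralCurve(grid, unpolarized_T(stack, 0.0, grid), f"{prefix}_0deg"),
        f"{prefix}_{deg1:g}deg_s": SpectralCurve(grid, sr1.T_s, f"{prefix}_{deg1:g}deg_s"),
        f"{prefix}_{deg1:g}deg_p": SpectralCurve(grid, sr1.T_p, f"{prefix}_{deg1:g}deg_p"),
    }
    meta = {
        f"{prefix}_0deg": (0.0, "unpolarized"),
        f"{prefix}_{deg1:g}deg_s": (deg1, "s"),
        f"{prefix}_{deg1:g}deg_p": (deg1, "p"),
    }
    return curves, meta
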