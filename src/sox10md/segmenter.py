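"""Trainable pixel segmenter shared by the epidermis and nuclei detectors.

The segmenter is a classical pixel classifier: multiscale image features
(intensity, gradient magnitude at several Gaussian scales, per channel)
feed a logistic-regression model fitted by stochastic gradient descent,
one pass per epoch over pixel samples drawn from the training tiles.
It honours the same training contract a neural backend would: image-level
80/20 train/validation split driven by a seed, per-epoch loss logging,
optional flip/rotation/brightness augmentation, probability-map output,
and single-file checkpoint serialisation with the config embedded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import joblib
import numpy as np
from skimage.feature import multiscale_basic_features
from sklearn.linear_model import SGDClassifier
from sklearn.metrics import log_loss

from .core import CalibratedImage, ProbabilityMap
from .errors import ConfigurationError

_CHECKPOINT_VERSION = 1


@dataclass
class SegmenterConfig:
    """Training hyperparameters for a pixel segmenter.

    ``patch_size_px`` and ``magnification_level`` describe the tiling
    regime the detector expects (epidermis at 10x, nuclei at 20x);
    ``binarisation_threshold`` converts probability maps to masks with the
    tie rule probability >= threshold => foreground.
    """

    patch_size_px: int = 512
    magnification_level: str = "10x"
    learning_rate: float = 1e-5
    augment_rotations: bool = True
    augment_flips: bool = True
    augment_brightness: bool = True
    validation_fraction: float = 0.2
    epochs: int = 5
    seed: int = 0
    binarisation_threshold: float = 0.5
    pixels_per_image: int = 8000

    def __post_init__(self) -> None:
        if not 0 < self.validation_fraction < 1:
            raise ConfigurationError("validation_fraction must lie in (0, 1)")
        if not 0 < self.binarisation_threshold < 1:
            raise ConfigurationError("binarisation_threshold must lie strictly in (0, 1)")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.patch_size_px % 16 != 0:
            raise ConfigurationError("patch_size_px must be divisible by 16")


def split_fixtures(n: int, validation_fraction: float, seed: int) -> tuple[list[int], list[int]]:
    """Deterministic image-level train/validation split.

    Returns (train_indices, val_indices); at least one image lands on each
    side whenever ``n >= 2``.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(n).tolist()
    n_val = int(round(n * validation_fraction))
    n_val = max(1, min(n - 1, n_val)) if n >= 2 else 0
    return sorted(order[n_val:]), sorted(order[:n_val])


def _features(pixels: np.ndarray) -> np.ndarray:
    img = pixels.astype(np.float32) / 255.0
    feat = multiscale_basic_features(
        img,
        channel_axis=-1,
        intensity=True,
        edges=True,
        texture=False,
        sigma_min=1.0,
        sigma_max=8.0,
        num_sigma=3,
    )
    return feat.reshape(-1, feat.shape[-1])


def _augment(pixels: np.ndarray, mask: np.ndarray, cfg: SegmenterConfig, rng: np.random.Generator):
    if cfg.augment_rotations:
        k = int(rng.integers(0, 4))
        pixels, mask = np.rot90(pixels, k, axes=(0, 1)), np.rot90(mask, k)
    if cfg.augment_flips and rng.random() < 0.5:
        pixels, mask = pixels[:, ::-1], mask[:, ::-1]
    if cfg.augment_brightness:
        # mild jitter: the hematoxylin counterstain separates compartments by
        # only ~20 grey levels, so aggressive shifts would erase the signal
        gain = rng.uniform(0.97, 1.03)
        bias = rng.uniform(-4.0, 4.0)
        pixels = np.clip(pixels.astype(np.float32) * gain + bias, 0, 255).astype(np.uint8)
    return pixels, mask


class PixelSegmenter:
    """Logistic pixel classifier over multiscale features.

    An *untrained* instance is a valid baseline: it predicts probability
    0.5 everywhere, which the binarisation tie rule maps to all-foreground.
    """

    def __init__(self, config: SegmenterConfig | None = None, kind: str = "epidermis"):
        self.config = config or SegmenterConfig()
        self.kind = kind
        self.classifier: SGDClassifier | None = None
        self.loss_history: list[float] = []

    @property
    def trained(self) -> bool:
        return self.classifier is not None and hasattr(self.classifier, "coef_")

    # -- training -----------------------------------------------------------

    def fit(self, images: list[CalibratedImage], masks: list[np.ndarray]) -> "PixelSegmenter":
        if len(images) == 0:
            raise ConfigurationError("empty fixture set")
        if len(images) != len(masks):
            raise ConfigurationError("images and masks length mismatch")
        for im, m in zip(images, masks):
            if im.shape != m.shape[:2]:
                raise ConfigurationError("mask not aligned with image")
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        clf = SGDClassifier(
            loss="log_loss",
            learning_rate="constant",
            eta0=max(cfg.learning_rate * 5e4, 1e-3),  # rescaled for unit-range features
            alpha=1e-6,
            random_state=cfg.seed,
        )
        classes = np.array([0, 1])
        self.loss_history = []
        for _epoch in range(cfg.epochs):
            epoch_losses = []
            for im, m in zip(images, masks):
                px, mk = _augment(im.pixels, m.astype(bool), cfg, rng)
                X = _features(px)
                y = mk.reshape(-1).astype(int)
                idx = _balanced_sample(y, cfg.pixels_per_image, rng)
                clf.partial_fit(X[idx], y[idx], classes=classes)
                p = np.clip(_sigmoid(clf.decision_function(X[idx])), 1e-7, 1 - 1e-7)
                epoch_losses.append(log_loss(y[idx], p, labels=[0, 1]))
            self.loss_history.append(float(np.mean(epoch_losses)))
        self.classifier = clf
        return self

    # -- inference ----------------------------------------------------------

    def predict_probability(self, image: CalibratedImage) -> ProbabilityMap:
        if not self.trained:
            values = np.full(image.shape, 0.5)
        else:
            X = _features(image.pixels)
            values = _sigmoid(self.classifier.decision_function(X)).reshape(image.shape)
        return ProbabilityMap(values, image.microns_per_pixel)

    def predict_mask(self, image: CalibratedImage, threshold: float | None = None) -> np.ndarray:
        thr = self.config.binarisation_threshold if threshold is None else threshold
        return self.predict_probability(image).values >= thr

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        joblib.dump(
            {
                "version": _CHECKPOINT_VERSION,
                "kind": self.kind,
                "config": asdict(self.config),
                "classifier": self.classifier,
                "loss_history": self.loss_history,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "PixelSegmenter":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"checkpoint not found: {path}")
        blob = joblib.load(path)
        seg = cls(SegmenterConfig(**blob["config"]), kind=blob["kind"])
        seg.classifier = blob["classifier"]
        seg.loss_history = blob.get("loss_history", [])
        return seg


@dataclass
class TrainResult:
    """Outcome of a training run: the model plus its validation score."""

    segmenter: PixelSegmenter
    val_score: float
    baseline_score: float
    train_indices: list[int]
    val_indices: list[int]
    loss_history: list[float] = field(default_factory=list)
    metric: str = "iou"


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -40, 40)))


def _balanced_sample(y: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0 or len(neg) == 0:
        return rng.choice(len(y), size=min(n, len(y)), replace=False)
    half = n // 2
    take_pos = rng.choice(pos, size=min(half, len(pos)), replace=False)
    take_neg = rng.choice(neg, size=min(half, len(neg)), replace=False)
    return np.concatenate([take_pos, take_neg])


def iou_score(pred: np.ndarray, truth: np.ndarray) -> float:
    """Intersection over union of two binary masks (1.0 when both empty)."""
    pred, truth = pred.astype(bool), truth.astype(bool)
    union = np.logical_or(pred, truth).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(pred, truth).sum() / union)


def pixel_f1(pred: np.ndarray, truth: np.ndarray) -> float:
    """Pixelwise F1 of a binary prediction (1.0 when both empty)."""
    pred, truth = pred.astype(bool), truth.astype(bool)
    tp = np.logical_and(pred, truth).sum()
    denom = pred.sum() + truth.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * tp / denom)


def train_segmenter(
    images: list[CalibratedImage],
    masks: list[np.ndarray],
    config: SegmenterConfig,
    kind: str = "epidermis",
    metric: str = "iou",
) -> TrainResult:
    """Train a pixel segmenter with an image-level 80/20 split.

    The validation score is the mean IoU (or pixel F1) of thresholded
    probability maps over held-out tiles; ``baseline_score`` is the same
    quantity for an untrained segmenter, so callers can assert that
    training helped.
    """
    if len(images) == 0:
        raise ConfigurationError("empty fixture set")
    if len(images) < 2:
        raise ConfigurationError("need at least 2 fixtures for a train/validation split")
    tr_idx, va_idx = split_fixtures(len(images), config.validation_fraction, config.seed)

    seg = PixelSegmenter(config, kind=kind).fit(
        [images[i] for i in tr_idx], [masks[i] for i in tr_idx]
    )
    baseline = PixelSegmenter(config, kind=kind)

    score_fn = iou_score if metric == "iou" else pixel_f1
    scores, base_scores = [], []
    for i in va_idx:
        truth = masks[i].astype(bool)
        scores.append(score_fn(seg.predict_mask(images[i]), truth))
        base_scores.append(score_fn(baseline.predict_mask(images[i]), truth))
    return TrainResult(
        segmenter=seg,
        val_score=float(np.mean(scores)),
        baseline_score=float(np.mean(base_scores)),
        train_indices=tr_idx,
        val_indices=va_idx,
        loss_history=seg.loss_history,
        metric=metric,
    )
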