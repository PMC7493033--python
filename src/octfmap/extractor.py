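"""B-scan feature extraction: training-sample generation, normalization,
augmentation, and the trainable extractor backbones.

A B-scan feature extractor maps one grayscale B-scan to a fixed-length
feature vector L. The reference backbone is a 50-layer residual network whose
global average pooling yields L=2048; its pretrained weights are not bundled
with this package, so instantiating it raises with instructions. The fully
working backbone is ``tiny-cnn``: three conv/BN/LeakyReLU/pool stages and a
global average pool to L=64, trainable on CPU in seconds, which makes every
downstream stage testable at desk scale.

Because only volume-level diagnoses exist, B-scan training samples inherit
their volume's label ("label inheritance"); a diseased volume usually
contains normal-looking B-scans, so the inherited labels are noisy — a
property the synthetic fixtures deliberately reproduce.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
from skimage.transform import resize as _sk_resize

from . import nn
from .data_model import Volume

__all__ = [
    "ExtractorConfig", "FineTuneConfig", "BScanSample",
    "make_bscan_training_set", "normalize_bscan", "unnormalize_bscan",
    "augment_bscan", "TinyCNNExtractor", "create_extractor", "fine_tune",
    "save_extractor", "load_extractor",
]

# Standardization constants used for every B-scan (ImageNet-style grayscale)
DEFAULT_NORM_MEAN = 0.45
DEFAULT_NORM_SD = 0.23


@dataclass(frozen=True)
class ExtractorConfig:
    """Backbone selection and its fixed-length feature geometry."""

    backbone: str = "tiny-cnn"
    feature_length: int = 64
    input_size: int = 24
    normalization_mean: float = DEFAULT_NORM_MEAN
    normalization_sd: float = DEFAULT_NORM_SD

    def __post_init__(self):
        if self.feature_length < 1:
            raise ValueError("feature_length must be >= 1")
        if self.normalization_sd <= 0:
            raise ValueError("normalization_sd must be positive")

    @staticmethod
    def resnet50(pretrained_only: bool = True) -> "ExtractorConfig":
        """Reference-backbone geometry: 224x224 input, L=2048."""
        kind = "resnet50-pretrained" if pretrained_only else "resnet50-finetuned"
        return ExtractorConfig(backbone=kind, feature_length=2048, input_size=224)


@dataclass(frozen=True)
class FineTuneConfig:
    """Training protocol for the extractor head and unfrozen stages.

    Defaults are the reference fine-tuning protocol: freeze the first three
    conv stages, train the last two and the classification head with
    momentum SGD (lr 5e-4, momentum 0.95, batch 64, 3 epochs) under online
    crop/flip augmentation. When training the tiny backbone from random
    initialisation, pass an empty ``frozen_blocks`` and a from-scratch
    learning rate.
    """

    frozen_blocks: frozenset[str] = frozenset({"conv1", "conv2", "conv3"})
    n_classes: int = 2
    lr: float = 5e-4
    momentum: float = 0.95
    batch_size: int = 64
    epochs: int = 3
    crop_scale_range: tuple[float, float] = (0.7, 1.0)
    aspect_ratio_range: tuple[float, float] = (3.0 / 4.0, 4.0 / 3.0)
    flip_prob: float = 0.5
    augment: bool = True
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.crop_scale_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("crop_scale_range must satisfy 0 < low <= high <= 1")
        if not (0 <= self.flip_prob <= 1):
            raise ValueError("flip_prob must be in [0, 1]")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")


@dataclass(frozen=True)
class BScanSample:
    """One B-scan with the label inherited from its source volume."""

    image: np.ndarray
    label: str
    source_volume_id: str


def make_bscan_training_set(volumes: Iterable[Volume]) -> list[BScanSample]:
    """Assign each volume's label to each of its B-scans.

    The output size is the total B-scan count over the input volumes.
    """
    volumes = list(volumes)
    if not volumes:
        raise ValueError("cannot build a B-scan training set from no volumes")
    samples: list[BScanSample] = []
    for vol in volumes:
        if vol.label is None:
            raise ValueError(f"volume {vol.volume_id!r} has no label")
        for scan in vol.bscans:
            samples.append(BScanSample(image=scan, label=vol.label,
                                       source_volume_id=vol.volume_id))
    return samples


def normalize_bscan(image: np.ndarray, mean: float = DEFAULT_NORM_MEAN,
                    sd: float = DEFAULT_NORM_SD, n_channels: int = 3) -> np.ndarray:
    """Standardize a [0,1] B-scan and replicate it across channels.

    ``out = (in - mean) / sd`` per pixel; the same plane is repeated in each
    of ``n_channels`` channels (the reference backbone expects RGB input, the
    tiny backbone a single channel).
    """
    image = np.asarray(image, dtype=np.float64)
    normed = (image - mean) / sd
    return np.broadcast_to(normed, (n_channels,) + normed.shape).copy()


def unnormalize_bscan(planes: np.ndarray, mean: float = DEFAULT_NORM_MEAN,
                      sd: float = DEFAULT_NORM_SD) -> np.ndarray:
    """Invert :func:`normalize_bscan` (first channel)."""
    planes = np.asarray(planes, dtype=np.float64)
    first = planes[0] if planes.ndim == 3 else planes
    return first * sd + mean


def _resize(image: np.ndarray, size: int) -> np.ndarray:
    if image.shape == (size, size):
        return np.asarray(image, dtype=np.float64)
    return _sk_resize(image, (size, size), order=1, preserve_range=True,
                      anti_aliasing=False).astype(np.float64)


def augment_bscan(image: np.ndarray, rng: np.random.Generator, input_size: int,
                  crop_scale_range: tuple[float, float] = (0.7, 1.0),
                  aspect_ratio_range: tuple[float, float] = (3.0 / 4.0, 4.0 / 3.0),
                  flip_prob: float = 0.5) -> np.ndarray:
    """Random resized crop plus random horizontal flip.

    A crop window is drawn with area a uniform fraction of the image area in
    ``crop_scale_range`` and aspect ratio uniform in ``aspect_ratio_range``;
    after 10 infeasible draws the full centered frame is used. The crop is
    resized to ``input_size`` x ``input_size`` and flipped horizontally iff a
    uniform draw is below ``flip_prob``.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.shape[0] < 2 or image.shape[1] < 2:
        raise ValueError("image must be at least 2x2 for augmentation")
    h, w = image.shape
    area = h * w
    crop = None
    for _ in range(10):
        target_area = rng.uniform(*crop_scale_range) * area
        ratio = rng.uniform(*aspect_ratio_range)
        cw = int(round(np.sqrt(target_area * ratio)))
        ch = int(round(np.sqrt(target_area / ratio)))
        if 0 < cw <= w and 0 < ch <= h:
            top = rng.integers(0, h - ch + 1)
            left = rng.integers(0, w - cw + 1)
            crop = image[top:top + ch, left:left + cw]
            break
    if crop is None:  # fall back to the full centered frame
        crop = image
    out = _resize(crop, input_size)
    if rng.uniform() < flip_prob:
        out = out[:, ::-1].copy()
    return out


class TinyCNNExtractor(nn.Module):
    """Three-stage convolutional backbone with global average pooling.

    Stages conv1-conv3 are ConvBlocks (channels 8, 16, 64); the spatial
    output is globally average-pooled to the L=64 feature vector, feeding a
    linear classification head during training. Exists so the full pipeline
    trains in seconds on one CPU core.
    """

    STAGE_NAMES = ("conv1", "conv2", "conv3")

    def __init__(self, config: ExtractorConfig, n_classes: int = 2, seed: int = 0):
        super().__init__()
        if config.feature_length != 64:
            raise ValueError("tiny-cnn produces L=64 features")
        rng = np.random.default_rng(seed)
        self.config = config
        self.n_classes = n_classes
        self.conv1 = nn.ConvBlock(1, 8, 3, 0.01, rng)
        self.conv2 = nn.ConvBlock(8, 16, 3, 0.01, rng)
        self.conv3 = nn.ConvBlock(16, 64, 3, 0.01, rng)
        self.head = nn.Linear(64, n_classes, rng)
        self.class_names: list[str] = []

    @property
    def extractor_id(self) -> str:
        return f"tiny-cnn-L{self.config.feature_length}"

    @property
    def feature_length(self) -> int:
        return self.config.feature_length

    def features(self, x: nn.Tensor) -> nn.Tensor:
        """(N, 1, S, S) -> (N, 64) via the three stages and global avg pool."""
        x = self.conv3(self.conv2(self.conv1(x)))
        return x.mean(axis=(2, 3))

    def logits(self, x: nn.Tensor) -> nn.Tensor:
        return self.head(self.features(x))

    # ------------------------------------------------------------- inference
    def _prepare(self, images: np.ndarray) -> nn.Tensor:
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 2:
            images = images[None]
        size = self.config.input_size
        batch = np.stack([_resize(im, size) for im in images])
        batch = (batch - self.config.normalization_mean) / self.config.normalization_sd
        return nn.Tensor(batch[:, None, :, :])

    def extract_features(self, images: np.ndarray) -> np.ndarray:
        """Deterministic inference-mode feature extraction, (N, H, W) -> (N, L)."""
        was_training = self.training
        self.eval()
        out = self.features(self._prepare(images)).data.copy()
        if was_training:
            self.train()
        return out

    def extract_feature(self, image: np.ndarray) -> np.ndarray:
        """Single B-scan -> length-L feature vector."""
        return self.extract_features(np.asarray(image)[None])[0]

    def classify_bscans(self, images: np.ndarray) -> list[str]:
        """Predict per-B-scan labels with the classification head."""
        if not self.class_names:
            raise RuntimeError("extractor head has no class names; fine-tune first")
        was_training = self.training
        self.eval()
        scores = nn.softmax(self.logits(self._prepare(images)).data)
        if was_training:
            self.train()
        return [self.class_names[i] for i in scores.argmax(axis=1)]


def create_extractor(config: ExtractorConfig, n_classes: int = 2, seed: int = 0):
    """Instantiate the configured backbone."""
    if config.backbone == "tiny-cnn":
        return TinyCNNExtractor(config, n_classes=n_classes, seed=seed)
    if config.backbone.startswith("resnet50"):
        raise RuntimeError(
            "The resnet50 backbones require pretrained weights that are not "
            "bundled with this package; install them separately or use the "
            "'tiny-cnn' backbone for desk-scale runs.")
    raise ValueError(f"unknown backbone {config.backbone!r}")


def fine_tune(extractor: TinyCNNExtractor, samples: Sequence[BScanSample],
              cfg: FineTuneConfig) -> tuple[TinyCNNExtractor, list[float]]:
    """Train the unfrozen stages and head with momentum SGD.

    Stages named in ``cfg.frozen_blocks`` are completely fixed: their
    parameters are excluded from the optimizer and their batch-norm layers
    stay in inference mode, so their state is bit-identical before and after.
    Augmentation (random resized crop + flip) is applied online to every
    training sample; the loss history holds one entry per minibatch,
    ``epochs * ceil(n / batch_size)`` in total. ``epochs=0`` returns the
    extractor unchanged.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("no training samples")
    class_names = sorted({s.label for s in samples})
    if len(class_names) < 2:
        raise ValueError("fine-tuning requires samples from at least two classes")
    if len(class_names) != cfg.n_classes:
        raise ValueError(
            f"head has {cfg.n_classes} classes but samples carry {len(class_names)}")
    extractor.class_names = class_names
    extractor.trained_volume_ids = sorted({s.source_volume_id for s in samples})
    if cfg.epochs == 0:
        return extractor, []

    label_to_idx = {c: i for i, c in enumerate(class_names)}
    targets = np.array([label_to_idx[s.label] for s in samples])
    unknown = set(cfg.frozen_blocks) - set(TinyCNNExtractor.STAGE_NAMES)
    if unknown:
        raise ValueError(f"unknown frozen stage(s): {sorted(unknown)}")

    trainable: list[nn.Parameter] = list(extractor.head.parameters())
    for name in TinyCNNExtractor.STAGE_NAMES:
        if name not in cfg.frozen_blocks:
            trainable.extend(getattr(extractor, name).parameters())
    opt = nn.SGD(trainable, lr=cfg.lr, momentum=cfg.momentum)
    rng = np.random.default_rng(cfg.seed)

    size = extractor.config.input_size
    mean, sd = extractor.config.normalization_mean, extractor.config.normalization_sd
    n = len(samples)
    losses: list[float] = []
    for _ in range(cfg.epochs):
        extractor.train()
        for name in cfg.frozen_blocks:  # frozen BN stays in inference mode
            getattr(extractor, name).eval()
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if cfg.augment:
                batch = np.stack([
                    augment_bscan(samples[i].image, rng, size,
                                  cfg.crop_scale_range, cfg.aspect_ratio_range,
                                  cfg.flip_prob) for i in idx])
            else:
                batch = np.stack([_resize(samples[i].image, size) for i in idx])
            x = nn.Tensor(((batch - mean) / sd)[:, None, :, :])
            loss = nn.softmax_cross_entropy(extractor.logits(x), targets[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
    extractor.eval()
    return extractor, losses


# ----------------------------------------------------------------- checkpoints

def save_extractor(extractor: TinyCNNExtractor, path: str | Path) -> Path:
    path = Path(path)
    cfg = extractor.config
    meta = {"backbone": cfg.backbone, "feature_length": cfg.feature_length,
            "input_size": cfg.input_size,
            "normalization_mean": cfg.normalization_mean,
            "normalization_sd": cfg.normalization_sd,
            "n_classes": extractor.n_classes,
            "class_names": extractor.class_names}
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(meta)
        for key, arr in extractor.state_arrays().items():
            f.create_dataset(f"state/{key}", data=arr)
    return path


def load_extractor(path: str | Path) -> TinyCNNExtractor:
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["config"])
        state = {k: f[f"state/{k}"][()] for k in f["state"]}
    cfg = ExtractorConfig(backbone=meta["backbone"],
                          feature_length=meta["feature_length"],
                          input_size=meta["input_size"],
                          normalization_mean=meta["normalization_mean"],
                          normalization_sd=meta["normalization_sd"])
    ext = TinyCNNExtractor(cfg, n_classes=meta["n_classes"])
    ext.load_state_arrays(state)
    ext.class_names = list(meta["class_names"])
    ext.eval()
    return ext
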