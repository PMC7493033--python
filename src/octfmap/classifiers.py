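"""Volume-level classifiers for 2-D feature maps.

Three classifiers operate on the (n_bscans, L) feature map of a volume:

* ``lsvm`` — a linear support vector machine with L2 penalty and squared
  hinge loss on the row-major ("lexicographic") flattening of the map;
* ``cnn`` — n convolution blocks (3x3 same-padded conv to 4 channels, batch
  norm, LeakyReLU, 2x2 floor max pooling), a fully connected layer and a
  softmax classifier; the constraint ``2**n < n_rows`` guarantees every
  block has rows to pool;
* ``cnn_cbam`` — the same network with a convolutional block attention
  module refining the last block's output (channel attention then spatial
  attention) before the FC layer.

For an n=4 network on a 100x2048 map the block outputs are (4,50,1024),
(4,25,512), (4,12,256), (4,6,128), and the FC layer sees a flattened vector
of 4*6*128 = 3072 elements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
from sklearn.svm import LinearSVC

from . import nn
from .feature_map import FeatureMap, flatten_lexicographic

__all__ = [
    "VolumeClassifierConfig", "VolumeCNN", "VolumeCNNClassifier",
    "LSVMClassifier", "shape_chain", "conv_block_forward", "cbam_refine",
    "train_volume_classifier", "predict_volume",
    "save_classifier", "load_classifier",
]


@dataclass(frozen=True)
class VolumeClassifierConfig:
    """Architecture and training hyperparameters for a volume classifier.

    Defaults follow the reference protocol: 3x3 kernels with four channels,
    momentum SGD with lr 1e-3 and momentum 0.9, 150 epochs, minibatch 64;
    the LSVM uses an L2 penalty with squared hinge loss (C=1).
    """

    kind: str = "cnn_cbam"
    n_blocks: int = 4
    channels: int = 4
    kernel: int = 3
    leaky_slope: float = 0.01
    cbam_reduction: int = 2
    cbam_spatial_kernel: int = 7
    n_classes: int = 2
    lr: float = 1e-3
    momentum: float = 0.9
    epochs: int = 150
    batch_size: int = 64
    svm_c: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("lsvm", "cnn", "cnn_cbam"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.kind == "cnn_cbam" and self.cbam_reduction > self.channels:
            raise ValueError("cbam_reduction must not exceed channels")
        if self.lr <= 0 or self.epochs < 0:
            raise ValueError("lr must be positive and epochs non-negative")


def shape_chain(rows: int, cols: int, n_blocks: int, channels: int = 4
                ) -> list[tuple[int, int, int]]:
    """Per-block output shapes (channels, H, W) under 2x2 floor pooling."""
    shapes = []
    h, w = rows, cols
    for _ in range(n_blocks):
        h, w = h // 2, w // 2
        shapes.append((channels, h, w))
    return shapes


class VolumeCNN(nn.Module):
    """The n-block convolutional classifier, optionally with CBAM."""

    def __init__(self, cfg: VolumeClassifierConfig, input_shape: tuple[int, int]):
        super().__init__()
        rows, cols = input_shape
        if 2 ** cfg.n_blocks >= rows:
            raise ValueError(
                f"configuration invalid: 2**n_blocks = {2 ** cfg.n_blocks} must be "
                f"less than the feature-map row count {rows}")
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.input_shape = tuple(input_shape)
        self.blocks = [
            nn.ConvBlock(1 if i == 0 else cfg.channels, cfg.channels, cfg.kernel,
                         cfg.leaky_slope, rng)
            for i in range(cfg.n_blocks)]
        self.cbam = (nn.CBAM(cfg.channels, cfg.cbam_reduction,
                             cfg.cbam_spatial_kernel, rng)
                     if cfg.kind == "cnn_cbam" else None)
        c, h, w = shape_chain(rows, cols, cfg.n_blocks, cfg.channels)[-1]
        if h < 1 or w < 1:
            raise ValueError(
                f"map of shape {input_shape} collapses to {h}x{w} after "
                f"{cfg.n_blocks} pooling stages")
        self.flat_len = c * h * w
        self.fc = nn.Linear(self.flat_len, cfg.n_classes, rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        """(N, 1, rows, cols) -> (N, K) logits."""
        for block in self.blocks:
            x = block(x)
        if self.cbam is not None:
            x = self.cbam(x)
        return self.fc(x.reshape(x.shape[0], self.flat_len))

    __call__ = forward

    def block_outputs(self, x: nn.Tensor) -> list[nn.Tensor]:
        outs = []
        for block in self.blocks:
            x = block(x)
            outs.append(x)
        return outs


def conv_block_forward(x: np.ndarray, block: nn.ConvBlock) -> np.ndarray:
    """Forward one (C, H, W) tensor through a conv block, returning (C', H//2, W//2)."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError("expected a (C, H, W) input")
    if x.shape[1] < 2 or x.shape[2] < 2:
        raise ValueError(f"spatial dims {x.shape[1:]} too small for pooling")
    return block(nn.Tensor(x[None])).data[0]


def cbam_refine(x: np.ndarray, cbam: nn.CBAM) -> np.ndarray:
    """Apply channel-then-spatial attention to one (C, H, W) tensor."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError("expected a (C, H, W) input")
    return cbam(nn.Tensor(x[None])).data[0]


def _stack_maps(maps: Sequence[FeatureMap]) -> np.ndarray:
    shapes = {m.values.shape for m in maps}
    if len(shapes) > 1:
        raise ValueError(f"heterogeneous feature-map shapes: {sorted(shapes)}")
    return np.stack([m.values for m in maps])


class VolumeCNNClassifier:
    """A trained CNN / CNN_CBAM plus its label vocabulary."""

    def __init__(self, model: VolumeCNN, class_names: list[str]):
        self.model = model
        self.class_names = class_names
        self.trained_volume_ids: list[str] = []

    @property
    def kind(self) -> str:
        return self.model.cfg.kind

    def predict(self, fmap: FeatureMap) -> tuple[str, np.ndarray]:
        if fmap.values.shape != self.model.input_shape:
            raise ValueError(
                f"map shape {fmap.values.shape} does not match the training "
                f"shape {self.model.input_shape}")
        self.model.eval()
        logits = self.model(nn.Tensor(fmap.values[None, None])).data
        probs = nn.softmax(logits)[0]
        return self.class_names[int(np.argmax(probs))], probs


class LSVMClassifier:
    """Linear SVM (L2 penalty, squared hinge) on flattened feature maps."""

    def __init__(self, svc: LinearSVC, class_names: list[str],
                 input_shape: tuple[int, int]):
        self.svc = svc
        self.class_names = class_names
        self.input_shape = tuple(input_shape)
        self.trained_volume_ids: list[str] = []

    kind = "lsvm"

    def predict(self, fmap: FeatureMap) -> tuple[str, np.ndarray]:
        if fmap.values.shape != self.input_shape:
            raise ValueError(
                f"map shape {fmap.values.shape} does not match the training "
                f"shape {self.input_shape}")
        vec = flatten_lexicographic(fmap)[None, :]
        decision = self.svc.decision_function(vec)
        if decision.ndim == 1:  # binary: signed distance to the hyperplane
            scores = np.array([-decision[0], decision[0]])
        else:
            scores = decision[0]
        idx = int(self.svc.predict(vec)[0])
        return self.class_names[idx], scores


def train_volume_classifier(maps: Sequence[FeatureMap], cfg: VolumeClassifierConfig
                            ) -> tuple[VolumeCNNClassifier | LSVMClassifier, list[float]]:
    """Fit the configured classifier on labeled feature maps.

    Returns the classifier and a per-minibatch loss history (empty for the
    LSVM). Deterministic for a fixed ``cfg.seed``.
    """
    maps = list(maps)
    if not maps:
        raise ValueError("no training maps")
    class_names = sorted({m.label for m in maps if m.label is not None})
    if len(class_names) < 2:
        raise ValueError("training requires maps from at least two classes")
    if len(class_names) != cfg.n_classes:
        raise ValueError(
            f"config declares {cfg.n_classes} classes but maps carry "
            f"{len(class_names)}")
    x = _stack_maps(maps)
    label_to_idx = {c: i for i, c in enumerate(class_names)}
    y = np.array([label_to_idx[m.label] for m in maps])
    volume_ids = [m.volume_id for m in maps]

    if cfg.kind == "lsvm":
        svc = LinearSVC(penalty="l2", loss="squared_hinge", C=cfg.svm_c,
                        random_state=cfg.seed)
        flat = x.reshape(len(maps), -1)
        svc.fit(flat, y)
        clf = LSVMClassifier(svc, class_names, x.shape[1:])
        clf.trained_volume_ids = volume_ids
        return clf, []

    model = VolumeCNN(cfg, x.shape[1:])
    opt = nn.SGD(model.parameters(), lr=cfg.lr, momentum=cfg.momentum)
    rng = np.random.default_rng(cfg.seed + 1)
    losses: list[float] = []
    n = len(maps)
    model.train()
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = nn.Tensor(x[idx][:, None])
            loss = nn.softmax_cross_entropy(model(batch), y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
    model.eval()
    clf = VolumeCNNClassifier(model, class_names)
    clf.trained_volume_ids = volume_ids
    return clf, losses


def predict_volume(classifier, fmap: FeatureMap) -> tuple[str, np.ndarray]:
    """Predicted class label and per-class score vector for one map.

    Ties in the score vector resolve to the lowest class index.
    """
    return classifier.predict(fmap)


# ----------------------------------------------------------------- checkpoints

def save_classifier(clf, path: str | Path) -> Path:
    path = Path(path)
    if isinstance(clf, LSVMClassifier):
        with h5py.File(path, "w") as f:
            f.attrs["meta"] = json.dumps({
                "kind": "lsvm", "class_names": clf.class_names,
                "input_shape": list(clf.input_shape),
                "C": clf.svc.C})
            f.create_dataset("coef", data=clf.svc.coef_)
            f.create_dataset("intercept", data=clf.svc.intercept_)
            f.create_dataset("classes", data=clf.svc.classes_)
        return path
    cfg = clf.model.cfg
    with h5py.File(path, "w") as f:
        f.attrs["meta"] = json.dumps({
            "kind": cfg.kind, "class_names": clf.class_names,
            "input_shape": list(clf.model.input_shape),
            "config": {k: getattr(cfg, k) for k in (
                "kind", "n_blocks", "channels", "kernel", "leaky_slope",
                "cbam_reduction", "cbam_spatial_kernel", "n_classes", "lr",
                "momentum", "epochs", "batch_size", "svm_c", "seed")}})
        for key, arr in clf.model.state_arrays().items():
            f.create_dataset(f"state/{key}", data=arr)
    return path


def load_classifier(path: str | Path):
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta"])
        if meta["kind"] == "lsvm":
            svc = LinearSVC(penalty="l2", loss="squared_hinge", C=meta["C"])
            svc.coef_ = f["coef"][()]
            svc.intercept_ = f["intercept"][()]
            svc.classes_ = f["classes"][()]
            return LSVMClassifier(svc, meta["class_names"],
                                  tuple(meta["input_shape"]))
        state = {k: f[f"state/{k}"][()] for k in f["state"]}
    cfg = VolumeClassifierConfig(**meta["config"])
    model = VolumeCNN(cfg, tuple(meta["input_shape"]))
    model.load_state_arrays(state)
    model.eval()
    return VolumeCNNClassifier(model, meta["class_names"])
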