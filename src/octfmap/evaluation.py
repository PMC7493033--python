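"""Evaluation: ACC/SE/SP metrics, stratified fivefold cross-validation at the
volume level, and the repeated stratified 40/60 split protocol.

The confusion matrix is oriented by the manifest's designated positive class
(e.g. AMD positive / NOR negative on Duke-style data, DME positive / AMD
negative on two-disease data). Sensitivity is TP/(TP+FN), specificity
TN/(TN+FP), accuracy (TP+TN)/all; a metric whose denominator is zero is
reported as absent (NaN), never silently as 0. Reports carry per-fold
metrics as percentages with mean and sample standard deviation (ddof=1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classifiers import VolumeClassifierConfig, predict_volume, train_volume_classifier
from .data_model import DatasetManifest, Volume
from .extractor import (ExtractorConfig, FineTuneConfig, create_extractor,
                        fine_tune, make_bscan_training_set)
from .feature_map import build_feature_map

__all__ = [
    "ConfusionCounts", "Metrics", "EvalReport", "compute_metrics",
    "stratified_kfold", "partition_sizes", "run_cv", "run_repeated_split",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN oriented by the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @staticmethod
    def from_predictions(truth: Sequence[str], predicted: Sequence[str],
                         positive_class: str) -> "ConfusionCounts":
        if len(truth) != len(predicted):
            raise ValueError("truth and predicted lengths differ")
        tp = tn = fp = fn = 0
        for t, p in zip(truth, predicted):
            if t == positive_class:
                if p == positive_class:
                    tp += 1
                else:
                    fn += 1
            else:
                if p == positive_class:
                    fp += 1
                else:
                    tn += 1
        return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


@dataclass(frozen=True)
class Metrics:
    """ACC/SE/SP as fractions in [0, 1]; an undefined metric is None."""

    acc: float
    se: float | None
    sp: float | None


def compute_metrics(c: ConfusionCounts) -> Metrics:
    """ACC=(TP+TN)/all, SE=TP/(TP+FN), SP=TN/(TN+FP).

    SE is absent when no positive volumes were evaluated, SP when no
    negative volumes were; evaluating zero volumes is an error.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics over zero volumes")
    acc = (c.tp + c.tn) / c.total
    se = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    return Metrics(acc=acc, se=se, sp=sp)


def partition_sizes(n: int, k: int) -> list[int]:
    """Sizes of a near-equal partition of n into k parts (differ by <= 1)."""
    q, r = divmod(n, k)
    return [q + 1] * r + [q] * (k - r)


def stratified_kfold(manifest: DatasetManifest, k: int = 5, seed: int = 0
                     ) -> list[list[str]]:
    """Class-wise near-equal random partition into k volume-level folds.

    Each class is shuffled and split into k parts whose sizes differ by at
    most one; fold i is the union of part i over all classes. Folds are
    pairwise disjoint and cover the manifest.
    """
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    for cls in manifest.class_names:
        ids = [e.volume_id for e in manifest.entries if e.label == cls]
        if len(ids) < k:
            raise ValueError(
                f"class {cls!r} has {len(ids)} volumes, fewer than k={k}")
        order = rng.permutation(len(ids))
        sizes = partition_sizes(len(ids), k)
        # parts are assigned to folds in shuffled order so the odd-sized
        # parts do not always land in the first folds
        fold_order = rng.permutation(k)
        start = 0
        for part, size in enumerate(sizes):
            members = [ids[j] for j in order[start:start + size]]
            folds[fold_order[part]].extend(members)
            start += size
    return folds


@dataclass
class EvalReport:
    """Per-fold and aggregate ACC/SE/SP, as percentages."""

    protocol: str
    seed: int
    per_fold: list[dict[str, float]]
    mean: dict[str, float] = field(default_factory=dict)
    std: dict[str, float] = field(default_factory=dict)
    notes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.per_fold and not self.mean:
            self._aggregate()

    def _aggregate(self):
        for key in ("acc", "se", "sp"):
            vals = np.array([f[key] for f in self.per_fold], dtype=float)
            vals = vals[~np.isnan(vals)]
            self.mean[key] = float(vals.mean()) if vals.size else float("nan")
            # sample standard deviation over folds/repeats; 0 by convention
            # for a single fold
            self.std[key] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        if len(self.per_fold) == 1:
            self.notes["single_repeat"] = True
        self.notes.setdefault("std_ddof", 1)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {"protocol": self.protocol, "seed": self.seed,
                   "per_fold": self.per_fold, "mean": self.mean,
                   "std": self.std, "notes": self.notes}
        path.write_text(json.dumps(payload, indent=2))
        return path

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = pd.DataFrame(self.per_fold)
        df.loc["mean"] = pd.Series(self.mean)
        df.loc["std"] = pd.Series(self.std)
        df.to_csv(path)
        return path


def _metrics_percent(m: Metrics) -> dict[str, float]:
    return {"acc": 100.0 * m.acc,
            "se": 100.0 * m.se if m.se is not None else float("nan"),
            "sp": 100.0 * m.sp if m.sp is not None else float("nan")}


def _evaluate_split(volumes_by_id: dict[str, Volume], manifest: DatasetManifest,
                    train_ids: list[str], test_ids: list[str],
                    extractor_cfg: ExtractorConfig, finetune_cfg: FineTuneConfig,
                    clf_cfg: VolumeClassifierConfig, split_seed: int
                    ) -> dict[str, float]:
    """Train on the training volumes only and evaluate on the held-out ones.

    The leakage guard asserts that no test volume's ID appears in any
    training-stage log (extractor fine-tuning or classifier fitting).
    """
    train_vols = [volumes_by_id[i] for i in train_ids]
    test_vols = [volumes_by_id[i] for i in test_ids]

    extractor = create_extractor(extractor_cfg, n_classes=len(manifest.class_names),
                                 seed=split_seed)
    samples = make_bscan_training_set(train_vols)
    extractor, _ = fine_tune(extractor, samples, replace(finetune_cfg, seed=split_seed))
    train_maps = [build_feature_map(v, extractor) for v in train_vols]
    clf, _ = train_volume_classifier(train_maps, replace(clf_cfg, seed=split_seed))

    trained_ids = set(clf.trained_volume_ids) | set(
        getattr(extractor, "trained_volume_ids", []))
    leaked = trained_ids & set(test_ids)
    if leaked:
        raise RuntimeError(
            f"leakage guard violated: test volume(s) {sorted(leaked)} appear "
            f"in training-stage logs")

    truth, predicted = [], []
    for vol in test_vols:
        fmap = build_feature_map(vol, extractor)
        label, _ = predict_volume(clf, fmap)
        truth.append(vol.label)
        predicted.append(label)
    counts = ConfusionCounts.from_predictions(truth, predicted,
                                              manifest.positive_class)
    return _metrics_percent(compute_metrics(counts))


def run_cv(volumes: Sequence[Volume], manifest: DatasetManifest,
           extractor_cfg: ExtractorConfig, finetune_cfg: FineTuneConfig,
           clf_cfg: VolumeClassifierConfig, k: int = 5, seed: int = 0
           ) -> EvalReport:
    """Stratified fivefold cross-validation at the volume level.

    Per fold: fine-tune the extractor on the training folds' B-scans only,
    build feature maps, train the volume classifier on training maps, and
    evaluate on the held-out fold. No test volume influences any training
    stage (asserted per fold).
    """
    volumes_by_id = {v.volume_id: v for v in volumes}
    folds = stratified_kfold(manifest, k=k, seed=seed)
    all_ids = set(manifest.volume_ids)
    per_fold = []
    for i, test_ids in enumerate(folds):
        train_ids = sorted(all_ids - set(test_ids))
        per_fold.append(_evaluate_split(
            volumes_by_id, manifest, train_ids, sorted(test_ids),
            extractor_cfg, finetune_cfg, clf_cfg, split_seed=seed * 1000 + i))
    return EvalReport(protocol=f"stratified-{k}fold", seed=seed, per_fold=per_fold)


def run_repeated_split(volumes: Sequence[Volume], manifest: DatasetManifest,
                       extractor_cfg: ExtractorConfig, finetune_cfg: FineTuneConfig,
                       clf_cfg: VolumeClassifierConfig,
                       train_fraction: float = 0.4, repeats: int = 5,
                       seed: int = 0) -> EvalReport:
    """Repeated per-class stratified split at ``train_fraction``.

    Each repeat draws a fresh random split: within each class,
    round-half-up(train_fraction * class size) volumes train, the rest test.
    Metrics aggregate over repeats as mean +/- sample std.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    volumes_by_id = {v.volume_id: v for v in volumes}
    per_fold = []
    for r in range(repeats):
        rng = np.random.default_rng(seed * 1000 + r)
        train_ids: list[str] = []
        test_ids: list[str] = []
        for cls in manifest.class_names:
            ids = [e.volume_id for e in manifest.entries if e.label == cls]
            n_train = int(np.floor(train_fraction * len(ids) + 0.5))  # half-up
            if n_train == 0 or n_train == len(ids):
                raise ValueError(
                    f"train_fraction {train_fraction} leaves an empty train or "
                    f"test set for class {cls!r}")
            order = rng.permutation(len(ids))
            train_ids.extend(ids[j] for j in order[:n_train])
            test_ids.extend(ids[j] for j in order[n_train:])
        per_fold.append(_evaluate_split(
            volumes_by_id, manifest, sorted(train_ids), sorted(test_ids),
            extractor_cfg, finetune_cfg, clf_cfg, split_seed=seed * 1000 + r))
    report = EvalReport(protocol=f"repeated-split-{train_fraction:.2f}",
                        seed=seed, per_fold=per_fold)
    report.notes["repeats"] = repeats
    return report


def train_sizes_for_split(class_sizes: Sequence[int], train_fraction: float = 0.4
                          ) -> list[int]:
    """Round-half-up per-class training-set sizes (448, 462 at 40% -> 179, 185)."""
    return [int(np.floor(train_fraction * n + 0.5)) for n in class_sizes]
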