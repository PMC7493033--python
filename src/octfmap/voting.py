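"""Slice-voting baseline: volume-level decisions from per-B-scan labels.

For a two-class problem, a volume is called positive when the fraction of
its B-scans predicted positive strictly exceeds a threshold epsilon
(boundary case: a fraction exactly equal to epsilon yields the negative
class). A threshold sweep over a grid reports ACC/SE/SP per epsilon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .evaluation import ConfusionCounts, compute_metrics

__all__ = ["VoteSummary", "vote_volume", "sweep_thresholds"]


@dataclass(frozen=True)
class VoteSummary:
    """Outcome of thresholded voting over one volume's B-scan labels."""

    volume_id: str
    fractions: dict[str, float]       # per-class fraction of B-scans, sums to 1
    bscan_labels: tuple[str, ...]
    decision: str
    threshold: float


def vote_volume(bscan_labels: Sequence[str], positive_class: str,
                negative_class: str, eps: float, volume_id: str = "") -> VoteSummary:
    """Decide a volume's label from its per-B-scan labels.

    The decision is the positive class iff the positive fraction is
    strictly larger than ``eps``; otherwise the negative class.
    """
    labels = tuple(bscan_labels)
    if not labels:
        raise ValueError("cannot vote over an empty B-scan label list")
    if not (0.0 <= eps < 1.0):
        raise ValueError("eps must lie in [0, 1)")
    n = len(labels)
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    # single division per class: 60 of 100 compares exactly equal to 0.6
    fractions = {lab: c / n for lab, c in counts.items()}
    p_pos = fractions.get(positive_class, 0.0)
    decision = positive_class if p_pos > eps else negative_class
    return VoteSummary(volume_id=volume_id, fractions=fractions,
                       bscan_labels=labels, decision=decision, threshold=eps)


def sweep_thresholds(bscan_predictions: Mapping[str, Sequence[str]],
                     truth: Mapping[str, str], positive_class: str,
                     negative_class: str,
                     eps_grid: Sequence[float]) -> pd.DataFrame:
    """Re-decide every volume at every epsilon and tabulate ACC/SE/SP.

    ``bscan_predictions`` maps volume_id to its per-B-scan predicted labels;
    ``truth`` maps volume_id to the true volume-level label. Returns one row
    per epsilon with columns eps, acc, se, sp (fractions in [0, 1]).
    """
    eps_grid = list(eps_grid)
    if not eps_grid:
        raise ValueError("epsilon grid is empty")
    for eps in eps_grid:
        if not (0.0 <= eps < 1.0):
            raise ValueError(f"grid value {eps} outside [0, 1)")
    rows = []
    for eps in eps_grid:
        decisions = {
            vid: vote_volume(labels, positive_class, negative_class, eps, vid).decision
            for vid, labels in bscan_predictions.items()}
        counts = ConfusionCounts.from_predictions(
            [truth[vid] for vid in decisions],
            [decisions[vid] for vid in decisions], positive_class)
        m = compute_metrics(counts)
        rows.append({"eps": eps, "acc": m.acc, "se": m.se, "sp": m.sp,
                     "n_positive_decisions": sum(
                         d == positive_class for d in decisions.values())})
    return pd.DataFrame(rows)
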