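"""Pixel-level evaluation metrics for binary segmentation.

Seven quantities computed from a confusion matrix: accuracy, precision,
recall, Dice score, F1, intersection-over-union and the Matthews
correlation coefficient. For a binary mask pair the count-form Dice
2TP/(2TP+FP+FN) coincides with the set form 2|A∩B|/(|A|+|B|), and Dice and
IoU satisfy D = 2J/(1+J).

Zero denominators (e.g. precision with no positive predictions) yield 0
with a logged warning; the both-empty Dice convention is 1.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .exceptions import ShapeMismatch
from .geometry import as_binary_mask

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "compute_metrics",
    "dice_overlap",
    "micro_average",
    "reports_to_frame",
    "save_reports",
    "plot_confusion",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise ValueError("confusion counts must total at least 1")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    dice: float
    f1: float
    iou: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def confusion_counts(pred, gt) -> ConfusionCounts:
    """Per-pixel TP/FP/TN/FN tallies for a prediction/ground-truth pair."""
    p = as_binary_mask(pred).astype(bool)
    g = as_binary_mask(gt).astype(bool)
    if p.shape != g.shape:
        raise ShapeMismatch(f"prediction {p.shape} vs ground truth {g.shape}")
    tp = int(np.sum(p & g))
    fp = int(np.sum(p & ~g))
    fn = int(np.sum(~p & g))
    tn = int(np.sum(~p & ~g))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); returning 0", name)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """All seven metrics from confusion counts.

    MCC uses the product form (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN));
    undefined ratios return 0 with a warning.
    """
    tp, fp, tn, fn = (float(c.tp), float(c.fp), float(c.tn), float(c.fn))
    accuracy = _ratio(tp + tn, tp + tn + fp + fn, "accuracy")
    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    dice = _ratio(2 * tp, 2 * tp + fp + fn, "dice")
    f1 = _ratio(2 * precision * recall, precision + recall, "f1")
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _ratio(tp * tn - fp * fn, mcc_den, "mcc")
    iou = _ratio(tp, tp + fp + fn, "iou")
    return MetricsReport(accuracy=accuracy, precision=precision, recall=recall,
                         dice=dice, f1=f1, iou=iou, mcc=mcc)


def dice_overlap(pred, gt) -> float:
    """Set-form Dice 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    p = as_binary_mask(pred).astype(bool)
    g = as_binary_mask(gt).astype(bool)
    if p.shape != g.shape:
        raise ShapeMismatch(f"prediction {p.shape} vs ground truth {g.shape}")
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.sum(p & g)) / denom


def overlap_scores(pred, gt) -> tuple[float, float]:
    """Per-image (dice, iou) with the both-empty = perfect (1.0) convention.

    Suited to per-image averaging over datasets where many images contain
    no foreground: a clean rejection counts as a perfect score instead of
    an undefined 0/0.
    """
    p = as_binary_mask(pred).astype(bool)
    g = as_binary_mask(gt).astype(bool)
    if p.shape != g.shape:
        raise ShapeMismatch(f"prediction {p.shape} vs ground truth {g.shape}")
    union = int(np.sum(p | g))
    if union == 0:
        return 1.0, 1.0
    inter = int(np.sum(p & g))
    iou = inter / union
    return 2 * iou / (1 + iou), iou


def micro_average(counts: list[ConfusionCounts]) -> MetricsReport:
    """Pool pixel counts over an evaluation set, then compute metrics."""
    total = counts[0]
    for c in counts[1:]:
        total = total + c
    return compute_metrics(total)


def reports_to_frame(rows: dict[str, MetricsReport]) -> pd.DataFrame:
    """One row per configuration label."""
    frame = pd.DataFrame({name: r.as_dict() for name, r in rows.items()}).T
    frame.index.name = "configuration"
    return frame


def save_reports(rows: dict[str, MetricsReport], csv_path=None, json_path=None) -> pd.DataFrame:
    frame = reports_to_frame(rows)
    if csv_path is not None:
        frame.to_csv(csv_path)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump({name: r.as_dict() for name, r in rows.items()}, fh, indent=2)
    return frame


def plot_confusion(c: ConfusionCounts, path, title: str = "Confusion matrix") -> None:
    """Render a 2x2 confusion-matrix heatmap to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = np.array([[c.tn, c.fp], [c.fn, c.tp]], dtype=float)
    fig, ax = plt.subplots(figsize=(3.2, 3.0))
    ax.imshow(mat, cmap="Blues")
    for (i, j), val in np.ndenumerate(mat):
        ax.text(j, i, f"{int(val)}", ha="center", va="center")
    ax.set_xticks([0, 1], ["pred normal", "pred tumor"])
    ax.set_yticks([0, 1], ["true normal", "true tumor"])
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
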