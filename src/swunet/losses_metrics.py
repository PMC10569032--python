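"""Training losses and evaluation metrics for segmentation masks.

Losses
------
* soft Dice loss  ``1 - (2 sum(y y') + eps) / (sum(y) + sum(y') + eps)``
* Focal loss      ``sum_i [ -y (1-y')^g log y' - (1-y) y'^g log(1-y') ]``
* the compound training objective ``alpha * L_Dice + beta * L_Focal`` with
  the reference weighting alpha = 0.8, beta = 0.2.

Metrics (the five columns reported per case and aggregated):
accuracy, Dice ``2TP / (2TP + FP + FN)``, sensitivity, specificity, and the
Hausdorff distance between mask boundary point sets, usually at the robust
95th percentile (H95).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

#: column order used by the report tables
REPORT_COLUMNS = ("Accuracy", "Dice", "Sensitivity", "Specificity", "H95")


class UndefinedMetricError(ValueError):
    """A metric is undefined for this input (e.g. Hausdorff with an empty set)."""


# ---------------------------------------------------------------------------
# confusion counts and count-based metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred_mask, true_mask, class_id: int = 1) -> ConfusionCounts:
    """One-vs-rest pixel counts for ``class_id``."""
    pred_mask = np.asarray(pred_mask)
    true_mask = np.asarray(true_mask)
    if pred_mask.shape != true_mask.shape:
        raise ValueError(f"mask shapes differ: {pred_mask.shape} vs {true_mask.shape}")
    p = pred_mask == class_id
    t = true_mask == class_id
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tn=int(np.sum(~p & ~t)),
    )


def dice_coefficient(counts: ConfusionCounts) -> float:
    """``2TP / (2TP + FP + FN)``; two empty masks agree perfectly (1.0)."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        return 1.0
    return 2.0 * counts.tp / denom


def accuracy(counts: ConfusionCounts) -> float:
    return (counts.tp + counts.tn) / counts.total


def sensitivity(counts: ConfusionCounts) -> float | None:
    denom = counts.tp + counts.fn
    return counts.tp / denom if denom else None


def specificity(counts: ConfusionCounts) -> float | None:
    denom = counts.tn + counts.fp
    return counts.tn / denom if denom else None


# ---------------------------------------------------------------------------
# Hausdorff distances
# ---------------------------------------------------------------------------

def hausdorff(x_points, y_points, percentile: float = 100) -> float:
    """``max{ d(X, Y), d(Y, X) }`` between two pixel-coordinate sets.

    The directed distance ``d(X, Y)`` collects, for each point of ``X``, its
    Euclidean distance to the nearest point of ``Y`` and aggregates at
    ``percentile`` (100 gives the classical maximum; 95 the robust H95).
    """
    x = np.atleast_2d(np.asarray(list(x_points), dtype=float))
    y = np.atleast_2d(np.asarray(list(y_points), dtype=float))
    if x.size == 0 or y.size == 0:
        raise UndefinedMetricError("Hausdorff distance is undefined for an empty point set")

    def directed(a, b):
        d, _ = cKDTree(b).query(a, k=1)
        return float(np.max(d)) if percentile >= 100 else float(np.percentile(d, percentile))

    return max(directed(x, y), directed(y, x))


def boundary_points(mask) -> np.ndarray:
    """Coordinates of foreground pixels with at least one 4-neighbour outside."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.empty((0, mask.ndim), dtype=int)
    interior = ndimage.binary_erosion(mask, border_value=0)
    return np.argwhere(mask & ~interior)


# ---------------------------------------------------------------------------
# losses (numpy reference forms, used for offline verification and reports)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LossConfig:
    """Weights and constants of the compound segmentation loss."""

    alpha: float = 0.8
    beta: float = 0.2
    gamma: float = 2.0
    epsilon: float = 1e-5
    clip: float = 1e-7
    #: reduction of the focal term; "sum" is the literal equation (and the
    #: training default), "mean" reports on a per-pixel scale
    reduction: str = "sum"

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("loss weights must be non-negative")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def dice_loss(pred_probs, true_mask, eps: float = 1e-5) -> float:
    """Soft Dice loss ``1 - (2 sum(y y') + eps) / (sum(y) + sum(y') + eps)``."""
    p = np.asarray(pred_probs, dtype=float)
    t = np.asarray(true_mask, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"shapes differ: {p.shape} vs {t.shape}")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("pred_probs must lie in [0, 1]")
    inter = float((p * t).sum())
    denom = float(p.sum() + t.sum())
    return 1.0 - (2.0 * inter + eps) / (denom + eps)


def focal_loss(pred_probs, true_mask, gamma: float = 2.0, clip: float = 1e-7,
               reduction: str = "sum") -> float:
    """Focal loss; ``gamma = 0`` reduces to plain binary cross-entropy."""
    p = np.clip(np.asarray(pred_probs, dtype=float), clip, 1.0 - clip)
    t = np.asarray(true_mask, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"shapes differ: {p.shape} vs {t.shape}")
    terms = -t * (1.0 - p) ** gamma * np.log(p) - (1.0 - t) * p ** gamma * np.log(1.0 - p)
    return float(terms.mean()) if reduction == "mean" else float(terms.sum())


def combined_loss(pred_probs, true_mask, cfg: LossConfig = LossConfig()) -> float:
    """``alpha * L_Dice + beta * L_Focal`` exactly."""
    return cfg.alpha * dice_loss(pred_probs, true_mask, cfg.epsilon) + cfg.beta * focal_loss(
        pred_probs, true_mask, cfg.gamma, cfg.clip, cfg.reduction
    )


def segmentation_loss(class_probs, labels, cfg: LossConfig = LossConfig()) -> float:
    """Compound loss on multi-class probabilities, one-vs-rest per foreground
    class and averaged; mirrors the differentiable training objective."""
    class_probs = np.asarray(class_probs, dtype=float)
    labels = np.asarray(labels)
    if class_probs.ndim == labels.ndim:  # (C, ...) vs (...)
        class_probs = class_probs[None]
        labels = labels[None]
    n_classes = class_probs.shape[1]
    vals = []
    for c in range(1, n_classes):
        vals.append(combined_loss(class_probs[:, c], (labels == c).astype(float), cfg))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# per-case report
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Per-class metric values for one case; ``None`` marks undefined entries."""

    per_class: dict = field(default_factory=dict)
    n_undefined: int = 0
    case_id: str = ""

    def aggregate(self) -> dict:
        """Unweighted mean over foreground classes, skipping undefined values."""
        out = {}
        for col in REPORT_COLUMNS:
            vals = [m[col] for m in self.per_class.values() if m[col] is not None]
            out[col] = float(np.mean(vals)) if vals else None
        return out

    def to_json(self) -> str:
        return json.dumps(
            {"case_id": self.case_id, "per_class": self.per_class,
             "aggregate": self.aggregate(), "n_undefined": self.n_undefined},
            indent=2,
        )


def full_report(pred_mask, true_mask, classes=None, percentile: float = 95,
                case_id: str = "") -> MetricsReport:
    """Accuracy, Dice, sensitivity, specificity and H95 per foreground class."""
    pred_mask = np.asarray(pred_mask)
    true_mask = np.asarray(true_mask)
    if pred_mask.shape != true_mask.shape:
        raise ValueError(f"mask shapes differ: {pred_mask.shape} vs {true_mask.shape}")
    if classes is None:
        top = int(max(pred_mask.max(initial=0), true_mask.max(initial=0)))
        classes = list(range(1, top + 1)) or [1]

    report = MetricsReport(case_id=case_id)
    for c in classes:
        counts = confusion(pred_mask, true_mask, c)
        row = {
            "Accuracy": accuracy(counts),
            "Dice": dice_coefficient(counts),
            "Sensitivity": sensitivity(counts),
            "Specificity": specificity(counts),
        }
        pb = boundary_points(pred_mask == c)
        tb = boundary_points(true_mask == c)
        if len(pb) and len(tb):
            row["H95"] = hausdorff(pb, tb, percentile)
        elif len(pb) == 0 and len(tb) == 0:
            row["H95"] = 0.0  # both empty: identical boundaries
        else:
            row["H95"] = None
        report.n_undefined += sum(v is None for v in row.values())
        report.per_class[c] = row
    return report


def aggregate_reports(reports: list) -> dict:
    """Mean over cases of each per-case aggregate column (undefined skipped)."""
    out = {}
    for col in REPORT_COLUMNS:
        vals = [r.aggregate()[col] for r in reports if r.aggregate()[col] is not None]
        out[col] = float(np.mean(vals)) if vals else None
    return out


def reports_to_csv(reports: list) -> str:
    """Per-case aggregate rows plus a mean row, in the report column order."""
    lines = ["case_id," + ",".join(REPORT_COLUMNS)]
    for r in reports:
        agg = r.aggregate()
        lines.append(
            r.case_id + "," + ",".join(
                "" if agg[c] is None else f"{agg[c]:.6f}" for c in REPORT_COLUMNS
            )
        )
    mean = aggregate_reports(reports)
    lines.append(
        "mean," + ",".join("" if mean[c] is None else f"{mean[c]:.6f}" for c in REPORT_COLUMNS)
    )
    return "\n".join(lines) + "\n"
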