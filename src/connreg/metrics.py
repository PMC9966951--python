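"""Pixelwise segmentation evaluation.

Confusion counts with foreground as the positive class, the five scalar
scores built from them (accuracy, precision, sensitivity, specificity, F1),
the area under the ROC curve traced by (1 - specificity, sensitivity) over a
threshold sweep, and a connected-component count used as a connectivity
diagnostic for thin structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

__all__ = [
    "ConfusionCounts",
    "ScalarMetrics",
    "MetricReport",
    "confusion",
    "scalar_metrics",
    "roc_auc",
    "component_count",
    "evaluate_masks",
]

# 8-connectivity: diagonal neighbours belong to the same component.
_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ScalarMetrics:
    """Scalar scores; a 0/0 case is NaN and listed in ``undefined``."""

    acc: float
    pre: float
    sen: float
    spe: float
    f1: float
    undefined: frozenset[str] = frozenset()

    def defined(self, name: str) -> bool:
        return name not in self.undefined


@dataclass(frozen=True)
class MetricReport:
    acc: float
    pre: float
    sen: float
    spe: float
    f1: float
    auc: float | None
    component_count_pred: int
    component_count_gt: int
    undefined: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["undefined"] = list(self.undefined)
        return d


def _as_bool_mask(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m)
    if m.ndim != 2:
        raise ValueError(f"{name} must be a 2-D mask")
    return m.astype(bool)


def confusion(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Exact pixel confusion counts (foreground = positive class)."""
    pred = _as_bool_mask(pred, "pred")
    gt = _as_bool_mask(gt, "gt")
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    tp = int(np.sum(pred & gt))
    tn = int(np.sum(~pred & ~gt))
    fp = int(np.sum(pred & ~gt))
    fn = int(np.sum(~pred & gt))
    return ConfusionCounts(tp, tn, fp, fn)


def _ratio(num: int, den: int) -> tuple[float, bool]:
    if den == 0:
        return math.nan, False
    return num / den, True


def scalar_metrics(c: ConfusionCounts) -> ScalarMetrics:
    """Accuracy, precision, sensitivity, specificity and F1 from counts.

    Acc = (TP+TN)/(TP+TN+FP+FN), Pre = TP/(TP+FP), Sen = TP/(TP+FN),
    Spe = TN/(TN+FP), F1 = 2*Sen*Pre/(Sen+Pre). Any 0/0 is returned as NaN
    and flagged by name in ``undefined`` rather than coerced to 0 or 1.
    """
    if c.total == 0:
        raise ValueError("confusion counts are empty")
    undefined: set[str] = set()
    acc = (c.tp + c.tn) / c.total
    pre, ok = _ratio(c.tp, c.tp + c.fp)
    if not ok:
        undefined.add("pre")
    sen, ok = _ratio(c.tp, c.tp + c.fn)
    if not ok:
        undefined.add("sen")
    spe, ok = _ratio(c.tn, c.tn + c.fp)
    if not ok:
        undefined.add("spe")
    if math.isnan(pre) or math.isnan(sen) or (sen + pre) == 0:
        f1 = math.nan
        undefined.add("f1")
    else:
        f1 = 2.0 * sen * pre / (sen + pre)
    return ScalarMetrics(acc, pre, sen, spe, f1, frozenset(undefined))


def roc_auc(prob: np.ndarray, gt: np.ndarray, n_thresholds: int = 256) -> float:
    """Area under the (1 - Spe, Sen) curve over a fixed threshold sweep.

    Thresholds are swept over [0, 1] inclusive; the curve endpoints (0, 0)
    and (1, 1) are appended and the area is integrated by the trapezoid
    rule. A pixel is predicted positive when its score is >= the threshold.
    """
    prob = np.asarray(prob, dtype=float)
    gt = _as_bool_mask(gt, "gt")
    if prob.shape != gt.shape:
        raise ValueError("prob and gt must share a shape")
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("prob values must lie in [0, 1]")
    n_pos = int(gt.sum())
    n_neg = gt.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("gt must contain both classes")
    pos = np.sort(prob[gt])
    neg = np.sort(prob[~gt])
    thresholds = np.linspace(0.0, 1.0, n_thresholds + 1)
    # count of scores >= t via binary search on the sorted score lists
    tp = n_pos - np.searchsorted(pos, thresholds, side="left")
    fp = n_neg - np.searchsorted(neg, thresholds, side="left")
    sen = tp / n_pos
    fpr = fp / n_neg
    x = np.concatenate(([0.0], fpr[::-1], [1.0]))
    y = np.concatenate(([0.0], sen[::-1], [1.0]))
    order = np.argsort(x, kind="stable")
    return float(np.trapezoid(y[order], x[order]))


def component_count(mask: np.ndarray) -> int:
    """Number of 8-connected foreground components."""
    mask = _as_bool_mask(mask, "mask")
    _, n = ndimage.label(mask, structure=_EIGHT)
    return int(n)


def evaluate_masks(
    pred: np.ndarray, gt: np.ndarray, prob: np.ndarray | None = None
) -> MetricReport:
    """Full report for a predicted mask (and optional soft scores) vs ground truth."""
    c = confusion(pred, gt)
    s = scalar_metrics(c)
    auc = None if prob is None else roc_auc(prob, gt)
    return MetricReport(
        acc=s.acc,
        pre=s.pre,
        sen=s.sen,
        spe=s.spe,
        f1=s.f1,
        auc=auc,
        component_count_pred=component_count(pred),
        component_count_gt=component_count(gt),
        undefined=tuple(sorted(s.undefined)),
    )
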