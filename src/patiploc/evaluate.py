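"""Detection matching, performance metrics, ROC operating-point selection,
and stratified position errors.

A retained detection (confidence above its class threshold) is a true
positive when a same-class ground truth overlaps it with IoU > 0.5; any
other retained detection is a false positive, and a false positive is
additionally a misclassification when an opposite-class truth overlaps it
with IoU > 0.5.  Every truth lands in exactly one of {detected,
misclassified, missed}, so per class

    recall + misclassification rate + missed detection rate = 100 %.

ROC curves sweep the confidence threshold; since object detection has no
true negatives, the false positive rate is normalized by the false
positive count at threshold zero, giving FPR(0) = 1.  The optimal
threshold slides a line of slope FP0/TP0 from the ideal operating point
(0, 1) down-and-right until it first touches the curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import BoxAnnotation
from .geometry import GridGeometry, TransducerSpec
from .simulate import ARTIFACT, SOURCE

__all__ = [
    "Detection",
    "MatchedFrame",
    "ClassMetrics",
    "EvaluationReport",
    "RocCurve",
    "iou",
    "categorize",
    "compute_metrics",
    "roc_curve",
    "optimal_threshold",
    "position_errors",
    "summarize_errors",
]

IOU_THRESHOLD = 0.5


@dataclass(frozen=True)
class Detection:
    """A detector output: class, 32x16 box (by center), confidence, frame."""

    object_class: str
    center_col: float
    center_row: float
    confidence: float
    frame_id: int | None = None
    width: float = 32.0
    height: float = 16.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def box(self) -> BoxAnnotation:
        return BoxAnnotation(self.object_class, self.center_col,
                             self.center_row, self.width, self.height)


def iou(a: BoxAnnotation | Detection, b: BoxAnnotation | Detection) -> float:
    """Intersection-over-union of two axis-aligned boxes (continuous coords)."""
    ax0, ay0 = a.center_col - a.width / 2, a.center_row - a.height / 2
    ax1, ay1 = a.center_col + a.width / 2, a.center_row + a.height / 2
    bx0, by0 = b.center_col - b.width / 2, b.center_row - b.height / 2
    bx1, by1 = b.center_col + b.width / 2, b.center_row + b.height / 2
    iw = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    ih = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = iw * ih
    union = a.width * a.height + b.width * b.height - inter
    return inter / union if union > 0 else 0.0


@dataclass
class MatchedFrame:
    """Outcome of matching one frame's detections against its truths."""

    # (detection, status 'TP'|'FP', misclassified flag, matched truth index or None)
    detections: list[tuple[Detection, str, bool, int | None]]
    # per truth: 'detected' | 'misclassified' | 'missed'
    truth_status: list[str]
    truths: list[BoxAnnotation]


def categorize(detections: list[Detection], truths: list[BoxAnnotation],
               thresholds: dict[str, float]) -> MatchedFrame:
    """Filter by per-class confidence threshold and match greedily.

    Detections are processed in descending confidence order; each truth is
    consumed at most once, either by a same-class true positive or by an
    opposite-class misclassification.  Detections at or below their class
    threshold are discarded entirely (strict inequality).
    """
    retained = [d for d in detections
                if d.confidence > thresholds.get(d.object_class, 0.0)]
    retained.sort(key=lambda d: -d.confidence)
    truth_status = ["missed"] * len(truths)
    records: list[tuple[Detection, str, bool, int | None]] = []
    for det in retained:
        best_same, best_same_iou = None, IOU_THRESHOLD
        best_opp, best_opp_iou = None, IOU_THRESHOLD
        for ti, truth in enumerate(truths):
            if truth_status[ti] != "missed":
                continue
            v = iou(det, truth)
            if v > best_same_iou and truth.object_class == det.object_class:
                best_same, best_same_iou = ti, v
            elif v > best_opp_iou and truth.object_class != det.object_class:
                best_opp, best_opp_iou = ti, v
        if best_same is not None:
            truth_status[best_same] = "detected"
            records.append((det, "TP", False, best_same))
        elif best_opp is not None:
            truth_status[best_opp] = "misclassified"
            records.append((det, "FP", True, best_opp))
        else:
            records.append((det, "FP", False, None))
    return MatchedFrame(detections=records, truth_status=truth_status,
                        truths=truths)


@dataclass
class ClassMetrics:
    """Per-class counts and percentage scores."""

    n_truths: int
    n_detections: int
    tp: int
    fp: int
    misclassified_truths: int
    missed_truths: int

    @property
    def recall_pct(self) -> float:
        return 100.0 * self.tp / self.n_truths if self.n_truths else math.nan

    @property
    def precision_pct(self) -> float:
        denom = self.tp + self.fp
        return 100.0 * self.tp / denom if denom else math.nan

    @property
    def precision_defined(self) -> bool:
        return (self.tp + self.fp) > 0

    @property
    def f1_pct(self) -> float:
        p, r = self.precision_pct, self.recall_pct
        if math.isnan(p) or math.isnan(r) or p + r == 0:
            return math.nan
        return 2.0 * p * r / (p + r)

    @property
    def misclassification_rate_pct(self) -> float:
        return (100.0 * self.misclassified_truths / self.n_truths
                if self.n_truths else math.nan)

    @property
    def missed_detection_rate_pct(self) -> float:
        return (100.0 * self.missed_truths / self.n_truths
                if self.n_truths else math.nan)


@dataclass
class EvaluationReport:
    per_class: dict[str, ClassMetrics]
    frames: list[MatchedFrame] = field(default_factory=list)


def compute_metrics(matched: list[MatchedFrame]) -> EvaluationReport:
    """Aggregate matched frames into per-class recall/precision/F1 and rates.

    A class's false positives are detections *of that class*; its
    misclassification rate counts truths *of that class* consumed by
    opposite-class detections, so the three truth-side rates partition
    each class's ground truths.
    """
    per_class = {}
    for cls in (SOURCE, ARTIFACT):
        n_truths = n_det = tp = fp = mis_truth = missed = 0
        for mf in matched:
            for truth, status in zip(mf.truths, mf.truth_status):
                if truth.object_class == cls:
                    n_truths += 1
                    if status == "misclassified":
                        mis_truth += 1
                    elif status == "missed":
                        missed += 1
            for det, status, _mis, _ti in mf.detections:
                if det.object_class == cls:
                    n_det += 1
                    if status == "TP":
                        tp += 1
                    else:
                        fp += 1
        per_class[cls] = ClassMetrics(n_truths=n_truths, n_detections=n_det,
                                      tp=tp, fp=fp,
                                      misclassified_truths=mis_truth,
                                      missed_truths=missed)
    return EvaluationReport(per_class=per_class, frames=matched)


def f1_from_precision_recall(precision_pct: float, recall_pct: float) -> float:
    """F1 (%) from precision and recall percentages: 2PR / (P + R)."""
    if precision_pct + recall_pct == 0:
        return math.nan
    return 2.0 * precision_pct * recall_pct / (precision_pct + recall_pct)


@dataclass
class RocCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    fp0: int
    tp0: int
    object_class: str


def _counts_at(dets_sorted: list[Detection], truths_by_frame,
               object_class: str, tau: float) -> tuple[int, int]:
    tp = fp = 0
    by_frame: dict = {}
    for d in dets_sorted:
        if d.confidence > tau:
            by_frame.setdefault(d.frame_id, []).append(d)
    for fid, dets in by_frame.items():
        mf = categorize(dets, truths_by_frame.get(fid, []), {object_class: tau})
        for det, status, _m, _t in mf.detections:
            if status == "TP":
                tp += 1
            else:
                fp += 1
    return tp, fp


def roc_curve(detections: list[Detection],
              truths_by_frame: dict[int | None, list[BoxAnnotation]],
              object_class: str) -> RocCurve:
    """ROC for one class by sweeping the confidence threshold.

    TPR(tau) = TP(tau) / n_truths; FPR(tau) = FP(tau) / FP(0) (object
    detection has no true negatives, so the threshold-zero false positive
    count normalizes the x axis; with zero false positives the curve is a
    vertical segment at FPR 0).  AUC is the trapezoid integral over the
    swept curve closed at (0, 0).
    """
    dets = [d for d in detections if d.object_class == object_class]
    n_truths = sum(1 for ts in truths_by_frame.values()
                   for t in ts if t.object_class == object_class)
    if n_truths == 0:
        raise ValueError(f"no ground truths of class {object_class!r}")
    confidences = sorted({d.confidence for d in dets}, reverse=True)
    taus = np.array([1.0] + [c - 1e-12 for c in confidences] + [0.0])
    tp0, fp0 = _counts_at(dets, truths_by_frame, object_class, 0.0)
    tpr, fpr = [], []
    for tau in taus:
        tp, fp = _counts_at(dets, truths_by_frame, object_class, float(tau))
        tpr.append(tp / n_truths)
        fpr.append(fp / fp0 if fp0 > 0 else 0.0)
    tpr_a, fpr_a = np.array(tpr), np.array(fpr)
    order = np.argsort(fpr_a, kind="stable")
    auc = float(np.trapezoid(tpr_a[order], fpr_a[order]))
    return RocCurve(thresholds=taus, tpr=tpr_a, fpr=fpr_a, auc=auc,
                    fp0=fp0, tp0=tp0, object_class=object_class)


def optimal_threshold(curve: RocCurve) -> float:
    """Line-shift operating point: slope FP0/TP0 slid from (FPR 0, TPR 1).

    A line of that slope through the ideal corner is translated down and
    to the right; the first curve point it touches maximizes
    TPR - slope * FPR (the supporting-line point).  Ties take the point
    with the smallest FPR (highest threshold).
    """
    if len(curve.thresholds) == 1:
        return float(curve.thresholds[0])
    slope = curve.fp0 / curve.tp0 if curve.tp0 > 0 else 0.0
    score = curve.tpr - slope * curve.fpr
    best = np.lexsort((curve.fpr, -score))[0]
    return float(curve.thresholds[best])


def position_errors(matched: list[MatchedFrame], grid: GridGeometry,
                    spec: TransducerSpec) -> pd.DataFrame:
    """World-space localization errors of the true-positive source detections.

    Box centers are converted to (lateral, axial) mm through the processed
    grid.  Each row carries the aperture stratum (under: |lateral| <=
    aperture half-width; outside otherwise) and the 10 mm axial bin of the
    ground truth, left-open right-closed (group 1 = (15, 25] mm).
    """
    rows = []
    half_ap = spec.aperture_width_mm / 2.0
    for mf in matched:
        for det, status, _m, ti in mf.detections:
            if status != "TP" or ti is None:
                continue
            truth = mf.truths[ti]
            dl, da = grid.pixel_to_world(det.center_col, det.center_row)
            tl, ta = grid.pixel_to_world(truth.center_col, truth.center_row)
            lat_err, ax_err = abs(dl - tl), abs(da - ta)
            depth_group = int(math.ceil((ta - 15.0) / 10.0)) if ta > 15.0 else 0
            rows.append({
                "object_class": det.object_class,
                "truth_lateral_mm": tl, "truth_axial_mm": ta,
                "lateral_error_mm": lat_err, "axial_error_mm": ax_err,
                "euclidean_error_mm": math.hypot(dl - tl, da - ta),
                "aperture_stratum": "under" if abs(tl) <= half_ap else "outside",
                "depth_group": depth_group,
            })
    return pd.DataFrame(rows, columns=[
        "object_class", "truth_lateral_mm", "truth_axial_mm",
        "lateral_error_mm", "axial_error_mm", "euclidean_error_mm",
        "aperture_stratum", "depth_group"])


def summarize_errors(errors: pd.DataFrame,
                     by: str | None = None) -> pd.DataFrame:
    """Mean +/- std summary of the error columns, optionally per stratum."""
    cols = ["lateral_error_mm", "axial_error_mm", "euclidean_error_mm"]
    if by is None:
        return errors[cols].agg(["mean", "std"])
    return errors.groupby(by)[cols].agg(["mean", "std"])
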