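"""Detection and classification evaluation: AP / mAP, PR curves,
confusion matrices.

AP is the area under the precision-recall curve (all-points
interpolation), computed per class after greedy one-to-one matching of
score-sorted detections to ground-truth boxes at an IoU threshold.
mAP is the arithmetic mean of the per-class APs; mAP@0.5-0.95
additionally averages over the ten IoU thresholds 0.50, 0.55, ...,
0.95.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .detector import Box, Detection, box_iou
from .errors import ValidationError
from .imaging import BoxLabel

logger = logging.getLogger(__name__)

#: The standard IoU threshold grid: 0.50 to 0.95 in steps of 0.05.
IOU_THRESHOLDS = tuple(np.round(np.arange(0.5, 0.951, 0.05), 2))


@dataclass
class EvalResult:
    """Per-class AP at each IoU threshold plus the two mAP summaries."""

    ap: dict                      # {iou_thresh: {class_id: AP or None}}
    map50: float
    map50_95: float
    pr_curves: dict = field(default_factory=dict)   # {class_id: (recall, precision)}


def _match_detections(dets, gts, iou_thresh):
    """Greedy matching by descending confidence; ties broken by higher
    IoU then lower detection index.  Returns a TP/FP flag per detection
    (in sorted order) and the sort order."""
    order = sorted(range(len(dets)),
                   key=lambda i: (-dets[i].confidence, i))
    matched = set()
    flags = np.zeros(len(order), dtype=bool)
    for rank, di in enumerate(order):
        d = dets[di]
        best_iou, best_gt = 0.0, None
        for gi, g in enumerate(gts):
            if gi in matched or g.image_path != d.image_path:
                continue
            iou = box_iou(d.box, Box.from_label(g))
            if iou > best_iou:
                best_iou, best_gt = iou, gi
        if best_gt is not None and best_iou >= iou_thresh:
            matched.add(best_gt)
            flags[rank] = True
    return flags, order


def _ap_from_flags(flags: np.ndarray, n_gt: int) -> tuple:
    """All-points-interpolated area under the PR curve."""
    tp = np.cumsum(flags)
    fp = np.cumsum(~flags)
    recall = tp / n_gt
    precision = tp / np.maximum(tp + fp, 1)
    # precision envelope, then sum over recall increments
    r = np.concatenate([[0.0], recall, [recall[-1] if len(recall) else 0.0]])
    p = np.concatenate([[1.0], precision, [0.0]])
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    ap = float(np.sum((r[1:] - r[:-1]) * p[1:]))
    return ap, (recall, precision)


def average_precision(dets, gts, iou_thresh: float = 0.5,
                      return_curves: bool = False):
    """Per-class AP at one IoU threshold.

    Classes present in the ground truth but never detected get AP 0;
    classes with no ground truth get AP ``None`` (excluded from means,
    logged).
    """
    classes = sorted({g.class_id for g in gts} | {d.class_id for d in dets})
    aps, curves = {}, {}
    for cls in classes:
        cls_gts = [g for g in gts if g.class_id == cls]
        cls_dets = [d for d in dets if d.class_id == cls]
        if not cls_gts:
            logger.info("class %d has no ground truth; AP undefined", cls)
            aps[cls] = None
            continue
        if not cls_dets:
            aps[cls] = 0.0
            curves[cls] = (np.array([]), np.array([]))
            continue
        flags, _ = _match_detections(cls_dets, cls_gts, iou_thresh)
        aps[cls], curves[cls] = _ap_from_flags(flags, len(cls_gts))
    return (aps, curves) if return_curves else aps


def mean_ap(dets, gts, thresholds=IOU_THRESHOLDS) -> EvalResult:
    """mAP@0.5 and mAP over the full threshold grid."""
    thresholds = tuple(float(t) for t in thresholds)
    if 0.5 not in thresholds:
        raise ValidationError("threshold grid must include 0.5")
    ap_by_thresh = {}
    curves50 = {}
    for t in thresholds:
        if t == 0.5:
            aps, curves50 = average_precision(dets, gts, t, return_curves=True)
        else:
            aps = average_precision(dets, gts, t)
        ap_by_thresh[t] = aps

    def mean_over_classes(aps):
        vals = [v for v in aps.values() if v is not None]
        return float(np.mean(vals)) if vals else float("nan")

    map50 = mean_over_classes(ap_by_thresh[0.5])
    all_means = [mean_over_classes(ap_by_thresh[t]) for t in thresholds]
    return EvalResult(ap=ap_by_thresh, map50=map50,
                      map50_95=float(np.mean(all_means)),
                      pr_curves=curves50)


# ---------------------------------------------------------------------------
# Classification


def confusion_matrix(pred_classes, true_classes, m: int = 6) -> np.ndarray:
    """m x m counts; entry (i, j) counts true class i+1 predicted j+1."""
    pred = np.asarray(pred_classes, dtype=int)
    true = np.asarray(true_classes, dtype=int)
    if pred.shape != true.shape:
        raise ValidationError("prediction and truth lists differ in length")
    if ((pred < 1) | (pred > m) | (true < 1) | (true > m)).any():
        raise ValidationError(f"labels must lie in 1..{m}")
    mat = np.zeros((m, m), dtype=int)
    np.add.at(mat, (true - 1, pred - 1), 1)
    return mat


#: Pooling of the six motions into the three degrees of freedom.
DOF_GROUPS = {1: "wrist_EC", 2: "wrist_EC", 3: "wrist_RLR", 4: "wrist_RLR",
              5: "elbow", 6: "elbow"}
DOF_ORDER = ("elbow", "wrist_EC", "wrist_RLR")


def confusion_matrix_dof(pred_classes, true_classes) -> np.ndarray:
    """3x3 confusion matrix over joint degrees of freedom
    (elbow, wrist_EC, wrist_RLR)."""
    idx = {name: i + 1 for i, name in enumerate(DOF_ORDER)}
    pred = [idx[DOF_GROUPS[int(p)]] for p in pred_classes]
    true = [idx[DOF_GROUPS[int(t)]] for t in true_classes]
    return confusion_matrix(pred, true, m=3)


def accuracy(pred_classes, true_classes) -> float:
    pred = np.asarray(pred_classes)
    true = np.asarray(true_classes)
    if pred.shape != true.shape:
        raise ValidationError("prediction and truth lists differ in length")
    return float(np.mean(pred == true))
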