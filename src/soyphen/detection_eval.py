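"""Detection and segmentation evaluation.

Scores detector output against ground-truth boxes with the PASCAL-style
protocol: detections are ranked by confidence and greedily matched
one-to-one to ground truth at an IOU threshold (default 0.5); the ranked
TP/FP flags yield precision, recall and average precision

    AP = sum_k Precision(k) * dRecall(k)

over ranked detections k, with mAP the unweighted mean of class APs.
Semantic segmentation masks are scored with MIoU, the mean over classes
(background included) of per-class pixel IoU.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from soyphen.annotations_io import BoundingBox, ImageAnnotation
from soyphen.errors import DataValidationError


@dataclass(frozen=True)
class Detection:
    """One detector output box; confidence is mandatory."""

    image_id: str
    box: BoundingBox
    label: str
    confidence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise DataValidationError(f"confidence {self.confidence} outside [0,1]")


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one class's detections to ground truth.

    ``flags`` holds True (TP) / False (FP) per detection in
    descending-confidence order; conservation holds by construction:
    tp + fn == number of ground-truth boxes, tp + fp == len(flags).
    """

    label: str
    tp: int
    fp: int
    fn: int
    flags: tuple[bool, ...]
    confidences: tuple[float, ...]
    unmatched_gt: tuple[tuple[str, int], ...] = field(default_factory=tuple)

    @property
    def n_gt(self) -> int:
        return self.tp + self.fn


def box_iou(a: BoundingBox, b: BoundingBox) -> float:
    """Positional intersection-over-union of two boxes; 0 when disjoint.

    Half-open coordinates: boxes sharing only an edge or corner have zero
    intersection.
    """
    iw = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    ih = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (a.area + b.area - inter)


def match_detections(
    gt: Iterable[ImageAnnotation],
    dets: Iterable[Detection],
    label: str,
    iou_thresh: float = 0.5,
) -> MatchResult:
    """Greedy one-to-one matching of one class's detections to ground truth.

    Detections are sorted by descending confidence (ties keep input order)
    and each is matched to the unmatched same-class ground-truth box of its
    image with the highest IOU >= ``iou_thresh``; IOU ties break toward the
    earlier ground-truth index.  A detection overlapping only already
    matched ground truth is an FP; leftover ground truth are FN.
    """
    gt_by_image: dict[str, list[BoundingBox]] = {}
    for ann in gt:
        if ann.image_id in gt_by_image:
            raise DataValidationError(f"duplicate ground-truth image id {ann.image_id!r}")
        gt_by_image[ann.image_id] = [b for b in ann.boxes if b.label == label]

    class_dets = [d for d in dets if d.label == label]
    for d in class_dets:
        if d.image_id not in gt_by_image:
            raise DataValidationError(f"detection references unknown image_id {d.image_id!r}")
    order = sorted(range(len(class_dets)), key=lambda i: (-class_dets[i].confidence, i))

    matched: dict[str, set[int]] = {iid: set() for iid in gt_by_image}
    flags: list[bool] = []
    confs: list[float] = []
    for i in order:
        det = class_dets[i]
        candidates = gt_by_image[det.image_id]
        best_j, best_iou = -1, 0.0
        for j, g in enumerate(candidates):
            if j in matched[det.image_id]:
                continue
            iou = box_iou(det.box, g)
            if iou > best_iou:  # strict: IOU ties keep the earlier gt index
                best_j, best_iou = j, iou
        if best_j >= 0 and best_iou >= iou_thresh:
            matched[det.image_id].add(best_j)
            flags.append(True)
        else:
            flags.append(False)
        confs.append(det.confidence)

    tp = sum(flags)
    n_gt = sum(len(v) for v in gt_by_image.values())
    unmatched = tuple(
        (iid, j)
        for iid, boxes in gt_by_image.items()
        for j in range(len(boxes))
        if j not in matched[iid]
    )
    return MatchResult(
        label=label,
        tp=tp,
        fp=len(flags) - tp,
        fn=n_gt - tp,
        flags=tuple(flags),
        confidences=tuple(confs),
        unmatched_gt=unmatched,
    )


def precision_recall(mr: MatchResult) -> tuple[float, float]:
    """Precision = TP/(TP+FP), recall = TP/(TP+FN).

    Empty denominators yield 0 with a warning rather than an error, so bulk
    evaluation over many classes does not abort on a class with no
    detections (or no ground truth).
    """
    if mr.tp + mr.fp == 0:
        warnings.warn(f"{mr.label}: no detections; precision defined as 0", stacklevel=2)
        precision = 0.0
    else:
        precision = mr.tp / (mr.tp + mr.fp)
    if mr.tp + mr.fn == 0:
        warnings.warn(f"{mr.label}: no ground truth; recall defined as 0", stacklevel=2)
        recall = 0.0
    else:
        recall = mr.tp / (mr.tp + mr.fn)
    return precision, recall


@dataclass(frozen=True)
class APResult:
    """Ranked precision/recall walk and its average precision for one class."""

    label: str
    precision: np.ndarray
    recall: np.ndarray
    ap: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ap <= 1.0):
            raise DataValidationError(f"AP {self.ap} outside [0,1]")


def average_precision(mr: MatchResult, mode: str = "raw") -> APResult:
    """Average precision from the ranked TP/FP flags of one class.

    ``raw`` (default) accumulates Precision(k)*dRecall(k) over ranked
    detections exactly; ``interp`` first applies the all-point monotone
    precision envelope (the convention of most benchmark toolkits), for
    cross-tool comparison.
    """
    if mr.n_gt == 0:
        raise DataValidationError(f"{mr.label}: AP undefined without ground truth")
    if mode not in ("raw", "interp"):
        raise DataValidationError(f"unknown AP mode {mode!r}")

    tp_cum = np.cumsum(mr.flags, dtype=float)
    k = np.arange(1, len(mr.flags) + 1, dtype=float)
    precision = tp_cum / k
    recall = tp_cum / mr.n_gt

    if len(mr.flags) == 0:
        return APResult(label=mr.label, precision=precision, recall=recall, ap=0.0)

    if mode == "interp":
        env = np.maximum.accumulate(precision[::-1])[::-1]
        d_recall = np.diff(np.concatenate([[0.0], recall]))
        ap = float((env * d_recall).sum())
    else:
        d_recall = np.diff(np.concatenate([[0.0], recall]))
        ap = float((precision * d_recall).sum())
    return APResult(label=mr.label, precision=precision, recall=recall, ap=ap)


def mean_average_precision(per_class: Sequence[APResult]) -> float:
    """Unweighted mean of the class APs."""
    if not per_class:
        raise DataValidationError("mAP needs at least one class")
    return float(np.mean([r.ap for r in per_class]))


def evaluate_detections(
    gt: Sequence[ImageAnnotation],
    dets: Sequence[Detection],
    labels: Sequence[str] = ("flower", "pod"),
    iou_thresh: float = 0.5,
    ap_mode: str = "raw",
) -> dict:
    """Full per-class + summary evaluation used by the CLI."""
    per_class = {}
    ap_results = []
    for label in labels:
        mr = match_detections(gt, dets, label, iou_thresh=iou_thresh)
        if mr.n_gt == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p, r = precision_recall(mr)
        ap = average_precision(mr, mode=ap_mode)
        ap_results.append(ap)
        per_class[label] = {
            "tp": mr.tp, "fp": mr.fp, "fn": mr.fn,
            "precision": p, "recall": r, "ap": ap.ap,
        }
    return {"per_class": per_class, "map": mean_average_precision(ap_results)}


def mean_iou_segmentation(pred, gt) -> float:
    """Mean intersection-over-union of two integer label grids.

    Per class i (background = 0 included):
    ``IoU_i = TP_i / (TP_i + FP_i + FN_i)`` from the pixel confusion
    matrix; the result is the unweighted mean over the K+1 classes, with K
    inferred as the largest label present in either mask.  A class absent
    from both masks has zero union and counts as IoU 1 (the masks agree it
    is absent); a warning flags this case.
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise DataValidationError(f"mask shape mismatch {pred.shape} vs {gt.shape}")
    if pred.size == 0:
        raise DataValidationError("empty masks")
    if np.any(pred < 0) or np.any(gt < 0):
        raise DataValidationError("labels must be non-negative")
    n_classes = int(max(pred.max(), gt.max())) + 1
    return _miou_from_masks(pred, gt, n_classes)


def _miou_from_masks(pred: np.ndarray, gt: np.ndarray, n_classes: int) -> float:

    ious = np.empty(n_classes)
    for i in range(n_classes):
        inter = int(np.sum((pred == i) & (gt == i)))
        union = int(np.sum((pred == i) | (gt == i)))
        if union == 0:
            warnings.warn(
                f"class {i} absent from both masks; IoU counted as 1", stacklevel=2
            )
            ious[i] = 1.0
        else:
            ious[i] = inter / union
    return float(ious.mean())


# ---------------------------------------------------------------------------
# CSV dialect: image_id,label,x_min,y_min,x_max,y_max,confidence


def detections_csv(dets: Sequence[Detection]) -> str:
    lines = ["image_id,label,x_min,y_min,x_max,y_max,confidence"]
    for d in dets:
        b = d.box
        lines.append(
            f"{d.image_id},{d.label},{b.x_min:.3f},{b.y_min:.3f},"
            f"{b.x_max:.3f},{b.y_max:.3f},{d.confidence:.6f}"
        )
    return "\n".join(lines) + "\n"


def read_detections_csv(text: str) -> list[Detection]:
    import pandas as pd
    from io import StringIO

    df = pd.read_csv(StringIO(text), dtype={"image_id": str})
    required = {"image_id", "label", "x_min", "y_min", "x_max", "y_max", "confidence"}
    if not required.issubset(df.columns):
        raise DataValidationError(f"detection CSV needs columns {sorted(required)}")
    return [
        Detection(
            image_id=row.image_id,
            box=BoundingBox(
                row.x_min, row.y_min, row.x_max, row.y_max, label=row.label
            ),
            label=row.label,
            confidence=float(row.confidence),
        )
        for row in df.itertuples()
    ]
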