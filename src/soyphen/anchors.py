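"""Anchor-box optimization and box-size stratification.

Detection networks place prior boxes ("anchors") whose width/height
distribution should match the annotated organs.  Here anchors are found by
k-means over normalized (w, h) pairs under the distance

    d(box, centroid) = 1 - IOU(box, centroid)

where the two boxes are co-anchored at a common corner, so only their
shapes matter.  A Mean-IOU-vs-k curve supports elbow selection of the
anchor count, and the centroid aspect ratios are condensed into a few
representative ratios.  Boxes are also stratified into small / medium /
large using the Microsoft COCO pixel-area criteria.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from soyphen.annotations_io import BoundingBox, ImageAnnotation
from soyphen.errors import DataValidationError

# COCO pixel-area stratum boundaries
AREA_SMALL = 32 * 32   # 1024 px^2
AREA_LARGE = 96 * 96   # 9216 px^2

SizeClass = Literal["small", "medium", "large"]


def _as_wh_array(boxes) -> np.ndarray:
    wh = np.asarray(boxes, dtype=float)
    if wh.ndim == 1:
        wh = wh.reshape(1, 2)
    if wh.ndim != 2 or wh.shape[1] != 2:
        raise DataValidationError(f"expected (n, 2) width/height array, got shape {wh.shape}")
    if np.any(wh <= 0):
        raise DataValidationError("box dimensions must be positive")
    return wh


def iou_aligned(a, b) -> float:
    """IOU of two width/height pairs co-anchored at a common corner.

    intersection = min(w_a, w_b) * min(h_a, h_b);
    union = w_a*h_a + w_b*h_b - intersection.  The clustering distance is
    ``1 - iou_aligned(a, b)``.  Always in (0, 1] for positive dimensions.
    """
    (wa, ha), (wb, hb) = _as_wh_array(a)[0], _as_wh_array(b)[0]
    inter = min(wa, wb) * min(ha, hb)
    union = wa * ha + wb * hb - inter
    return inter / union


def _iou_matrix(boxes: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """(n_boxes, k) matrix of co-anchored IOUs."""
    w = np.minimum(boxes[:, None, 0], centroids[None, :, 0])
    h = np.minimum(boxes[:, None, 1], centroids[None, :, 1])
    inter = w * h
    union = (boxes[:, 0] * boxes[:, 1])[:, None] + (centroids[:, 0] * centroids[:, 1])[None, :] - inter
    return inter / union


@dataclass(frozen=True)
class AnchorModel:
    """Result of one anchor clustering: k centroid shapes plus diagnostics."""

    k: int
    centroids: np.ndarray            # (k, 2) w/h, sorted by area ascending
    assignments: np.ndarray          # (n,) centroid index per input box
    mean_iou: float                  # mean over boxes of best IOU with any centroid

    def __post_init__(self) -> None:
        if self.k < 1:
            raise DataValidationError("k must be >= 1")
        if not (0.0 < self.mean_iou <= 1.0):
            raise DataValidationError(f"mean_iou {self.mean_iou} outside (0,1]")

    @property
    def aspect_ratios(self) -> np.ndarray:
        """Centroid aspect ratios h/w (tall organs, e.g. hanging pods, > 1)."""
        return self.centroids[:, 1] / self.centroids[:, 0]


def _kmeanspp_init(boxes: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding under the 1-IOU distance."""
    n = boxes.shape[0]
    idx = [int(rng.integers(n))]
    for _ in range(1, k):
        d = 1.0 - _iou_matrix(boxes, boxes[idx]).max(axis=1)
        d[idx] = 0.0
        total = d.sum()
        if total <= 0:  # all remaining boxes coincide with a centroid
            choices = np.setdiff1d(np.arange(n), idx)
            idx.append(int(rng.choice(choices)))
        else:
            idx.append(int(rng.choice(n, p=d / total)))
    return boxes[idx].copy()


def _lloyd(
    boxes: np.ndarray,
    centroids: np.ndarray,
    max_iter: int,
    update: str,
    trace: list | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Lloyd iteration under the 1-IOU distance.

    Assignment maximizes IOU; the update is the per-dimension median
    (robust under the non-Euclidean distance) or mean.  Stops when the
    assignment is unchanged between two consecutive iterations.  Because
    the median/mean update does not exactly minimize the 1-IOU objective,
    an update that would increase the objective is rejected and iteration
    stops there, so the objective is non-increasing by construction.
    ``trace``, when given, collects the objective after each accepted step.
    """
    reduce = np.median if update == "median" else np.mean

    def objective(cents: np.ndarray) -> float:
        return float((1.0 - _iou_matrix(boxes, cents).max(axis=1)).sum())

    assign = _iou_matrix(boxes, centroids).argmax(axis=1)
    obj = objective(centroids)
    if trace is not None:
        trace.append(obj)
    for _ in range(max_iter):
        new_centroids = centroids.copy()
        for j in range(centroids.shape[0]):
            members = boxes[assign == j]
            if members.shape[0] == 0:
                # re-seed an empty cluster from the farthest box
                d = 1.0 - _iou_matrix(boxes, centroids).max(axis=1)
                new_centroids[j] = boxes[int(d.argmax())]
            else:
                new_centroids[j] = reduce(members, axis=0)
        new_obj = objective(new_centroids)
        if new_obj > obj + 1e-12:
            break
        centroids = new_centroids
        new_assign = _iou_matrix(boxes, centroids).argmax(axis=1)
        obj = new_obj
        if trace is not None:
            trace.append(obj)
        if np.array_equal(new_assign, assign):
            assign = new_assign
            break
        assign = new_assign
    return centroids, assign


def kmeans_anchors(
    boxes,
    k: int,
    seed: int = 0,
    max_iter: int = 100,
    restarts: int = 5,
    update: str = "median",
) -> AnchorModel:
    """Cluster normalized box shapes into ``k`` anchors under 1-IOU distance.

    The best of ``restarts`` seeded initializations (by resulting mean best
    IOU) is returned; centroids are sorted by area so output order is
    deterministic.

    Parameters
    ----------
    boxes : (n, 2) array-like of normalized (w, h) pairs, each in (0, 1].
    k : number of anchors; must not exceed the number of distinct boxes.
    update : "median" (default) or "mean" centroid update.
    """
    wh = _as_wh_array(boxes)
    n_distinct = np.unique(wh, axis=0).shape[0]
    if k > n_distinct:
        raise DataValidationError(f"k={k} exceeds {n_distinct} distinct boxes")
    if update not in ("median", "mean"):
        raise DataValidationError(f"unknown update rule {update!r}")

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(max(1, restarts)):
        init = _kmeanspp_init(wh, k, rng)
        centroids, assign = _lloyd(wh, centroids=init, max_iter=max_iter, update=update)
        miou = float(_iou_matrix(wh, centroids).max(axis=1).mean())
        if best is None or miou > best[0]:
            best = (miou, centroids, assign)

    miou, centroids, _ = best
    order = np.argsort(centroids[:, 0] * centroids[:, 1], kind="stable")
    centroids = centroids[order]
    assign = _iou_matrix(wh, centroids).argmax(axis=1)
    return AnchorModel(k=k, centroids=centroids, assignments=assign, mean_iou=miou)


def mean_iou_curve(
    boxes,
    k_values: Sequence[int],
    seed: int = 0,
    restarts: int = 5,
) -> list[tuple[int, float]]:
    """Mean best-IOU as a function of anchor count, for elbow selection.

    With best-of-restarts clustering the curve is non-decreasing in k up to
    restart noise; the elbow (where it flattens) is the usual choice of
    anchor count.
    """
    ks = list(k_values)
    if ks != sorted(ks):
        raise DataValidationError("k_values must be sorted ascending")
    return [(k, kmeans_anchors(boxes, k, seed=seed, restarts=restarts).mean_iou) for k in ks]


def _best_contiguous_partition(values: np.ndarray, n_groups: int) -> list[np.ndarray]:
    """Optimal contiguous partition of sorted 1-D values minimizing within-group SSE.

    Exact dynamic program; deterministic, so the grouping needs no restarts.
    """
    n = len(values)
    prefix = np.concatenate([[0.0], np.cumsum(values)])
    prefix2 = np.concatenate([[0.0], np.cumsum(values**2)])

    def sse(i: int, j: int) -> float:  # values[i:j]
        s = prefix[j] - prefix[i]
        s2 = prefix2[j] - prefix2[i]
        return s2 - s * s / (j - i)

    INF = float("inf")
    cost = np.full((n_groups + 1, n + 1), INF)
    back = np.zeros((n_groups + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for g in range(1, n_groups + 1):
        for j in range(g, n + 1):
            for i in range(g - 1, j):
                c = cost[g - 1, i] + sse(i, j)
                if c < cost[g, j]:
                    cost[g, j] = c
                    back[g, j] = i
    bounds = [n]
    for g in range(n_groups, 0, -1):
        bounds.append(back[g, bounds[-1]])
    bounds = bounds[::-1]
    return [values[bounds[g]:bounds[g + 1]] for g in range(n_groups)]


def derive_aspect_ratios(model: AnchorModel, n_groups: int = 3) -> np.ndarray:
    """Condense the k centroid aspect ratios into ``n_groups`` representative ratios.

    The centroid ratios h/w are sorted and partitioned into contiguous
    groups (minimum within-group sum of squares); the group means are
    returned sorted ascending.  On ratio sets clustered around
    {~0.75, ~1.8, ~3.2} this recovers that triple.
    """
    if n_groups > model.k:
        raise DataValidationError(f"n_groups={n_groups} exceeds k={model.k}")
    ratios = np.sort(model.aspect_ratios)
    groups = _best_contiguous_partition(ratios, n_groups)
    return np.array([g.mean() for g in groups])


def classify_size(box: BoundingBox) -> SizeClass:
    """COCO-criterion size stratum of a box from its pixel area.

    area <= 32*32 -> "small"; 32*32 < area < 96*96 -> "medium";
    area >= 96*96 -> "large".  The published strata overlap at the
    boundaries; equality goes to the outer strata (small / large).
    """
    area = box.area
    if area <= AREA_SMALL:
        return "small"
    if area >= AREA_LARGE:
        return "large"
    return "medium"


def size_stratum_counts(anns: Sequence[ImageAnnotation]) -> dict[SizeClass, int]:
    """Count boxes per size stratum over a set of annotations."""
    counts: dict[SizeClass, int] = {"small": 0, "medium": 0, "large": 0}
    for ann in anns:
        for b in ann.boxes:
            counts[classify_size(b)] += 1
    return counts


def area_fraction(box: BoundingBox, ann: ImageAnnotation) -> float:
    """Fraction of the image area occupied by a box, in (0, 1]."""
    return box.area / (ann.width * ann.height)


def normalized_wh(anns: Sequence[ImageAnnotation]) -> np.ndarray:
    """Extract all boxes as image-normalized (w, h) pairs for clustering."""
    pairs = [
        (b.width / ann.width, b.height / ann.height)
        for ann in anns
        for b in ann.boxes
    ]
    if not pairs:
        raise DataValidationError("no boxes in annotation set")
    return np.asarray(pairs)
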