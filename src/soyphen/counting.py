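"""Fused per-node counting and agreement with manual counts.

The fusion pipeline runs a flower detector and then a pod detector over
each per-node image, counts the detections per class, writes one CSV row
per node plus a TOTAL row per plant, and quantifies agreement between
predicted and manual counts: the fraction of nodes with absolute error
0 / <=1 / <=2 and the linear fit (slope, intercept, R^2) of manual on
predicted counts.

The detector is a pluggable callable (``DetectorAdapter``): the synthetic
oracle detector from :mod:`soyphen.simulate` slots in here, and so would a
trained CNN.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from soyphen.detection_eval import Detection
from soyphen.errors import DataValidationError

#: Contract for a pluggable detector: one scene reference in, detections out.
DetectorAdapter = Callable[[object], list[Detection]]


@dataclass(frozen=True)
class ImageRef:
    """Reference to one per-node image with its provenance metadata."""

    ref: object          # whatever the detector adapter consumes
    plant_id: str
    node_index: int
    date: dt.date


@dataclass(frozen=True)
class NodeObservation:
    """Flower and pod counts of one node on one date."""

    plant_id: str
    node_index: int
    date: dt.date
    flower_count: int
    pod_count: int

    def __post_init__(self) -> None:
        if self.flower_count < 0 or self.pod_count < 0:
            raise DataValidationError("counts must be non-negative")


def run_fusion(
    images: Sequence[ImageRef],
    flower_det: DetectorAdapter,
    pod_det: DetectorAdapter,
    confidence_threshold: float = 0.5,
) -> list[NodeObservation]:
    """Serial flower-then-pod detection and counting over per-node images.

    Each image goes through the flower detector first and the pod detector
    second; the per-node counts are the numbers of emitted detections of
    the matching class with confidence >= ``confidence_threshold``.
    """
    seen = set()
    observations = []
    for img in images:
        key = (img.plant_id, img.node_index, img.date)
        if key in seen:
            raise DataValidationError(f"duplicate (plant, node, date) {key}")
        seen.add(key)
        flowers = [
            d for d in flower_det(img.ref)
            if d.label == "flower" and d.confidence >= confidence_threshold
        ]
        pods = [
            d for d in pod_det(img.ref)
            if d.label == "pod" and d.confidence >= confidence_threshold
        ]
        observations.append(
            NodeObservation(
                plant_id=img.plant_id,
                node_index=img.node_index,
                date=img.date,
                flower_count=len(flowers),
                pod_count=len(pods),
            )
        )
    return observations


def plant_totals(observations: Iterable[NodeObservation]) -> dict[str, tuple[int, int]]:
    """Per-plant (flower, pod) totals: the sum over that plant's node rows."""
    totals: dict[str, list[int]] = {}
    for obs in observations:
        t = totals.setdefault(obs.plant_id, [0, 0])
        t[0] += obs.flower_count
        t[1] += obs.pod_count
    return {p: (f, q) for p, (f, q) in totals.items()}


def counts_csv(observations: Sequence[NodeObservation]) -> str:
    """Counting CSV: one row per node plus a TOTAL pseudo-node row per plant.

    Rows are ordered by (plant, node, date) so output is bit-exact for a
    given observation set.
    """
    ordered = sorted(observations, key=lambda o: (o.plant_id, o.node_index, o.date))
    lines = ["plant_id,node_index,date,flower_count,pod_count"]
    totals = plant_totals(ordered)
    current = None
    for obs in ordered:
        if current is not None and obs.plant_id != current:
            f, q = totals[current]
            lines.append(f"{current},TOTAL,,{f},{q}")
        current = obs.plant_id
        lines.append(
            f"{obs.plant_id},{obs.node_index},{obs.date.isoformat()},"
            f"{obs.flower_count},{obs.pod_count}"
        )
    if current is not None:
        f, q = totals[current]
        lines.append(f"{current},TOTAL,,{f},{q}")
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class AgreementReport:
    """Agreement between predicted and manual counts over paired samples."""

    n: int
    frac_exact: float      # |error| == 0
    frac_within_1: float   # |error| <= 1
    frac_within_2: float   # |error| <= 2
    histogram: dict[int, int]
    slope: float
    intercept: float
    r2: float


def error_distribution(
    pred: Sequence[int], manual: Sequence[int]
) -> tuple[float, float, float, dict[int, int]]:
    """Fractions of pairs with |pred - manual| equal 0, <= 1, <= 2, plus histogram.

    The three fractions are nested, hence non-decreasing.
    """
    if len(pred) != len(manual):
        raise DataValidationError(f"length mismatch {len(pred)} vs {len(manual)}")
    if len(pred) == 0:
        raise DataValidationError("need at least one pair")
    err = np.abs(np.asarray(pred) - np.asarray(manual))
    hist = {int(v): int(c) for v, c in zip(*np.unique(err, return_counts=True))}
    n = len(err)
    return (
        float(np.mean(err == 0)),
        float(np.mean(err <= 1)),
        float(np.mean(err <= 2)),
        hist,
    )


def agreement_r2(
    pred: Sequence[float], manual: Sequence[float]
) -> tuple[float, float, float]:
    """OLS fit of manual counts on predicted counts: (slope, intercept, R^2).

    R^2 is the squared Pearson correlation, which for simple linear
    regression is identical in either direction.
    """
    pred = np.asarray(pred, dtype=float)
    manual = np.asarray(manual, dtype=float)
    if len(pred) != len(manual):
        raise DataValidationError(f"length mismatch {len(pred)} vs {len(manual)}")
    if len(pred) < 3:
        raise DataValidationError("need >= 3 pairs for a linear fit")
    if np.ptp(pred) == 0:
        raise DataValidationError("constant predictor; R^2 undefined")
    fit = stats.linregress(pred, manual)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def agreement_report(pred: Sequence[int], manual: Sequence[int]) -> AgreementReport:
    """Full agreement summary: error fractions, histogram and linear fit."""
    f0, f1, f2, hist = error_distribution(pred, manual)
    slope, intercept, r2 = agreement_r2(pred, manual)
    return AgreementReport(
        n=len(pred),
        frac_exact=f0,
        frac_within_1=f1,
        frac_within_2=f2,
        histogram=hist,
        slope=slope,
        intercept=intercept,
        r2=r2,
    )
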