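"""Synthetic inputs for every pipeline stage.

Three seeded generators stand in for the data a field campaign and trained
CNN detectors would provide:

* :func:`simulate_annotations` — box populations over 640x640 images with
  the study's size structure: a small-heavy mixture over the COCO
  small/medium/large strata, image-area fractions within (0, 0.25], and
  aspect ratios scattered around the representative triple
  (0.75, 1.8, 3.2).
* :func:`simulate_detections` — detector output with controllable miss
  probability, spurious-box rate and coordinate jitter, with hidden TP/FP
  provenance for validating the evaluator.
* :func:`simulate_phenology` — per-node flower-fate event streams across
  reproductive stages R1-R8 with configurable stage-dependent flowering
  intensity and fate probabilities, conservation-complete by construction.

Identical seeds give byte-identical output.  No visual realism is claimed:
the generators emulate the *statistics* the pipeline consumes (counts,
box shapes, event streams), not occlusion, lighting or plant architecture.
"""

from __future__ import annotations

import datetime as dt
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from soyphen.annotations_io import BoundingBox, ImageAnnotation
from soyphen.anchors import AREA_LARGE, AREA_SMALL, classify_size
from soyphen.detection_eval import Detection
from soyphen.errors import DataValidationError
from soyphen.phenology import FateCounts, PhenologyEvent, StageCalendar, STAGES

#: Representative anchor aspect ratios (h/w) of the annotated organs.
DEFAULT_ASPECT_RATIOS = (0.75, 1.8, 3.2)
#: Observed annotation density: ~6,334 boxes over 1,938 training images.
DEFAULT_BOXES_PER_IMAGE = 3.3
#: Small-heavy stratum mixture; most annotated organs are small targets.
DEFAULT_SIZE_MIXTURE = (0.5, 0.35, 0.15)


# ---------------------------------------------------------------------------
# Annotations


def _sample_box(
    rng: np.random.Generator,
    stratum: str,
    width: int,
    height: int,
    max_area_fraction: float,
    aspect_ratios: Sequence[float],
    label: str,
) -> BoundingBox:
    cap = max_area_fraction * width * height
    lo, hi = {
        "small": (64.0, AREA_SMALL),
        "medium": (AREA_SMALL + 1.0, AREA_LARGE - 1.0),
        "large": (AREA_LARGE, cap),
    }[stratum]
    if hi < lo:
        raise DataValidationError(
            f"stratum {stratum!r} infeasible for image {width}x{height} "
            f"with max_area_fraction={max_area_fraction}"
        )
    for _ in range(200):
        area = np.exp(rng.uniform(np.log(lo), np.log(hi)))
        ratio = rng.choice(aspect_ratios) * np.exp(rng.normal(0.0, 0.1))
        w = max(1, round(float(np.sqrt(area / ratio))))
        h = max(1, round(float(np.sqrt(area * ratio))))
        if w > width or h > height:
            continue
        a = w * h
        if a > cap or classify_size(
            BoundingBox(0, 0, w, h, label=label)
        ) != stratum:
            continue  # integer rounding crossed a stratum boundary; redraw
        x0 = int(rng.integers(0, width - w + 1))
        y0 = int(rng.integers(0, height - h + 1))
        return BoundingBox(x0, y0, x0 + w, y0 + h, label=label)
    raise DataValidationError(f"could not draw a {stratum} box after 200 tries")


def simulate_annotations(
    n_images: int,
    seed: int,
    boxes_per_image: float = DEFAULT_BOXES_PER_IMAGE,
    size_mixture: Sequence[float] = DEFAULT_SIZE_MIXTURE,
    image_size: tuple[int, int] = (640, 640),
    max_area_fraction: float = 0.25,
    aspect_ratios: Sequence[float] = DEFAULT_ASPECT_RATIOS,
    labels: Sequence[str] = ("flower", "pod"),
) -> list[ImageAnnotation]:
    """Generate ground-truth annotation sets with the study's box structure.

    Per image the box count is Poisson(``boxes_per_image``); each box draws
    its stratum from ``size_mixture`` (small, medium, large), its pixel
    area log-uniformly within the stratum (capped at
    ``max_area_fraction`` of the image), its aspect ratio around one of
    ``aspect_ratios``, and its position uniformly.  Every generated box
    satisfies ``classify_size(box) == its stratum`` and has an area
    fraction within (0, ``max_area_fraction``].
    """
    mixture = np.asarray(size_mixture, dtype=float)
    if mixture.shape != (3,) or np.any(mixture < 0) or not np.isclose(mixture.sum(), 1.0):
        raise DataValidationError("size_mixture must be 3 non-negative weights summing to 1")
    width, height = image_size
    rng = np.random.default_rng(seed)
    strata = np.array(["small", "medium", "large"])
    anns = []
    for i in range(n_images):
        n_boxes = int(rng.poisson(boxes_per_image))
        boxes = tuple(
            _sample_box(
                rng,
                stratum=str(rng.choice(strata, p=mixture)),
                width=width,
                height=height,
                max_area_fraction=max_area_fraction,
                aspect_ratios=aspect_ratios,
                label=str(rng.choice(np.array(labels))),
            )
            for _ in range(n_boxes)
        )
        anns.append(
            ImageAnnotation(image_id=f"img{i:05d}", width=width, height=height, boxes=boxes)
        )
    return anns


# ---------------------------------------------------------------------------
# Detections


@dataclass(frozen=True)
class DetectionNoiseConfig:
    """Error model of a stand-in detector.

    Each true box is missed independently with ``p_miss``; emitted boxes
    get per-coordinate Normal(0, ``jitter_sd``) pixel jitter clipped to the
    image; Poisson(``p_spurious_per_image``) spurious boxes per image are
    placed with sizes from the same mixture as true boxes, so false
    positives are not trivially separable by shape.  Confidences are
    Beta-distributed, higher for true detections, so ranking-based AP is
    informative.
    """

    p_miss: float = 0.0
    p_spurious_per_image: float = 0.0
    jitter_sd: float = 0.0
    tp_conf: tuple[float, float] = (5.0, 1.0)   # Beta(a, b) for true boxes
    fp_conf: tuple[float, float] = (1.0, 3.0)   # Beta(a, b) for spurious boxes
    size_mixture: tuple[float, float, float] = DEFAULT_SIZE_MIXTURE
    max_area_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_miss < 1.0):
            raise DataValidationError("p_miss must lie in [0,1)")
        if self.p_spurious_per_image < 0 or self.jitter_sd < 0:
            raise DataValidationError("noise rates must be non-negative")


def _jittered(box: BoundingBox, rng, sd: float, width: int, height: int) -> BoundingBox:
    if sd == 0.0:
        return box
    x0, y0, x1, y1 = (
        c + float(rng.normal(0.0, sd))
        for c in (box.x_min, box.y_min, box.x_max, box.y_max)
    )
    x0, x1 = sorted((max(0.0, min(x0, width - 1.0)), max(1.0, min(x1, width * 1.0))))
    y0, y1 = sorted((max(0.0, min(y0, height - 1.0)), max(1.0, min(y1, height * 1.0))))
    if x1 <= x0:
        x1 = x0 + 1.0
    if y1 <= y0:
        y1 = y0 + 1.0
    return BoundingBox(x0, y0, x1, y1, label=box.label)


def _conf(rng, ab: tuple[float, float]) -> float:
    return float(np.clip(rng.beta(*ab), 1e-9, 1.0))


def simulate_detections(
    truth: Sequence[ImageAnnotation],
    cfg: DetectionNoiseConfig,
) -> tuple[list[Detection], list[tuple[str, str, int]]]:
    """Noisy detector output for a ground-truth set, with hidden provenance.

    Returns ``(detections, provenance)`` where each provenance entry is
    ``("tp", image_id, gt_box_index)`` for an emitted true box or
    ``("fp", image_id, -1)`` for a spurious one, aligned with the
    detection list.  With an all-zero config the detections reproduce the
    truth exactly at confidence drawn from ``tp_conf``.
    """
    rng = np.random.default_rng(cfg.seed)
    detections: list[Detection] = []
    provenance: list[tuple[str, str, int]] = []
    for ann in truth:
        for j, box in enumerate(ann.boxes):
            if rng.random() < cfg.p_miss:
                continue
            jb = _jittered(box, rng, cfg.jitter_sd, ann.width, ann.height)
            detections.append(
                Detection(
                    image_id=ann.image_id,
                    box=jb,
                    label=box.label,
                    confidence=_conf(rng, cfg.tp_conf),
                )
            )
            provenance.append(("tp", ann.image_id, j))
        for _ in range(int(rng.poisson(cfg.p_spurious_per_image))):
            stratum = str(
                rng.choice(
                    np.array(["small", "medium", "large"]),
                    p=np.asarray(cfg.size_mixture, dtype=float),
                )
            )
            label = str(rng.choice(np.array(["flower", "pod"])))
            sp = _sample_box(
                rng, stratum, ann.width, ann.height,
                cfg.max_area_fraction, DEFAULT_ASPECT_RATIOS, label,
            )
            detections.append(
                Detection(
                    image_id=ann.image_id,
                    box=sp,
                    label=label,
                    confidence=_conf(rng, cfg.fp_conf),
                )
            )
            provenance.append(("fp", ann.image_id, -1))
    return detections, provenance


def oracle_detector(label: str | None = None):
    """Perfect detector adapter: emits every ground-truth box at confidence 1.

    The adapter consumes an :class:`ImageAnnotation` as its scene reference
    (the synthetic pipeline's image stand-in).
    """

    def detect(ann: ImageAnnotation) -> list[Detection]:
        return [
            Detection(image_id=ann.image_id, box=b, label=b.label, confidence=1.0)
            for b in ann.boxes
            if label is None or b.label == label
        ]

    return detect


def noisy_detector(cfg: DetectionNoiseConfig, label: str | None = None):
    """Detector adapter with the configured error model.

    Per-image randomness is keyed by (config seed, image id), so results
    do not depend on the order in which images are presented.
    """

    def detect(ann: ImageAnnotation) -> list[Detection]:
        sub_seed = zlib.crc32(ann.image_id.encode()) % (2**31)
        sub_cfg = DetectionNoiseConfig(
            p_miss=cfg.p_miss,
            p_spurious_per_image=cfg.p_spurious_per_image,
            jitter_sd=cfg.jitter_sd,
            tp_conf=cfg.tp_conf,
            fp_conf=cfg.fp_conf,
            size_mixture=cfg.size_mixture,
            max_area_fraction=cfg.max_area_fraction,
            seed=(cfg.seed * 1_000_003 + sub_seed) % (2**31),
        )
        dets, _ = simulate_detections([ann], sub_cfg)
        return [d for d in dets if label is None or d.label == label]

    return detect


# ---------------------------------------------------------------------------
# Phenology


def default_calendar(start: dt.date = dt.date(2019, 6, 27)) -> StageCalendar:
    """Stage calendar spanning the study's observation window.

    R1 at ``start`` (default 2019-06-27) through R8 ninety-five days later
    (2019-09-30), with boundaries spaced across the season.
    """
    offsets = (0, 12, 24, 38, 52, 66, 80, 95)
    return StageCalendar(tuple(start + dt.timedelta(days=o) for o in offsets))


@dataclass(frozen=True)
class PhenologySimConfig:
    """Conditions of a simulated flowering season.

    ``flower_intensity`` is the expected number of newly opened flowers
    per node per day in each stage (zero where omitted); the defaults give
    roughly 4-7 new flowers per plant per day in full bloom, in line with
    field observations.  ``fate_probs`` = (p_flower_drop, p_pod_drop,
    p_pod_survive) must sum to 1; defaults approximate the observed season
    totals (FDR ~62%).  Lags are mean day counts; every fate resolves
    within the calendar window, so simulated logs are
    conservation-complete.
    """

    n_plants: int = 3
    n_nodes: int = 15
    calendar: StageCalendar = field(default_factory=default_calendar)
    flower_intensity: dict = field(
        default_factory=lambda: {"R1": 0.4, "R2": 0.6, "R3": 0.4, "R4": 0.2, "R5": 0.05}
    )
    fate_probs: tuple[float, float, float] = (0.62, 0.14, 0.24)
    flower_drop_lag: float = 8.0
    pod_form_lag: float = 7.0     # pods set about a week after flowering
    pod_drop_lag: float = 14.0
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.fate_probs, dtype=float)
        if p.shape != (3,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise DataValidationError("fate_probs must be 3 non-negative values summing to 1")
        if any(v < 0 for v in self.flower_intensity.values()):
            raise DataValidationError("flower intensities must be non-negative")
        unknown = set(self.flower_intensity) - set(STAGES)
        if unknown:
            raise DataValidationError(f"unknown stages in flower_intensity: {sorted(unknown)}")
        span = (self.calendar.end - self.calendar.start).days
        max_lag = self.pod_form_lag + self.pod_drop_lag
        if span <= max_lag:
            raise DataValidationError(
                f"calendar span {span} d shorter than maximum mean lag {max_lag} d"
            )


@dataclass(frozen=True)
class PhenologySimResult:
    """Simulated event log plus the simulator's hidden fate tally."""

    events: tuple[PhenologyEvent, ...]
    fate_counts: FateCounts
    calendar: StageCalendar


def simulate_phenology(cfg: PhenologySimConfig) -> PhenologySimResult:
    """Simulate a conservation-complete flower-fate event stream.

    Daily per-node flower openings are Poisson with the stage's intensity;
    each flower independently draws its fate and resolves it after
    1 + Poisson(lag - 1) days, clamped to the end of the window so every
    opened flower is accounted for.  The hidden tally in the result equals
    the exact fate bookkeeping the pipeline should recover.
    """
    rng = np.random.default_rng(cfg.seed)
    cal = cfg.calendar
    end = cal.end
    events: list[PhenologyEvent] = []
    tally = {"drop": 0, "pod_drop": 0, "pod_survive": 0}

    def lag(mean: float) -> dt.timedelta:
        return dt.timedelta(days=1 + int(rng.poisson(max(mean - 1.0, 0.0))))

    n_days = (end - cal.start).days
    for p in range(cfg.n_plants):
        plant = f"plant{p + 1:02d}"
        for node in range(1, cfg.n_nodes + 1):
            for offset in range(n_days):
                day = cal.start + dt.timedelta(days=offset)
                intensity = cfg.flower_intensity.get(cal.stage_of(day), 0.0)
                if intensity <= 0:
                    continue
                for _ in range(int(rng.poisson(intensity))):
                    events.append(PhenologyEvent(plant, node, day, "flower_open"))
                    fate = rng.choice(3, p=np.asarray(cfg.fate_probs))
                    if fate == 0:
                        tally["drop"] += 1
                        d = min(day + lag(cfg.flower_drop_lag), end)
                        events.append(PhenologyEvent(plant, node, d, "flower_drop"))
                    else:
                        form = min(day + lag(cfg.pod_form_lag), end)
                        events.append(PhenologyEvent(plant, node, form, "pod_form"))
                        if fate == 1:
                            tally["pod_drop"] += 1
                            d = min(form + lag(cfg.pod_drop_lag), end)
                            events.append(PhenologyEvent(plant, node, d, "pod_drop"))
                        else:
                            tally["pod_survive"] += 1
    return PhenologySimResult(
        events=tuple(events),
        fate_counts=FateCounts(
            tnofd=tally["drop"], tnopd=tally["pod_drop"], tnopf=tally["pod_survive"]
        ),
        calendar=cal,
    )


def events_from_breakdown(
    sample: str,
    stage_percentages: dict[str, float],
    n_dropped: int,
    n_total: int,
    cal: StageCalendar,
    drop_type: str = "flower_drop",
) -> list[PhenologyEvent]:
    """Reconstruct a minimal event log from a published breakdown row.

    Per-interval drop counts are the largest-remainder integer
    apportionment of ``n_dropped`` over the printed percentages; drops are
    dated at the interval's start boundary and ``n_total`` opening events
    are dated at R1.  Feeding the log back through
    :func:`soyphen.phenology.stage_breakdown` reproduces the printed cells.
    """
    shares = np.array([stage_percentages.get(iv, 0.0) for iv in cal.intervals]) / 100.0
    raw = shares * n_dropped
    base = np.floor(raw).astype(int)
    remainder = n_dropped - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:remainder]] += 1

    events = [
        PhenologyEvent(sample, 1, cal.start, "flower_open") for _ in range(n_total)
    ]
    for iv, count in zip(cal.intervals, base):
        start = cal.boundaries[STAGES.index(iv.split("~")[0])]
        events.extend(PhenologyEvent(sample, 1, start, drop_type) for _ in range(count))
    return events
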