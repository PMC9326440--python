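"""Flower/pod fate statistics and drop-pattern phenology.

Every opened soybean flower meets one of three fates: it drops as a flower,
it forms a pod that later drops, or it forms a pod that survives.  With
TNOFD / TNOPD / TNOPF the totals of those fates, the rates share one
denominator:

    FDR = TNOFD / (TNOFD + TNOPD + TNOPF) * 100
    PDR = TNOPD / (TNOFD + TNOPD + TNOPF) * 100
    PFR = TNOPF / (TNOFD + TNOPD + TNOPF) * 100

so FDR + PDR + PFR = 100 identically.  Drop events are additionally broken
down across the reproductive stages R1 (start of flowering) through R8
(full maturity), across lower/middle/upper node layers, and as daily
standing-count series.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from io import StringIO
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from soyphen.errors import DataValidationError, InconsistentLogError

EVENT_TYPES = ("flower_open", "flower_drop", "pod_form", "pod_drop")
STAGES = ("R1", "R2", "R3", "R4", "R5", "R6", "R7", "R8")
LAYERS = ("lower", "middle", "upper")


def _as_date(d) -> dt.date:
    if isinstance(d, dt.datetime):
        return d.date()
    if isinstance(d, dt.date):
        return d
    return dt.date.fromisoformat(str(d))


@dataclass(frozen=True)
class PhenologyEvent:
    """One observed event on one node: (plant, node, date, event type)."""

    plant_id: str
    node_index: int
    date: dt.date
    event_type: str

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise DataValidationError(f"unknown event type {self.event_type!r}")
        if self.node_index < 1:
            raise DataValidationError(f"node_index must be >= 1, got {self.node_index}")
        object.__setattr__(self, "date", _as_date(self.date))


@dataclass(frozen=True)
class StageCalendar:
    """Ordered boundary dates of the reproductive stages R1..R8.

    The stage of a date is the last boundary on or before it; dates before
    R1 are invalid.  Stage intervals are half-open [Rk, Rk+1), except that
    the final interval R7~R8 is closed at R8 (the end of the window).
    """

    boundaries: tuple[dt.date, ...]

    def __post_init__(self) -> None:
        bounds = tuple(_as_date(b) for b in self.boundaries)
        if len(bounds) != len(STAGES):
            raise DataValidationError(f"expected {len(STAGES)} stage boundaries, got {len(bounds)}")
        if any(b1 >= b2 for b1, b2 in zip(bounds, bounds[1:])):
            raise DataValidationError("stage boundaries must be strictly increasing")
        object.__setattr__(self, "boundaries", bounds)

    @property
    def start(self) -> dt.date:
        return self.boundaries[0]

    @property
    def end(self) -> dt.date:
        return self.boundaries[-1]

    def stage_of(self, date) -> str:
        date = _as_date(date)
        if date < self.start:
            raise DataValidationError(f"date {date} precedes R1 ({self.start})")
        idx = int(np.searchsorted(np.array(self.boundaries), date, side="right")) - 1
        return STAGES[idx]

    def interval_of(self, date) -> str:
        """Stage interval label ("R1~R2" ... "R7~R8") containing a date."""
        date = _as_date(date)
        if date > self.end:
            raise DataValidationError(f"date {date} beyond R8 ({self.end})")
        stage = self.stage_of(date)
        k = min(STAGES.index(stage), len(STAGES) - 2)  # R8 boundary folds into R7~R8
        return f"{STAGES[k]}~{STAGES[k + 1]}"

    @property
    def intervals(self) -> tuple[str, ...]:
        return tuple(f"{a}~{b}" for a, b in zip(STAGES, STAGES[1:]))


@dataclass(frozen=True)
class FateCounts:
    """Totals of the three flower fates; denominator of the rate formulas."""

    tnofd: int  # flowers dropped
    tnopd: int  # pods dropped
    tnopf: int  # pods formed and surviving

    def __post_init__(self) -> None:
        if min(self.tnofd, self.tnopd, self.tnopf) < 0:
            raise DataValidationError("fate counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tnofd + self.tnopd + self.tnopf


def fate_rates(fc: FateCounts) -> tuple[float, float, float]:
    """(FDR, PDR, PFR) percentages over the shared denominator.

    The triple sums to exactly 100 before any rounding.
    """
    if fc.total == 0:
        raise DataValidationError("fate rates undefined for zero total")
    return (
        100.0 * fc.tnofd / fc.total,
        100.0 * fc.tnopd / fc.total,
        100.0 * fc.tnopf / fc.total,
    )


def fate_counts_from_events(events: Iterable[PhenologyEvent]) -> FateCounts:
    """Tally TNOFD/TNOPD/TNOPF from a complete event log.

    In a conservation-complete log every opened flower resolves to exactly
    one fate, so tnofd + tnopd + tnopf equals the number of flower_open
    events; that identity is enforced here.
    """
    n = {t: 0 for t in EVENT_TYPES}
    for e in events:
        n[e.event_type] += 1
    if n["pod_drop"] > n["pod_form"]:
        raise DataValidationError(
            f"{n['pod_drop']} pod drops exceed {n['pod_form']} pods formed"
        )
    fc = FateCounts(
        tnofd=n["flower_drop"],
        tnopd=n["pod_drop"],
        tnopf=n["pod_form"] - n["pod_drop"],
    )
    if fc.total != n["flower_open"]:
        raise DataValidationError(
            f"log not conservation-complete: {n['flower_open']} flowers opened "
            f"but {fc.total} fates recorded"
        )
    return fc


def flower_drop_rate(dropped: int, total_flowers: int) -> float:
    """Simple drop percentage dropped/total*100.

    Equals the shared-denominator FDR when ``total_flowers`` is the full
    fate total TNOFD + TNOPD + TNOPF.
    """
    if total_flowers <= 0:
        raise DataValidationError("total_flowers must be positive")
    if not (0 <= dropped <= total_flowers):
        raise DataValidationError(f"dropped={dropped} outside [0, {total_flowers}]")
    return 100.0 * dropped / total_flowers


def organ_conditional_rate(count_a: int, count_b: int) -> float:
    """Auxiliary two-count rate 100*b/(a+b).

    Published pod-drop tables report a rate consistent with this arithmetic
    over their two count columns rather than with the shared-denominator
    PDR; both readings are provided and neither is asserted as canonical.
    """
    if count_a < 0 or count_b < 0 or count_a + count_b == 0:
        raise DataValidationError("counts must be non-negative with positive sum")
    return 100.0 * count_b / (count_a + count_b)


@dataclass(frozen=True)
class StageBreakdown:
    """Per-stage-interval percentage split of one drop type for one sample."""

    drop_type: str
    percentages: dict[str, float]   # interval label -> % of total drops
    counts: dict[str, int]
    total_drops: int
    total_flowers: int | None       # flower_open events seen, if any
    overall_rate: float | None      # drops / total_flowers * 100


def stage_breakdown(
    events: Iterable[PhenologyEvent],
    cal: StageCalendar,
    drop_type: str = "flower_drop",
) -> StageBreakdown:
    """Split one sample's drop events across the stage intervals.

    Each interval's percentage is 100 * (drops in interval) / (total drops
    of that type); the percentages sum to 100 up to rounding.  When the log
    also carries flower_open events the overall drop rate
    drops/opened*100 is reported alongside.
    """
    if drop_type not in ("flower_drop", "pod_drop"):
        raise DataValidationError(f"drop_type must be a drop event, got {drop_type!r}")
    events = list(events)
    counts = {iv: 0 for iv in cal.intervals}
    n_open = 0
    for e in events:
        if e.event_type == drop_type:
            counts[cal.interval_of(e.date)] += 1
        elif e.event_type == "flower_open":
            n_open += 1
    total = sum(counts.values())
    if total == 0:
        raise DataValidationError(f"no {drop_type} events in log")
    percentages = {iv: 100.0 * c / total for iv, c in counts.items()}
    overall = 100.0 * total / n_open if (n_open and drop_type == "flower_drop") else None
    return StageBreakdown(
        drop_type=drop_type,
        percentages=percentages,
        counts=counts,
        total_drops=total,
        total_flowers=n_open or None,
        overall_rate=overall,
    )


def breakdown_table(
    events: Iterable[PhenologyEvent],
    cal: StageCalendar,
    drop_type: str = "flower_drop",
) -> pd.DataFrame:
    """Per-plant stage breakdown shaped like the published drop-rate tables.

    One row per plant with the interval percentages, drop count, flower
    total and overall rate, plus an "average" row of column means.
    """
    events = list(events)
    plants = sorted({e.plant_id for e in events})
    rows = []
    for plant in plants:
        sb = stage_breakdown([e for e in events if e.plant_id == plant], cal, drop_type)
        row = {"sample": plant, **sb.percentages,
               "n_dropped": sb.total_drops, "n_total": sb.total_flowers,
               "rate": sb.overall_rate}
        rows.append(row)
    df = pd.DataFrame(rows).set_index("sample")
    df.loc["average"] = df.mean(numeric_only=True)
    return df


@dataclass(frozen=True)
class LayerAssignment:
    """Contiguous split of main-stem nodes into lower/middle/upper thirds."""

    node_to_layer: dict[int, str]

    @property
    def n_nodes(self) -> int:
        return len(self.node_to_layer)

    def layer_of(self, node_index: int) -> str:
        try:
            return self.node_to_layer[node_index]
        except KeyError:
            raise DataValidationError(f"node {node_index} outside layer map") from None


def assign_layers(n_nodes: int) -> LayerAssignment:
    """Split nodes 1..n (1 = lowest) into three contiguous layers.

    Layer sizes differ by at most one; when n mod 3 = r the lowest r layers
    take the extra node (plants fill from the bottom).
    """
    if n_nodes < 3:
        raise DataValidationError(f"need >= 3 nodes for three layers, got {n_nodes}")
    base, r = divmod(n_nodes, 3)
    sizes = [base + (1 if i < r else 0) for i in range(3)]
    mapping: dict[int, str] = {}
    node = 1
    for layer, size in zip(LAYERS, sizes):
        for _ in range(size):
            mapping[node] = layer
            node += 1
    return LayerAssignment(node_to_layer=mapping)


def spatial_distribution(
    counts_per_node: Mapping[int, int],
    layers: LayerAssignment,
) -> dict[str, float]:
    """Per-layer percentage share of a per-node quantity; sums to 100."""
    totals = {layer: 0 for layer in LAYERS}
    for node, count in counts_per_node.items():
        if count < 0:
            raise DataValidationError(f"negative count at node {node}")
        totals[layers.layer_of(node)] += count
    grand = sum(totals.values())
    if grand == 0:
        raise DataValidationError("all counts zero; shares undefined")
    return {layer: 100.0 * c / grand for layer, c in totals.items()}


def node_event_counts(
    events: Iterable[PhenologyEvent], event_type: str
) -> dict[int, int]:
    """Count events of one type per node, for spatial_distribution."""
    counts: dict[int, int] = {}
    for e in events:
        if e.event_type == event_type:
            counts[e.node_index] = counts.get(e.node_index, 0) + 1
    return counts


@dataclass(frozen=True)
class DailySeries:
    """Standing-count time series and its summary statistics.

    ``table`` is indexed by calendar day with columns new_flowers,
    flowers_open (opens - flower drops - pod formations to date) and
    pods_live (pod formations - pod drops to date).
    """

    table: pd.DataFrame
    mean_daily_new_flowers: float
    peak_flower_day: dt.date
    peak_pod_day: dt.date | None


def daily_series(events: Iterable[PhenologyEvent]) -> DailySeries | None:
    """Daily standing counts of open flowers and live pods.

    flowers_open(t) = opens<=t - flower_drops<=t - pod_forms<=t;
    pods_live(t)  = pod_forms<=t - pod_drops<=t.  Both must stay
    non-negative; a violation raises :class:`InconsistentLogError` naming
    the first offending date.  An empty log returns None.
    """
    events = list(events)
    if not events:
        return None
    dates = [e.date for e in events]
    index = pd.date_range(min(dates), max(dates), freq="D").date
    by_day = {t: {d: 0 for d in index} for t in EVENT_TYPES}
    for e in events:
        by_day[e.event_type][e.date] += 1

    rows = []
    opens = fdrops = forms = pdrops = 0
    for day in index:
        opens += by_day["flower_open"][day]
        fdrops += by_day["flower_drop"][day]
        forms += by_day["pod_form"][day]
        pdrops += by_day["pod_drop"][day]
        flowers_open = opens - fdrops - forms
        pods_live = forms - pdrops
        if flowers_open < 0 or pods_live < 0:
            raise InconsistentLogError(
                f"negative standing count on {day} "
                f"(flowers_open={flowers_open}, pods_live={pods_live})",
                date=day,
            )
        rows.append(
            {"date": day, "new_flowers": by_day["flower_open"][day],
             "flowers_open": flowers_open, "pods_live": pods_live}
        )
    table = pd.DataFrame(rows).set_index("date")
    peak_flower = table["flowers_open"].idxmax()
    peak_pod = table["pods_live"].idxmax() if table["pods_live"].max() > 0 else None
    return DailySeries(
        table=table,
        mean_daily_new_flowers=float(table["new_flowers"].mean()),
        peak_flower_day=peak_flower,
        peak_pod_day=peak_pod,
    )


# ---------------------------------------------------------------------------
# CSV dialects


def read_events_csv(text: str) -> list[PhenologyEvent]:
    """Event-log CSV: plant_id,node_index,date,event_type."""
    df = pd.read_csv(StringIO(text), dtype={"plant_id": str})
    required = {"plant_id", "node_index", "date", "event_type"}
    if not required.issubset(df.columns):
        raise DataValidationError(f"event CSV needs columns {sorted(required)}")
    return [
        PhenologyEvent(
            plant_id=row.plant_id,
            node_index=int(row.node_index),
            date=_as_date(row.date),
            event_type=row.event_type,
        )
        for row in df.itertuples()
    ]


def write_events_csv(events: Sequence[PhenologyEvent]) -> str:
    df = pd.DataFrame(
        [
            {"plant_id": e.plant_id, "node_index": e.node_index,
             "date": e.date.isoformat(), "event_type": e.event_type}
            for e in events
        ]
    )
    return df.to_csv(index=False)


def read_calendar_csv(text: str) -> StageCalendar:
    """Stage-calendar CSV: stage,start_date with stages R1..R8."""
    df = pd.read_csv(StringIO(text))
    if not {"stage", "start_date"}.issubset(df.columns):
        raise DataValidationError("calendar CSV needs columns stage,start_date")
    by_stage = dict(zip(df["stage"], df["start_date"]))
    missing = [s for s in STAGES if s not in by_stage]
    if missing:
        raise DataValidationError(f"calendar missing stages {missing}")
    return StageCalendar(boundaries=tuple(_as_date(by_stage[s]) for s in STAGES))


def write_calendar_csv(cal: StageCalendar) -> str:
    df = pd.DataFrame(
        {"stage": STAGES, "start_date": [b.isoformat() for b in cal.boundaries]}
    )
    return df.to_csv(index=False)
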