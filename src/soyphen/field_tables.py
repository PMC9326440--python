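"""Published field observations for cultivars DN252 and HN51.

Three plants per cultivar were followed through the reproductive period
(Harbin, 2019).  For each plant the tables record the per-stage-interval
percentage split of drop events, the drop count, the organ total, and the
printed drop rate.  These rows are pipeline inputs: the drop-rate columns
and the row/column averages are recomputed from the counts by the
phenology module, and event logs reconstructed from a row's percentages
reproduce its printed cells.

Percentages in the flower table are shares of each plant's total flower
drops across intervals R1~R2 .. R5~R6; in the pod table, shares across
R3~R4 .. R7~R8.  The printed pod "drop rate" column follows the
organ-conditional arithmetic rate = total/(dropped+total) of its two count
columns (see :func:`soyphen.phenology.organ_conditional_rate`); several
printed cells are truncated rather than rounded at 2 dp.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class DropObservation:
    """One plant's drop record: stage shares (%), counts, printed rate (%)."""

    sample: str
    stage_percentages: dict[str, float]
    n_dropped: int
    n_total: int
    printed_rate: float


FLOWER_DROP_INTERVALS = ("R1~R2", "R2~R3", "R3~R4", "R4~R5", "R5~R6")

FLOWER_DROP_OBSERVATIONS: tuple[DropObservation, ...] = tuple(
    DropObservation(
        sample=sample,
        stage_percentages=dict(zip(FLOWER_DROP_INTERVALS, pcts)),
        n_dropped=dropped,
        n_total=total,
        printed_rate=rate,
    )
    for sample, pcts, dropped, total, rate in [
        ("DN252(1)", (3.62, 12.24, 21.26, 24.88, 38.00), 110, 221, 49.77),
        ("DN252(2)", (3.50, 15.38, 20.29, 16.78, 44.05), 101, 143, 70.63),
        ("DN252(3)", (2.04, 5.11, 36.73, 26.53, 29.59), 74, 98, 75.51),
        ("HN51(1)", (0.26, 2.06, 45.62, 15.72, 36.34), 196, 388, 50.52),
        ("HN51(2)", (1.02, 5.10, 13.95, 29.59, 50.34), 179, 294, 60.88),
        ("HN51(3)", (0.94, 4.25, 28.80, 26.01, 40.00), 142, 210, 67.62),
    ]
)

# Printed column averages of the flower table (stage shares at 2 dp except
# the final column, printed at 0 dp), and the printed row-average cells.
FLOWER_DROP_PRINTED_AVERAGES = {
    "R1~R2": 1.90, "R2~R3": 7.36, "R3~R4": 27.78, "R4~R5": 23.25, "R5~R6": 40.0,
    "n_dropped": 133.67, "n_total": 225.67, "rate": 62.49,
}

POD_DROP_INTERVALS = ("R3~R4", "R4~R5", "R5~R6", "R6~R7", "R7~R8")

POD_DROP_OBSERVATIONS: tuple[DropObservation, ...] = tuple(
    DropObservation(
        sample=sample,
        stage_percentages=dict(zip(POD_DROP_INTERVALS, pcts)),
        n_dropped=dropped,
        n_total=total,
        printed_rate=rate,
    )
    for sample, pcts, dropped, total, rate in [
        ("HN51(1)", (11.71, 17.11, 23.42, 4.50, 0.00), 111, 81, 42.18),
        ("HN51(2)", (0.00, 11.90, 47.61, 2.38, 2.40), 47, 68, 59.13),
        ("HN51(3)", (8.88, 8.88, 29.17, 12.50, 0.00), 35, 33, 48.53),
        ("DN252(1)", (10.42, 9.90, 18.29, 2.08, 1.56), 48, 63, 56.75),
        ("DN252(2)", (6.96, 13.04, 30.43, 5.22, 3.47), 15, 27, 64.28),
        ("DN252(3)", (7.35, 13.23, 22.06, 1.47, 4.41), 10, 14, 58.33),
    ]
)

POD_DROP_PRINTED_AVERAGE_RATE = 54.87

# Dataset sizes of the two annotation campaigns (images per organ class).
N_FLOWER_IMAGES = 1895
N_POD_IMAGES = 2693
# Printed train/val/test sizes under the 8:2 then 9:1 splits.
FLOWER_SPLIT_SIZES = (1364, 152, 379)
POD_SPLIT_SIZES = (1938, 216, 539)
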