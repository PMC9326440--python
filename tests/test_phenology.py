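"""Fate rates, stage breakdowns, node layering, and daily standing counts."""

import datetime as dt

import pytest
from hypothesis import given
from hypothesis import strategies as st

from soyphen.errors import DataValidationError, InconsistentLogError
from soyphen.field_tables import (
    FLOWER_DROP_OBSERVATIONS,
    POD_DROP_OBSERVATIONS,
)
from soyphen.phenology import (
    FateCounts,
    PhenologyEvent,
    StageCalendar,
    assign_layers,
    daily_series,
    fate_counts_from_events,
    fate_rates,
    flower_drop_rate,
    node_event_counts,
    organ_conditional_rate,
    read_calendar_csv,
    read_events_csv,
    spatial_distribution,
    stage_breakdown,
    write_calendar_csv,
    write_events_csv,
)
from soyphen.simulate import default_calendar, events_from_breakdown

CAL = default_calendar()


class TestFateRates:
    def test_shared_denominator_arithmetic(self):
        assert fate_rates(FateCounts(10, 5, 5)) == (50.0, 25.0, 25.0)

    def test_observed_plant_fdr(self):
        # 196 of 388 flowers dropped on one observed plant
        fdr, _, _ = fate_rates(FateCounts(196, 100, 92))
        assert fdr == pytest.approx(50.52, abs=0.01)

    @given(st.tuples(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500)))
    def test_rates_sum_to_hundred(self, counts):
        if sum(counts) == 0:
            return
        assert sum(fate_rates(FateCounts(*counts))) == pytest.approx(100.0, abs=1e-9)

    def test_zero_denominator_rejected(self):
        with pytest.raises(DataValidationError):
            fate_rates(FateCounts(0, 0, 0))


class TestFlowerDropRate:
    @pytest.mark.parametrize("dropped, total, expected", [(110, 221, 49.77), (101, 143, 70.63)])
    def test_observed_plants(self, dropped, total, expected):
        assert flower_drop_rate(dropped, total) == pytest.approx(expected, abs=0.01)

    def test_zero_drops(self):
        assert flower_drop_rate(0, 57) == 0.0

    def test_dropped_exceeding_total_rejected(self):
        with pytest.raises(DataValidationError):
            flower_drop_rate(5, 4)


class TestOrganConditionalRate:
    def test_two_count_arithmetic(self):
        assert organ_conditional_rate(111, 81) == pytest.approx(42.1875)

    def test_degenerate_rejected(self):
        with pytest.raises(DataValidationError):
            organ_conditional_rate(0, 0)

    @pytest.mark.parametrize("row", POD_DROP_OBSERVATIONS, ids=lambda r: r.sample)
    def test_observed_pod_rates_follow_two_count_arithmetic(self, row):
        # several printed cells are truncated rather than rounded at 2 dp
        rate = organ_conditional_rate(row.n_dropped, row.n_total)
        assert rate == pytest.approx(row.printed_rate, abs=0.01)


class TestStageCalendar:
    def test_stage_of_boundary_and_interior(self):
        assert CAL.stage_of(CAL.boundaries[0]) == "R1"
        assert CAL.stage_of(CAL.boundaries[2] + dt.timedelta(days=1)) == "R3"

    def test_date_before_r1_rejected(self):
        with pytest.raises(DataValidationError, match="precedes R1"):
            CAL.stage_of(CAL.start - dt.timedelta(days=1))

    def test_final_boundary_folds_into_last_interval(self):
        assert CAL.interval_of(CAL.end) == "R7~R8"

    def test_round_trips_through_csv(self):
        assert read_calendar_csv(write_calendar_csv(CAL)) == CAL


class TestStageBreakdown:
    def test_all_drops_in_one_interval(self):
        events = [
            PhenologyEvent("p", 1, CAL.boundaries[2], "flower_drop") for _ in range(5)
        ]
        sb = stage_breakdown(events, CAL)
        assert sb.percentages["R3~R4"] == 100.0
        assert sum(sb.percentages.values()) == 100.0

    @pytest.mark.parametrize("row", FLOWER_DROP_OBSERVATIONS, ids=lambda r: r.sample)
    def test_reconstructed_rows_within_count_granularity(self, row):
        """Apportioning a row's drops by its printed shares and re-deriving the
        shares agrees with print to within one count's worth of percentage
        (some plants' printed cells are not exactly consistent with any
        integer count set, so half-count rounding accuracy is unattainable)."""
        events = events_from_breakdown(
            row.sample, row.stage_percentages, row.n_dropped, row.n_total, CAL
        )
        sb = stage_breakdown(events, CAL)
        granularity = 100.0 / row.n_dropped
        for interval, printed in row.stage_percentages.items():
            assert sb.percentages[interval] == pytest.approx(
                printed, abs=granularity + 0.01
            )
        assert sb.overall_rate == pytest.approx(row.printed_rate, abs=0.01)

    def test_consistent_row_reproduced_exactly_at_2dp(self):
        # this plant's printed shares are exactly consistent with integer
        # drop counts over a 294-event log
        row = next(r for r in FLOWER_DROP_OBSERVATIONS if r.sample == "HN51(2)")
        events = events_from_breakdown(
            row.sample, row.stage_percentages, n_dropped=294, n_total=294, cal=CAL
        )
        sb = stage_breakdown(events, CAL)
        for interval, printed in row.stage_percentages.items():
            assert round(sb.percentages[interval], 2) == printed

    def test_invariant_to_order_and_plantwise_merging(self):
        events = events_from_breakdown(
            "p1", {"R1~R2": 40.0, "R3~R4": 60.0}, 10, 20, CAL
        ) + events_from_breakdown("p2", {"R2~R3": 100.0}, 5, 9, CAL)
        merged = stage_breakdown(events, CAL)
        reversed_ = stage_breakdown(list(reversed(events)), CAL)
        assert merged == reversed_

    def test_percentages_sum_to_hundred_after_rounding(self):
        events = events_from_breakdown(
            "p", {"R1~R2": 33.0, "R2~R3": 33.0, "R3~R4": 34.0}, 3, 6, CAL
        )
        sb = stage_breakdown(events, CAL)
        assert sum(round(v, 2) for v in sb.percentages.values()) == pytest.approx(
            100.0, abs=0.05
        )


class TestLayers:
    @pytest.mark.parametrize(
        "n, lower, middle, upper",
        [
            (15, range(1, 6), range(6, 11), range(11, 16)),
            (17, range(1, 7), range(7, 13), range(13, 18)),
            (3, range(1, 2), range(2, 3), range(3, 4)),
        ],
    )
    def test_contiguous_thirds_remainder_to_bottom(self, n, lower, middle, upper):
        layers = assign_layers(n)
        for node in lower:
            assert layers.layer_of(node) == "lower"
        for node in middle:
            assert layers.layer_of(node) == "middle"
        for node in upper:
            assert layers.layer_of(node) == "upper"

    def test_too_few_nodes_rejected(self):
        with pytest.raises(DataValidationError):
            assign_layers(2)

    def test_all_on_lowest_node(self):
        layers = assign_layers(9)
        assert spatial_distribution({1: 12}, layers) == {
            "lower": 100.0, "middle": 0.0, "upper": 0.0,
        }

    def test_uniform_counts_split_evenly(self):
        layers = assign_layers(9)
        shares = spatial_distribution({n: 4 for n in range(1, 10)}, layers)
        for v in shares.values():
            assert v == pytest.approx(100 / 3)

    def test_node_outside_map_rejected(self):
        with pytest.raises(DataValidationError, match="outside layer map"):
            spatial_distribution({10: 1}, assign_layers(9))


class TestDailySeries:
    def test_single_flower_lifecycle(self):
        d1, d3 = dt.date(2019, 7, 1), dt.date(2019, 7, 3)
        events = [
            PhenologyEvent("p", 1, d1, "flower_open"),
            PhenologyEvent("p", 1, d3, "flower_drop"),
        ]
        series = daily_series(events)
        assert series.table["flowers_open"].tolist() == [1, 1, 0]

    def test_flower_to_pod_bookkeeping(self):
        base = dt.date(2019, 7, 1)
        events = [
            PhenologyEvent("p", 1, base, "flower_open"),
            PhenologyEvent("p", 1, base + dt.timedelta(days=4), "pod_form"),
            PhenologyEvent("p", 1, base + dt.timedelta(days=8), "pod_drop"),
        ]
        series = daily_series(events)
        assert series.table["flowers_open"].tolist() == [1, 1, 1, 1, 0, 0, 0, 0, 0]
        assert series.table["pods_live"].tolist() == [0, 0, 0, 0, 1, 1, 1, 1, 0]

    def test_empty_log(self):
        assert daily_series([]) is None

    def test_inconsistent_log_names_the_date(self):
        bad_day = dt.date(2019, 7, 2)
        events = [
            PhenologyEvent("p", 1, dt.date(2019, 7, 1), "flower_open"),
            PhenologyEvent("p", 1, bad_day, "flower_drop"),
            PhenologyEvent("p", 1, bad_day, "pod_form"),  # double-spends the flower
        ]
        with pytest.raises(InconsistentLogError) as err:
            daily_series(events)
        assert err.value.date == bad_day


class TestEventBookkeeping:
    def test_fate_counts_require_conservation(self):
        d = dt.date(2019, 7, 1)
        with pytest.raises(DataValidationError, match="conservation"):
            fate_counts_from_events([PhenologyEvent("p", 1, d, "flower_open")])

    def test_node_event_counts(self):
        d = dt.date(2019, 7, 1)
        events = [
            PhenologyEvent("p", 1, d, "flower_open"),
            PhenologyEvent("p", 1, d, "flower_open"),
            PhenologyEvent("p", 3, d, "flower_open"),
            PhenologyEvent("p", 3, d, "pod_form"),
        ]
        assert node_event_counts(events, "flower_open") == {1: 2, 3: 1}

    def test_events_csv_round_trip(self):
        d = dt.date(2019, 7, 1)
        events = [
            PhenologyEvent("p1", 2, d, "flower_open"),
            PhenologyEvent("p2", 5, d + dt.timedelta(days=3), "pod_form"),
        ]
        assert read_events_csv(write_events_csv(events)) == events
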