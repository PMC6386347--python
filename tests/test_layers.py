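"""Layer update rules: weighted sums, winner-take-all, tracking, speed."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from bioniceye import (
    DirectionEvent,
    LocationFrame,
    PerceptionFrame,
    RangeFrame,
    TrackState,
    direction_code,
    distance_estimate,
    location_identification_step,
    range_estimation_step,
    refine_direction,
    track_recognition_step,
    velocity_estimate,
)
from bioniceye.layers import CODE_TO_STEP, step_length


def brute_force_range(values: np.ndarray, kernel) -> np.ndarray:
    """Independent nested-loop weighted sum with border truncation."""
    H, W = values.shape
    k = kernel.n - 1
    out = np.zeros((H, W), dtype=np.int64)
    for r in range(H):
        for c in range(W):
            total = 0
            for dr in range(-k, k + 1):
                for dc in range(-k, k + 1):
                    sr, sc = r + dr, c + dc
                    if 0 <= sr < H and 0 <= sc < W:
                        total += int(values[sr, sc]) * kernel.weight_at(dr, dc)
            out[r, c] = total
    return out


def brute_force_location(values: np.ndarray) -> np.ndarray:
    """Independent exhaustive winner-take-all: a cell fires iff its value
    is positive, not beaten in its plus neighborhood, and not beaten
    anywhere on the layer."""
    H, W = values.shape
    overall = max(int(values[r, c]) for r in range(H) for c in range(W))
    out = np.zeros((H, W), dtype=np.uint8)
    for r in range(H):
        for c in range(W):
            if values[r, c] <= 0:
                continue
            neigh = [values[r, c]]
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                if 0 <= r + dr < H and 0 <= c + dc < W:
                    neigh.append(values[r + dr, c + dc])
            out[r, c] = values[r, c] == max(neigh) and values[r, c] == overall
    return out


class TestRangeEstimation:
    def test_zero_frame_maps_to_zero(self, default_net):
        frame = PerceptionFrame(values=np.zeros((8, 8)))
        assert range_estimation_step(frame, default_net).values.sum() == 0

    def test_single_spike_places_kernel(self, default_net):
        values = np.zeros((8, 8))
        values[3, 3] = 1
        out = range_estimation_step(PerceptionFrame(values=values), default_net).values
        assert out[3, 3] == 3
        moore = [(r, c) for r in (2, 3, 4) for c in (2, 3, 4) if (r, c) != (3, 3)]
        assert all(out[rc] == 1 for rc in moore)
        assert out.sum() == 3 + 8

    def test_plus_pattern_weighted_sums(self, default_net):
        values = np.zeros((8, 8))
        for r, c in ((3, 3), (2, 3), (4, 3), (3, 2), (3, 4)):
            values[r, c] = 1
        out = range_estimation_step(PerceptionFrame(values=values), default_net).values
        assert out[3, 3] == 7  # 3*1 at center + 4 active neighbors
        assert out[2, 3] == 6  # 3*1 + 3 active neighbors in its field
        assert np.array_equal(out, brute_force_range(values, default_net.kernel))

    def test_shape_mismatch_rejected(self, default_net):
        with pytest.raises(ValueError):
            range_estimation_step(PerceptionFrame(values=np.zeros((5, 5))), default_net)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(values=arrays(np.uint8, (8, 8), elements=st.integers(0, 1)))
    def test_matches_brute_force_oracle(self, default_net, values):
        out = range_estimation_step(PerceptionFrame(values=values), default_net).values
        assert np.array_equal(out, brute_force_range(values, default_net.kernel))


class TestLocationIdentification:
    def test_zero_activity_yields_no_spikes(self, default_net):
        out = location_identification_step(RangeFrame(values=np.zeros((8, 8))), default_net)
        assert out.values.sum() == 0

    def test_strict_maximum_fires_alone(self, default_net):
        values = np.zeros((8, 8))
        for r, c in ((3, 3), (2, 3), (4, 3), (3, 2), (3, 4)):
            values[r, c] = 1
        rframe = range_estimation_step(PerceptionFrame(values=values), default_net)
        out = location_identification_step(rframe, default_net)
        assert out.values.sum() == 1
        assert out.values[3, 3] == 1

    def test_plateau_fires_all_tied_cells(self, default_net):
        values = np.zeros((8, 8), dtype=np.int64)
        values[3, 3] = values[3, 4] = 7
        out = location_identification_step(RangeFrame(values=values), default_net)
        assert out.values[3, 3] == 1 and out.values[3, 4] == 1
        assert out.values.sum() == 2

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(values=arrays(np.int64, (8, 8), elements=st.integers(0, 30)))
    def test_matches_exhaustive_oracle(self, default_net, values):
        out = location_identification_step(RangeFrame(values=values), default_net)
        assert np.array_equal(out.values, brute_force_location(values))


class TestDirectionCodes:
    @pytest.mark.parametrize(
        "new_cell, code",
        [
            ((2, 2), 1),  # upper-left step is the anchor of the code table
            ((2, 3), 2),
            ((2, 4), 3),
            ((3, 4), 4),
            ((4, 4), 5),
            ((4, 3), 6),
            ((4, 2), 7),
            ((3, 2), 8),
            ((3, 3), 0),
        ],
    )
    def test_code_table(self, new_cell, code):
        assert direction_code((3, 3), new_cell) == code

    def test_codes_cover_all_unit_steps_distinctly(self):
        codes = {direction_code((3, 3), (3 + dr, 3 + dc)) for dr, dc in CODE_TO_STEP.values()}
        assert codes == set(range(1, 9))

    def test_non_adjacent_cells_rejected(self):
        with pytest.raises(ValueError):
            direction_code((3, 3), (5, 5))


def _frame(cells):
    values = np.zeros((8, 8), dtype=np.uint8)
    for rc in cells:
        values[rc] = 1
    return LocationFrame(values=values)


class TestTrackRecognition:
    def test_first_spike_arms_without_event(self):
        state, events = track_recognition_step(TrackState(), _frame([(3, 3)]), tick=0)
        assert state.armed_cell == (3, 3) and state.armed_tick == 0
        assert events == []

    def test_adjacent_spike_emits_from_previous_location(self):
        state, _ = track_recognition_step(TrackState(), _frame([(3, 3)]), tick=0)
        state, events = track_recognition_step(state, _frame([(2, 2)]), tick=1)
        assert len(events) == 1
        ev = events[0]
        assert ev.cell == (3, 3) and ev.code == 1 and ev.tick == 1
        assert ev.step == (-1, -1) and ev.step_length == pytest.approx(math.sqrt(2))
        assert state.armed_cell == (2, 2)

    def test_static_refire_is_silent(self):
        state, _ = track_recognition_step(TrackState(), _frame([(3, 3)]), tick=0)
        state, events = track_recognition_step(state, _frame([(3, 3)]), tick=1)
        assert events == [] and state.armed_cell == (3, 3)

    def test_out_of_neighborhood_jump_drops_track(self):
        state, _ = track_recognition_step(TrackState(), _frame([(3, 3)]), tick=0)
        state, events = track_recognition_step(state, _frame([(6, 6)]), tick=1)
        assert events == [] and state.armed_cell == (6, 6)

    def test_no_spikes_disarm(self):
        state, _ = track_recognition_step(TrackState(), _frame([(3, 3)]), tick=0)
        state, events = track_recognition_step(state, _frame([]), tick=1)
        assert events == [] and state.armed_cell is None

    def test_plateau_arms_lowest_row_major_cell(self):
        state, _ = track_recognition_step(TrackState(), _frame([(3, 4), (3, 3)]), tick=0)
        assert state.armed_cell == (3, 3)


class TestRefineDirection:
    @pytest.mark.parametrize(
        "a, b, angle",
        [
            (4, 4, 0.0),    # repeated east stays east
            (2, 4, 45.0),   # north then east refines to NE
            (6, 0, 270.0),  # single code falls back to its own heading
            (1, 2, 112.5),  # NW then N: a 16th-turn refinement
        ],
    )
    def test_circular_mean(self, a, b, angle):
        assert refine_direction(a, b) == pytest.approx(angle)

    def test_opposite_codes_fall_back_to_first(self):
        assert refine_direction(4, 8) == pytest.approx(0.0)

    def test_zero_first_code_rejected(self):
        with pytest.raises(ValueError):
            refine_direction(0, 4)


class TestDistanceEstimate:
    @pytest.mark.parametrize(
        "active, klass",
        [(0, 0), (1, 1), (5, 1), (9, 1), (10, 2), (25, 2), (26, 3), (64, 3)],
    )
    def test_default_thresholds(self, active, klass):
        est = distance_estimate(active, (9, 25))
        assert est.klass == klass and est.active == active

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            distance_estimate(5, (9, 9))


def _axis_events(ticks, col0=0, row=3):
    events = []
    for i, t in enumerate(ticks):
        events.append(
            DirectionEvent(tick=t, cell=(row, col0 + i), code=4, step=(0, 1),
                           step_length=1.0)
        )
    return events


class TestVelocityEstimate:
    def test_no_events_gives_zero_speed(self):
        out = velocity_estimate([], subfield_size=4, interval_T=8, trajectory_cells=[])
        assert len(out) == 1
        assert out[0].speed == 0.0 and out[0].spike_count == 0

    def test_full_speed_axis_trajectory(self):
        # one transition per tick over 8 ticks inside one sub-field
        cells = [(t, (3, t)) for t in range(9)]
        events = _axis_events(range(1, 9))
        out = velocity_estimate(events, subfield_size=9, interval_T=8,
                                trajectory_cells=cells, grid_width=9)
        assert len(out) == 1
        assert out[0].spike_count == 8 and out[0].window_ticks == 8
        assert out[0].speed == pytest.approx(1.0)

    def test_half_speed_axis_trajectory(self):
        # transitions only at ticks 2, 4, 6, 8: half-speed recovery
        cells = [(t, (3, t // 2)) for t in range(9)]
        events = _axis_events([2, 4, 6, 8])
        out = velocity_estimate(events, subfield_size=9, interval_T=8,
                                trajectory_cells=cells, grid_width=9)
        assert len(out) == 1
        assert out[0].speed == pytest.approx(0.5)

    def test_window_closes_on_subfield_exit(self):
        # track crosses from the first 4-wide sub-field into the second
        cells = [(t, (3, 1 + t)) for t in range(6)]
        events = _axis_events(range(1, 6), col0=1)
        out = velocity_estimate(events, subfield_size=4, interval_T=8,
                                trajectory_cells=cells, grid_width=8)
        assert len(out) == 2
        assert [v.speed for v in out] == [pytest.approx(1.0)] * 2
        assert out[0].subfield != out[1].subfield

    def test_diagonal_speed_is_sqrt2(self):
        cells = [(t, (1 + t, 1 + t)) for t in range(5)]
        events = [
            DirectionEvent(tick=t, cell=(t, t), code=5, step=(1, 1),
                           step_length=math.sqrt(2))
            for t in range(1, 5)
        ]
        out = velocity_estimate(events, subfield_size=8, interval_T=8,
                                trajectory_cells=cells, grid_width=8)
        assert len(out) == 1
        assert out[0].speed == pytest.approx(math.sqrt(2))


def test_step_length_values():
    assert step_length((0, 1)) == 1.0
    assert step_length((1, 1)) == pytest.approx(math.sqrt(2))
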