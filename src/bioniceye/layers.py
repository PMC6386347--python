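"""Per-tick update rules of layers 2-5.

Layer 2 (range estimation) computes, for every grid cell, the
ring-weighted sum of the perception bits in its kernel field; because
the center carries the largest weight, a compact perceived disc yields
a strict maximum directly under the object.  Layer 3 (location
identification) is a local winner-take-all: a cell fires iff its range
output is positive and not exceeded anywhere in its 5-cell plus
neighborhood; equal maxima on a plateau all fire.  Layer 4 (track
recognition) needs two detection cycles: a firing cell arms its
watcher, and a Moore-adjacent spike on the next tick emits a single
direction-coded event from the previous location.  Layer 5 converts
the event stream into per-sub-field speed estimates over a fixed
decision window.

Direction codes (clockwise from the upper-left step, 0 = no motion):

    1 NW   2 N   3 NE
    8 W    0     4 E
    7 SW   6 S   5 SE
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import PerceptionFrame
from .topology import Network

Cell = tuple[int, int]

# step (drow, dcol) for each nonzero code; row grows downward so N = (-1, 0)
CODE_TO_STEP: dict[int, Cell] = {
    1: (-1, -1),
    2: (-1, 0),
    3: (-1, 1),
    4: (0, 1),
    5: (1, 1),
    6: (1, 0),
    7: (1, -1),
    8: (0, -1),
}
STEP_TO_CODE: dict[Cell, int] = {v: k for k, v in CODE_TO_STEP.items()}

# heading of each code in degrees, counterclockwise from East with North up
CODE_TO_ANGLE: dict[int, float] = {
    1: 135.0,
    2: 90.0,
    3: 45.0,
    4: 0.0,
    5: 315.0,
    6: 270.0,
    7: 225.0,
    8: 180.0,
}

_PLUS_FOOTPRINT = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class RangeFrame:
    """Integer weighted-sum output of the range-estimation layer."""

    values: np.ndarray
    tick: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if (self.values < 0).any():
            raise ValueError("range frame entries must be non-negative")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RangeFrame):
            return NotImplemented
        return self.tick == other.tick and np.array_equal(self.values, other.values)


@dataclass
class LocationFrame:
    """Binary winner-take-all output of the location-identification layer."""

    values: np.ndarray
    tick: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LocationFrame):
            return NotImplemented
        return self.tick == other.tick and np.array_equal(self.values, other.values)


@dataclass(frozen=True)
class DirectionEvent:
    """One track-layer spike: a coded step from ``cell`` (the previous
    location) taken at ``tick``."""

    tick: int
    cell: Cell
    code: int
    step: Cell
    step_length: float

    def to_dict(self) -> dict:
        return {
            "tick": self.tick,
            "cell": list(self.cell),
            "code": self.code,
            "step": list(self.step),
            "step_length": self.step_length,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DirectionEvent":
        return cls(
            tick=d["tick"],
            cell=tuple(d["cell"]),
            code=d["code"],
            step=tuple(d["step"]),
            step_length=d["step_length"],
        )


@dataclass
class TrackState:
    """Arming state of the track-recognition layer (single-object)."""

    armed_cell: Cell | None = None
    armed_tick: int | None = None
    last_code: int | None = None


@dataclass(frozen=True)
class DistanceEstimate:
    """Coarse distance class from the perceived-area size.

    klass 0 = nothing seen, 1 = near, 2 = middle, 3 = far away; the
    class grows with the number of active sensors because a higher
    object projects a wider footprint.
    """

    klass: int
    active: int

    def to_dict(self) -> dict:
        return {"klass": self.klass, "active": self.active}


@dataclass(frozen=True)
class VelocityEstimate:
    """Speed decided over one sub-field window."""

    subfield: int
    spike_count: int
    window_ticks: int
    speed: float

    def to_dict(self) -> dict:
        return {
            "subfield": self.subfield,
            "spike_count": self.spike_count,
            "window_ticks": self.window_ticks,
            "speed": self.speed,
        }


def range_estimation_step(frame: PerceptionFrame, net: Network) -> RangeFrame:
    """Kernel-weighted sum of perception bits at every cell (layer 2).

    Receptive fields truncate at the border, which equals correlating
    with zero padding since absent sensors contribute nothing.
    """
    if frame.values.shape != net.grid.shape:
        raise ValueError(
            f"frame shape {frame.values.shape} does not match grid {net.grid.shape}"
        )
    out = ndimage.correlate(
        frame.values.astype(np.int64),
        net.kernel.to_array(),
        mode="constant",
        cval=0,
    )
    return RangeFrame(values=out, tick=frame.tick)


def location_identification_step(rframe: RangeFrame, net: Network) -> LocationFrame:
    """Winner-take-all over the range surface (layer 3).

    A cell fires iff its range output is positive, equals the maximum
    over its 5-cell plus neighborhood (the wired comparison), and
    carries the layer-wide maximum.  The ring weights are designed so a
    compact perceived disc produces exactly one maximum, hence normally
    exactly one spike; genuine ties (plateaus) all fire.  The layer-wide
    condition keeps the weight-1 outskirts of the kernel ring from
    firing spuriously when the object is low and only one sensor is
    active; without it those cells tie with their equally dark
    neighbors.  An all-zero range frame yields no spikes.
    """
    local_max = ndimage.maximum_filter(
        rframe.values, footprint=_PLUS_FOOTPRINT, mode="constant", cval=0
    )
    fired = (
        (rframe.values > 0)
        & (rframe.values == local_max)
        & (rframe.values == rframe.values.max())
    )
    return LocationFrame(values=fired.astype(np.uint8), tick=rframe.tick)


def direction_code(old_cell: Cell, new_cell: Cell) -> int:
    """Code 0-8 for the step between two Moore-adjacent cells."""
    step = (new_cell[0] - old_cell[0], new_cell[1] - old_cell[1])
    if step == (0, 0):
        return 0
    code = STEP_TO_CODE.get(step)
    if code is None:
        raise ValueError(
            f"cells {old_cell} and {new_cell} are not Moore-adjacent"
        )
    return code


def step_length(step: Cell) -> float:
    """Euclidean length of a unit grid step: 1 on an axis, sqrt(2) diagonal."""
    return math.hypot(step[0], step[1])


def track_recognition_step(
    state: TrackState, lframe: LocationFrame, tick: int
) -> tuple[TrackState, list[DirectionEvent]]:
    """Advance the track layer by one tick (two-cycle detection).

    Arming rules: with no armed cell, arm at the lowest row-major firing
    cell.  Once armed, a Moore-adjacent spike emits one DirectionEvent
    from the OLD cell and re-arms at the new one; a re-fire of the armed
    cell itself is code 0 and emits nothing (static objects are near
    invisible to this layer); a spike outside the Moore neighborhood
    drops the track and re-arms silently.  No spikes at all disarm.
    """
    fired = np.argwhere(lframe.values == 1)
    if fired.size == 0:
        return TrackState(), []

    # plateaus disambiguate to the lowest row-major index
    candidates = [tuple(int(v) for v in rc) for rc in fired]
    old = state.armed_cell
    if old is not None and old in candidates:
        # armed cell re-fires: keep the track, emit nothing
        return TrackState(armed_cell=old, armed_tick=state.armed_tick,
                          last_code=state.last_code), []

    new_cell = min(candidates)
    if old is None:
        return TrackState(armed_cell=new_cell, armed_tick=tick), []

    adjacent = [
        c for c in candidates
        if max(abs(c[0] - old[0]), abs(c[1] - old[1])) == 1
    ]
    if adjacent:
        target = min(adjacent)
        code = direction_code(old, target)
        step = (target[0] - old[0], target[1] - old[1])
        event = DirectionEvent(
            tick=tick,
            cell=old,
            code=code,
            step=step,
            step_length=step_length(step),
        )
        return TrackState(armed_cell=target, armed_tick=tick, last_code=code), [event]

    # jump outside the neighborhood: drop the track, re-arm silently
    return TrackState(armed_cell=new_cell, armed_tick=tick), []


def refine_direction(code_a: int, code_b: int = 0) -> float:
    """Refined heading (degrees CCW from East) from two coded steps.

    The circular mean of the two step vectors doubles the angular
    resolution to 16 distinguishable headings; with only one code the
    coarse 8-direction heading is returned.
    """
    if code_a not in CODE_TO_ANGLE:
        raise ValueError(f"code_a must be 1-8, got {code_a}")
    a = math.radians(CODE_TO_ANGLE[code_a])
    if code_b == 0:
        return CODE_TO_ANGLE[code_a]
    if code_b not in CODE_TO_ANGLE:
        raise ValueError(f"code_b must be 0-8, got {code_b}")
    b = math.radians(CODE_TO_ANGLE[code_b])
    vx = math.cos(a) + math.cos(b)
    vy = math.sin(a) + math.sin(b)
    if math.hypot(vx, vy) < 1e-12:
        # opposite steps cancel; fall back to the first heading
        return CODE_TO_ANGLE[code_a]
    return math.degrees(math.atan2(vy, vx)) % 360.0


def distance_estimate(active: int, thresholds: tuple[int, int]) -> DistanceEstimate:
    """Classify distance from the active-sensor count.

    0 = nothing seen; 1 (near) while the footprint covers at most c1
    sensors; 2 up to c2; 3 (far away) beyond.
    """
    c1, c2 = thresholds
    if c1 >= c2:
        raise ValueError(f"thresholds must be increasing, got ({c1}, {c2})")
    if active == 0:
        klass = 0
    elif active <= c1:
        klass = 1
    elif active <= c2:
        klass = 2
    else:
        klass = 3
    return DistanceEstimate(klass=klass, active=active)


def _subfield_index(cell: Cell, subfield_size: int, grid_width: int) -> int:
    n_cols = -(-grid_width // subfield_size)  # ceil division
    return (cell[0] // subfield_size) * n_cols + cell[1] // subfield_size


def velocity_estimate(
    events: list[DirectionEvent],
    subfield_size: int,
    interval_T: int,
    trajectory_cells: list[tuple[int, Cell]],
    grid_width: int = 8,
) -> list[VelocityEstimate]:
    """Per-sub-field speed decisions from the event stream (layer 5).

    The plane is tiled into subfield_size x subfield_size sub-fields.
    A decision window opens when the track enters a sub-field and
    closes at exit or after ``interval_T`` ticks, whichever comes
    first; the window's speed is the summed step length of the events
    inside it divided by its tick span.  Tiling the plane stops an
    object circling the field of view from inflating one endless
    window.
    """
    if not events:
        return [VelocityEstimate(subfield=0, spike_count=0, window_ticks=0, speed=0.0)]

    events = sorted(events, key=lambda e: e.tick)
    estimates: list[VelocityEstimate] = []

    def close(t_open: int, t_end: int, sf: int) -> None:
        ticks = t_end - t_open
        if ticks <= 0:
            return
        window = [e for e in events if t_open < e.tick <= t_end]
        total = sum(e.step_length for e in window)
        estimates.append(
            VelocityEstimate(
                subfield=sf,
                spike_count=len(window),
                window_ticks=ticks,
                speed=total / ticks,
            )
        )

    t_open: int | None = None
    sf_open = 0
    last_t = 0
    for t, cell in trajectory_cells:
        sf = _subfield_index(cell, subfield_size, grid_width)
        if t_open is None:
            t_open, sf_open = t, sf
        elif sf != sf_open or t - t_open >= interval_T:
            close(t_open, t, sf_open)
            t_open, sf_open = t, sf
        last_t = t
    if t_open is not None:
        close(t_open, last_t, sf_open)

    if not estimates:
        return [VelocityEstimate(subfield=sf_open, spike_count=0, window_ticks=0, speed=0.0)]
    return estimates
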