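"""Simulation engine: drive all five layers over a scene, tick by tick.

``run_simulation`` is purely deterministic: identical (config, scene)
pairs produce bit-identical traces, and the outputs at tick t depend
only on ticks <= t (the track layer carries one tick of state, the
velocity layer integrates over closed windows).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

from .geometry import PerceptionFrame, active_count, perception_frame
from .layers import (
    CODE_TO_ANGLE,
    DirectionEvent,
    DistanceEstimate,
    LocationFrame,
    RangeFrame,
    TrackState,
    VelocityEstimate,
    distance_estimate,
    location_identification_step,
    range_estimation_step,
    track_recognition_step,
    velocity_estimate,
)
from .scenes import Scene
from .topology import Network, NetworkConfig, build_network


@dataclass
class LayerTrace:
    """Full record of one simulation: every layer, every tick."""

    config: NetworkConfig
    ticks: list[int]
    perception: list[PerceptionFrame]
    range_: list[RangeFrame]
    location: list[LocationFrame]
    events: list[DirectionEvent]
    distances: list[DistanceEstimate]
    velocities: list[VelocityEstimate]
    armed_cells: list[tuple[int, tuple[int, int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.ticks)
        if not (len(self.perception) == len(self.range_) == len(self.location)
                == len(self.distances) == n):
            raise ValueError("frame series lengths must equal scene length")
        lo, hi = self.ticks[0], self.ticks[-1]
        if any(not lo <= e.tick <= hi for e in self.events):
            raise ValueError("event ticks must lie within the scene range")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LayerTrace):
            return NotImplemented
        return (
            self.config == other.config
            and self.ticks == other.ticks
            and self.perception == other.perception
            and self.range_ == other.range_
            and self.location == other.location
            and self.events == other.events
            and self.distances == other.distances
            and self.velocities == other.velocities
            and self.armed_cells == other.armed_cells
        )


def run_simulation(config: NetworkConfig, scene: Scene) -> LayerTrace:
    """Evaluate layers 1-5 over every tick of the scene."""
    for objs in scene.objects_at:
        for obj in objs:
            if not (
                0 <= obj.x <= (config.grid.width - 1) * config.grid.spacing
                and 0 <= obj.y <= (config.grid.height - 1) * config.grid.spacing
            ):
                raise ValueError(
                    f"scene object at (x={obj.x}, y={obj.y}) lies outside the "
                    f"{config.grid.height}x{config.grid.width} sensor plane"
                )
    net = build_network(config)

    pframes: list[PerceptionFrame] = []
    rframes: list[RangeFrame] = []
    lframes: list[LocationFrame] = []
    events: list[DirectionEvent] = []
    distances: list[DistanceEstimate] = []
    armed: list[tuple[int, tuple[int, int]]] = []

    state = TrackState()
    for tick, objs in zip(scene.ticks, scene.objects_at):
        pf = perception_frame(objs, config.cone, config.grid, tick=tick)
        rf = range_estimation_step(pf, net)
        lf = location_identification_step(rf, net)
        state, new_events = track_recognition_step(state, lf, tick)
        events.extend(new_events)
        distances.append(distance_estimate(active_count(pf), config.distance_thresholds))
        if state.armed_cell is not None:
            armed.append((tick, state.armed_cell))
        pframes.append(pf)
        rframes.append(rf)
        lframes.append(lf)

    velocities = velocity_estimate(
        events,
        subfield_size=config.subfield_size,
        interval_T=config.interval_T,
        trajectory_cells=armed,
        grid_width=config.grid.width,
    )
    return LayerTrace(
        config=config,
        ticks=list(scene.ticks),
        perception=pframes,
        range_=rframes,
        location=lframes,
        events=events,
        distances=distances,
        velocities=velocities,
        armed_cells=armed,
    )


def summarize(trace: LayerTrace) -> dict:
    """Condense a trace into the network's verdict about the object.

    Returns the majority direction code (None without events), the
    refined mean heading in degrees, per-window speeds, the aggregate
    speed (total step length / total window ticks), the modal nonzero
    distance class, and the event count.
    """
    n_events = len(trace.events)
    if n_events == 0:
        direction = None
        angle = None
    else:
        direction = Counter(e.code for e in trace.events).most_common(1)[0][0]
        vx = sum(math.cos(math.radians(CODE_TO_ANGLE[e.code])) for e in trace.events)
        vy = sum(math.sin(math.radians(CODE_TO_ANGLE[e.code])) for e in trace.events)
        angle = (
            math.degrees(math.atan2(vy, vx)) % 360.0
            if math.hypot(vx, vy) > 1e-12
            else CODE_TO_ANGLE[direction]
        )
    total_ticks = sum(v.window_ticks for v in trace.velocities)
    total_length = sum(v.speed * v.window_ticks for v in trace.velocities)
    speed = total_length / total_ticks if total_ticks else 0.0
    nonzero = [d.klass for d in trace.distances if d.klass > 0]
    modal_distance = Counter(nonzero).most_common(1)[0][0] if nonzero else 0
    return {
        "events": n_events,
        "direction": direction,
        "refined_angle_deg": angle,
        "window_speeds": [v.speed for v in trace.velocities],
        "speed": speed,
        "distance_class": modal_distance,
    }
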