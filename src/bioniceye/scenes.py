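"""Synthetic scene generation: imitation tracks of a moving object.

A Scene is a per-tick list of object states over the sensor plane.
Generators cover the study conditions used throughout the tests and
demos: straight transverse trajectories in each of the 8 coded
directions, vertical approach/recede trajectories, static objects, and
seeded random walks.  Diagonal codes step one full cell per axis, so a
speed-1 diagonal trajectory moves sqrt(2) grid units per tick and cell
transitions stay aligned with tick boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import GridSpec, ObjectState
from .layers import CODE_TO_STEP


@dataclass
class Scene:
    """Ordered per-tick object states plus generator provenance."""

    ticks: list[int]
    objects_at: list[list[ObjectState]]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ticks) < 1:
            raise ValueError("scene must have at least one tick")
        if len(self.objects_at) != len(self.ticks):
            raise ValueError("objects_at length must equal number of ticks")
        if any(b - a != 1 for a, b in zip(self.ticks, self.ticks[1:])):
            raise ValueError("scene ticks must be consecutive")

    def __len__(self) -> int:
        return len(self.ticks)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Scene):
            return NotImplemented
        return (
            self.ticks == other.ticks
            and self.objects_at == other.objects_at
            and self.metadata == other.metadata
        )

    def to_dict(self) -> dict:
        return {
            "ticks": self.ticks,
            "objects": [
                [o.model_dump() for o in objs] for objs in self.objects_at
            ],
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scene":
        return cls(
            ticks=list(d["ticks"]),
            objects_at=[
                [ObjectState(**o) for o in objs] for objs in d["objects"]
            ],
            metadata=dict(d.get("metadata", {})),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "Scene":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _check_in_grid(x: float, y: float, grid: GridSpec, tick: int, kind: str) -> None:
    if not (0 <= x <= grid.width - 1 and 0 <= y <= grid.height - 1):
        raise ValueError(
            f"{kind} trajectory exits the grid at tick {tick}: "
            f"(x={x:.3f}, y={y:.3f}) outside "
            f"[0, {grid.width - 1}] x [0, {grid.height - 1}]"
        )


def linear_scene(
    start: tuple[float, float, float],
    code: int,
    speed: float,
    ticks: int,
    grid: GridSpec | None = None,
    radius: float = 0.0,
) -> Scene:
    """Straight transverse trajectory along a coded direction.

    The object moves ``speed`` cells per tick along each axis of the
    code's step vector at constant height; speed 0 reduces to a static
    scene.  Raises if any tick leaves the grid, naming the first
    offending tick.
    """
    if code not in CODE_TO_STEP:
        raise ValueError(f"direction code must be 1-8, got {code}")
    if speed < 0 or ticks < 1:
        raise ValueError("speed must be >= 0 and ticks >= 1")
    grid = grid or GridSpec()
    x0, y0, z = start
    if z < 0:
        raise ValueError("height z must be >= 0")
    drow, dcol = CODE_TO_STEP[code]
    states = []
    for t in range(ticks):
        x = x0 + dcol * speed * t
        y = y0 + drow * speed * t
        _check_in_grid(x, y, grid, t, "linear")
        states.append([ObjectState(x=x, y=y, z=z, radius=radius)])
    return Scene(
        ticks=list(range(ticks)),
        objects_at=states,
        metadata={
            "generator": "linear",
            "start": list(start),
            "code": code,
            "speed": speed,
        },
    )


def static_scene(
    position: tuple[float, float, float],
    ticks: int,
    grid: GridSpec | None = None,
    radius: float = 0.0,
) -> Scene:
    """Object that never moves (equals a speed-0 linear scene)."""
    scene = linear_scene(position, code=4, speed=0.0, ticks=ticks, grid=grid,
                         radius=radius)
    scene.metadata = {"generator": "static", "position": list(position)}
    return scene


def vertical_scene(
    xy: tuple[float, float],
    z_start: float,
    z_step: float,
    ticks: int,
    grid: GridSpec | None = None,
    radius: float = 0.0,
) -> Scene:
    """Vertical approach/recede: fixed (x, y), linearly changing z."""
    grid = grid or GridSpec()
    x, y = xy
    _check_in_grid(x, y, grid, 0, "vertical")
    states = []
    for t in range(ticks):
        z = z_start + z_step * t
        if z < 0:
            raise ValueError(
                f"vertical trajectory goes below the plane at tick {t} (z={z:.3f})"
            )
        states.append([ObjectState(x=x, y=y, z=z, radius=radius)])
    return Scene(
        ticks=list(range(ticks)),
        objects_at=states,
        metadata={
            "generator": "vertical",
            "xy": list(xy),
            "z_start": z_start,
            "z_step": z_step,
        },
    )


def random_scene(
    seed: int,
    ticks: int,
    speed: float = 1.0,
    start: tuple[float, float, float] | None = None,
    grid: GridSpec | None = None,
) -> Scene:
    """Seeded random walk over the 8 direction codes, reflected at borders."""
    if ticks < 1:
        raise ValueError("ticks must be >= 1")
    grid = grid or GridSpec()
    rng = np.random.default_rng(seed)
    if start is None:
        start = ((grid.width - 1) / 2, (grid.height - 1) / 2, 0.8)
    x, y, z = start
    states = [[ObjectState(x=x, y=y, z=z)]]
    steps = list(CODE_TO_STEP.values())
    for _ in range(1, ticks):
        drow, dcol = steps[rng.integers(len(steps))]
        nx, ny = x + dcol * speed, y + drow * speed
        # reflect at the borders so the walk stays on the plane
        if not 0 <= nx <= grid.width - 1:
            nx = x - dcol * speed
        if not 0 <= ny <= grid.height - 1:
            ny = y - drow * speed
        x, y = min(max(nx, 0), grid.width - 1), min(max(ny, 0), grid.height - 1)
        states.append([ObjectState(x=x, y=y, z=z)])
    return Scene(
        ticks=list(range(ticks)),
        objects_at=states,
        metadata={"generator": "random-walk", "seed": seed, "speed": speed},
    )
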