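"""Sensor plane, viewing cones, and the perception layer.

The sensor plane is an H x W grid of perceive neurons (one per
ommatidium).  Each neuron looks straight up through a cone with a fixed
apex angle; an object at height ``z`` is perceived by every neuron whose
grid position lies within the object's projected footprint, a disc of
radius ``z * tan(apex/2) + radius`` centred on the object's horizontal
position.  As the object rises, that disc grows and more neurons fire;
far enough away the whole plane fires at once and the eye can no longer
localize it.

Coordinates are row-major and 0-based: row increases downward, column
increases rightward, "north" is decreasing row.  Neuron (r, c) sits at
the continuous point (x=c*spacing, y=r*spacing); object coordinates
share the same frame, in grid units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, Field


class GridSpec(BaseModel):
    """Dimensions and pitch of the sensor plane."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    height: int = Field(default=8, ge=3)
    width: int = Field(default=8, ge=3)
    spacing: float = Field(default=1.0, gt=0)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @property
    def n_neurons(self) -> int:
        return self.height * self.width


class ViewCone(BaseModel):
    """Upward viewing cone of a single perceive neuron.

    ``apex_angle`` is the full opening angle in degrees; the default 120
    degrees is the compound-eye figure the network is built around.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    apex_angle: float = Field(default=120.0, gt=0, lt=180)

    @property
    def half_angle_rad(self) -> float:
        return math.radians(self.apex_angle) / 2.0


class ObjectState(BaseModel):
    """Position and extent of one object above the plane, in grid units."""

    model_config = ConfigDict(extra="forbid")

    x: float
    y: float
    z: float = Field(ge=0)
    radius: float = Field(default=0.0, ge=0)


@dataclass
class PerceptionFrame:
    """Binary output of the perception layer at one tick."""

    values: np.ndarray  # H x W array of {0, 1}
    tick: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.ndim != 2:
            raise ValueError("perception frame must be a 2-D grid")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("perception frame entries must be 0 or 1")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PerceptionFrame):
            return NotImplemented
        return self.tick == other.tick and np.array_equal(self.values, other.values)


def footprint_radius(obj: ObjectState, cone: ViewCone) -> float:
    """Radius of the perceived disc projected by ``obj`` on the plane."""
    return obj.z * math.tan(cone.half_angle_rad) + obj.radius


def perceives(
    neuron_row: int,
    neuron_col: int,
    obj: ObjectState,
    cone: ViewCone,
    grid: GridSpec,
) -> bool:
    """Whether the neuron at (neuron_row, neuron_col) observes ``obj``.

    True iff the horizontal distance from the neuron's position to the
    object's (x, y) projection does not exceed the footprint radius.  At
    z = 0 only an object whose own radius covers the neuron is seen.
    """
    nx = neuron_col * grid.spacing
    ny = neuron_row * grid.spacing
    dist = math.hypot(obj.x - nx, obj.y - ny)
    return dist <= footprint_radius(obj, cone)


def perception_frame(
    objs: list[ObjectState],
    cone: ViewCone,
    grid: GridSpec,
    tick: int = 0,
) -> PerceptionFrame:
    """Evaluate the perception layer: 1 where any object is observed.

    Multiple objects are OR-ed together; an empty object list yields an
    all-zero frame (nothing observed, not an error).
    """
    values = np.zeros(grid.shape, dtype=np.uint8)
    if objs:
        rows = np.arange(grid.height, dtype=float)[:, None] * grid.spacing
        cols = np.arange(grid.width, dtype=float)[None, :] * grid.spacing
        for obj in objs:
            r = footprint_radius(obj, cone)
            d2 = (obj.x - cols) ** 2 + (obj.y - rows) ** 2
            values |= (d2 <= r * r + 1e-12).astype(np.uint8)
    return PerceptionFrame(values=values, tick=tick)


def active_count(frame: PerceptionFrame) -> int:
    """Number of perceive neurons currently firing."""
    return int(frame.values.sum())
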