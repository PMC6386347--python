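"""Network construction: five layers, receptive fields, weight kernel.

The network is feed-forward and entirely constructed (no training):

1. perception layer      — H x W sensors, one per grid cell;
2. range estimation      — each cell sums its kernel field of sensors
                           with ring weights 2(n-d)-1 (Chebyshev rings);
3. location identification — local winner-take-all over a 5-cell plus
                           neighborhood, unit weights;
4. track recognition     — each cell watches its 3x3 Moore block, unit
                           weights, and codes step directions 1-8;
5. final (velocity)      — one neuron fed by every layer-4 cell.

Receptive fields truncate at the grid border: no padding, no wrap, so
interior and corner fan-ins differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .geometry import GridSpec, ViewCone

# (drow, dcol) offsets of the two neighborhood shapes used by layers 3-4
VON_NEUMANN_5: tuple[tuple[int, int], ...] = ((0, 0), (-1, 0), (1, 0), (0, -1), (0, 1))
MOORE_9: tuple[tuple[int, int], ...] = tuple(
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
)
CENTER_ONLY: tuple[tuple[int, int], ...] = ((0, 0),)

_SHAPE_OFFSETS = {
    "center-only": CENTER_ONLY,
    "von-Neumann-5": VON_NEUMANN_5,
    "Moore-9": MOORE_9,
}


class NeighborhoodSpec(BaseModel):
    """Shape and size of a layer's per-neuron receptive neighborhood."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    shape: Literal["center-only", "von-Neumann-5", "Moore-9"] = "von-Neumann-5"
    size: int = 5

    @model_validator(mode="after")
    def _size_matches_shape(self) -> "NeighborhoodSpec":
        expected = len(_SHAPE_OFFSETS[self.shape])
        if self.size != expected:
            raise ValueError(
                f"neighborhood size {self.size} inconsistent with shape "
                f"{self.shape!r} (expected {expected})"
            )
        return self

    @property
    def offsets(self) -> tuple[tuple[int, int], ...]:
        return _SHAPE_OFFSETS[self.shape]


@dataclass(frozen=True)
class WeightKernel:
    """Ring weights of a range-estimation receptive field.

    ``weights`` maps Chebyshev ring distance d (0 at the center) to the
    integer connection weight w(d) = 2(n-d) - 1: the center weight is
    2n-1, the outermost ring has weight 1, and weights fall by 2 per
    ring, all odd.  The field spans (2n-1) x (2n-1) cells.
    """

    n: int
    weights: dict[int, int]

    @property
    def side(self) -> int:
        return 2 * self.n - 1

    def weight_at(self, drow: int, dcol: int) -> int:
        """Weight for an offset within the field (0 outside it)."""
        d = max(abs(drow), abs(dcol))
        return self.weights.get(d, 0)

    def to_array(self):
        """The kernel as a (2n-1) x (2n-1) integer array."""
        k = self.n - 1
        arr = np.zeros((self.side, self.side), dtype=np.int64)
        for dr in range(-k, k + 1):
            for dc in range(-k, k + 1):
                arr[dr + k, dc + k] = self.weight_at(dr, dc)
        return arr


def ring_weights(n: int) -> WeightKernel:
    """Construct the ring-weight kernel for radius parameter ``n``.

    w(d) = 2(n-d) - 1 for d = 0 ... n-1; endpoints are always w(0)=2n-1
    and w(n-1)=1.  n=2 is the default 3x3 kernel with 9 connections.
    """
    if not isinstance(n, int) or n < 1:
        raise ValueError(f"kernel radius parameter must be a positive integer, got {n!r}")
    return WeightKernel(n=n, weights={d: 2 * (n - d) - 1 for d in range(n)})


class NetworkConfig(BaseModel):
    """Everything needed to construct the network and run it."""

    model_config = ConfigDict(extra="forbid")

    grid: GridSpec = Field(default_factory=GridSpec)
    cone: ViewCone = Field(default_factory=ViewCone)
    kernel_n: int = Field(default=2, ge=1)
    loc_neighborhood: NeighborhoodSpec = Field(
        default_factory=lambda: NeighborhoodSpec(shape="von-Neumann-5", size=5)
    )
    track_neighborhood: NeighborhoodSpec = Field(
        default_factory=lambda: NeighborhoodSpec(shape="Moore-9", size=9)
    )
    subfield_size: int = Field(default=4, ge=1)
    interval_T: int = Field(default=8, ge=2)
    distance_thresholds: tuple[int, int] = (9, 25)

    @model_validator(mode="after")
    def _check(self) -> "NetworkConfig":
        c1, c2 = self.distance_thresholds
        if not 0 < c1 < c2:
            raise ValueError(
                f"distance_thresholds must satisfy 0 < c1 < c2, got ({c1}, {c2})"
            )
        return self


# adjacency: for each target neuron (flat row-major index), the list of
# (source flat index, integer weight) feeding it from the layer below
Adjacency = list[list[tuple[int, int]]]


@dataclass
class Network:
    """The constructed five-layer network."""

    config: NetworkConfig
    layer_sizes: list[int]
    adjacency: dict[int, Adjacency]  # keyed by target layer 2..5
    kernel: WeightKernel

    @property
    def grid(self) -> GridSpec:
        return self.config.grid

    def fan_in(self, layer: int, neuron: int) -> int:
        """Number of incoming connections of one neuron (0 for sensors)."""
        if layer == 1:
            if not 0 <= neuron < self.layer_sizes[0]:
                raise IndexError(f"neuron {neuron} out of range for layer 1")
            return 0
        if layer not in self.adjacency:
            raise IndexError(f"layer must be in 1..5, got {layer}")
        targets = self.adjacency[layer]
        if not 0 <= neuron < len(targets):
            raise IndexError(f"neuron {neuron} out of range for layer {layer}")
        return len(targets[neuron])


def _grid_adjacency(
    grid: GridSpec,
    offsets: tuple[tuple[int, int], ...],
    weight_of=lambda dr, dc: 1,
) -> Adjacency:
    """Same-size layer-to-layer wiring, truncated at the borders."""
    H, W = grid.shape
    adj: Adjacency = []
    for r in range(H):
        for c in range(W):
            incoming = []
            for dr, dc in offsets:
                sr, sc = r + dr, c + dc
                if 0 <= sr < H and 0 <= sc < W:
                    incoming.append((sr * W + sc, weight_of(dr, dc)))
            adj.append(incoming)
    return adj


def build_network(config: NetworkConfig) -> Network:
    """Wire all five layers from the configuration.

    Raises a configuration error if the grid cannot hold the kernel
    field (requires H, W >= 2n - 1).
    """
    grid = config.grid
    kernel = ring_weights(config.kernel_n)
    if grid.height < kernel.side or grid.width < kernel.side:
        raise ValueError(
            f"grid {grid.height}x{grid.width} too small for kernel field "
            f"{kernel.side}x{kernel.side} (n={config.kernel_n})"
        )

    k = config.kernel_n - 1
    kernel_offsets = tuple(
        (dr, dc) for dr in range(-k, k + 1) for dc in range(-k, k + 1)
    )
    adjacency = {
        2: _grid_adjacency(grid, kernel_offsets, kernel.weight_at),
        3: _grid_adjacency(grid, config.loc_neighborhood.offsets),
        4: _grid_adjacency(grid, config.track_neighborhood.offsets),
        5: [[(i, 1) for i in range(grid.n_neurons)]],
    }
    n = grid.n_neurons
    return Network(
        config=config,
        layer_sizes=[n, n, n, n, 1],
        adjacency=adjacency,
        kernel=kernel,
    )


def fan_in(net: Network, layer: int, neuron: int) -> int:
    """Module-level alias of :meth:`Network.fan_in`."""
    return net.fan_in(layer, neuron)
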