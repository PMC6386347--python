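"""On-disk formats: JSON config, CSV frame grids, JSON-lines events.

Frames are written as plain comma-separated integer grids, one file per
tick per layer and one row per grid row, so a run's output diffs
cleanly against printed grids.  Events go to an events.jsonl log (one
record per line) and scalar results to summary.json.  Everything round
trips losslessly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from pydantic import ValidationError

from . import __version__
from .engine import LayerTrace
from .geometry import PerceptionFrame
from .layers import (
    DirectionEvent,
    DistanceEstimate,
    LocationFrame,
    RangeFrame,
    VelocityEstimate,
)
from .topology import NetworkConfig


class ConfigError(ValueError):
    """Malformed or invalid network configuration file."""


class TraceIOError(IOError):
    """Missing or corrupt trace artifact."""


def read_config(path: str | Path) -> NetworkConfig:
    """Load a NetworkConfig from JSON, rejecting unknown keys."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path}: malformed JSON at line {exc.lineno}: {exc.msg}") from exc
    try:
        return NetworkConfig(**raw)
    except ValidationError as exc:
        details = "; ".join(
            (".".join(str(p) for p in err["loc"]) or "config") + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ConfigError(f"{path}: invalid configuration: {details}") from exc
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: invalid configuration: {exc}") from exc


def write_config(config: NetworkConfig, path: str | Path) -> None:
    Path(path).write_text(config.model_dump_json(indent=1))


def content_hash(obj) -> str:
    """Stable sha256 of a JSON-serializable object."""
    blob = json.dumps(obj, sort_keys=True, separators=(",", ":")).encode()
    return hashlib.sha256(blob).hexdigest()


@dataclass(frozen=True)
class RunManifest:
    """Provenance record written alongside every simulation output."""

    version: str
    config_hash: str
    scene_hash: str
    outputs: list[str]
    created_unix: float

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config_hash": self.config_hash,
            "scene_hash": self.scene_hash,
            "outputs": self.outputs,
            "created_unix": self.created_unix,
        }


def make_manifest(config: NetworkConfig, scene_dict: dict, outputs: list[str]) -> RunManifest:
    return RunManifest(
        version=__version__,
        config_hash=content_hash(json.loads(config.model_dump_json())),
        scene_hash=content_hash(scene_dict),
        outputs=sorted(outputs),
        created_unix=time.time(),
    )


def _write_frame_csv(values: np.ndarray, path: Path) -> None:
    np.savetxt(path, values, fmt="%d", delimiter=",")


def _read_frame_csv(path: Path) -> np.ndarray:
    if not path.exists():
        raise TraceIOError(f"missing frame file: {path}")
    return np.loadtxt(path, dtype=np.int64, delimiter=",", ndmin=2)


_LAYER_DIRS = {"perception": "perception", "range": "range", "location": "location"}


def write_trace(trace: LayerTrace, out_dir: str | Path) -> None:
    """Write a full trace: per-layer CSV frames, events, summary."""
    out = Path(out_dir)
    for sub in _LAYER_DIRS.values():
        (out / sub).mkdir(parents=True, exist_ok=True)
    for name, frames in (
        ("perception", trace.perception),
        ("range", trace.range_),
        ("location", trace.location),
    ):
        for f in frames:
            _write_frame_csv(f.values, out / name / f"tick_{f.tick:04d}.csv")
    with (out / "events.jsonl").open("w") as fh:
        for e in trace.events:
            fh.write(json.dumps(e.to_dict()) + "\n")
    (out / "summary.json").write_text(
        json.dumps(
            {
                "config": json.loads(trace.config.model_dump_json()),
                "ticks": trace.ticks,
                "distances": [d.to_dict() for d in trace.distances],
                "velocities": [v.to_dict() for v in trace.velocities],
                "armed_cells": [[t, list(c)] for t, c in trace.armed_cells],
            },
            indent=1,
        )
    )


def read_trace(dir_path: str | Path) -> LayerTrace:
    """Reconstruct a LayerTrace written by :func:`write_trace`."""
    out = Path(dir_path)
    summary_path = out / "summary.json"
    if not summary_path.exists():
        raise TraceIOError(f"missing trace summary: {summary_path}")
    summary = json.loads(summary_path.read_text())
    config = NetworkConfig(**summary["config"])
    ticks = list(summary["ticks"])

    def frames(name, cls, cast):
        result = []
        for t in ticks:
            arr = _read_frame_csv(out / name / f"tick_{t:04d}.csv")
            result.append(cls(values=arr.astype(cast), tick=t))
        return result

    events_path = out / "events.jsonl"
    if not events_path.exists():
        raise TraceIOError(f"missing events log: {events_path}")
    events = []
    for i, line in enumerate(events_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            events.append(DirectionEvent.from_dict(json.loads(line)))
        except (json.JSONDecodeError, KeyError) as exc:
            raise TraceIOError(f"{events_path}: corrupt record at line {i}") from exc

    return LayerTrace(
        config=config,
        ticks=ticks,
        perception=frames("perception", PerceptionFrame, np.uint8),
        range_=frames("range", RangeFrame, np.int64),
        location=frames("location", LocationFrame, np.uint8),
        events=events,
        distances=[DistanceEstimate(**d) for d in summary["distances"]],
        velocities=[VelocityEstimate(**v) for v in summary["velocities"]],
        armed_cells=[(t, tuple(c)) for t, c in summary["armed_cells"]],
    )


def track_display_grid(trace: LayerTrace, tick_index: int) -> np.ndarray:
    """Layer-4 style grid for one tick: the direction code printed at the
    previous location and 0 at the current location; -1 elsewhere."""
    grid = np.full(trace.config.grid.shape, -1, dtype=np.int64)
    tick = trace.ticks[tick_index]
    for t, cell in trace.armed_cells:
        if t == tick:
            grid[cell] = 0
    for e in trace.events:
        if e.tick == tick:
            grid[e.cell] = e.code
    return grid
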