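"""Readers, writers and run configuration.

On-disk formats:

* track tables — CSV with header ``track_id,frame,t_seconds,x_um,y_um``
  (``t_minutes`` accepted for minute-based cell tracks);
* phenotype counts — CSV with header ``condition,category,count``, one row
  per cell of the table, categories ordered by first appearance;
* image stacks — single-channel multi-frame TIFF;
* results, configuration and ground truth — flat JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import ImageStack, Track
from .errors import DomainError, ParseError
from .phenostats import OutcomeTable

__all__ = [
    "RunConfig",
    "read_track_table",
    "write_track_table",
    "read_counts_table",
    "write_counts_table",
    "read_stack",
    "write_stack",
    "provenance_record",
]

_TRACK_COLUMNS = ("track_id", "frame", "x_um", "y_um")


@dataclass
class RunConfig:
    """Pipeline-wide parameters with the study's acquisition defaults."""

    seed: int = 0
    pixel_size: float = 0.25  # um/px
    frame_interval: float = 0.25  # s (4 Hz)
    size_range: tuple[float, float] = (0.75, 1.25)  # um detection gate
    brightness_quantile: float = 0.99
    max_step: float = 2.5  # um linking gate
    min_duration: float = 1.0  # s, MSD window
    max_duration: float = 8.0  # s
    n_resamples: int = 100_000
    output_dir: str = "."

    def __post_init__(self):
        if min(self.pixel_size, self.frame_interval, self.max_step) <= 0:
            raise DomainError("gates and scales must be positive")
        if self.n_resamples < 1:
            raise DomainError("n_resamples must be >= 1")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        if "size_range" in data:
            data["size_range"] = tuple(data["size_range"])
        return cls(**data)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def read_track_table(path, time_unit: str = "s") -> list[Track]:
    """Read a track CSV into :class:`~kvflow.core.Track` objects.

    ``time_unit`` selects the expected time column: ``"s"`` -> ``t_seconds``
    (stored as-is), ``"min"`` -> ``t_minutes`` (kept in minutes; callers of
    the bead pipeline should use seconds).  Duplicate ``(track_id, frame)``
    rows and non-increasing frames within a track raise :class:`ParseError`
    naming the offending row.
    """
    if time_unit not in {"s", "min"}:
        raise ParseError(f"unknown time unit {time_unit!r}")
    tcol = "t_seconds" if time_unit == "s" else "t_minutes"
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in (*_TRACK_COLUMNS, tcol) if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    if df.empty:
        return []
    dup = df.duplicated(subset=["track_id", "frame"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ParseError(f"{path}: duplicated (track_id, frame) at data row {row}")

    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_index()
        frames = grp["frame"].to_numpy()
        if len(frames) >= 2 and not np.all(np.diff(frames) > 0):
            bad = int(grp.index[np.flatnonzero(np.diff(frames) <= 0)[0] + 1])
            raise ParseError(
                f"{path}: non-increasing frame within track {tid} at data row {bad}"
            )
        tracks.append(
            Track(
                track_id=int(tid),
                frame=frames,
                t=grp[tcol].to_numpy(dtype=float),
                x=grp["x_um"].to_numpy(dtype=float),
                y=grp["y_um"].to_numpy(dtype=float),
            )
        )
    return tracks


def write_track_table(tracks: list[Track], path, time_unit: str = "s") -> None:
    """Write tracks to CSV; full float precision so read(write(x)) == x."""
    if time_unit not in {"s", "min"}:
        raise ParseError(f"unknown time unit {time_unit!r}")
    tcol = "t_seconds" if time_unit == "s" else "t_minutes"
    rows = {
        "track_id": np.concatenate([np.full(len(tr), tr.track_id, dtype=np.int64) for tr in tracks]) if tracks else [],
        "frame": np.concatenate([tr.frame for tr in tracks]) if tracks else [],
        tcol: np.concatenate([tr.t for tr in tracks]) if tracks else [],
        "x_um": np.concatenate([tr.x for tr in tracks]) if tracks else [],
        "y_um": np.concatenate([tr.y for tr in tracks]) if tracks else [],
    }
    # shortest-repr floats + round_trip parsing give exact write/read identity
    pd.DataFrame(rows, columns=["track_id", "frame", tcol, "x_um", "y_um"]).to_csv(
        path, index=False
    )


def read_counts_table(path) -> dict[str, OutcomeTable]:
    """Read a ``condition,category,count`` CSV into outcome tables.

    Categories are ordered by first appearance; every condition must cover
    the same categories (ragged tables are rejected so that two-sample
    comparisons are well defined).
    """
    df = pd.read_csv(path)
    missing = [c for c in ("condition", "category", "count") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    if (df["count"] < 0).any():
        row = int(df.index[df["count"] < 0][0])
        raise ParseError(f"{path}: negative count at data row {row}")
    categories = tuple(dict.fromkeys(df["category"]))
    tables: dict[str, OutcomeTable] = {}
    for cond, grp in df.groupby("condition", sort=False):
        cats = tuple(grp["category"])
        if set(cats) != set(categories) or len(cats) != len(categories):
            raise ParseError(
                f"{path}: condition {cond!r} has categories {cats}, "
                f"expected {categories}"
            )
        counts = dict(zip(grp["category"], grp["count"]))
        tables[str(cond)] = OutcomeTable(
            condition=str(cond),
            categories=categories,
            counts=tuple(int(counts[c]) for c in categories),
        )
    return tables


def write_counts_table(tables: dict[str, OutcomeTable], path) -> None:
    rows = [
        {"condition": t.condition, "category": cat, "count": cnt}
        for t in tables.values()
        for cat, cnt in zip(t.categories, t.counts)
    ]
    pd.DataFrame(rows, columns=["condition", "category", "count"]).to_csv(path, index=False)


def read_stack(path, pixel_size: float = 0.25, frame_interval: float = 0.25) -> ImageStack:
    """Read a single-channel multi-frame TIFF as an :class:`ImageStack`."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        raise DomainError(f"{path}: single frame; a time-lapse needs T >= 2")
    if arr.ndim != 3:
        raise DomainError(f"{path}: expected (T, H, W) data, got shape {arr.shape}")
    return ImageStack(frames=arr, pixel_size=pixel_size, frame_interval=frame_interval)


def write_stack(stack: ImageStack, path) -> None:
    tifffile.imwrite(
        path, np.asarray(stack.frames, dtype=np.float32), photometric="minisblack"
    )


def provenance_record(command: str, params: dict, seed: int | None = None) -> dict:
    """JSON-serialisable record of how a result was produced."""
    from . import __version__

    record = {
        "command": command,
        "params": params,
        "kvflow_version": __version__,
        "numpy_version": np.__version__,
    }
    if seed is not None:
        record["seed"] = seed
    return record
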