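"""Shared in-memory containers: trajectories and image stacks.

Conventions (used consistently across the package):

* coordinates are continuous micrometres; image coordinates have their
  origin at the centre of the top-left pixel, x rightward (columns), y
  downward (rows);
* pixel and frame indices are 0-based;
* time is stored in seconds internally; minute-based track tables are
  converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

__all__ = ["Track", "ImageStack"]


@dataclass
class Track:
    """One particle's ordered positions.

    ``frame`` holds 0-based frame indices, ``t`` the matching times in
    seconds (minutes for cell tracks handled by :mod:`kvflow.dfc_kinematics`;
    the container itself is unit-agnostic), ``x``/``y`` positions in um.
    """

    track_id: int
    frame: np.ndarray
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.frame = np.asarray(self.frame, dtype=np.int64)
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.frame)
        if not (len(self.t) == len(self.x) == len(self.y) == n):
            raise DomainError("frame/t/x/y must have equal length")
        if n >= 2 and not np.all(np.diff(self.t) > 0):
            raise DomainError(f"track {self.track_id}: times must strictly increase")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def duration(self) -> float:
        """Elapsed time between first and last point (0 for single points)."""
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) positions."""
        return np.column_stack([self.x, self.y])


@dataclass
class ImageStack:
    """A single-channel time-lapse: frames (T, H, W) with physical scales."""

    frames: np.ndarray
    pixel_size: float = 0.25  # um per pixel
    frame_interval: float = 0.25  # seconds (4 Hz acquisition)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise DomainError(
                f"expected a (T, H, W) stack, got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise DomainError("a time-lapse stack needs at least 2 frames")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise DomainError("pixel_size and frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]
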