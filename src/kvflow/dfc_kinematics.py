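"""Dorsal-forerunner-cell migration kinematics.

During epiboly the DFC cluster travels from the animal toward the vegetal
pole while tightening along the migration axis.  Given manually traced cell
tracks (times in minutes, +y toward the vegetal pole), this module computes
the three summary quantities used to compare genotypes:

* convergence ratio — the cluster's y-extent at the start of the recording
  divided by its extent at the end (> 1 means the cells converged);
* mean migration speed in um/min;
* migration index — a cluster position expressed as percent of the total
  embryo length along the animal-vegetal axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Track
from .errors import DomainError, EmptyResultError

__all__ = [
    "ConvergenceResult",
    "convergence_ratio",
    "migration_speed",
    "migration_index",
]


@dataclass(frozen=True)
class ConvergenceResult:
    """Extent-based convergence of a tracked cell group."""

    ratio: float  # initial extent / final extent; inf when final extent is 0
    initial_extent: float  # um
    final_extent: float  # um
    n_cells: int
    is_infinite: bool


def _y_at_frame(track: Track, frame: int) -> float | None:
    idx = np.flatnonzero(track.frame == frame)
    if idx.size == 0:
        return None
    return float(track.y[int(idx[0])])


def convergence_ratio(tracks: list[Track]) -> ConvergenceResult:
    """Ratio of the group's y-extent at the first vs last common frame.

    Extent is max(y) - min(y) over the cells present at that frame; cells
    lacking a sample at the first or last common frame (ragged manual
    tracks) are excluded.  The initial/final orientation is a convention
    chosen so that converging groups score above 1.  A zero final extent
    returns an infinite ratio flagged via ``is_infinite``.
    """
    usable = [tr for tr in tracks if len(tr) >= 2]
    if len(usable) < 2:
        raise DomainError("convergence needs at least two tracked cells")
    f0 = max(int(tr.frame[0]) for tr in usable)
    f1 = min(int(tr.frame[-1]) for tr in usable)
    if f1 <= f0:
        raise DomainError("tracks share no common frame window")

    y0, y1 = [], []
    for tr in usable:
        a = _y_at_frame(tr, f0)
        b = _y_at_frame(tr, f1)
        if a is None or b is None:
            continue
        y0.append(a)
        y1.append(b)
    if len(y0) < 2:
        raise DomainError("fewer than two cells present at both endpoints")

    initial = float(np.ptp(y0))
    final = float(np.ptp(y1))
    if final == 0.0:
        return ConvergenceResult(
            ratio=float("inf"), initial_extent=initial, final_extent=0.0,
            n_cells=len(y0), is_infinite=True,
        )
    return ConvergenceResult(
        ratio=initial / final, initial_extent=initial, final_extent=final,
        n_cells=len(y0), is_infinite=False,
    )


def migration_speed(tracks: list[Track]) -> float:
    """Mean step speed per cell, averaged unweighted across cells (um/min)."""
    speeds = []
    for tr in tracks:
        if len(tr) < 2:
            continue
        steps = np.hypot(np.diff(tr.x), np.diff(tr.y))
        speeds.append(float(np.mean(steps / np.diff(tr.t))))
    if not speeds:
        raise EmptyResultError("no track of length >= 2")
    return float(np.mean(speeds))


def migration_index(dfc_position_y: float, embryo_length: float) -> float:
    """Animal-to-vegetal progress as a percentage of embryo length."""
    if embryo_length <= 0:
        raise DomainError("embryo_length must be positive")
    if not 0.0 <= dfc_position_y <= embryo_length:
        raise DomainError(
            f"position {dfc_position_y} outside [0, {embryo_length}]"
        )
    return 100.0 * dfc_position_y / embryo_length
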