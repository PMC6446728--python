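"""Per-track motility statistics.

The headline statistic is the track mean speed — total path length divided
by elapsed time, matching the "track mean speed" that spot-tracking software
exports — plus net displacement, straightness, local displacement over a
sliding time window, and the number of distinct grid sites a cell visits
(an exploration measure).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, LeukotrackError, TrackTooShortError
from .io import Track, TrackSet

logger = logging.getLogger(__name__)

DEFAULT_GRID = 10.0    # µm; about one cell diameter
DEFAULT_WINDOW = 15.0  # min; five frames at the default 3-min interval


@dataclass(frozen=True)
class TrackStats:
    """Summary of one track. ``mean_speed = path_length / duration``;
    ``straightness = net_displacement / path_length`` (0 for zero paths)."""

    track_id: str
    n_points: int
    duration: float
    path_length: float
    mean_speed: float
    net_displacement: float
    straightness: float
    distinct_sites: int


def _step_displacements(track: Track) -> np.ndarray:
    return np.linalg.norm(np.diff(track.positions, axis=0), axis=1)


def track_path_length(track: Track) -> float:
    """Sum of consecutive point-to-point Euclidean displacements, in µm."""
    if track.n_points < 2:
        raise TrackTooShortError(f"track {track.track_id!r}: need >= 2 points")
    return float(_step_displacements(track).sum())


def track_net_displacement(track: Track) -> float:
    """Straight-line distance from first to last position, in µm."""
    if track.n_points < 2:
        raise TrackTooShortError(f"track {track.track_id!r}: need >= 2 points")
    return float(np.linalg.norm(track.positions[-1] - track.positions[0]))


def track_mean_speed(track: Track) -> float:
    """Path length over elapsed time (µm min⁻¹); gaps contribute their true Δt."""
    return track_path_length(track) / track.duration


def track_straightness(track: Track) -> float:
    """Net displacement over path length, in [0, 1]; 0 for a zero-length path."""
    path = track_path_length(track)
    if path == 0.0:
        return 0.0
    return track_net_displacement(track) / path


def _modal_dt(track: Track) -> float:
    diffs = np.diff(track.times)
    vals, counts = np.unique(np.round(diffs, 9), return_counts=True)
    return float(vals[np.argmax(counts)])


def local_displacement(track: Track, window: float) -> np.ndarray:
    """Displacement over a sliding time window.

    For each point whose time ``t`` has a successor observed at ``t + window``
    (matched within half a frame interval, to survive small export jitter),
    returns the Euclidean distance between the two positions. The result is
    empty when no point pair spans the window.
    """
    if track.n_points < 2:
        raise TrackTooShortError(f"track {track.track_id!r}: need >= 2 points")
    dt = _modal_dt(track)
    if window < dt * (1 - 1e-9):
        raise InvalidParameterError(
            f"window ({window} min) shorter than the frame interval ({dt} min)")
    tol = dt / 2.0
    t = track.times
    out = []
    j = 0
    for i in range(track.n_points):
        target = t[i] + window
        while j < track.n_points and t[j] < target - tol:
            j += 1
        if j < track.n_points and abs(t[j] - target) <= tol:
            out.append(np.linalg.norm(track.positions[j] - track.positions[i]))
    return np.asarray(out, dtype=float)


def distinct_sites_visited(track: Track, grid: float = DEFAULT_GRID) -> int:
    """Number of unique grid cells containing at least one track point.

    Cells are half-open hypercubes of side ``grid`` µm with the origin at 0;
    the cell of a point is ``floor(coordinate / grid)`` per axis.
    """
    if grid <= 0:
        raise InvalidParameterError("grid must be > 0")
    cells = np.floor(track.positions / grid).astype(np.int64)
    return len({tuple(row) for row in cells})


def cohort_stats_table(trackset: TrackSet, grid: float = DEFAULT_GRID,
                       window: float = DEFAULT_WINDOW) -> pd.DataFrame:
    """One row of :class:`TrackStats` per track, ordered by track id.

    Also reports ``mean_local_disp``, the mean windowed displacement (NaN when
    no pair spans the window). Per-track failures are re-raised with the
    offending track id named.
    """
    rows = []
    for tr in sorted(trackset, key=lambda t: t.track_id):
        try:
            path = track_path_length(tr)
            local = local_displacement(tr, window)
            rows.append({
                "track_id": tr.track_id,
                "n_points": tr.n_points,
                "duration": tr.duration,
                "path_length": path,
                "mean_speed": path / tr.duration,
                "net_displacement": track_net_displacement(tr),
                "straightness": track_straightness(tr),
                "distinct_sites": distinct_sites_visited(tr, grid),
                "mean_local_disp": float(local.mean()) if local.size else float("nan"),
                "disease": tr.labels.disease,
                "stage": tr.labels.stage,
                "epoch": tr.labels.epoch,
            })
        except LeukotrackError as exc:
            raise type(exc)(f"track {tr.track_id!r}: {exc}") from exc
    table = pd.DataFrame(rows)
    logger.info("cohort_stats_table: %d tracks summarised", len(table))
    return table
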