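"""Trajectory data model and CSV readers/writers.

Units are fixed package-wide: time in minutes, positions in micrometres.
Readers perform no unit conversion — input tables are declared to be in
these units (the study design images every 3 min and reports speeds in
µm min⁻¹, so nothing else is sensible).

Two table dialects are supported:

``plain``
    Header ``track_id,t,x,y[,z]``; optional cohort-label columns
    ``disease,stage,epoch`` survive a round trip.
``imaris-like``
    The flavour of CSV that spot-tracking software such as Imaris exports:
    any number of leading metadata lines, then a header row containing
    ``Position X``; columns ``Position X/Y/Z``, ``Time`` and ``TrackID``
    are mapped onto the plain schema.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateTimepointError,
    EmptyTrackSetError,
    InvalidParameterError,
    MissingColumnError,
    NonNumericCoordinateError,
)

logger = logging.getLogger(__name__)

DISEASES = ("AML", "T-ALL", "other")
STAGES = ("seeding", "chemoresistant", "other")
EPOCHS = ("pre", "post", "none")

LABEL_COLUMNS = ("disease", "stage", "epoch")


class TrackPoint(NamedTuple):
    """One cell observation: time (min) and position (µm); ``z`` is None in 2D."""

    t: float
    x: float
    y: float
    z: float | None = None


@dataclass(frozen=True)
class TrackLabels:
    """Cohort annotations attached to a track."""

    disease: str = "other"
    stage: str = "other"
    epoch: str = "none"

    def __post_init__(self) -> None:
        if self.disease not in DISEASES:
            raise InvalidParameterError(f"disease must be one of {DISEASES}, got {self.disease!r}")
        if self.stage not in STAGES:
            raise InvalidParameterError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if self.epoch not in EPOCHS:
            raise InvalidParameterError(f"epoch must be one of {EPOCHS}, got {self.epoch!r}")

    @property
    def is_default(self) -> bool:
        return self == TrackLabels()


@dataclass
class Track:
    """One cell's time-ordered trajectory.

    Parameters
    ----------
    track_id
        Identifier, unique within a :class:`TrackSet`.
    times
        Strictly increasing observation times in minutes, all finite, ≥ 0.
    positions
        Array of shape ``(n_points, dims)`` in micrometres.
    labels
        Cohort annotations (disease, disease stage, pre/post-drug epoch).
    """

    track_id: str
    times: np.ndarray
    positions: np.ndarray
    labels: TrackLabels = field(default_factory=TrackLabels)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or self.times.size < 1:
            raise InvalidParameterError("a track needs at least one timepoint")
        if self.positions.ndim != 2 or self.positions.shape[0] != self.times.size:
            raise InvalidParameterError("positions must be (n_points, dims) matching times")
        if not np.all(np.isfinite(self.times)) or np.any(self.times < 0):
            raise InvalidParameterError("times must be finite and non-negative")
        if not np.all(np.isfinite(self.positions)):
            raise InvalidParameterError("positions must be finite")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise InvalidParameterError("times must be strictly increasing")

    @property
    def n_points(self) -> int:
        return self.times.size

    @property
    def dims(self) -> int:
        return self.positions.shape[1]

    @property
    def duration(self) -> float:
        """Elapsed time between first and last observation, in minutes."""
        return float(self.times[-1] - self.times[0])

    @property
    def points(self) -> Iterator[TrackPoint]:
        for i in range(self.n_points):
            z = float(self.positions[i, 2]) if self.dims >= 3 else None
            yield TrackPoint(float(self.times[i]), float(self.positions[i, 0]),
                             float(self.positions[i, 1]), z)

    @classmethod
    def from_points(cls, track_id: str, points: Sequence[TrackPoint],
                    labels: TrackLabels | None = None) -> "Track":
        pts = sorted(points, key=lambda p: p.t)
        has_z = pts[0].z is not None
        pos = np.array([[p.x, p.y, p.z] if has_z else [p.x, p.y] for p in pts], dtype=float)
        return cls(track_id, np.array([p.t for p in pts]), pos,
                   labels if labels is not None else TrackLabels())


@dataclass
class TrackSet:
    """A collection of tracks from one acquisition, with shared metadata."""

    tracks: list[Track]
    frame_interval: float
    dims: int
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.frame_interval <= 0 or not math.isfinite(self.frame_interval):
            raise InvalidParameterError("frame_interval must be positive and finite")
        if self.dims not in (2, 3):
            raise InvalidParameterError("dims must be 2 or 3")
        for tr in self.tracks:
            if tr.dims != self.dims:
                raise InvalidParameterError(
                    f"track {tr.track_id!r} has {tr.dims} dims, TrackSet declares {self.dims}")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)


@dataclass(frozen=True)
class ClusterIntensityRecord:
    """Mean fluorescence intensity of one region before and after treatment."""

    region_id: str
    mfi_before: float
    mfi_after: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mfi_before) and math.isfinite(self.mfi_after)):
            raise InvalidParameterError("intensities must be finite")
        if self.mfi_before < 0 or self.mfi_after < 0:
            raise InvalidParameterError("intensities must be non-negative")


# ---------------------------------------------------------------------------
# reading

_IMARIS_COLUMN_MAP = {
    "Position X": "x",
    "Position Y": "y",
    "Position Z": "z",
    "Time": "t",
    "TrackID": "track_id",
}


def _modal_step(diffs: np.ndarray) -> float:
    """Most common positive time step, rounded to ns precision for binning."""
    if diffs.size == 0:
        return 1.0
    counts = Counter(np.round(diffs, 9))
    return float(counts.most_common(1)[0][0])


def _coerce_numeric(frame: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    for col in columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            value = frame.loc[bad.idxmax(), col]
            raise NonNumericCoordinateError(
                f"column {col!r} contains non-numeric value {value!r}")
        if coerced.isna().any():
            raise NonNumericCoordinateError(f"column {col!r} contains empty cells")
        frame[col] = coerced.astype(float)
    return frame


def _read_imaris_like(path: Path) -> pd.DataFrame:
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    header_row = None
    for i, line in enumerate(lines):
        if "Position X" in line:
            header_row = i
            break
    if header_row is None:
        raise MissingColumnError(f"{path}: no header containing 'Position X' found")
    from io import StringIO

    frame = pd.read_csv(StringIO("".join(lines[header_row:])), float_precision="round_trip")
    frame = frame.rename(columns=lambda c: _IMARIS_COLUMN_MAP.get(c.strip(), c.strip()))
    return frame


def read_tracks(path: str | Path, dialect: str = "plain") -> TrackSet:
    """Read a track table into a :class:`TrackSet`.

    One :class:`Track` is built per distinct track id, points sorted by time.
    Dimensionality is inferred from the presence of a ``z`` column and the
    frame interval is inferred as the modal time step over all tracks.

    Raises
    ------
    FileNotFoundError, MissingColumnError, DuplicateTimepointError,
    NonNumericCoordinateError
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"track table not found: {path}")
    if dialect == "plain":
        frame = pd.read_csv(path, float_precision="round_trip")
        frame = frame.rename(columns=lambda c: c.strip())
    elif dialect == "imaris-like":
        frame = _read_imaris_like(path)
    else:
        raise InvalidParameterError(f"unknown dialect {dialect!r}")

    for col in ("track_id", "t", "x", "y"):
        if col not in frame.columns:
            raise MissingColumnError(f"{path}: required column {col!r} missing")
    has_z = "z" in frame.columns and frame["z"].notna().all()
    coord_cols = ["t", "x", "y"] + (["z"] if has_z else [])
    frame = _coerce_numeric(frame, coord_cols)

    dup = frame.duplicated(subset=["track_id", "t"])
    if dup.any():
        row = frame.loc[dup.idxmax()]
        raise DuplicateTimepointError(
            f"{path}: duplicate timepoint t={row['t']} for track {row['track_id']!r}")

    tracks: list[Track] = []
    all_diffs: list[np.ndarray] = []
    for track_id, sub in frame.groupby("track_id", sort=True):
        sub = sub.sort_values("t")
        labels = TrackLabels()
        if all(c in sub.columns for c in LABEL_COLUMNS):
            labels = TrackLabels(str(sub["disease"].iloc[0]), str(sub["stage"].iloc[0]),
                                 str(sub["epoch"].iloc[0]))
        pos = sub[["x", "y", "z"] if has_z else ["x", "y"]].to_numpy(dtype=float)
        tr = Track(str(track_id), sub["t"].to_numpy(dtype=float), pos, labels)
        tracks.append(tr)
        all_diffs.append(np.diff(tr.times))
    frame_interval = _modal_step(np.concatenate(all_diffs) if all_diffs else np.array([]))
    ts = TrackSet(tracks, frame_interval=frame_interval, dims=3 if has_z else 2,
                  provenance=f"read from {path.name} ({dialect})")
    logger.info("read %d tracks (%d points) from %s", len(tracks), len(frame), path)
    return ts


# ---------------------------------------------------------------------------
# writing

def write_tracks(trackset: TrackSet, path: str | Path) -> None:
    """Write a TrackSet as a plain-dialect CSV.

    Coordinates are written with shortest-roundtrip float formatting, so
    ``read_tracks(write_tracks(ts))`` reproduces every id, time and
    coordinate to full precision. The ``z`` column appears only for 3D sets;
    label columns appear only when some track carries non-default labels.
    """
    if not trackset.tracks:
        raise EmptyTrackSetError("refusing to write an empty TrackSet")
    import csv

    want_labels = any(not tr.labels.is_default for tr in trackset)
    header = ["track_id", "t", "x", "y"] + (["z"] if trackset.dims == 3 else [])
    if want_labels:
        header += list(LABEL_COLUMNS)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for tr in trackset:
            for i in range(tr.n_points):
                # repr() is the shortest representation that parses back to
                # the identical float, guaranteeing a lossless round trip
                row = [tr.track_id, repr(float(tr.times[i]))]
                row += [repr(float(c)) for c in tr.positions[i]]
                if want_labels:
                    row += [tr.labels.disease, tr.labels.stage, tr.labels.epoch]
                writer.writerow(row)


def read_cluster_table(path: str | Path) -> list[ClusterIntensityRecord]:
    """Read a region-intensity table: header ``region_id,mfi_before,mfi_after``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cluster table not found: {path}")
    frame = pd.read_csv(path, float_precision="round_trip")
    for col in ("region_id", "mfi_before", "mfi_after"):
        if col not in frame.columns:
            raise MissingColumnError(f"{path}: required column {col!r} missing")
    frame = _coerce_numeric(frame, ["mfi_before", "mfi_after"])
    return [ClusterIntensityRecord(str(r.region_id), float(r.mfi_before), float(r.mfi_after))
            for r in frame.itertuples()]


def write_cluster_table(records: Sequence[ClusterIntensityRecord], path: str | Path) -> None:
    pd.DataFrame([{"region_id": r.region_id, "mfi_before": r.mfi_before,
                   "mfi_after": r.mfi_after} for r in records]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# quality control

def filter_tracks(trackset: TrackSet, min_points: int = 5,
                  max_gap: float = 2.0) -> TrackSet:
    """Quality-filter tracks before statistics.

    Keeps tracks with at least ``min_points`` observations and no inter-point
    time gap exceeding ``max_gap`` frame intervals. The defaults (5 points,
    2 frames) guarantee at least 4 usable MSD lags per retained track.
    Counts in/out are logged; an empty result is legal but warned about.
    """
    if min_points < 2:
        raise InvalidParameterError("min_points must be >= 2")
    limit = max_gap * trackset.frame_interval
    kept = []
    for tr in trackset:
        if tr.n_points < min_points:
            continue
        if np.any(np.diff(tr.times) > limit * (1 + 1e-9)):
            continue
        kept.append(tr)
    logger.info("filter_tracks: kept %d of %d tracks (min_points=%d, max_gap=%g frames)",
                len(kept), len(trackset), min_points, max_gap)
    if not kept:
        logger.warning("filter_tracks: no tracks passed the quality filter")
    return TrackSet(kept, trackset.frame_interval, trackset.dims, trackset.provenance)


def split_epochs(trackset: TrackSet) -> tuple[TrackSet, TrackSet]:
    """Split a mixed TrackSet into (pre, post) by the epoch label."""
    pre = [t for t in trackset if t.labels.epoch == "pre"]
    post = [t for t in trackset if t.labels.epoch == "post"]
    mk = lambda trs: TrackSet(trs, trackset.frame_interval, trackset.dims, trackset.provenance)
    return mk(pre), mk(post)


def relabel(trackset: TrackSet, **labels: str) -> TrackSet:
    """Return a copy with the given label fields replaced on every track."""
    new = [replace(tr, labels=replace(tr.labels, **labels)) for tr in trackset]
    return TrackSet(new, trackset.frame_interval, trackset.dims, trackset.provenance)
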