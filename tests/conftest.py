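"""Shared fixtures and independent oracles.

The brute-force TA-MSD here is the reference the fast implementation is
checked against: a literal double loop over all ordered point pairs,
grouped by time difference. It must stay independent of the library's
estimator.
"""

from __future__ import annotations

import numpy as np
import pytest

from leukotrack import Track, TrackLabels, TrackSet


def brute_force_tamsd(track: Track, max_lag_fraction: float, frame_interval: float):
    """O(n²) all-pairs TA-MSD: dict lag (min) -> (mean squared disp, n_pairs)."""
    t, pos = track.times, track.positions
    kmax = int(np.floor(max_lag_fraction * (t[-1] - t[0]) / frame_interval + 1e-9))
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for i in range(len(t)):
        for j in range(i + 1, len(t)):
            dt = t[j] - t[i]
            k = int(round(dt / frame_interval))
            if abs(dt - k * frame_interval) > 1e-9 or k < 1 or k > kmax:
                continue
            sums[k] = sums.get(k, 0.0) + float(np.sum((pos[j] - pos[i]) ** 2))
            counts[k] = counts.get(k, 0) + 1
    return {k * frame_interval: (sums[k] / counts[k], counts[k]) for k in sorted(sums)}


def random_gapped_track(rng: np.random.Generator, track_id: str = "rand",
                        frame_interval: float = 3.0, dims: int = 3,
                        min_points: int = 5, max_points: int = 30,
                        gapped: bool = True) -> Track:
    """A random-walk track on the frame grid, optionally with missing frames."""
    n = int(rng.integers(min_points, max_points + 1))
    n_slots = n + (int(rng.integers(1, n)) if gapped else 0)
    idx = np.sort(rng.choice(n_slots, size=n, replace=False))
    times = idx * frame_interval
    pos = np.cumsum(rng.normal(0, 2.0, size=(n, dims)), axis=0)
    return Track(track_id, times, pos)


def assert_tracksets_equal(a: TrackSet, b: TrackSet) -> None:
    assert len(a) == len(b)
    assert a.dims == b.dims
    for ta, tb in zip(sorted(a, key=lambda t: t.track_id),
                      sorted(b, key=lambda t: t.track_id)):
        assert ta.track_id == tb.track_id
        np.testing.assert_array_equal(ta.times, tb.times)
        np.testing.assert_array_equal(ta.positions, tb.positions)
        assert ta.labels == tb.labels


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


@pytest.fixture
def straight_track() -> Track:
    """Constant velocity 2 µm/min along x, sampled every 3 min for 30 min."""
    t = np.arange(11) * 3.0
    pos = np.column_stack([2.0 * t, np.zeros(11)])
    return Track("straight", t, pos)


@pytest.fixture
def stationary_track() -> Track:
    return Track("still", np.arange(11) * 3.0, np.zeros((11, 2)))


@pytest.fixture
def small_trackset(rng: np.random.Generator) -> TrackSet:
    tracks = [random_gapped_track(rng, f"tr{i}", gapped=False) for i in range(4)]
    return TrackSet(tracks, 3.0, 3)


@pytest.fixture
def labeled_track() -> Track:
    return Track("lbl", np.array([0.0, 3.0]), np.array([[0.0, 0.0], [1.0, 1.0]]),
                 TrackLabels(disease="AML", stage="seeding", epoch="pre"))
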