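"""Synthetic trajectory cohorts with known motion regimes.

The generators emulate the study's intravital imaging design — positions in
the marrow imaged every 3 min for a 90-min pre-drug epoch, then, after a
15-min injection gap, for a further 180 min — and produce cohorts whose
ensemble mean-squared displacement follows a known closed form, so every
downstream statistic can be validated against analytic truth:

========== =============================================== ==============
kind       model                                           ensemble MSD
========== =============================================== ==============
brownian   independent Gaussian increments, diffusivity D  2·d·D·τ
fbm        fractional Brownian motion, Hurst H, scale K    d·K·τ^(2H)
prw        persistent random walk (OU velocity), speed s,  Fürth relation
           persistence time P
ballistic  straight-line motion at speed s, random heading s²·τ²
stationary no motion                                       0
========== =============================================== ==============

Randomness uses one master seed with counter-based per-track substreams
(``SeedSequence([seed, stream, track_index])``), so cohorts are bit-for-bit
reproducible and each track's trajectory is independent of how many other
tracks are generated or in what order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import InvalidParameterError
from .io import Track, TrackLabels, TrackSet

__all__ = [
    "ImagingDesign", "MotionModel", "CohortSpec",
    "simulate_brownian", "simulate_fbm", "simulate_prw", "simulate_ballistic",
    "add_localization_noise", "simulate_cohort",
    "fgn_autocovariance", "furth_msd",
]

# substream tags for SeedSequence([seed, tag, track_index])
_STREAM_GENERIC = 0
_STREAM_PRE = 1
_STREAM_POST = 2
_STREAM_NOISE = 3
_STREAM_MOBILIZE = 4


def _track_rng(seed: int, stream: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream, index]))


# ---------------------------------------------------------------------------
# specification types

@dataclass(frozen=True)
class ImagingDesign:
    """Timelapse schedule: frame interval and epoch durations, in minutes.

    Defaults follow the study design: 3-min frames over a 90-min pre-drug
    epoch, a 15-min injection gap (no frames acquired), then 180 min of
    post-drug imaging of the same positions.
    """

    frame_interval: float = 3.0
    pre_duration: float = 90.0
    gap_duration: float = 15.0
    post_duration: float = 180.0

    def __post_init__(self) -> None:
        for name in ("frame_interval", "pre_duration", "gap_duration", "post_duration"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise InvalidParameterError(f"{name} must be positive and finite")
        for name in ("pre_duration", "post_duration"):
            ratio = getattr(self, name) / self.frame_interval
            if abs(ratio - round(ratio)) > 1e-9:
                raise InvalidParameterError(
                    f"frame_interval must divide {name} ({getattr(self, name)} min)")

    @property
    def n_pre_frames(self) -> int:
        return round(self.pre_duration / self.frame_interval) + 1

    @property
    def n_post_frames(self) -> int:
        return round(self.post_duration / self.frame_interval) + 1


_MODEL_PARAMS = {
    "brownian": {"D"},
    "fbm": {"H", "K"},
    "prw": {"speed", "persistence"},
    "ballistic": {"speed"},
    "stationary": set(),
}


@dataclass(frozen=True)
class MotionModel:
    """A named motion regime plus its parameters.

    brownian: ``D`` (µm² min⁻¹); fbm: ``H`` in (0,1) and ``K`` (µm² min^(−2H));
    prw: ``speed`` (µm min⁻¹, per-axis RMS velocity) and ``persistence`` (min);
    ballistic: ``speed`` (µm min⁻¹, drawn with a fixed random heading).
    """

    kind: str
    params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _MODEL_PARAMS:
            raise InvalidParameterError(f"unknown motion model {self.kind!r}")
        expected = _MODEL_PARAMS[self.kind]
        if set(self.params) != expected:
            raise InvalidParameterError(
                f"model {self.kind!r} needs params {sorted(expected)}, got {sorted(self.params)}")
        for name, v in self.params.items():
            if not math.isfinite(v):
                raise InvalidParameterError(f"{name} must be finite")
        if self.kind == "brownian" and self.params["D"] < 0:
            raise InvalidParameterError("D must be >= 0")
        if self.kind == "fbm":
            if not 0 < self.params["H"] < 1:
                raise InvalidParameterError("Hurst exponent H must lie in (0, 1)")
            if self.params["K"] <= 0:
                raise InvalidParameterError("K must be > 0")
        if self.kind == "prw":
            if self.params["speed"] < 0:
                raise InvalidParameterError("speed must be >= 0")
            if self.params["persistence"] <= 0:
                raise InvalidParameterError("persistence must be > 0")
        if self.kind == "ballistic" and self.params["speed"] < 0:
            raise InvalidParameterError("speed must be >= 0")

    @classmethod
    def brownian(cls, D: float) -> "MotionModel":
        return cls("brownian", {"D": D})

    @classmethod
    def fbm(cls, H: float, K: float) -> "MotionModel":
        return cls("fbm", {"H": H, "K": K})

    @classmethod
    def prw(cls, speed: float, persistence: float) -> "MotionModel":
        return cls("prw", {"speed": speed, "persistence": persistence})

    @classmethod
    def ballistic(cls, speed: float) -> "MotionModel":
        return cls("ballistic", {"speed": speed})

    @classmethod
    def stationary(cls) -> "MotionModel":
        return cls("stationary", {})

    def to_dict(self) -> dict[str, Any]:
        return {"kind": self.kind, **self.params}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "MotionModel":
        d = dict(d)
        return cls(d.pop("kind"), {k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for a paired pre/post-drug synthetic cohort."""

    design: ImagingDesign = field(default_factory=ImagingDesign)
    dims: int = 3
    n_tracks: int = 100
    pre_model: MotionModel = field(default_factory=lambda: MotionModel.brownian(2.0))
    post_model: MotionModel = field(default_factory=lambda: MotionModel.brownian(2.0))
    mobilized_fraction: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tracks < 1:
            raise InvalidParameterError("n_tracks must be >= 1")
        if self.dims not in (2, 3):
            raise InvalidParameterError("dims must be 2 or 3")
        if not 0.0 <= self.mobilized_fraction <= 1.0:
            raise InvalidParameterError("mobilized_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")

    def to_dict(self) -> dict[str, Any]:
        return {
            "design": {"frame_interval": self.design.frame_interval,
                       "pre_duration": self.design.pre_duration,
                       "gap_duration": self.design.gap_duration,
                       "post_duration": self.design.post_duration},
            "dims": self.dims,
            "n_tracks": self.n_tracks,
            "pre_model": self.pre_model.to_dict(),
            "post_model": self.post_model.to_dict(),
            "mobilized_fraction": self.mobilized_fraction,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "CohortSpec":
        return cls(design=ImagingDesign(**d.get("design", {})),
                   dims=int(d.get("dims", 3)),
                   n_tracks=int(d["n_tracks"]),
                   pre_model=MotionModel.from_dict(d["pre_model"]),
                   post_model=MotionModel.from_dict(d["post_model"]),
                   mobilized_fraction=float(d.get("mobilized_fraction", 0.0)),
                   noise_sd=float(d.get("noise_sd", 0.0)),
                   seed=int(d.get("seed", 0)))


# ---------------------------------------------------------------------------
# closed forms

def fgn_autocovariance(n_steps: int, H: float, step_var: float) -> np.ndarray:
    """Autocovariance γ(0..n_steps−1) of fractional Gaussian noise.

    γ(k) = (step_var / 2)·(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}), where
    ``step_var`` is the variance of a single increment.
    """
    k = np.arange(n_steps, dtype=float)
    g = 0.5 * step_var * (np.abs(k + 1) ** (2 * H) - 2 * np.abs(k) ** (2 * H)
                          + np.abs(k - 1) ** (2 * H))
    return g


def furth_msd(lags: np.ndarray, dims: int, speed: float, persistence: float) -> np.ndarray:
    """Fürth relation: MSD(τ) = 2·d·s²·P·(τ − P·(1 − e^(−τ/P)))."""
    lags = np.asarray(lags, dtype=float)
    return 2.0 * dims * speed**2 * persistence * (
        lags - persistence * (1.0 - np.exp(-lags / persistence)))


# ---------------------------------------------------------------------------
# per-track increment samplers

def _brownian_steps(rng: np.random.Generator, n_steps: int, dims: int,
                    D: float, dt: float) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(2.0 * D * dt), size=(n_steps, dims))


def _fgn_davies_harte(rng: np.random.Generator, n_steps: int, dims: int,
                      gamma: np.ndarray) -> np.ndarray:
    """Exact fractional-Gaussian-noise sample via circulant embedding.

    Embeds the n×n Toeplitz covariance in a circulant of size m = 2^k ≥ 2n
    whose eigenvalues are the FFT of the first row; for fGn these are
    non-negative, making the construction exact. Falls back to a Cholesky
    factorization in the (never observed for fGn) event of a negative
    eigenvalue.
    """
    m = 1
    while m < 2 * n_steps:
        m *= 2
    row = np.zeros(m)
    row[:n_steps] = gamma
    row[m - n_steps + 1:] = gamma[1:][::-1]
    lam = np.fft.fft(row).real
    if lam.min() < -1e-9 * max(1.0, lam.max()):
        L = np.linalg.cholesky(_toeplitz(gamma) + 1e-12 * np.eye(n_steps))
        return (L @ rng.standard_normal((n_steps, dims)))
    lam = np.clip(lam, 0.0, None)
    out = np.empty((n_steps, dims))
    half = m // 2
    for ax in range(dims):
        z = rng.standard_normal(m)
        w = np.empty(m, dtype=complex)
        w[0] = math.sqrt(lam[0] / m) * z[0]
        w[half] = math.sqrt(lam[half] / m) * z[half]
        re = z[1:half]
        im = z[half + 1:]
        w[1:half] = np.sqrt(lam[1:half] / (2 * m)) * (re + 1j * im)
        w[half + 1:] = np.conj(w[1:half][::-1])
        out[:, ax] = np.fft.fft(w)[:n_steps].real
    return out


def _toeplitz(gamma: np.ndarray) -> np.ndarray:
    idx = np.abs(np.subtract.outer(np.arange(gamma.size), np.arange(gamma.size)))
    return gamma[idx]


def _prw_track(rng: np.random.Generator, n_steps: int, dims: int,
               speed: float, persistence: float, dt: float) -> np.ndarray:
    """Exact discrete sampling of an integrated Ornstein–Uhlenbeck velocity.

    Velocity per axis is stationary OU with variance s² and correlation time
    P; the (Δx, v') pair over one frame is jointly Gaussian and is sampled
    from its exact 2×2 covariance, so the Fürth relation holds at any step
    size with no integration bias.
    """
    phi = math.exp(-dt / persistence)
    var_v = speed**2 * (1.0 - phi**2)
    cov_xv = speed**2 * persistence * (1.0 - phi) ** 2
    var_x = speed**2 * persistence**2 * (2.0 * dt / persistence - 3.0 + 4.0 * phi - phi**2)
    a = math.sqrt(max(var_x, 0.0))
    b = cov_xv / a if a > 0 else 0.0
    c = math.sqrt(max(var_v - b * b, 0.0))
    v = rng.normal(0.0, speed, size=dims)  # stationary start
    steps = np.empty((n_steps, dims))
    for k in range(n_steps):
        z = rng.standard_normal((2, dims))
        dx = persistence * (1.0 - phi) * v + a * z[0]
        v = phi * v + b * z[0] + c * z[1]
        steps[k] = dx
    return steps


def _sample_steps(model: MotionModel, rng: np.random.Generator, n_steps: int,
                  dims: int, dt: float) -> np.ndarray:
    """Displacement increments of shape (n_steps, dims) for one track."""
    kind, p = model.kind, model.params
    if kind == "brownian":
        return _brownian_steps(rng, n_steps, dims, p["D"], dt)
    if kind == "fbm":
        gamma = fgn_autocovariance(n_steps, p["H"], p["K"] * dt ** (2 * p["H"]))
        return _fgn_davies_harte(rng, n_steps, dims, gamma)
    if kind == "prw":
        return _prw_track(rng, n_steps, dims, p["speed"], p["persistence"], dt)
    if kind == "ballistic":
        u = rng.standard_normal(dims)
        norm = np.linalg.norm(u)
        u = u / norm if norm > 0 else np.eye(dims)[0]
        return np.tile(p["speed"] * dt * u, (n_steps, 1))
    if kind == "stationary":
        return np.zeros((n_steps, dims))
    raise InvalidParameterError(f"unknown motion model {kind!r}")  # pragma: no cover


def _make_trackset(model: MotionModel, n_tracks: int, n_frames: int,
                   frame_interval: float, dims: int, seed: int) -> TrackSet:
    if n_frames < 2:
        raise InvalidParameterError("n_frames must be >= 2")
    if n_tracks < 1:
        raise InvalidParameterError("n_tracks must be >= 1")
    times = np.arange(n_frames) * frame_interval
    tracks = []
    for i in range(n_tracks):
        rng = _track_rng(seed, _STREAM_GENERIC, i)
        steps = _sample_steps(model, rng, n_frames - 1, dims, frame_interval)
        pos = np.vstack([np.zeros(dims), np.cumsum(steps, axis=0)])
        tracks.append(Track(f"sim{i:05d}", times.copy(), pos))
    return TrackSet(tracks, frame_interval, dims,
                    provenance=f"simulated {model.kind} (seed={seed})")


# ---------------------------------------------------------------------------
# public generators

def simulate_brownian(n_tracks: int, n_frames: int, frame_interval: float,
                      dims: int, D: float, seed: int) -> TrackSet:
    """Brownian tracks: i.i.d. Gaussian increments, variance 2·D·Δt per axis."""
    return _make_trackset(MotionModel.brownian(D), n_tracks, n_frames,
                          frame_interval, dims, seed)


def simulate_fbm(n_tracks: int, n_frames: int, frame_interval: float,
                 dims: int, H: float, K: float, seed: int) -> TrackSet:
    """Fractional Brownian motion per axis: E[X(t)²] = K·t^(2H).

    Increments are stationary fractional Gaussian noise with the exact
    Toeplitz covariance; ensemble MSD(τ) = d·K·τ^(2H), so the fitted
    anomalous exponent recovers α = 2H.
    """
    return _make_trackset(MotionModel.fbm(H, K), n_tracks, n_frames,
                          frame_interval, dims, seed)


def simulate_prw(n_tracks: int, n_frames: int, frame_interval: float,
                 dims: int, speed: float, persistence: float, seed: int) -> TrackSet:
    """Persistent random walk: stationary OU velocity, Fürth-relation MSD."""
    return _make_trackset(MotionModel.prw(speed, persistence), n_tracks, n_frames,
                          frame_interval, dims, seed)


def simulate_ballistic(n_tracks: int, n_frames: int, frame_interval: float,
                       dims: int, speed: float, seed: int) -> TrackSet:
    """Straight-line tracks at constant speed with a fixed random heading."""
    return _make_trackset(MotionModel.ballistic(speed), n_tracks, n_frames,
                          frame_interval, dims, seed)


def add_localization_noise(trackset: TrackSet, noise_sd: float, seed: int) -> TrackSet:
    """Add i.i.d. zero-mean Gaussian jitter (sd ``noise_sd`` µm) to every
    coordinate, modelling spot-centroid localization error. The input set is
    not modified. Pure noise on stationary tracks yields MSD(τ) = 2·d·σ²."""
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    if noise_sd == 0:
        return TrackSet([Track(t.track_id, t.times.copy(), t.positions.copy(), t.labels)
                         for t in trackset],
                        trackset.frame_interval, trackset.dims, trackset.provenance)
    tracks = []
    for i, tr in enumerate(trackset):
        rng = _track_rng(seed, _STREAM_NOISE, i)
        jitter = rng.normal(0.0, noise_sd, size=tr.positions.shape)
        tracks.append(Track(tr.track_id, tr.times.copy(), tr.positions + jitter, tr.labels))
    return TrackSet(tracks, trackset.frame_interval, trackset.dims,
                    trackset.provenance + f" + noise sd={noise_sd}")


def simulate_cohort(spec: CohortSpec) -> TrackSet:
    """Simulate a paired pre/post-drug cohort under the imaging design.

    Each cell gets a pre-epoch trajectory from ``pre_model`` over the
    pre-drug window. A seeded random subset of ⌊mobilized_fraction·n⌋ cells
    is *mobilized* — they leave the tissue at drug time and contribute no
    post-epoch points. Every other cell continues from its final pre-drug
    position under ``post_model``, with post-epoch times offset by the
    injection gap. Localization noise is applied last to all points.

    Pre and post observations of cell *i* are returned as separate tracks
    ``cell{i}-pre`` / ``cell{i}-post`` carrying the matching epoch label.
    """
    design = spec.design
    dt = design.frame_interval
    pre_times = np.arange(design.n_pre_frames) * dt
    post_start = design.pre_duration + design.gap_duration
    post_times = post_start + np.arange(design.n_post_frames) * dt

    n_mobilized = int(spec.mobilized_fraction * spec.n_tracks)
    rng_mob = _track_rng(spec.seed, _STREAM_MOBILIZE, 0)
    mobilized = set(rng_mob.permutation(spec.n_tracks)[:n_mobilized].tolist())

    tracks: list[Track] = []
    for i in range(spec.n_tracks):
        rng_pre = _track_rng(spec.seed, _STREAM_PRE, i)
        steps = _sample_steps(spec.pre_model, rng_pre, design.n_pre_frames - 1,
                              spec.dims, dt)
        pre_pos = np.vstack([np.zeros(spec.dims), np.cumsum(steps, axis=0)])
        tracks.append(Track(f"cell{i:04d}-pre", pre_times.copy(), pre_pos,
                            TrackLabels(epoch="pre")))
        if i in mobilized:
            continue
        rng_post = _track_rng(spec.seed, _STREAM_POST, i)
        steps = _sample_steps(spec.post_model, rng_post, design.n_post_frames - 1,
                              spec.dims, dt)
        post_pos = pre_pos[-1] + np.vstack([np.zeros(spec.dims),
                                            np.cumsum(steps, axis=0)])
        tracks.append(Track(f"cell{i:04d}-post", post_times.copy(), post_pos,
                            TrackLabels(epoch="post")))
    cohort = TrackSet(tracks, dt, spec.dims,
                      provenance=f"simulated cohort (seed={spec.seed})")
    if spec.noise_sd > 0:
        cohort = add_localization_noise(cohort, spec.noise_sd, spec.seed)
    return cohort
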