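"""Time-averaged mean-squared displacement and diffusivity classification.

For a single trajectory sampled on a frame grid, the time-averaged MSD at
lag τ = k·Δt is the average squared Euclidean displacement over *all*
point pairs (t, t + τ) present in the track (the maximal overlapping-pair
estimator); pairs spanning a gap are included whenever both endpoints were
observed. The ensemble curve pools pairs across tracks.

Anomalous diffusion is summarised by fitting MSD(τ) ≈ C·τ^α by ordinary
least squares in log–log coordinates. α = 1 is Brownian/diffusive motion,
α < 1 subdiffusive, α > 1 superdiffusive, α = 2 ballistic. The companion
MSD(τ)/τ representation makes the regime visible as the local slope α − 1:
flat for diffusive, rising for superdiffusive, falling for subdiffusive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    TimeGridError,
    TrackTooShortError,
)
from .io import Track, TrackSet

logger = logging.getLogger(__name__)

DEFAULT_MAX_LAG_FRACTION = 0.25
DEFAULT_MIN_PAIRS = 10          # ensemble-fit lag cutoff (variance control)
REGIME_THRESHOLDS = (0.9, 1.1)  # alpha below/above => sub/superdiffusive


@dataclass
class MSDCurve:
    """Lags (min), TA-MSD values (µm²) and pair counts, for one track or an ensemble."""

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray
    source: str = "ensemble"

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if not (self.lags.size == self.msd.size == self.n_pairs.size):
            raise InvalidParameterError("lags, msd and n_pairs must align")
        if np.any(self.lags <= 0) or np.any(np.diff(self.lags) <= 0):
            raise InvalidParameterError("lags must be strictly increasing and > 0")
        if np.any(self.msd < 0):
            raise InvalidParameterError("msd values must be >= 0")
        if np.any(self.n_pairs < 1):
            raise InvalidParameterError("each retained lag needs >= 1 pair")


@dataclass
class AlphaFit:
    """Log–log power-law fit of an MSD curve.

    ``alpha`` is the slope (anomalous exponent), ``log_coeff`` the natural-log
    intercept (so MSD ≈ exp(log_coeff)·τ^alpha), ``alpha_se`` the regression
    standard error of the slope.
    """

    alpha: float
    log_coeff: float
    alpha_se: float
    fit_lags: np.ndarray
    regime: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha):
            raise InvalidParameterError("alpha must be finite")


def classify_regime(alpha: float, alpha_se: float = 0.0,
                    thresholds: tuple[float, float] = REGIME_THRESHOLDS,
                    se_aware: bool = False) -> str:
    """Map a fitted exponent onto {subdiffusive, diffusive, superdiffusive}.

    With ``se_aware`` the call stays "diffusive" unless |α − 1| > 2·SE(α) in
    addition to crossing the threshold.
    """
    lo, hi = thresholds
    if se_aware and abs(alpha - 1.0) <= 2.0 * alpha_se:
        return "diffusive"
    if alpha < lo:
        return "subdiffusive"
    if alpha > hi:
        return "superdiffusive"
    return "diffusive"


# ---------------------------------------------------------------------------
# estimators

def _frame_indices(track: Track, frame_interval: float) -> np.ndarray:
    rel = track.times - track.times[0]
    idx = np.rint(rel / frame_interval).astype(np.int64)
    if not np.allclose(rel, idx * frame_interval, atol=frame_interval * 0.25):
        raise TimeGridError(
            f"track {track.track_id!r}: times do not align to a "
            f"{frame_interval}-min frame grid")
    return idx


def _tamsd_sums(track: Track, max_lag_fraction: float,
                frame_interval: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-lag (sum of squared displacements, pair count); index = lag in frames."""
    idx = _frame_indices(track, frame_interval)
    kmax = int(np.floor(max_lag_fraction * track.duration / frame_interval + 1e-9))
    n_slots = idx[-1] + 1
    pos = np.full((n_slots, track.dims), np.nan)
    pos[idx] = track.positions
    present = np.zeros(n_slots, dtype=bool)
    present[idx] = True
    sums = np.zeros(kmax + 1)
    counts = np.zeros(kmax + 1, dtype=np.int64)
    for k in range(1, min(kmax, n_slots - 1) + 1):
        valid = present[k:] & present[:-k]
        if not valid.any():
            continue
        d = pos[k:][valid] - pos[:-k][valid]
        sums[k] = np.einsum("ij,ij->", d, d)
        counts[k] = valid.sum()
    return sums, counts


def _infer_dt(track: Track) -> float:
    diffs = np.round(np.diff(track.times), 9)
    vals, counts = np.unique(diffs, return_counts=True)
    return float(vals[np.argmax(counts)])


def track_tamsd(track: Track, max_lag_fraction: float = DEFAULT_MAX_LAG_FRACTION,
                frame_interval: float | None = None) -> MSDCurve:
    """Time-averaged MSD of one track over lags up to ``max_lag_fraction`` of
    its duration. Lags with zero pairs are omitted. ``frame_interval``
    defaults to the track's modal time step."""
    if track.n_points < 3:
        raise TrackTooShortError(f"track {track.track_id!r}: need >= 3 points for TA-MSD")
    if not 0 < max_lag_fraction <= 1:
        raise InvalidParameterError("max_lag_fraction must lie in (0, 1]")
    dt = frame_interval if frame_interval is not None else _infer_dt(track)
    sums, counts = _tamsd_sums(track, max_lag_fraction, dt)
    keep = counts > 0
    keep[0] = False
    ks = np.nonzero(keep)[0]
    if ks.size == 0:
        raise InsufficientDataError(
            f"track {track.track_id!r}: no usable lags at max_lag_fraction={max_lag_fraction}")
    return MSDCurve(ks * dt, sums[ks] / counts[ks], counts[ks], source=track.track_id)


def ensemble_msd(trackset: TrackSet, max_lag_fraction: float = DEFAULT_MAX_LAG_FRACTION,
                 min_pairs: int = 1, weighting: str = "pairs") -> MSDCurve:
    """Ensemble TA-MSD over a TrackSet.

    ``weighting="pairs"`` (default) weights per-track values by their pair
    counts — identical to pooling every displacement pair from every track.
    ``weighting="track"`` averages per-track TA-MSD values unweighted, as a
    sensitivity check. Lags with fewer than ``min_pairs`` pooled pairs are
    dropped; tracks too short for TA-MSD are skipped with a log message.
    """
    if weighting not in ("pairs", "track"):
        raise InvalidParameterError("weighting must be 'pairs' or 'track'")
    dt = trackset.frame_interval
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    track_vals: dict[int, list[float]] = {}
    n_used = 0
    for tr in trackset:
        if tr.n_points < 3:
            logger.debug("ensemble_msd: skipping short track %s", tr.track_id)
            continue
        s, c = _tamsd_sums(tr, max_lag_fraction, dt)
        n_used += 1
        for k in np.nonzero(c)[0]:
            if k == 0:
                continue
            sums[k] = sums.get(k, 0.0) + s[k]
            counts[k] = counts.get(k, 0) + int(c[k])
            track_vals.setdefault(k, []).append(s[k] / c[k])
    if n_used == 0:
        raise InsufficientDataError("no track long enough for an ensemble TA-MSD")
    ks = sorted(k for k in counts if counts[k] >= min_pairs)
    if not ks:
        raise InsufficientDataError(f"no lag reaches min_pairs={min_pairs}")
    if weighting == "pairs":
        msd = np.array([sums[k] / counts[k] for k in ks])
    else:
        msd = np.array([float(np.mean(track_vals[k])) for k in ks])
    return MSDCurve(np.array(ks, dtype=float) * dt, msd,
                    np.array([counts[k] for k in ks]), source="ensemble")


def msd_over_lag(curve: MSDCurve) -> MSDCurve:
    """The MSD(τ)/τ transform (µm² min⁻¹). On log–log axes its slope is
    α − 1: flat ⇔ diffusive, rising ⇔ superdiffusive, falling ⇔ subdiffusive."""
    if np.any(curve.lags <= 0):
        raise InvalidParameterError("msd_over_lag requires strictly positive lags")
    return MSDCurve(curve.lags.copy(), curve.msd / curve.lags,
                    curve.n_pairs.copy(), source=curve.source)


# ---------------------------------------------------------------------------
# fitting

def fit_anomalous_exponent(curve: MSDCurve,
                           fit_lags: tuple[float, float] | None = None,
                           thresholds: tuple[float, float] = REGIME_THRESHOLDS,
                           se_aware: bool = False) -> AlphaFit:
    """OLS fit of log MSD on log τ; the slope is the anomalous exponent α.

    ``fit_lags`` restricts the fit to a (lo, hi) lag interval in minutes
    (inclusive); default is all retained lags. Zero-MSD lags (stationary
    stretches) are excluded with a warning rather than clamped. Natural logs
    are used internally.
    """
    mask = np.ones(curve.lags.size, dtype=bool)
    if fit_lags is not None:
        lo, hi = fit_lags
        mask &= (curve.lags >= lo) & (curve.lags <= hi)
    zero = curve.msd <= 0
    if np.any(zero & mask):
        warnings.warn("fit_anomalous_exponent: dropping zero-MSD lags from the fit",
                      stacklevel=2)
        mask &= ~zero
    if mask.sum() < 3:
        raise InsufficientDataError(
            f"need >= 3 positive-MSD lags in the fit range, have {int(mask.sum())}")
    res = stats.linregress(np.log(curve.lags[mask]), np.log(curve.msd[mask]))
    alpha = float(res.slope)
    return AlphaFit(alpha=alpha, log_coeff=float(res.intercept),
                    alpha_se=float(res.stderr), fit_lags=curve.lags[mask].copy(),
                    regime=classify_regime(alpha, float(res.stderr), thresholds, se_aware))


@dataclass
class MSDReport:
    """Paired pre/post ensemble MSD analysis with a regime-shift statement."""

    pre_curve: MSDCurve
    post_curve: MSDCurve
    pre_over_lag: MSDCurve
    post_over_lag: MSDCurve
    pre_fit: AlphaFit
    post_fit: AlphaFit
    shift: str = field(init=False)
    regime_changed: bool = field(init=False)

    def __post_init__(self) -> None:
        self.shift = f"{self.pre_fit.regime} -> {self.post_fit.regime}"
        self.regime_changed = self.pre_fit.regime != self.post_fit.regime


def cohort_msd_report(pre: TrackSet, post: TrackSet,
                      max_lag_fraction: float = DEFAULT_MAX_LAG_FRACTION,
                      min_pairs: int = DEFAULT_MIN_PAIRS,
                      weighting: str = "pairs",
                      fit_lags: tuple[float, float] | None = None,
                      thresholds: tuple[float, float] = REGIME_THRESHOLDS,
                      se_aware: bool = False) -> MSDReport:
    """Ensemble MSD, MSD/τ transform and exponent fit for each epoch, plus
    the pre → post regime-shift statement."""
    if not pre.tracks or not post.tracks:
        raise InsufficientDataError("both epochs must contain tracks")
    curves = {}
    fits = {}
    for name, ts in (("pre", pre), ("post", post)):
        curve = ensemble_msd(ts, max_lag_fraction, min_pairs, weighting)
        curves[name] = curve
        fits[name] = fit_anomalous_exponent(curve, fit_lags, thresholds, se_aware)
    report = MSDReport(pre_curve=curves["pre"], post_curve=curves["post"],
                       pre_over_lag=msd_over_lag(curves["pre"]),
                       post_over_lag=msd_over_lag(curves["post"]),
                       pre_fit=fits["pre"], post_fit=fits["post"])
    logger.info("cohort_msd_report: alpha %.3f -> %.3f (%s)",
                report.pre_fit.alpha, report.post_fit.alpha, report.shift)
    return report
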