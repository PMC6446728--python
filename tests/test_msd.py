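"""TA-MSD estimation, the MSD/τ transform and exponent fitting."""

from __future__ import annotations

import numpy as np
import pytest

import leukotrack as lt
from leukotrack.errors import (
    InsufficientDataError,
    InvalidParameterError,
    TrackTooShortError,
)
from leukotrack.msd import classify_regime

from conftest import brute_force_tamsd, random_gapped_track


def make_1d(xs, ts=None):
    xs = np.asarray(xs, dtype=float)
    t = np.asarray(ts, dtype=float) if ts is not None else np.arange(len(xs))
    pos = np.zeros((len(xs), 2))
    pos[:, 0] = xs
    return lt.Track("t", t, pos)


def power_law_curve(alpha, coeff=1.0, lags=None):
    lags = np.asarray(lags if lags is not None else np.arange(1, 11) * 3.0)
    return lt.MSDCurve(lags, coeff * lags**alpha, np.full(lags.size, 100))


class TestTrackTamsd:
    def test_uniform_unit_steps_ballistic(self):
        tr = make_1d([0, 1, 2, 3])
        curve = lt.track_tamsd(tr, max_lag_fraction=1.0)
        np.testing.assert_allclose(curve.lags, [1, 2, 3])
        np.testing.assert_allclose(curve.msd, [1, 4, 9])
        np.testing.assert_array_equal(curve.n_pairs, [3, 2, 1])

    def test_stationary_zero_everywhere(self, stationary_track):
        curve = lt.track_tamsd(stationary_track, max_lag_fraction=1.0)
        np.testing.assert_array_equal(curve.msd, 0.0)

    def test_matches_brute_force_on_random_track(self, rng):
        tr = random_gapped_track(rng, min_points=20, max_points=20)
        curve = lt.track_tamsd(tr, max_lag_fraction=1.0, frame_interval=3.0)
        oracle = brute_force_tamsd(tr, 1.0, 3.0)
        assert list(curve.lags) == list(oracle)
        for lag, msd, n in zip(curve.lags, curve.msd, curve.n_pairs):
            assert n == oracle[lag][1]
            assert msd == pytest.approx(oracle[lag][0], rel=1e-12)

    def test_gap_pairs_use_existing_endpoints(self):
        # frames 0,1,2,6: no pair spans lag 3; lag 4 uses the (2,6) pair
        tr = make_1d([0, 1, 2, 10], ts=[0, 1, 2, 6])
        curve = lt.track_tamsd(tr, max_lag_fraction=1.0, frame_interval=1.0)
        assert 3.0 not in curve.lags
        at4 = curve.msd[list(curve.lags).index(4.0)]
        assert at4 == pytest.approx((10 - 2) ** 2)

    def test_too_short_track(self):
        with pytest.raises(TrackTooShortError):
            lt.track_tamsd(make_1d([0, 1]))

    def test_max_lag_fraction_limits_lags(self, straight_track):
        curve = lt.track_tamsd(straight_track, max_lag_fraction=0.25)
        assert curve.lags.max() <= 0.25 * straight_track.duration

    def test_rigid_motion_invariance(self, rng):
        tr = random_gapped_track(rng, dims=2, gapped=False)
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = lt.Track("m", tr.times, tr.positions @ rot.T + 7.0)
        a = lt.track_tamsd(tr, 1.0, 3.0)
        b = lt.track_tamsd(moved, 1.0, 3.0)
        np.testing.assert_allclose(a.msd, b.msd, rtol=1e-9)


class TestEnsembleMsd:
    def test_singleton_equals_track_tamsd(self, rng):
        tr = random_gapped_track(rng, gapped=False)
        ts = lt.TrackSet([tr], 3.0, 3)
        ens = lt.ensemble_msd(ts, max_lag_fraction=1.0)
        single = lt.track_tamsd(tr, max_lag_fraction=1.0, frame_interval=3.0)
        np.testing.assert_allclose(ens.msd, single.msd)
        np.testing.assert_array_equal(ens.n_pairs, single.n_pairs)

    def test_duplicated_track_leaves_curve_unchanged(self, rng):
        tr = random_gapped_track(rng, gapped=False)
        one = lt.ensemble_msd(lt.TrackSet([tr], 3.0, 3), 1.0)
        two = lt.ensemble_msd(lt.TrackSet([tr, tr], 3.0, 3), 1.0)
        np.testing.assert_allclose(one.msd, two.msd)
        np.testing.assert_array_equal(two.n_pairs, 2 * one.n_pairs)

    def test_heterogeneous_lengths_match_pooled_brute_force(self, rng):
        tracks = [random_gapped_track(rng, f"h{i}") for i in range(6)]
        ts = lt.TrackSet(tracks, 3.0, 3)
        ens = lt.ensemble_msd(ts, max_lag_fraction=1.0)
        pooled_sum: dict[float, float] = {}
        pooled_n: dict[float, int] = {}
        for tr in tracks:
            if tr.n_points < 3:
                continue
            for lag, (msd, n) in brute_force_tamsd(tr, 1.0, 3.0).items():
                pooled_sum[lag] = pooled_sum.get(lag, 0.0) + msd * n
                pooled_n[lag] = pooled_n.get(lag, 0) + n
        for lag, msd, n in zip(ens.lags, ens.msd, ens.n_pairs):
            assert n == pooled_n[lag]
            assert msd == pytest.approx(pooled_sum[lag] / pooled_n[lag], rel=1e-12)

    def test_min_pairs_drops_sparse_lags(self, rng):
        tr = random_gapped_track(rng, min_points=10, max_points=10, gapped=False)
        ts = lt.TrackSet([tr], 3.0, 3)
        ens = lt.ensemble_msd(ts, max_lag_fraction=1.0, min_pairs=5)
        assert ens.n_pairs.min() >= 5

    def test_track_weighting_differs_but_close_for_homogeneous(self):
        ts = lt.simulate_brownian(50, 20, 3.0, 2, 1.0, seed=21)
        pairs = lt.ensemble_msd(ts, 0.25, weighting="pairs")
        track = lt.ensemble_msd(ts, 0.25, weighting="track")
        np.testing.assert_allclose(pairs.msd, track.msd)  # equal-length tracks

    def test_no_usable_track_is_error(self):
        short = lt.Track("s", np.array([0.0, 3.0]), np.zeros((2, 2)))
        with pytest.raises(InsufficientDataError):
            lt.ensemble_msd(lt.TrackSet([short], 3.0, 2), 0.25)


class TestMsdOverLag:
    @pytest.mark.parametrize("alpha,expected_slope", [(2.0, 1.0), (1.0, 0.0),
                                                      (0.5, -0.5)])
    def test_power_law_slope_is_alpha_minus_one(self, alpha, expected_slope):
        from scipy.stats import linregress

        curve = power_law_curve(alpha, coeff=2.5)
        over = lt.msd_over_lag(curve)
        res = linregress(np.log(over.lags), np.log(over.msd))
        assert res.slope == pytest.approx(expected_slope, abs=1e-9)

    def test_units_divide_by_lag(self):
        curve = power_law_curve(1.0, coeff=4.0)
        over = lt.msd_over_lag(curve)
        np.testing.assert_allclose(over.msd, 4.0)


class TestFitAnomalousExponent:
    def test_exact_ballistic(self):
        fit = lt.fit_anomalous_exponent(power_law_curve(2.0, coeff=3.0))
        assert fit.alpha == pytest.approx(2.0, abs=1e-9)
        assert fit.log_coeff == pytest.approx(np.log(3.0), abs=1e-9)
        assert fit.regime == "superdiffusive"

    def test_exact_brownian(self):
        fit = lt.fit_anomalous_exponent(power_law_curve(1.0, coeff=12.0))
        assert fit.alpha == pytest.approx(1.0, abs=1e-9)
        assert fit.regime == "diffusive"

    def test_monte_carlo_brownian_recovery(self):
        ts = lt.simulate_brownian(200, 31, 3.0, 3, 1.0, seed=23)
        fit = lt.fit_anomalous_exponent(lt.ensemble_msd(ts))
        assert 0.9 <= fit.alpha <= 1.1

    def test_fit_range_restricts_lags(self):
        curve = power_law_curve(1.0, lags=np.arange(1, 21) * 3.0)
        fit = lt.fit_anomalous_exponent(curve, fit_lags=(6.0, 30.0))
        assert fit.fit_lags.min() == 6.0 and fit.fit_lags.max() == 30.0

    def test_zero_msd_lags_dropped_with_warning(self):
        curve = lt.MSDCurve(np.array([1.0, 2, 3, 4]), np.array([0.0, 2, 3, 4]),
                            np.array([5, 5, 5, 5]))
        with pytest.warns(UserWarning):
            fit = lt.fit_anomalous_exponent(curve)
        assert 1.0 not in fit.fit_lags

    def test_too_few_lags_is_error(self):
        curve = lt.MSDCurve(np.array([1.0, 2.0]), np.array([1.0, 2.0]),
                            np.array([5, 5]))
        with pytest.raises(InsufficientDataError):
            lt.fit_anomalous_exponent(curve)

    def test_regime_thresholds(self):
        assert classify_regime(0.7) == "subdiffusive"
        assert classify_regime(1.0) == "diffusive"
        assert classify_regime(1.3) == "superdiffusive"
        # se-aware mode keeps noisy fits diffusive
        assert classify_regime(1.3, alpha_se=0.2, se_aware=True) == "diffusive"
        assert classify_regime(1.3, alpha_se=0.05, se_aware=True) == "superdiffusive"


class TestNoiseAdditivity:
    def test_noise_raises_msd_by_2d_sigma_squared(self):
        sigma, d = 2.0, 3
        ts = lt.simulate_brownian(500, 31, 3.0, d, 1.0, seed=25)
        noisy = lt.add_localization_noise(ts, sigma, seed=26)
        clean = lt.ensemble_msd(ts, 0.25)
        with_noise = lt.ensemble_msd(noisy, 0.25)
        offset = with_noise.msd - clean.msd
        np.testing.assert_allclose(offset, 2 * d * sigma**2, rtol=0.10)


class TestCohortReport:
    def test_identical_generators_same_regime(self):
        pre = lt.simulate_brownian(150, 31, 3.0, 3, 1.0, seed=27)
        post = lt.simulate_brownian(150, 31, 3.0, 3, 1.0, seed=28)
        rep = lt.cohort_msd_report(pre, post)
        assert not rep.regime_changed
        assert rep.shift == "diffusive -> diffusive"

    def test_brownian_to_ballistic_is_diffusive_to_superdiffusive(self):
        pre = lt.simulate_brownian(150, 31, 3.0, 3, 1.0, seed=29)
        post = lt.simulate_ballistic(150, 31, 3.0, 3, 1.0, seed=30)
        rep = lt.cohort_msd_report(pre, post)
        assert rep.pre_fit.regime == "diffusive"
        assert rep.post_fit.regime == "superdiffusive"
        assert rep.regime_changed

    def test_subdiffusive_to_diffusive_via_fbm(self):
        pre = lt.simulate_fbm(300, 31, 3.0, 3, H=0.35, K=1.0, seed=31)
        post = lt.simulate_brownian(300, 31, 3.0, 3, 1.0, seed=32)
        rep = lt.cohort_msd_report(pre, post)
        assert rep.pre_fit.regime == "subdiffusive"   # alpha = 2H = 0.7
        assert rep.post_fit.regime == "diffusive"

    def test_empty_epoch_is_error(self):
        pre = lt.simulate_brownian(5, 10, 3.0, 3, 1.0, seed=33)
        with pytest.raises(InsufficientDataError):
            lt.cohort_msd_report(pre, lt.TrackSet([], 3.0, 3))
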