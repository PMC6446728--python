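"""Synthetic-trajectory generators versus their closed-form expectations."""

from __future__ import annotations

import numpy as np
import pytest

import leukotrack as lt
from leukotrack.errors import InvalidParameterError
from leukotrack.simulate import CohortSpec, ImagingDesign, MotionModel

from conftest import assert_tracksets_equal


class TestBrownian:
    def test_zero_diffusivity_is_stationary(self):
        ts = lt.simulate_brownian(5, 10, 3.0, 2, D=0.0, seed=1)
        for tr in ts:
            np.testing.assert_array_equal(tr.positions, np.zeros((10, 2)))

    def test_same_seed_bit_identical(self):
        a = lt.simulate_brownian(10, 20, 3.0, 3, 1.0, seed=42)
        b = lt.simulate_brownian(10, 20, 3.0, 3, 1.0, seed=42)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.positions, tb.positions)

    def test_ensemble_msd_matches_2dD_tau(self):
        ts = lt.simulate_brownian(1000, 31, 3.0, 2, 1.0, seed=7)
        curve = lt.ensemble_msd(ts, max_lag_fraction=1 / 3)
        expected = 2 * 2 * 1.0 * curve.lags
        np.testing.assert_allclose(curve.msd, expected, rtol=0.05)

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            lt.simulate_brownian(5, 10, 3.0, 2, D=-1.0, seed=0)
        with pytest.raises(InvalidParameterError):
            lt.simulate_brownian(5, 1, 3.0, 2, D=1.0, seed=0)

    def test_track_substreams_independent_of_cohort_size(self):
        """Track i's trajectory does not depend on how many tracks are drawn."""
        few = lt.simulate_brownian(3, 15, 3.0, 3, 1.0, seed=9)
        many = lt.simulate_brownian(8, 15, 3.0, 3, 1.0, seed=9)
        for ta, tb in zip(few, many):
            np.testing.assert_array_equal(ta.positions, tb.positions)


class TestFbm:
    def test_h_half_reduces_to_uncorrelated_increments(self):
        ts = lt.simulate_fbm(1, 10001, 1.0, 2, H=0.5, K=1.0, seed=3)
        inc = np.diff(ts.tracks[0].positions[:, 0])
        n = inc.size
        for lag in (1, 2, 3):
            rho = np.corrcoef(inc[:-lag], inc[lag:])[0, 1]
            assert abs(rho) < 4 / np.sqrt(n)

    def test_increment_covariance_matches_closed_form(self):
        """Sample covariance over many realizations equals the fractional
        Gaussian-noise Toeplitz covariance, entrywise within 5% of the
        increment variance, for a 10-step track."""
        H, K, dt = 0.8, 1.0, 1.0
        ts = lt.simulate_fbm(20000, 11, dt, 2, H, K, seed=11)
        inc = np.array([np.diff(tr.positions[:, 0]) for tr in ts])
        sample = np.cov(inc.T, bias=False)
        gamma = lt.fgn_autocovariance(10, H, K * dt ** (2 * H))
        exact = gamma[np.abs(np.subtract.outer(np.arange(10), np.arange(10)))]
        assert np.abs(sample - exact).max() <= 0.05 * gamma[0]

    def test_subdiffusive_exponent_recovery(self):
        ts = lt.simulate_fbm(500, 31, 3.0, 3, H=0.25, K=1.0, seed=5)
        fit = lt.fit_anomalous_exponent(lt.ensemble_msd(ts))
        assert 0.4 <= fit.alpha <= 0.6

    def test_hurst_out_of_range(self):
        for H in (0.0, 1.0, -0.2, 1.3):
            with pytest.raises(InvalidParameterError):
                lt.simulate_fbm(2, 5, 3.0, 2, H=H, K=1.0, seed=0)


class TestPrw:
    def test_furth_relation_limits(self):
        """The closed form is ballistic (slope 2) well below the persistence
        time and diffusive (slope 1) well above it."""
        s, P, d = 2.0, 9.0, 3
        tau = np.array([1e-4, 2e-4])
        short = np.diff(np.log(lt.furth_msd(tau, d, s, P))) / np.diff(np.log(tau))
        tau = np.array([1e5, 2e5])
        long = np.diff(np.log(lt.furth_msd(tau, d, s, P))) / np.diff(np.log(tau))
        assert short[0] == pytest.approx(2.0, abs=1e-3)
        assert long[0] == pytest.approx(1.0, abs=1e-3)
        # short-lag Taylor value: MSD ~ d s^2 tau^2
        tau = 1e-4
        assert lt.furth_msd(np.array([tau]), d, s, P)[0] == pytest.approx(
            d * s**2 * tau**2, rel=1e-4)

    def test_ensemble_msd_matches_furth(self):
        ts = lt.simulate_prw(1000, 61, 3.0, 2, speed=2.0, persistence=9.0, seed=13)
        curve = lt.ensemble_msd(ts, max_lag_fraction=30.0 / 180.0)
        expected = lt.furth_msd(curve.lags, 2, 2.0, 9.0)
        np.testing.assert_allclose(curve.msd, expected, rtol=0.05)

    def test_non_positive_persistence_rejected(self):
        with pytest.raises(InvalidParameterError):
            lt.simulate_prw(2, 5, 3.0, 2, speed=1.0, persistence=0.0, seed=0)


class TestBallistic:
    def test_straight_lines_at_constant_speed(self):
        ts = lt.simulate_ballistic(20, 11, 3.0, 3, speed=1.5, seed=2)
        for tr in ts:
            steps = np.diff(tr.positions, axis=0)
            np.testing.assert_allclose(np.linalg.norm(steps, axis=1), 4.5, rtol=1e-12)
            # all steps parallel
            np.testing.assert_allclose(steps, np.broadcast_to(steps[0], steps.shape),
                                       rtol=1e-9)


class TestLocalizationNoise:
    def test_zero_noise_is_identity(self, small_trackset):
        out = lt.add_localization_noise(small_trackset, 0.0, seed=1)
        assert_tracksets_equal(out, small_trackset)
        assert out is not small_trackset

    def test_input_unmodified_and_reproducible(self, small_trackset):
        before = [tr.positions.copy() for tr in small_trackset]
        a = lt.add_localization_noise(small_trackset, 0.5, seed=4)
        b = lt.add_localization_noise(small_trackset, 0.5, seed=4)
        for tr, orig in zip(small_trackset, before):
            np.testing.assert_array_equal(tr.positions, orig)
        assert_tracksets_equal(a, b)

    def test_pure_noise_msd_is_2d_sigma_squared(self):
        tracks = [lt.Track(f"s{i}", np.arange(31) * 3.0, np.zeros((31, 3)))
                  for i in range(300)]
        still = lt.TrackSet(tracks, 3.0, 3)
        noisy = lt.add_localization_noise(still, 1.0, seed=6)
        curve = lt.ensemble_msd(noisy, max_lag_fraction=0.25)
        np.testing.assert_allclose(curve.msd, 2 * 3 * 1.0**2, rtol=0.05)

    def test_negative_sd_rejected(self, small_trackset):
        with pytest.raises(InvalidParameterError):
            lt.add_localization_noise(small_trackset, -0.1, seed=0)


class TestCohort:
    def test_default_design_spans_study_schedule(self):
        """Pre epoch: 3-min frames over 90 min; post epoch: 180 min starting
        15 min after drug injection."""
        spec = CohortSpec(n_tracks=3, seed=1)
        pre, post = lt.split_epochs(lt.simulate_cohort(spec))
        for tr in pre:
            np.testing.assert_allclose(tr.times, np.arange(31) * 3.0)
        for tr in post:
            np.testing.assert_allclose(tr.times, 105.0 + np.arange(61) * 3.0)

    def test_fully_mobilized_cohort_has_no_post_points(self):
        spec = CohortSpec(n_tracks=10, mobilized_fraction=1.0, seed=2)
        pre, post = lt.split_epochs(lt.simulate_cohort(spec))
        assert len(pre) == 10 and len(post) == 0

    def test_mobilized_count_is_floor_of_fraction(self):
        spec = CohortSpec(n_tracks=10, mobilized_fraction=0.35, seed=3)
        pre, post = lt.split_epochs(lt.simulate_cohort(spec))
        assert len(pre) == 10 and len(post) == 7

    def test_post_continues_from_pre_position(self):
        spec = CohortSpec(n_tracks=4, seed=4)
        cohort = lt.simulate_cohort(spec)
        by_id = {tr.track_id: tr for tr in cohort}
        for i in range(4):
            np.testing.assert_array_equal(
                by_id[f"cell{i:04d}-post"].positions[0],
                by_id[f"cell{i:04d}-pre"].positions[-1])

    def test_same_generator_both_epochs_agrees(self):
        """With pre_model == post_model and no noise, pooled pre and post MSD
        curves agree within Monte-Carlo error on shared lags."""
        spec = CohortSpec(n_tracks=300, pre_model=MotionModel.brownian(1.0),
                          post_model=MotionModel.brownian(1.0), seed=5)
        pre, post = lt.split_epochs(lt.simulate_cohort(spec))
        cp = lt.ensemble_msd(pre, 0.25)
        cq = lt.ensemble_msd(post, 0.25)
        shared = np.intersect1d(cp.lags, cq.lags)
        mp = cp.msd[np.isin(cp.lags, shared)]
        mq = cq.msd[np.isin(cq.lags, shared)]
        np.testing.assert_allclose(mp, mq, rtol=0.10)

    def test_deterministic_for_identical_spec(self):
        spec = CohortSpec(n_tracks=8, mobilized_fraction=0.25, noise_sd=0.3, seed=6)
        assert_tracksets_equal(lt.simulate_cohort(spec), lt.simulate_cohort(spec))

    def test_spec_round_trips_through_dict(self):
        spec = CohortSpec(design=ImagingDesign(3.0, 90.0, 15.0, 180.0), dims=2,
                          n_tracks=5, pre_model=MotionModel.fbm(0.3, 2.0),
                          post_model=MotionModel.prw(2.0, 9.0),
                          mobilized_fraction=0.2, noise_sd=0.1, seed=7)
        assert CohortSpec.from_dict(spec.to_dict()) == spec

    def test_invalid_spec_fields_are_named_errors(self):
        with pytest.raises(InvalidParameterError):
            CohortSpec(n_tracks=0)
        with pytest.raises(InvalidParameterError):
            CohortSpec(n_tracks=5, mobilized_fraction=1.5)
        with pytest.raises(InvalidParameterError):
            ImagingDesign(frame_interval=7.0)  # does not divide 90


def test_motion_model_validation():
    with pytest.raises(InvalidParameterError):
        MotionModel("warp", {})
    with pytest.raises(InvalidParameterError):
        MotionModel("brownian", {"D": 1.0, "extra": 2.0})
    assert MotionModel.from_dict({"kind": "prw", "speed": 2, "persistence": 9}) == \
        MotionModel.prw(2.0, 9.0)
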