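"""Band-limited analytic signals, lagged copula MI, surrogates, contrast."""

import numpy as np
import pytest

from speechtrack import CANONICAL_BANDS
from speechtrack.speech_features import BandSpec
from speechtrack.tracking import (
    AnalyticTrialSet,
    MIMap,
    TrialSet,
    bandpass_analytic,
    condition_contrast,
    lag_grid,
    subsample_size,
    surrogate_shuffle,
    surrogate_timereverse,
    tracking_mi,
    tracking_mi_map,
)

RATE = 150.0


class TestBandpassAnalytic:
    def test_in_band_sinusoid_has_constant_magnitude_and_advancing_phase(self):
        band = BandSpec("syllable", 2.8, 4.8)
        f0 = 3.8
        t = np.arange(int(20 * RATE)) / RATE
        z = bandpass_analytic(np.sin(2 * np.pi * f0 * t), band, RATE)
        core = z[300:-300]  # ignore filter edges
        assert np.ptp(np.abs(core)) < 0.1 * np.abs(core).mean()
        inst_freq = np.diff(np.unwrap(np.angle(core))) * RATE / (2 * np.pi)
        assert np.median(inst_freq) == pytest.approx(f0, rel=0.02)

    def test_out_of_band_tone_attenuated_by_20db(self):
        band = BandSpec("phrase", 0.6, 1.3)
        t = np.arange(int(40 * RATE)) / RATE
        in_band = bandpass_analytic(np.sin(2 * np.pi * 1.0 * t), band, RATE)
        out_band = bandpass_analytic(np.sin(2 * np.pi * 8.0 * t), band, RATE)
        ratio = np.abs(out_band[600:-600]).mean() / np.abs(in_band[600:-600]).mean()
        assert 20 * np.log10(ratio) < -20

    def test_zero_input_gives_zero_output(self):
        z = bandpass_analytic(np.zeros(2000), BandSpec("word", 1.8, 3.0), RATE)
        np.testing.assert_allclose(np.abs(z), 0.0, atol=1e-12)

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError, match="short"):
            bandpass_analytic(np.zeros(30), BandSpec("phrase", 0.6, 1.3), RATE)


class TestLagGrid:
    def test_canonical_grid_has_five_lags(self):
        assert lag_grid(60, 140, 20) == [60, 80, 100, 120, 140]

    def test_degenerate_single_lag(self):
        assert lag_grid(100, 100, 20) == [100]

    def test_non_dividing_step_raises(self):
        with pytest.raises(ValueError, match="divide"):
            lag_grid(60, 140, 30)


class TestTrackingMI:
    def test_delayed_copy_maximises_mi_at_true_lag(self, phoneme_trials):
        # generator injects the envelope at 100 ms in the effect point
        curve = {lag: tracking_mi(phoneme_trials, 1, [lag]).bits for lag in lag_grid()}
        assert max(curve, key=curve.get) == 100

    def test_zero_lag_copy_scores_below_matched_lag(self, phoneme_trials):
        zero_lag = tracking_mi(phoneme_trials, 1, [60]).bits
        matched = tracking_mi(phoneme_trials, 1, [100]).bits
        assert matched > zero_lag

    def test_independent_noise_point_has_near_zero_mi(self, phrase_trials):
        # grid point 0 carries no injected signal
        sur = surrogate_shuffle(phrase_trials, 0, n_iter=20, seed=2)
        true = tracking_mi(phrase_trials, 0).bits
        assert abs(true - sur.bits) < 0.1

    def test_lag_sum_equals_sum_of_single_lags(self, phrase_trials):
        lags = lag_grid()
        total = tracking_mi(phrase_trials, 1, lags).bits
        parts = sum(tracking_mi(phrase_trials, 1, [lag]).bits for lag in lags)
        assert total == pytest.approx(parts, abs=1e-10)

    def test_map_matches_scalar_path(self, phrase_trials):
        vals = tracking_mi_map(phrase_trials)
        for point in (0, 1, 5):
            assert vals[point] == pytest.approx(
                tracking_mi(phrase_trials, point).bits, abs=1e-6
            )

    def test_invariant_to_common_neural_rescaling(self, phrase_trials):
        scaled = AnalyticTrialSet(
            speech=phrase_trials.speech,
            neural=[37.0 * m for m in phrase_trials.neural],
            labels=phrase_trials.labels,
            grid=phrase_trials.grid,
            band=phrase_trials.band,
            rate=phrase_trials.rate,
        )
        assert tracking_mi(scaled, 1).bits == pytest.approx(
            tracking_mi(phrase_trials, 1).bits, abs=1e-9
        )

    def test_lag_longer_than_trial_raises(self, phrase_trials):
        with pytest.raises(ValueError, match="lag"):
            tracking_mi(phrase_trials, 1, [1e5])


class TestSurrogates:
    def test_shuffle_surrogate_destroys_strong_tracking(self, phrase_trials):
        true = tracking_mi(phrase_trials, 1).bits
        sur = surrogate_shuffle(phrase_trials, 1, n_iter=10, seed=3).bits
        assert sur < true

    def test_shuffle_is_deterministic_under_fixed_seed(self, phrase_trials):
        a = surrogate_shuffle(phrase_trials, 1, n_iter=5, seed=42).bits
        b = surrogate_shuffle(phrase_trials, 1, n_iter=5, seed=42).bits
        assert a == b

    def test_identical_envelopes_make_shuffling_ineffective(self, phrase_trials):
        # when every trial has the same stimulus, permuting trials cannot
        # destroy the dependence: this motivates averaging many shuffles
        same = AnalyticTrialSet(
            speech=[phrase_trials.speech[0][:450] for _ in phrase_trials.speech],
            neural=[m[:, :450] for m in phrase_trials.neural],
            labels=phrase_trials.labels,
            grid=phrase_trials.grid,
            band=phrase_trials.band,
            rate=phrase_trials.rate,
        )
        true = tracking_mi(same, 1).bits
        sur = surrogate_shuffle(same, 1, n_iter=5, seed=1).bits
        assert sur == pytest.approx(true, abs=1e-9)

    def test_timereverse_reduces_mi_for_asymmetric_tracking(self, phrase_trials):
        true = tracking_mi(phrase_trials, 1).bits
        sur = surrogate_timereverse(phrase_trials, 1).bits
        assert sur < true

    def test_too_few_trials_for_shuffle_raises(self, phrase_trials):
        with pytest.raises(ValueError, match="trials"):
            surrogate_shuffle(phrase_trials, 1, trial_idx=np.array([0, 1]))


class TestConditionContrast:
    def test_subsample_size_is_80pct_of_smaller_condition(self):
        assert subsample_size(70, 30) == 24
        assert subsample_size(50, 50) == 40

    def test_contrast_is_reproducible_under_fixed_seed(self, phrase_trials):
        a_c, a_i = condition_contrast(phrase_trials, n_repeats=2, seed=7)
        b_c, b_i = condition_contrast(phrase_trials, n_repeats=2, seed=7)
        np.testing.assert_array_equal(a_c.mi_bits, b_c.mi_bits)
        np.testing.assert_array_equal(a_i.mi_bits, b_i.mi_bits)
        assert a_c.n_trials_used == subsample_size(
            int(np.sum(phrase_trials.labels == "correct")),
            int(np.sum(phrase_trials.labels == "incorrect")),
        )

    def test_missing_condition_raises(self, phrase_trials):
        one_label = AnalyticTrialSet(
            speech=phrase_trials.speech,
            neural=phrase_trials.neural,
            labels=np.array(["correct"] * phrase_trials.n_trials),
            grid=phrase_trials.grid,
            band=phrase_trials.band,
            rate=phrase_trials.rate,
        )
        with pytest.raises(ValueError, match="condition"):
            condition_contrast(one_label)


class TestContainers:
    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            TrialSet(
                speech=[np.zeros(100)],
                neural=[np.zeros((2, 90))],
                labels=np.array(["correct"]),
                grid=np.array([[0.0, 0, 0], [6.0, 0, 0]]),
            )

    def test_duplicate_grid_coordinates_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            TrialSet(
                speech=[np.zeros(100)],
                neural=[np.zeros((2, 100))],
                labels=np.array(["correct"]),
                grid=np.zeros((2, 3)),
            )

    def test_mimap_clamps_negative_values(self):
        m = MIMap(
            mi_bits=np.array([-0.01, 0.5]),
            band=CANONICAL_BANDS["phrase"],
            lags_ms=[100],
            condition="all",
            n_trials_used=10,
        )
        assert m.mi_bits.min() >= 0.0
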