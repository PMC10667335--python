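"""Phonation features: pitch, cycles, jitter/shimmer, HNR, formants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdvoice import acoustic
from pdvoice.acoustic import (
    AcousticFeatureVector,
    CycleSequence,
    FEATURE_NAMES,
    extract_acoustic_features,
    extract_cycles,
    estimate_f0_contour,
    formant_frequencies,
    harmonics_to_noise_ratio,
    jitter_measures,
    shimmer_measures,
)
from pdvoice.audio import VoiceSample, rescale_amplitude
from pdvoice.exceptions import PdVoiceError, TooFewCyclesError, UnvoicedRecordingError

from conftest import make_voice


def jitter_oracle(periods):
    """Direct-summation jitter reference, independent of the implementation."""
    periods = np.asarray(periods, dtype=float)
    mean_t = periods.mean()
    local_abs = np.mean([abs(periods[i + 1] - periods[i]) for i in range(len(periods) - 1)])
    rap = np.mean(
        [abs(periods[i] - (periods[i - 1] + periods[i] + periods[i + 1]) / 3)
         for i in range(1, len(periods) - 1)]
    ) / mean_t * 100
    ppq5 = np.mean(
        [abs(periods[i] - periods[i - 2 : i + 3].mean()) for i in range(2, len(periods) - 2)]
    ) / mean_t * 100
    return {
        "jitter_local": local_abs / mean_t * 100,
        "jitter_local_abs": local_abs,
        "jitter_rap": rap,
        "jitter_ppq5": ppq5,
        "jitter_ddp": 3 * rap,
    }


def shimmer_oracle(amps):
    amps = np.asarray(amps, dtype=float)
    mean_a = amps.mean()
    local_abs = np.mean([abs(amps[i + 1] - amps[i]) for i in range(len(amps) - 1)])
    local_db = np.mean([abs(20 * np.log10(amps[i + 1] / amps[i])) for i in range(len(amps) - 1)])
    def quotient(k):
        half = k // 2
        return np.mean(
            [abs(amps[i] - amps[i - half : i + half + 1].mean())
             for i in range(half, len(amps) - half)]
        ) / mean_a * 100
    return {
        "shimmer_local": local_abs / mean_a * 100,
        "shimmer_local_db": local_db,
        "shimmer_apq3": quotient(3),
        "shimmer_apq5": quotient(5),
        "shimmer_apq11": quotient(11),
        "shimmer_dda": 3 * quotient(3),
    }


class TestF0Contour:
    def test_known_f0_recovered_within_two_percent(self):
        voice = make_voice(seed=2, f0_mean=120.0)
        _, f0, voiced = estimate_f0_contour(voice, 75, 300)
        assert abs(np.nanmean(f0[voiced]) - 120.0) <= 0.02 * 120.0

    def test_white_noise_is_unvoiced(self, rng):
        noise = VoiceSample(rng.standard_normal(16000) * 0.3, fs=8000)
        with pytest.raises(UnvoicedRecordingError):
            estimate_f0_contour(noise, 75, 300)

    def test_constant_period_f0_sd_small(self):
        voice = make_voice(seed=4, jitter_pct=0.0, shimmer_pct=0.0, f0_sd=0.0, hnr_target=40.0)
        _, f0, voiced = estimate_f0_contour(voice, 75, 300)
        assert np.nanstd(f0[voiced]) <= 1.0

    def test_bad_bounds_rejected(self):
        voice = make_voice(seed=2)
        with pytest.raises(PdVoiceError):
            estimate_f0_contour(voice, 300, 75)


class TestCycles:
    def test_zero_jitter_pulse_train_periods_constant(self):
        voice = make_voice(seed=6, f0_mean=100.0, jitter_pct=0.0, shimmer_pct=0.0,
                           f0_sd=0.0, hnr_target=40.0)
        cycles = extract_cycles(voice, floor=75, ceiling=300)
        assert np.all(np.abs(cycles.period_lengths - 0.010) <= 1.0 / 8000)

    def test_cycle_count_matches_duration_times_f0(self):
        voice = make_voice(seed=8, f0_mean=130.0, duration=2.0, jitter_pct=0.5)
        cycles = extract_cycles(voice)
        assert abs(cycles.period_lengths.size - 2.0 * 130.0) <= 4

    def test_cycle_sequence_validation(self):
        with pytest.raises(ValueError):
            CycleSequence(np.array([0.01]), np.array([1.0]))
        with pytest.raises(ValueError):
            CycleSequence(np.array([0.01, -0.01]), np.array([1.0, 1.0]))


class TestJitterShimmer:
    def test_constant_periods_all_jitter_zero(self):
        cycles = CycleSequence(np.full(20, 0.01), np.linspace(0.9, 1.1, 20))
        assert all(v == 0.0 for v in jitter_measures(cycles).values())

    def test_constant_amplitudes_all_shimmer_zero(self):
        cycles = CycleSequence(np.linspace(0.009, 0.011, 20), np.full(20, 1.0))
        assert all(v == 0.0 for v in shimmer_measures(cycles).values())

    def test_jitter_toy_sequence_matches_direct_summation_oracle(self):
        periods = np.array([10.0, 10.2, 9.9, 10.1, 10.0, 9.8]) * 1e-3
        cycles = CycleSequence(periods, np.full(6, 1.0))
        got = jitter_measures(cycles)
        expected = jitter_oracle(periods)
        for key in expected:
            assert got[key] == pytest.approx(expected[key], rel=1e-12)

    def test_shimmer_toy_sequence_matches_direct_summation_oracle(self):
        amps = np.array([1.0, 1.1, 0.95, 1.05, 1.0, 0.9, 1.0, 1.1, 1.0, 0.95, 1.05])
        cycles = CycleSequence(np.full(11, 0.01), amps)
        got = shimmer_measures(cycles)
        expected = shimmer_oracle(amps)
        for key in expected:
            assert got[key] == pytest.approx(expected[key], rel=1e-12)

    @given(st.lists(st.floats(8e-3, 12e-3), min_size=11, max_size=40),
           st.lists(st.floats(0.5, 1.5), min_size=11, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_ddp_and_dda_identities_hold_exactly(self, periods, amps):
        n = min(len(periods), len(amps))
        cycles = CycleSequence(np.array(periods[:n]), np.array(amps[:n]))
        j = jitter_measures(cycles)
        s = shimmer_measures(cycles)
        assert j["jitter_ddp"] == pytest.approx(3 * j["jitter_rap"], rel=1e-15)
        assert s["shimmer_dda"] == pytest.approx(3 * s["shimmer_apq3"], rel=1e-15)

    def test_too_few_cycles_rejected(self):
        cycles = CycleSequence(np.full(4, 0.01), np.full(4, 1.0))
        with pytest.raises(TooFewCyclesError):
            jitter_measures(cycles)
        with pytest.raises(TooFewCyclesError):
            shimmer_measures(CycleSequence(np.full(8, 0.01), np.full(8, 1.0)))


class TestHnr:
    def test_noiseless_pulse_train_hits_cap_region(self):
        voice = make_voice(seed=3, jitter_pct=0.0, shimmer_pct=0.0, f0_sd=0.0, hnr_target=60.0)
        assert harmonics_to_noise_ratio(voice, 75, 300) >= 30.0

    def test_source_hnr_twenty_recovered_within_three_db(self):
        voice = make_voice(seed=5, jitter_pct=0.0, shimmer_pct=0.0, f0_sd=0.0, hnr_target=20.0)
        assert abs(harmonics_to_noise_ratio(voice, 75, 300) - 20.0) <= 3.0

    def test_more_noise_lowers_estimate(self):
        estimates = [
            harmonics_to_noise_ratio(
                make_voice(seed=7, jitter_pct=0.0, shimmer_pct=0.0, f0_sd=0.0, hnr_target=h),
                75, 300,
            )
            for h in (30.0, 20.0, 10.0)
        ]
        assert estimates[0] > estimates[1] > estimates[2]


class TestFormants:
    def test_known_formants_recovered_within_seven_percent(self):
        truth = (700.0, 1220.0, 2600.0, 3400.0)
        voice = make_voice(seed=11, telephone=False)
        est = formant_frequencies(voice)
        for k, target in enumerate(truth):
            assert abs(est[f"f{k+1}_mean"] - target) <= 0.07 * target

    def test_stationary_vowel_formant_sds_small(self):
        voice = make_voice(seed=11, telephone=False, jitter_pct=0.0, shimmer_pct=0.0,
                           f0_sd=0.0, hnr_target=40.0)
        est = formant_frequencies(voice)
        for k in range(4):
            assert est[f"f{k+1}_sd"] <= 20.0

    def test_formant_means_sorted_ascending(self):
        voice = make_voice(seed=13)
        est = formant_frequencies(voice)
        means = [est[f"f{k+1}_mean"] for k in range(4)]
        assert means == sorted(means)


class TestFeatureVector:
    def test_vector_has_exactly_23_named_entries(self):
        voice = make_voice(seed=1)
        vec = extract_acoustic_features(voice, sex="male")
        assert vec.to_array().shape == (23,)
        assert len(FEATURE_NAMES) == 23
        # 2 F0 + 8 formant + 1 HNR + 5 jitter + 6 shimmer + 1 duration
        assert 2 + 8 + 1 + 5 + 6 + 1 == 23

    def test_identical_recordings_identical_vectors(self):
        a = extract_acoustic_features(make_voice(seed=1), sex="male")
        b = extract_acoustic_features(make_voice(seed=1), sex="male")
        assert np.array_equal(a.to_array(), b.to_array())

    def test_features_invariant_to_global_scaling_after_rescale(self):
        voice = make_voice(seed=2)
        half = VoiceSample(voice.samples * 0.5, voice.fs)
        a = extract_acoustic_features(rescale_amplitude(voice), sex="male")
        b = extract_acoustic_features(rescale_amplitude(half), sex="male")
        np.testing.assert_allclose(a.to_array(), b.to_array(), rtol=1e-9)

    def test_nonfinite_entries_rejected(self):
        kwargs = dict.fromkeys(FEATURE_NAMES, 1.0)
        kwargs["hnr"] = np.nan
        with pytest.raises(ValueError):
            AcousticFeatureVector(**kwargs)
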