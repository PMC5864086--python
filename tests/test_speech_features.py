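"""Envelope extraction, cochlear band placement, linguistic rates, spectra."""

import numpy as np
import pytest

from speechtrack.speech_features import (
    BandSpec,
    Category,
    RateSummary,
    SentenceAnnotation,
    band_edges_cochlear,
    derive_band,
    derive_stress_band,
    extract_wideband_envelope,
    power_spectrum,
    rates_from_onsets,
    read_annotations,
    read_textgrid,
    write_annotations,
)


class TestCochlearBands:
    def test_single_band_is_the_full_range(self):
        assert band_edges_cochlear(1, 100, 8000) == [(100.0, 8000.0)]

    def test_two_band_split_is_compressive(self):
        (lo1, mid), (mid2, hi) = band_edges_cochlear(2, 100, 8000)
        assert mid == mid2
        assert 100 < mid < 8000
        # cochlear spacing allocates more bandwidth to high frequencies
        # than a logarithmic split would
        assert mid > np.sqrt(100 * 8000)

    def test_eight_bands_are_equidistant_on_the_map(self):
        edges = band_edges_cochlear(8, 100, 8000)
        all_edges = np.array([e[0] for e in edges] + [edges[-1][1]])
        assert np.all(np.diff(all_edges) > 0)
        # map positions of the returned edges must be equally spaced
        from speechtrack.speech_features import _greenwood_position

        pos = _greenwood_position(all_edges)
        np.testing.assert_allclose(np.diff(pos), np.diff(pos)[0], rtol=1e-6)

    def test_invalid_range_raises(self):
        with pytest.raises(ValueError):
            band_edges_cochlear(4, -10, 8000)


class TestWidebandEnvelope:
    def test_silence_gives_zero_envelope(self):
        rate = 16_000
        env = extract_wideband_envelope(np.zeros(5 * rate), rate)
        assert env.rate == 150.0
        np.testing.assert_allclose(env.samples, 0.0, atol=1e-12)

    def test_am_tone_envelope_peaks_at_modulation_rate(self):
        rate, f_mod = 22_050, 2.0
        t = np.arange(int(5 * rate)) / rate
        audio = (1 + np.cos(2 * np.pi * f_mod * t)) * np.sin(2 * np.pi * 1000 * t)
        env = extract_wideband_envelope(audio, rate)
        f, p = power_spectrum(env.samples, env.rate, f_lo=0.5, f_hi=10.0)
        assert f[np.argmax(p)] == pytest.approx(f_mod, abs=0.11)

    def test_envelope_invariant_to_polarity_flip(self):
        rng = np.random.default_rng(0)
        rate = 16_000
        audio = rng.standard_normal(2 * rate)
        a = extract_wideband_envelope(audio, rate).samples
        b = extract_wideband_envelope(-audio, rate).samples
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_gated_noise_envelope_peaks_at_gate_rate(self):
        rng = np.random.default_rng(1)
        rate = 16_000
        t = np.arange(6 * rate) / rate
        gate = (t % 1.0) < 0.5  # 0.5 s on per 1 s
        audio = rng.standard_normal(t.size) * gate
        env = extract_wideband_envelope(audio, rate)
        f, p = power_spectrum(env.samples, env.rate, f_lo=0.5, f_hi=6.0)
        assert f[np.argmax(p)] == pytest.approx(1.0, abs=0.11)

    def test_low_rate_audio_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            extract_wideband_envelope(np.zeros(8000), 8000)

    def test_empty_audio_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_wideband_envelope(np.array([]), 22_050)


def _ann(sid, cat, onsets, durations=None):
    onsets = np.asarray(onsets, dtype=float)
    if durations is None:
        durations = np.full(onsets.size, 0.1)
    return SentenceAnnotation(sid, Category(cat), onsets, durations)


class TestRates:
    def test_uniform_one_second_spacing_gives_1hz(self):
        s = rates_from_onsets([_ann("a", "phrase", [0.0, 1.0, 2.0])], "phrase")
        assert s.mean == pytest.approx(1.0)

    def test_min_max_reciprocals_round_to_printed_band(self):
        anns = [
            _ann("slow", "phrase", [0.0, 1.667, 3.334]),
            _ann("fast", "phrase", [0.0, 0.769, 1.538]),
        ]
        band = derive_band(rates_from_onsets(anns, "phrase"))
        assert (band.f_lo, band.f_hi) == (0.6, 1.3)

    def test_equal_durations_have_zero_cv(self):
        s = rates_from_onsets(
            [_ann("a", "word", [0.0, 0.5, 1.0], durations=[0.4, 0.4, 0.4])], "word"
        )
        assert s.c_v == pytest.approx(0.0, abs=1e-12)

    def test_rates_invariant_to_global_time_shift(self):
        base = rates_from_onsets([_ann("a", "word", [0.0, 0.4, 1.0])], "word")
        shifted = rates_from_onsets([_ann("a", "word", [5.0, 5.4, 6.0])], "word")
        assert base.mean == pytest.approx(shifted.mean)

    def test_cv_is_scale_invariant(self):
        durs = np.array([0.2, 0.3, 0.5])
        a = rates_from_onsets([_ann("a", "word", [0, 1, 2], durs)], "word").c_v
        b = rates_from_onsets([_ann("a", "word", [0, 1, 2], 7.0 * durs)], "word").c_v
        assert a == pytest.approx(b)

    def test_single_onset_sentence_raises(self):
        with pytest.raises(ValueError, match="onsets"):
            rates_from_onsets([_ann("a", "phrase", [0.0])], "phrase")


class TestDerivedBands:
    def test_rounding_to_one_decimal(self):
        s = RateSummary(Category.phrase, np.array([0.599, 1.30]), 0.95, 0.3, 0.599, 1.304, 0.2)
        band = derive_band(s)
        assert (band.f_lo, band.f_hi) == (0.6, 1.3)

    def test_degenerate_band_raises(self):
        s = RateSummary(Category.word, np.array([2.0, 2.0]), 2.0, 0.0, 2.0, 2.0, 0.0)
        with pytest.raises(ValueError, match="degenerate"):
            derive_band(s)

    def test_stress_band_is_syllable_band_over_three(self):
        stress = derive_stress_band(BandSpec("syllable", 2.8, 4.8), every_nth=3)
        assert (stress.f_lo, stress.f_hi) == (0.9, 1.6)

    def test_stress_band_exact_division(self):
        stress = derive_stress_band(BandSpec("syllable", 3.0, 6.0), every_nth=3)
        assert (stress.f_lo, stress.f_hi) == (1.0, 2.0)

    def test_stress_every_first_is_identity(self):
        band = BandSpec("syllable", 2.8, 4.8)
        stress = derive_stress_band(band, every_nth=1)
        assert (stress.f_lo, stress.f_hi) == (band.f_lo, band.f_hi)


class TestPowerSpectrum:
    def test_pure_tone_peaks_at_its_frequency(self):
        t = np.arange(30 * 150) / 150.0
        f, p = power_spectrum(np.sin(2 * np.pi * 1.0 * t), 150.0)
        assert f[np.argmax(p)] == pytest.approx(1.0, abs=0.051)

    def test_two_tones_give_two_local_maxima(self):
        t = np.arange(60 * 150) / 150.0
        sig = np.sin(2 * np.pi * 1.0 * t) + np.sin(2 * np.pi * 2.4 * t)
        f, p = power_spectrum(sig, 150.0)
        is_peak = (p[1:-1] > p[:-2]) & (p[1:-1] > p[2:])
        peak_freqs = f[1:-1][is_peak & (p[1:-1] > 0.1 * p.max())]
        assert any(abs(pf - 1.0) <= 0.05 for pf in peak_freqs)
        assert any(abs(pf - 2.4) <= 0.05 for pf in peak_freqs)

    def test_white_noise_spectrum_is_flat_on_average(self):
        rng = np.random.default_rng(4)
        acc = None
        for _ in range(20):
            f, p = power_spectrum(rng.standard_normal(40 * 150), 150.0)
            acc = p if acc is None else acc + p
        acc /= 20
        assert acc.max() < 3.0 * np.median(acc)

    def test_too_short_signal_raises(self):
        with pytest.raises(ValueError, match="short"):
            power_spectrum(np.ones(8), 150.0)


class TestAnnotationIO:
    def test_tsv_round_trip(self, tmp_path):
        anns = [
            _ann("s1", "word", [0.1, 0.5, 1.0]),
            _ann("s1", "phrase", [0.1, 1.2]),
        ]
        path = tmp_path / "ann.tsv"
        write_annotations(anns, path)
        loaded = read_annotations(path)
        assert {(a.sentence_id, a.category) for a in loaded} == {
            ("s1", Category.word),
            ("s1", Category.phrase),
        }
        by_cat = {a.category: a for a in loaded}
        np.testing.assert_allclose(by_cat[Category.word].onsets, [0.1, 0.5, 1.0])

    def test_series_round_trip_infers_rate(self, tmp_path):
        from speechtrack.speech_features import read_series

        t = np.arange(300) / 150.0
        v = np.abs(np.sin(t))
        path = tmp_path / "env.tsv"
        np.savetxt(path, np.column_stack([t, v]), delimiter="\t",
                   header="time_s\tvalue", comments="")
        env = read_series(path)
        assert env.rate == pytest.approx(150.0)
        np.testing.assert_allclose(env.samples, v)

    def test_textgrid_interval_tiers(self, tmp_path):
        tg = """File type = "ooTextFile"
Object class = "TextGrid"
xmin = 0
xmax = 2
tiers? <exists>
size = 1
item []:
    item [1]:
        class = "IntervalTier"
        name = "words"
        xmin = 0
        xmax = 2
        intervals: size = 3
        intervals [1]:
            xmin = 0.0
            xmax = 0.4
            text = "hello"
        intervals [2]:
            xmin = 0.4
            xmax = 0.6
            text = ""
        intervals [3]:
            xmin = 0.6
            xmax = 1.1
            text = "world"
"""
        path = tmp_path / "s1.TextGrid"
        path.write_text(tg)
        anns = read_textgrid(path)
        assert len(anns) == 1
        assert anns[0].category == Category.word
        np.testing.assert_allclose(anns[0].onsets, [0.0, 0.6])
        np.testing.assert_allclose(anns[0].durations, [0.4, 0.5])
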