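"""Speech-side feature extraction.

Turns sentence audio and linguistic annotations into the quantities the
tracking analysis consumes:

* a wideband amplitude envelope, computed as the mean analytic-signal
  magnitude across 8 sub-bands spaced equidistantly on the cochlear
  (Greenwood) frequency map, resampled to 150 Hz;
* stimulus-specific frequency bands per linguistic category (phrase,
  word, syllable, phoneme), defined by the slowest and fastest
  per-sentence event rate across the corpus;
* dispersion statistics of event durations (coefficient of variation);
* Welch periodograms of envelopes and pitch contours on a 0.1-Hz grid.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from fractions import Fraction
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly, welch

from ._dsp import analytic, bandpass_zero_phase

__all__ = [
    "Category",
    "SentenceAnnotation",
    "EnvelopeSignal",
    "BandSpec",
    "RateSummary",
    "CANONICAL_BANDS",
    "band_edges_cochlear",
    "extract_wideband_envelope",
    "rates_from_onsets",
    "derive_band",
    "derive_stress_band",
    "power_spectrum",
    "read_annotations",
    "read_textgrid",
    "load_wav",
]

log = logging.getLogger(__name__)


class Category(str, Enum):
    phrase = "phrase"
    word = "word"
    syllable = "syllable"
    phoneme = "phoneme"


@dataclass(frozen=True)
class SentenceAnnotation:
    """Onset/duration intervals of one linguistic category in one sentence."""

    sentence_id: str
    category: Category
    onsets: np.ndarray  # seconds, strictly increasing
    durations: np.ndarray  # seconds, positive

    def __post_init__(self):
        onsets = np.asarray(self.onsets, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "durations", durations)
        if onsets.ndim != 1 or onsets.shape != durations.shape:
            raise ValueError("onsets and durations must be 1-D and aligned")
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise ValueError(f"onsets must be strictly increasing ({self.sentence_id})")
        if np.any(durations <= 0):
            raise ValueError(f"durations must be positive ({self.sentence_id})")


@dataclass(frozen=True)
class EnvelopeSignal:
    """Non-negative amplitude envelope of one sentence at a fixed rate."""

    sentence_id: str
    samples: np.ndarray
    rate: float = 150.0

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass(frozen=True)
class BandSpec:
    """Named frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self):
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError(f"invalid band edges ({self.f_lo}, {self.f_hi})")


#: Stimulus-tailored bands of the reference corpus plus the fixed
#: oscillation bands used as PAC power / control bands.
CANONICAL_BANDS: dict[str, BandSpec] = {
    "phrase": BandSpec("phrase", 0.6, 1.3),
    "word": BandSpec("word", 1.8, 3.0),
    "syllable": BandSpec("syllable", 2.8, 4.8),
    "phoneme": BandSpec("phoneme", 8.0, 12.4),
    "theta": BandSpec("theta", 4.0, 8.0),
    "alpha": BandSpec("alpha", 8.0, 12.0),
    "beta": BandSpec("beta", 13.0, 30.0),
}


@dataclass(frozen=True)
class RateSummary:
    """Per-sentence event rates of one category plus pooled dispersion."""

    category: Category
    per_sentence_rates: np.ndarray  # Hz
    mean: float
    sd: float
    min: float
    max: float
    c_v: float  # sd of pooled event durations / their mean (population SD)


# ---------------------------------------------------------------------------
# Cochlear map and wideband envelope

# Greenwood human cochlear position function F(x) = A (10^(a x) - k),
# x in [0, 1] from apex to base.
_GREENWOOD_A = 165.4
_GREENWOOD_ALPHA = 2.1
_GREENWOOD_K = 0.88


def _greenwood_position(f_hz: np.ndarray) -> np.ndarray:
    f_hz = np.asarray(f_hz, dtype=float)
    return np.log10(f_hz / _GREENWOOD_A + _GREENWOOD_K) / _GREENWOOD_ALPHA


def _greenwood_frequency(x: np.ndarray) -> np.ndarray:
    return _GREENWOOD_A * (10.0 ** (_GREENWOOD_ALPHA * np.asarray(x, dtype=float)) - _GREENWOOD_K)


def band_edges_cochlear(n_bands: int, f_lo: float, f_hi: float) -> list[tuple[float, float]]:
    """Contiguous band edges equally spaced on the Greenwood cochlear map.

    The n_bands+1 edges are the images of equally spaced cochlear
    positions between the positions of ``f_lo`` and ``f_hi``; the first
    and last edges equal the requested range exactly.
    """
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    if not 0 < f_lo < f_hi:
        raise ValueError("invalid frequency range")
    x = np.linspace(_greenwood_position(f_lo), _greenwood_position(f_hi), n_bands + 1)
    edges = _greenwood_frequency(x)
    edges[0], edges[-1] = f_lo, f_hi  # remove round-trip error at the ends
    return [(float(edges[i]), float(edges[i + 1])) for i in range(n_bands)]


def extract_wideband_envelope(
    audio: np.ndarray,
    rate: float,
    n_bands: int = 8,
    f_range: tuple[float, float] = (100.0, 8000.0),
    out_rate: float = 150.0,
    sentence_id: str = "",
) -> EnvelopeSignal:
    """Wideband envelope: mean |analytic signal| over cochlear sub-bands.

    The waveform is band-passed into ``n_bands`` third-order zero-phase
    Butterworth bands equidistant on the cochlear map, the Hilbert
    magnitude of each band is averaged, and the result is polyphase
    resampled to ``out_rate``.
    """
    audio = np.asarray(audio, dtype=float)
    if audio.size == 0:
        raise ValueError("empty audio input")
    if audio.ndim == 2:
        log.warning("multi-channel audio: averaging %d channels", audio.shape[1])
        audio = audio.mean(axis=1)
    if rate < 2 * f_range[1]:
        raise ValueError(
            f"audio rate {rate} Hz cannot represent the {f_range[1]} Hz band edge"
        )
    if audio.size < rate:
        raise ValueError("audio shorter than 1 s")

    # at exactly 2x the top edge the highest band would touch Nyquist;
    # cap marginally below so the band-pass filter is realisable
    top = min(f_range[1], 0.995 * rate / 2.0)
    env = np.zeros_like(audio)
    for lo, hi in band_edges_cochlear(n_bands, f_range[0], top):
        env += np.abs(analytic(bandpass_zero_phase(audio, lo, hi, rate)))
    env /= n_bands

    ratio = Fraction(out_rate / rate).limit_denominator(10000)
    env = resample_poly(env, ratio.numerator, ratio.denominator)
    np.maximum(env, 0.0, out=env)  # resampling ripple can undershoot 0
    return EnvelopeSignal(sentence_id=sentence_id, samples=env, rate=out_rate)


# ---------------------------------------------------------------------------
# Linguistic rates and stimulus-specific bands


def rates_from_onsets(
    annotations: list[SentenceAnnotation], category: Category | str
) -> RateSummary:
    """Per-sentence event rates (1 / mean inter-onset interval) of a category.

    ``c_v`` is the population SD of the pooled event durations divided by
    their mean — a scale-free measure of how variable unit lengths are.
    """
    category = Category(category)
    rates = []
    pooled: list[np.ndarray] = []
    seen = False
    for ann in annotations:
        if ann.category != category:
            continue
        seen = True
        if ann.onsets.size < 2:
            raise ValueError(
                f"sentence {ann.sentence_id}: need >= 2 {category.value} onsets for a rate"
            )
        rates.append(1.0 / np.mean(np.diff(ann.onsets)))
        pooled.append(ann.durations)
    if not seen:
        raise ValueError(f"no annotations for category {category.value}")
    rates = np.asarray(rates)
    durations = np.concatenate(pooled)
    return RateSummary(
        category=category,
        per_sentence_rates=rates,
        mean=float(rates.mean()),
        sd=float(rates.std(ddof=1)) if rates.size > 1 else 0.0,
        min=float(rates.min()),
        max=float(rates.max()),
        c_v=float(durations.std(ddof=0) / durations.mean()),
    )


def derive_band(summary: RateSummary, rounding: int = 1) -> BandSpec:
    """Stimulus-specific band: [min, max] per-sentence rate, rounded."""
    lo = round(summary.min, rounding)
    hi = round(summary.max, rounding)
    if lo >= hi:
        raise ValueError(f"degenerate band for {summary.category.value}: ({lo}, {hi})")
    return BandSpec(summary.category.value, lo, hi)


def derive_stress_band(syllable_band: BandSpec, every_nth: int = 3) -> BandSpec:
    """Stress timescale: syllable band divided by the stress period.

    Treating every ``every_nth`` syllable as stressed maps the syllable
    band onto a slower band; with the canonical syllable band 2.8-4.8 Hz
    and every third syllable stressed this gives 0.9-1.6 Hz.
    """
    if every_nth < 1:
        raise ValueError("every_nth must be >= 1")
    return BandSpec(
        f"stress({syllable_band.name}/{every_nth})",
        round(syllable_band.f_lo / every_nth, 1),
        round(syllable_band.f_hi / every_nth, 1),
    )


def power_spectrum(
    signal: np.ndarray,
    rate: float,
    f_lo: float = 0.1,
    f_hi: float = 12.0,
    df: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch periodogram evaluated on a regular frequency grid.

    The FFT length is set to ``rate / df`` so the Welch bins land exactly
    on the requested grid (segments are zero-padded when the signal is
    shorter); segment length is at most half the signal so at least two
    overlapping segments are averaged.
    """
    signal = np.asarray(signal, dtype=float)
    n = signal.size
    if n < 16:
        raise ValueError("signal too short for a Welch estimate")
    nfft = int(round(rate / df))
    nperseg = min(n // 2, nfft)
    freqs, power = welch(signal, fs=rate, nperseg=nperseg, nfft=nfft)
    grid = np.round(np.arange(f_lo, f_hi + df / 2, df), 10)
    power_on_grid = np.interp(grid, freqs, power)
    return grid, power_on_grid


# ---------------------------------------------------------------------------
# I/O dialects


def read_annotations(path: str | Path) -> list[SentenceAnnotation]:
    """Read tab-separated annotations (sentence_id, category, onset_s, duration_s)."""
    df = pd.read_csv(path, sep="\t", dtype={"sentence_id": str})
    required = {"sentence_id", "category", "onset_s", "duration_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation file must have columns {sorted(required)}")
    out = []
    for (sid, cat), grp in df.groupby(["sentence_id", "category"], sort=True):
        grp = grp.sort_values("onset_s")
        out.append(
            SentenceAnnotation(
                sentence_id=str(sid),
                category=Category(cat),
                onsets=grp["onset_s"].to_numpy(),
                durations=grp["duration_s"].to_numpy(),
            )
        )
    return out


def write_annotations(annotations: list[SentenceAnnotation], path: str | Path) -> None:
    rows = []
    for ann in annotations:
        for onset, dur in zip(ann.onsets, ann.durations):
            rows.append((ann.sentence_id, ann.category.value, onset, dur))
    pd.DataFrame(rows, columns=["sentence_id", "category", "onset_s", "duration_s"]).to_csv(
        path, sep="\t", index=False
    )


_TG_FLOAT = re.compile(r"(xmin|xmax)\s*=\s*([0-9.eE+-]+)")
_TG_TEXT = re.compile(r'text\s*=\s*"(.*)"')
_TG_TIER_NAME = re.compile(r'name\s*=\s*"(.*)"')


def read_textgrid(path: str | Path, sentence_id: str | None = None) -> list[SentenceAnnotation]:
    """Import Praat TextGrid interval tiers named after linguistic categories.

    Only tiers whose name matches a :class:`Category` (case-insensitive,
    trailing ``s`` ignored) are read; intervals with empty or whitespace
    text are treated as silences and skipped.
    """
    text = Path(path).read_text()
    sid = sentence_id or Path(path).stem
    out = []
    # split into tier chunks; the header before the first tier is dropped
    chunks = re.split(r"item\s*\[\d+\]\s*:", text)[1:]
    for chunk in chunks:
        m = _TG_TIER_NAME.search(chunk)
        if not m:
            continue
        name = m.group(1).strip().lower().rstrip("s")
        try:
            category = Category(name)
        except ValueError:
            continue
        onsets, durations = [], []
        intervals = re.split(r"intervals\s*\[\d+\]\s*:", chunk)[1:]
        for iv in intervals:
            bounds = dict((k, float(v)) for k, v in _TG_FLOAT.findall(iv))
            label = _TG_TEXT.search(iv)
            if label is None or not label.group(1).strip():
                continue
            onsets.append(bounds["xmin"])
            durations.append(bounds["xmax"] - bounds["xmin"])
        if onsets:
            out.append(
                SentenceAnnotation(
                    sentence_id=sid,
                    category=category,
                    onsets=np.asarray(onsets),
                    durations=np.asarray(durations),
                )
            )
    return out


def read_series(path: str | Path) -> EnvelopeSignal:
    """Read a two-column (time_s, value) series; the rate is inferred.

    Accepts envelope or F0 contours written by this package or by
    external tools, with or without a header line.
    """
    df = pd.read_csv(path, sep=r"\s+|\t|,", engine="python", comment="#")
    if df.shape[1] < 2:
        raise ValueError("expected two columns (time_s, value)")
    first = df.columns[0]
    try:
        float(first)
    except ValueError:
        pass  # header row present; pandas already consumed it
    else:
        df = pd.read_csv(path, sep=r"\s+|\t|,", engine="python", header=None, comment="#")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    dt = np.diff(t)
    if t.size < 2 or np.any(dt <= 0):
        raise ValueError("time column must be strictly increasing")
    rate = 1.0 / float(np.median(dt))
    return EnvelopeSignal(sentence_id=Path(path).stem, samples=v, rate=rate)


def load_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a PCM WAV file as float64 in [-1, 1]; channels are averaged."""
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / np.iinfo(data.dtype).max
    else:
        data = data.astype(float)
    if data.ndim == 2:
        log.warning("multi-channel WAV %s: averaging %d channels", path, data.shape[1])
        data = data.mean(axis=1)
    return data, float(rate)
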