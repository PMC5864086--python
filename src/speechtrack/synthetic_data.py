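"""Synthetic corpus and neural-trial generator with known ground truth.

Emulates the structure of the study conditions the pipeline is built
for: sentences of seven elements (two phrases followed by five content
words) whose phrase/word/syllable/phoneme onset rates centre near
1.0 / 2.4 / 3.8 / 10.4 Hz; wideband envelopes composed of sharp-attack
pulses at every annotated onset, with pauses after the two phrases that
carry the phrasal rhythm; and multi-participant source-grid trial sets
in which a compact "effect" region tracks the envelope at a fixed lag
with a label-dependent SNR, and beta-band power in a coupling region is
modulated by the phrasal-band phase of the same series.

Every quantity a pipeline stage is supposed to recover (effect region,
lag, SNRs, coupling depths) is part of the configuration, so tests can
compare recovered against injected values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._dsp import analytic, bandpass_zero_phase
from .speech_features import Category, EnvelopeSignal, SentenceAnnotation
from .tracking import CORRECT, INCORRECT, TrialSet, subsample_size

__all__ = ["SynthConfig", "generate_corpus", "generate_participant", "label_counts"]

RATE = 150.0


@dataclass
class SynthConfig:
    """Generator parameters; defaults emulate the reference study conditions."""

    n_sentences: int = 90
    #: target per-sentence onset-rate mean and SD (Hz) per category
    target_rates: dict = field(
        default_factory=lambda: {
            "phrase": (1.0, 0.1),
            "word": (2.4, 0.3),
            "syllable": (3.8, 0.4),
            "phoneme": (10.4, 0.8),
        }
    )
    n_participants: int = 20
    n_trials: int = 60
    p_correct: float = 0.7
    grid_shape: tuple = (8, 8, 8)
    grid_spacing_mm: float = 6.0
    #: grid indices of the tracking effect region; None -> central 3x3x3 block
    effect_region: np.ndarray | None = None
    #: grid indices of the PAC region; None -> same as effect_region
    pac_region: np.ndarray | None = None
    tracking_snr_correct: float = 0.6
    tracking_snr_incorrect: float = 0.2
    neural_lag_ms: float = 100.0
    pac_depth_correct: float = 0.8
    pac_depth_incorrect: float = 0.0
    noise_exponent: float = 1.0
    master_seed: int = 0

    def __post_init__(self):
        if not 0 < self.p_correct < 1:
            raise ValueError("p_correct must lie in (0, 1)")
        for cat, (mu, sd) in self.target_rates.items():
            if mu <= 0 or sd < 0:
                raise ValueError(f"invalid rate target for {cat}")
        if min(self.tracking_snr_correct, self.tracking_snr_incorrect) < 0:
            raise ValueError("SNRs must be non-negative")
        if not (0 <= self.pac_depth_correct <= 1 and 0 <= self.pac_depth_incorrect <= 1):
            raise ValueError("PAC depths must lie in [0, 1]")
        if self.effect_region is None:
            self.effect_region = _central_block(self.grid_shape, 3)
        self.effect_region = np.asarray(self.effect_region, dtype=int)
        if self.pac_region is None:
            self.pac_region = self.effect_region.copy()
        self.pac_region = np.asarray(self.pac_region, dtype=int)
        n_points = int(np.prod(self.grid_shape))
        for region in (self.effect_region, self.pac_region):
            if region.size and (region.min() < 0 or region.max() >= n_points):
                raise ValueError("region indices outside the grid")

    @property
    def n_points(self) -> int:
        return int(np.prod(self.grid_shape))

    def grid_coords(self) -> np.ndarray:
        idx = np.stack(
            np.meshgrid(*[np.arange(s) for s in self.grid_shape], indexing="ij"), axis=-1
        ).reshape(-1, 3)
        return idx * self.grid_spacing_mm

    def ground_truth(self) -> dict:
        return {
            "effect_region": self.effect_region.tolist(),
            "pac_region": self.pac_region.tolist(),
            "tracking_snr_correct": self.tracking_snr_correct,
            "tracking_snr_incorrect": self.tracking_snr_incorrect,
            "neural_lag_ms": self.neural_lag_ms,
            "pac_depth_correct": self.pac_depth_correct,
            "pac_depth_incorrect": self.pac_depth_incorrect,
        }


def _central_block(grid_shape, extent: int) -> np.ndarray:
    """Indices of a centred extent^3 block in a flattened 3-D lattice."""
    shape = tuple(grid_shape)
    starts = [max(0, s // 2 - extent // 2 - 1) for s in shape]
    sel = []
    for i in range(starts[0], min(starts[0] + extent, shape[0])):
        for j in range(starts[1], min(starts[1] + extent, shape[1])):
            for k in range(starts[2], min(starts[2] + extent, shape[2])):
                sel.append((i * shape[1] + j) * shape[2] + k)
    return np.asarray(sel, dtype=int)


# ---------------------------------------------------------------------------
# Corpus


def _positive_normal(rng, mu, sd, lo):
    while True:
        v = rng.normal(mu, sd)
        if v > lo:
            return v


def _split_weights(rng, n, sigma, total):
    w = rng.lognormal(0.0, sigma, size=n)
    return w / w.sum() * total


def _one_sentence(rng: np.random.Generator, cfg: SynthConfig):
    """Onsets/durations for one 7-element sentence plus its envelope pulses.

    Two phrase spans (3 words each, ending in a pause) are followed by
    five content words.  Phrase and word rates are controlled directly
    (the per-sentence rate is drawn from the target distribution and the
    onset geometry constructed to realise it); syllable and phoneme
    onsets subdivide word and syllable spans with counts chosen to land
    near their target rates.
    """
    r_phrase = _positive_normal(rng, *cfg.target_rates["phrase"], lo=0.5)
    i_p1 = 1.0 / r_phrase  # the single phrase inter-onset interval
    i_p2 = 1.0 / _positive_normal(rng, *cfg.target_rates["phrase"], lo=0.5)
    r_word = _positive_normal(rng, *cfg.target_rates["word"], lo=1.6)

    t0 = 0.10
    # word onset intervals: 3 within each phrase (the third includes the
    # phrase-final pause), then 4 between the 5 content words
    total_content = max(0.8, 10.0 / r_word - i_p1 - i_p2)
    iv_p1 = np.array([0.27, 0.27, 0.46]) * i_p1 * rng.lognormal(0, 0.05, 3)
    iv_p1 *= i_p1 / iv_p1.sum()
    iv_p2 = np.array([0.27, 0.27, 0.46]) * i_p2 * rng.lognormal(0, 0.05, 3)
    iv_p2 *= i_p2 / iv_p2.sum()
    iv_content = _split_weights(rng, 4, 0.30, total_content)
    intervals = np.concatenate([iv_p1, iv_p2, iv_content])
    word_onsets = t0 + np.concatenate([[0.0], np.cumsum(intervals)])  # 11 onsets

    # durations: words before a pause stop early; the rest nearly abut
    word_durs = np.empty(11)
    for j in range(10):
        pause = 0.0
        if j in (2, 5):  # phrase-final words precede a pause
            pause = (0.30 + 0.08 * rng.standard_normal()) * (i_p1 if j == 2 else i_p2)
            pause = np.clip(pause, 0.12, 0.6 * intervals[j])
        word_durs[j] = intervals[j] - pause - 0.01
    word_durs[10] = min(0.55 * rng.lognormal(0, 0.2), 0.9)
    word_durs = np.maximum(word_durs, 0.05)

    sent_end = word_onsets[-1] + word_durs[-1] + 0.15

    phrase_onsets = np.array([word_onsets[0], word_onsets[3]])
    phrase_durs = np.array(
        [word_onsets[2] + word_durs[2] - word_onsets[0], word_onsets[5] + word_durs[5] - word_onsets[3]]
    )

    # syllables: >=1 per word; total count targets the syllable rate
    r_syll = _positive_normal(rng, *cfg.target_rates["syllable"], lo=2.5)
    span = word_onsets[-1] + 0.47 * word_durs[-1] - word_onsets[0]
    n_syll = max(11, int(round(r_syll * span)) + 1)
    syll_counts = np.ones(11, dtype=int)
    extra = n_syll - 11
    # content words take extra syllables first (they are longer)
    order = np.concatenate([rng.permutation(np.arange(6, 11)), rng.permutation(6)])
    pos = 0
    while extra > 0:
        w = order[pos % order.size]
        if syll_counts[w] < 4:
            syll_counts[w] += 1
            extra -= 1
        pos += 1

    syll_onsets, syll_durs = [], []
    for j in range(11):
        shares = _split_weights(rng, syll_counts[j], 0.25, word_durs[j])
        on = word_onsets[j] + np.concatenate([[0.0], np.cumsum(shares[:-1])])
        syll_onsets.append(on)
        syll_durs.append(shares * 0.95)
    syll_onsets = np.concatenate(syll_onsets)
    syll_durs = np.concatenate(syll_durs)

    # phonemes subdivide syllables the same way
    r_phon = _positive_normal(rng, *cfg.target_rates["phoneme"], lo=7.0)
    span_ph = syll_onsets[-1] + 0.6 * syll_durs[-1] - syll_onsets[0]
    n_phon = max(syll_onsets.size, int(round(r_phon * span_ph)) + 1)
    phon_counts = np.ones(syll_onsets.size, dtype=int)
    extra = n_phon - phon_counts.sum()
    order = rng.permutation(syll_onsets.size)
    pos = 0
    while extra > 0:
        s = order[pos % order.size]
        if phon_counts[s] < 5:
            phon_counts[s] += 1
            extra -= 1
        pos += 1
    phon_onsets, phon_durs = [], []
    for s in range(syll_onsets.size):
        shares = _split_weights(rng, phon_counts[s], 0.2, syll_durs[s])
        on = syll_onsets[s] + np.concatenate([[0.0], np.cumsum(shares[:-1])])
        phon_onsets.append(on)
        phon_durs.append(shares * 0.95)

    events = {
        Category.phrase: (phrase_onsets, phrase_durs),
        Category.word: (word_onsets, word_durs),
        Category.syllable: (syll_onsets, syll_durs),
        Category.phoneme: (np.concatenate(phon_onsets), np.concatenate(phon_durs)),
    }
    return events, sent_end


# envelope pulse kernels: 2-sample linear attack, exponential decay (s)
_KERNEL = {
    Category.phrase: (0.8, 0.12),
    Category.word: (0.6, 0.10),
    Category.syllable: (0.5, 0.07),
    Category.phoneme: (0.45, 0.04),
}


def _envelope_from_events(events: dict, sent_end: float, rate: float = RATE) -> np.ndarray:
    n = int(math.ceil(sent_end * rate)) + 1
    t = np.arange(n) / rate
    env = np.zeros(n)
    attack = 2.0 / rate
    for cat, (onsets, durs) in events.items():
        amp, tau = _KERNEL[cat]
        for o, d in zip(onsets, durs):
            rel = t - o
            active = (rel >= 0) & (rel < d + 4 * tau)
            r = rel[active]
            pulse = np.where(r < attack, r / attack, np.exp(-(r - attack) / tau))
            env[active] += amp * pulse
    return env


def generate_corpus(
    cfg: SynthConfig, seed: int | None = None
) -> tuple[list[SentenceAnnotation], list[EnvelopeSignal]]:
    """Draw a corpus of annotated sentences and matching envelopes.

    Deterministic in ``cfg.master_seed`` (or the explicit ``seed``).
    Envelopes are sums of sharp-attack pulses at every annotated onset,
    so each onset coincides with a local envelope rise, and the
    phrase-final pauses imprint the phrasal rhythm on the spectrum.
    """
    root = np.random.SeedSequence(cfg.master_seed if seed is None else seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    annotations: list[SentenceAnnotation] = []
    envelopes: list[EnvelopeSignal] = []
    for s in range(cfg.n_sentences):
        sid = f"s{s:03d}"
        events, sent_end = _one_sentence(rng, cfg)
        for cat, (onsets, durs) in events.items():
            annotations.append(
                SentenceAnnotation(sentence_id=sid, category=cat, onsets=onsets, durations=durs)
            )
        envelopes.append(
            EnvelopeSignal(sentence_id=sid, samples=_envelope_from_events(events, sent_end), rate=RATE)
        )
    return annotations, envelopes


# ---------------------------------------------------------------------------
# Neural trials


def _one_over_f_noise(rng: np.random.Generator, shape: tuple, exponent: float) -> np.ndarray:
    """Noise with a 1/f^exponent power spectrum along the last axis, unit SD."""
    white = rng.standard_normal(shape)
    if exponent == 0:
        return white
    n = shape[-1]
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    scale[0] = scale[1]
    out = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


# beta carrier is drawn inside 15-28 Hz so the modulated power stays in the
# beta band and leaks minimally into the alpha control band below 13 Hz
_BETA_CARRIER = (15.0, 28.0)
_PHRASAL_BAND = (0.6, 1.3)
_PAC_GAIN = 0.6


def generate_participant(
    cfg: SynthConfig,
    envelopes: list[EnvelopeSignal],
    participant: int = 0,
) -> TrialSet:
    """Raw neural trials for one participant at the configured ground truth.

    Per trial a sentence envelope is the stimulus; every grid point
    receives independent 1/f noise; effect-region points additionally
    track the (z-scored) envelope delayed by ``neural_lag_ms`` with an
    amplitude set by the trial label's SNR; coupling-region points carry
    a beta-band noise carrier whose amplitude follows
    ``1 + depth * cos(phrasal-band phase)`` of that point's own series.
    """
    seq = np.random.SeedSequence([int(cfg.master_seed), 1000 + int(participant)])
    rng = np.random.default_rng(seq)
    n_points = cfg.n_points
    lag = int(round(cfg.neural_lag_ms * RATE / 1000.0))

    pick = (
        rng.choice(len(envelopes), size=cfg.n_trials, replace=False)
        if cfg.n_trials <= len(envelopes)
        else rng.choice(len(envelopes), size=cfg.n_trials, replace=True)
    )
    # the adaptive difficulty titration this emulates guarantees both
    # outcomes occur; redraw the (rare) degenerate label vectors
    while True:
        labels = np.where(rng.random(cfg.n_trials) < cfg.p_correct, CORRECT, INCORRECT)
        n_min = min(np.sum(labels == CORRECT), np.sum(labels == INCORRECT))
        if n_min >= min(2, cfg.n_trials // 2):
            break

    speech, neural = [], []
    for k, env_idx in enumerate(pick):
        env = envelopes[env_idx].samples
        n = env.size
        series = _one_over_f_noise(rng, (n_points, n), cfg.noise_exponent)

        snr = cfg.tracking_snr_correct if labels[k] == CORRECT else cfg.tracking_snr_incorrect
        if snr > 0 and cfg.effect_region.size:
            env_z = (env - env.mean()) / env.std()
            delayed = np.zeros(n)
            delayed[lag:] = env_z[: n - lag]
            series[cfg.effect_region] += snr * delayed

        depth = cfg.pac_depth_correct if labels[k] == CORRECT else cfg.pac_depth_incorrect
        if depth > 0 and cfg.pac_region.size:
            base = series[cfg.pac_region]
            phase = np.angle(
                analytic(bandpass_zero_phase(base, *_PHRASAL_BAND, RATE))
            )
            carrier = _one_over_f_noise(rng, (cfg.pac_region.size, n), 0.0)
            carrier = bandpass_zero_phase(carrier, *_BETA_CARRIER, RATE)
            carrier /= carrier.std(axis=-1, keepdims=True)
            series[cfg.pac_region] += _PAC_GAIN * (1.0 + depth * np.cos(phase)) * carrier

        speech.append(env.astype(float))
        neural.append(series)

    return TrialSet(
        speech=speech, neural=neural, labels=labels, grid=cfg.grid_coords(), rate=RATE
    )


def label_counts(labels: np.ndarray, frac: float = 0.8) -> tuple[int, int, int]:
    """(n_correct, n_incorrect, equalised subsample size at ``frac``)."""
    labels = np.asarray(labels)
    n_c = int(np.sum(labels == CORRECT))
    n_i = int(np.sum(labels == INCORRECT))
    return n_c, n_i, subsample_size(n_c, n_i, frac)


def write_ground_truth(cfg: SynthConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(cfg.ground_truth(), indent=2))


def save_trialset(raw: TrialSet, directory: str | Path) -> None:
    """Write a participant's trials as one .npz plus per-trial arrays."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(
        directory / "trials.npz",
        labels=raw.labels, grid=raw.grid, rate=raw.rate,
        **{f"speech_{i:03d}": s for i, s in enumerate(raw.speech)},
        **{f"neural_{i:03d}": m for i, m in enumerate(raw.neural)},
    )


def load_trialset(directory: str | Path) -> TrialSet:
    """Read a participant directory written by :func:`save_trialset`."""
    with np.load(Path(directory) / "trials.npz") as data:
        n = sum(1 for k in data.files if k.startswith("speech_"))
        return TrialSet(
            speech=[data[f"speech_{i:03d}"] for i in range(n)],
            neural=[data[f"neural_{i:03d}"] for i in range(n)],
            labels=data["labels"],
            grid=data["grid"],
            rate=float(data["rate"]),
        )
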