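"""Speech-tracking mutual information.

Per frequency band, speech envelope and neural source series are
band-pass filtered (zero-phase Butterworth), Hilbert transformed, and
their dependence quantified as the Gaussian-copula MI between the 2-D
analytic speech signal (real, imaginary) and the 2-D analytic neural
signal, evaluated at several stimulus-to-brain lags and summed over
lags.  Null values come from surrogate pairings (trial shuffling or
speech time reversal); perceptual relevance from a trial-subsampled
correct-vs-incorrect contrast.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._dsp import DEFAULT_FILTER_ORDER, analytic, bandpass_zero_phase
from .infotheory import MIValue, copula_normalise, gaussian_mi, mi_bias_bits, rank_normalise_rows
from .speech_features import BandSpec

__all__ = [
    "TrialSet",
    "AnalyticTrialSet",
    "MIMap",
    "bandpass_analytic",
    "prepare_trials",
    "lag_grid",
    "tracking_mi",
    "tracking_mi_map",
    "surrogate_shuffle",
    "surrogate_timereverse",
    "condition_contrast",
    "subsample_size",
    "write_mimap",
]

_LN2 = math.log(2.0)

CORRECT = "correct"
INCORRECT = "incorrect"


@dataclass
class TrialSet:
    """Raw (unfiltered) per-trial speech and neural series at a common rate.

    ``speech[i]`` is a 1-D envelope series; ``neural[i]`` is a
    (grid points x samples) array aligned with it.  Trials may differ in
    length (sentences do), but speech and neural agree within a trial.
    """

    speech: list[np.ndarray]
    neural: list[np.ndarray]
    labels: np.ndarray  # per-trial "correct" / "incorrect"
    grid: np.ndarray  # (P, 3) coordinates in mm
    rate: float = 150.0

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.grid = np.asarray(self.grid, dtype=float)
        if len(self.speech) != len(self.neural) or len(self.speech) != self.labels.size:
            raise ValueError("speech, neural and labels must have one entry per trial")
        for s, m in zip(self.speech, self.neural):
            if s.shape[-1] != m.shape[-1]:
                raise ValueError("speech and neural series must share length within a trial")
        if np.unique(self.grid, axis=0).shape[0] != self.grid.shape[0]:
            raise ValueError("grid coordinates must be unique")

    @property
    def n_trials(self) -> int:
        return len(self.speech)

    @property
    def n_points(self) -> int:
        return self.grid.shape[0]


@dataclass
class AnalyticTrialSet:
    """Band-limited complex analytic trials, edge-trimmed, ready for MI."""

    speech: list[np.ndarray]  # complex, 1-D per trial
    neural: list[np.ndarray]  # complex, (P, T) per trial
    labels: np.ndarray
    grid: np.ndarray
    band: BandSpec
    rate: float = 150.0

    @property
    def n_trials(self) -> int:
        return len(self.speech)

    @property
    def n_points(self) -> int:
        return self.grid.shape[0]

    def label_indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


@dataclass
class MIMap:
    """Per-grid-point lag-summed MI (bits, clamped at 0) with provenance."""

    mi_bits: np.ndarray
    band: BandSpec
    lags_ms: list[float]
    condition: str  # all | correct | incorrect | surrogate
    n_trials_used: int
    n_repeats: int = 1
    grid: np.ndarray | None = None

    def __post_init__(self):
        self.mi_bits = np.maximum(np.asarray(self.mi_bits, dtype=float), 0.0)


def bandpass_analytic(
    series: np.ndarray,
    band: BandSpec,
    rate: float = 150.0,
    order: int = DEFAULT_FILTER_ORDER,
) -> np.ndarray:
    """Complex analytic signal of the zero-phase band-filtered input.

    Works along the last axis, so a (points x samples) array is filtered
    per point.  Raises for series shorter than three filter time
    constants of the band's low edge (the transient would dominate).
    """
    series = np.asarray(series, dtype=float)
    # three time constants (tau = 1/(2 pi f_lo)) of the low band edge
    min_len = int(3 * rate / (2 * np.pi * band.f_lo)) + 1
    if series.shape[-1] < min_len:
        raise ValueError(
            f"series of {series.shape[-1]} samples too short for band "
            f"{band.name} (need >= {min_len} at {rate} Hz)"
        )
    return analytic(bandpass_zero_phase(series, band.f_lo, band.f_hi, rate, order))


def prepare_trials(
    raw: TrialSet,
    band: BandSpec,
    order: int = DEFAULT_FILTER_ORDER,
    edge_trim_s: float = 0.5,
) -> AnalyticTrialSet:
    """Filter + Hilbert every trial into a band and trim filter edges.

    ``edge_trim_s`` seconds are dropped from both ends of every filtered
    trial to suppress filter transients before any MI computation.
    """
    trim = int(round(edge_trim_s * raw.rate))
    speech, neural = [], []
    for s, m in zip(raw.speech, raw.neural):
        if s.shape[-1] <= 2 * trim:
            raise ValueError("trial shorter than twice the edge trim")
        sl = slice(trim, s.shape[-1] - trim) if trim else slice(None)
        speech.append(bandpass_analytic(s, band, raw.rate, order)[sl].astype(np.complex64))
        neural.append(bandpass_analytic(m, band, raw.rate, order)[..., sl].astype(np.complex64))
    return AnalyticTrialSet(
        speech=speech,
        neural=neural,
        labels=raw.labels.copy(),
        grid=raw.grid.copy(),
        band=band,
        rate=raw.rate,
    )


def lag_grid(lo_ms: float = 60.0, hi_ms: float = 140.0, step_ms: float = 20.0) -> list[float]:
    """Inclusive arithmetic lag grid; the canonical call gives 5 lags."""
    span = hi_ms - lo_ms
    n_steps = span / step_ms if step_ms else 0
    if span < 0 or abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(f"step {step_ms} ms does not divide the range ({lo_ms}, {hi_ms})")
    return [lo_ms + i * step_ms for i in range(int(round(n_steps)) + 1)]


def _lag_samples(lag_ms: float, rate: float) -> int:
    return int(round(lag_ms * rate / 1000.0))


def _lagged_pairs(
    speech: list[np.ndarray], neural: list[np.ndarray], lag: int, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Concatenate speech(t) / neural(t+lag) pairs across trials.

    The lag overhang is trimmed within each trial, so no sample pair
    spans a trial boundary.  Returns X (n, 2) float64 plus the neural
    real and imaginary planes as separate (P, n) arrays (kept in their
    storage dtype: ranks are dtype-insensitive and float32 sorts faster).
    """
    xs, ys = [], []
    for s, m in zip(speech, neural):
        t = s.shape[-1]
        if lag >= t:
            raise ValueError(f"lag of {lag} samples exceeds trial length {t}")
        xs.append(s[: t - lag])
        ys.append(m[points, lag:t])
    x = np.concatenate(xs)
    y = np.concatenate(ys, axis=-1)
    return (
        np.stack([x.real, x.imag], axis=-1).astype(np.float64),
        np.ascontiguousarray(y.real),
        np.ascontiguousarray(y.imag),
    )


def tracking_mi(
    trials: AnalyticTrialSet,
    grid_point: int,
    lags_ms: list[float] | None = None,
    trial_idx: np.ndarray | None = None,
    bias_correct: bool = True,
) -> MIValue:
    """Lag-summed speech-tracking MI at one grid point (reference path).

    For each lag, speech samples at ``t`` are paired with neural samples
    at ``t + lag`` within trials, concatenated across trials, real and
    imaginary parts z-scored separately, and the 2-D x 2-D copula MI
    computed; the per-lag values are summed.
    """
    lags_ms = lag_grid() if lags_ms is None else lags_ms
    speech, neural = _select_trials(trials, trial_idx)
    if len(speech) < 1:
        raise ValueError("no trials selected")
    total = 0.0
    n_last = 0
    for lag_ms in lags_ms:
        lag = _lag_samples(lag_ms, trials.rate)
        x, yr, yi = _lagged_pairs(speech, neural, lag, np.asarray([grid_point]))
        y = np.stack([yr[0], yi[0]], axis=-1).astype(np.float64)
        x = (x - x.mean(axis=0)) / x.std(axis=0)
        y = (y - y.mean(axis=0)) / y.std(axis=0)
        mi = gaussian_mi(copula_normalise(x), copula_normalise(y), bias_correct=bias_correct)
        total += mi.bits
        n_last = mi.n_obs
    return MIValue(bits=total, n_obs=n_last, dims=(2, 2), bias_corrected=bias_correct)


def _select_trials(trials: AnalyticTrialSet, trial_idx):
    if trial_idx is None:
        return trials.speech, trials.neural
    trial_idx = np.asarray(trial_idx)
    return [trials.speech[i] for i in trial_idx], [trials.neural[i] for i in trial_idx]


def tracking_mi_map(
    trials: AnalyticTrialSet,
    lags_ms: list[float] | None = None,
    trial_idx: np.ndarray | None = None,
    points: np.ndarray | None = None,
    bias_correct: bool = True,
) -> np.ndarray:
    """Lag-summed tracking MI for many grid points at once.

    Numerically equivalent to calling :func:`tracking_mi` per point but
    vectorised: ranks are taken along the sample axis for all points
    simultaneously and the 4x4 joint determinant is evaluated through
    the Schur complement of the shared speech block.
    """
    lags_ms = lag_grid() if lags_ms is None else lags_ms
    points = np.arange(trials.n_points) if points is None else np.asarray(points)
    speech, neural = _select_trials(trials, trial_idx)
    total = np.zeros(points.size)
    for lag_ms in lags_ms:
        lag = _lag_samples(lag_ms, trials.rate)
        x, yr, yi = _lagged_pairs(speech, neural, lag, points)
        n = x.shape[0]
        cx0 = copula_normalise(x[:, 0])
        cx1 = copula_normalise(x[:, 1])
        cyr = rank_normalise_rows(yr)  # (P, n)
        cyi = rank_normalise_rows(yi)
        d = float(n - 1)

        # speech block and its inverse (shared across grid points)
        sxx = np.array(
            [[cx0 @ cx0, cx0 @ cx1], [cx1 @ cx0, cx1 @ cx1]]
        ) / d
        a, b, c = _inv2(sxx)

        # neural block, per point
        s_rr = np.einsum("pn,pn->p", cyr, cyr) / d
        s_ii = np.einsum("pn,pn->p", cyi, cyi) / d
        s_ri = np.einsum("pn,pn->p", cyr, cyi) / d
        det_sy = s_rr * s_ii - s_ri**2

        # cross-covariances speech-dim x neural-plane, per point
        c0r = cyr @ cx0 / d
        c0i = cyi @ cx0 / d
        c1r = cyr @ cx1 / d
        c1i = cyi @ cx1 / d

        # Schur complement Sy - C^T Sx^-1 C with Sx^-1 = [[a, b], [b, c]]
        m_rr = a * c0r**2 + 2 * b * c0r * c1r + c * c1r**2
        m_ii = a * c0i**2 + 2 * b * c0i * c1i + c * c1i**2
        m_ri = a * c0r * c0i + b * (c0r * c1i + c1r * c0i) + c * c1r * c1i
        det_schur = (s_rr - m_rr) * (s_ii - m_ii) - (s_ri - m_ri) ** 2
        if np.any(det_sy <= 0) or np.any(det_schur <= 0):
            raise ValueError("singular covariance block: collinear input")

        mi_bits = 0.5 * (np.log(det_sy) - np.log(det_schur)) / _LN2
        if bias_correct:
            mi_bits -= mi_bias_bits(2, 2, n)
        total += mi_bits
    return total


def _inv2(m: np.ndarray) -> tuple[float, float, float]:
    """Inverse of a symmetric 2x2 matrix as (a, b, c) = [[a, b], [b, c]]."""
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    if det <= 0:
        raise ValueError("singular covariance block: collinear input")
    return m[1, 1] / det, -m[0, 1] / det, m[0, 0] / det


# ---------------------------------------------------------------------------
# Surrogates


def _derangement(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random permutation of 0..n-1 with no fixed point (redrawn until so)."""
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def surrogate_shuffle(
    trials: AnalyticTrialSet,
    grid_point: int,
    lags_ms: list[float] | None = None,
    n_iter: int = 50,
    seed: int | np.random.Generator = 0,
    trial_idx: np.ndarray | None = None,
    bias_correct: bool = True,
) -> MIValue:
    """Trial-shuffled surrogate MI: mean over ``n_iter`` derangements.

    Each iteration permutes which speech trial is paired with which
    neural trial (never pairing a trial with itself); mismatched trial
    lengths are truncated to the shorter of the pair.  Averaging over
    many shuffles matters because the stimulus sentences share one
    rhythmic structure, so single shuffles retain chance dependence.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    speech, neural = _select_trials(trials, trial_idx)
    n = len(speech)
    if n < 3:
        raise ValueError("need >= 3 trials for shuffle surrogates")
    lags_ms = lag_grid() if lags_ms is None else lags_ms
    values = []
    for _ in range(n_iter):
        perm = _derangement(rng, n)
        pse, pne = [], []
        for i in range(n):
            s = speech[perm[i]]
            m = neural[i]
            t = min(s.shape[-1], m.shape[-1])
            pse.append(s[:t])
            pne.append(m[:, :t])
        shuffled = AnalyticTrialSet(
            speech=pse, neural=pne, labels=trials.labels, grid=trials.grid,
            band=trials.band, rate=trials.rate,
        )
        values.append(tracking_mi(shuffled, grid_point, lags_ms, bias_correct=bias_correct).bits)
    return MIValue(bits=float(np.mean(values)), n_obs=n, dims=(2, 2), bias_corrected=bias_correct)


def surrogate_timereverse(
    trials: AnalyticTrialSet,
    grid_point: int,
    lags_ms: list[float] | None = None,
    trial_idx: np.ndarray | None = None,
    bias_correct: bool = True,
) -> MIValue:
    """Time-reversal surrogate: forward brain series vs reversed speech.

    Because the zero-phase filter commutes with time reversal, the
    reversed-speech analytic signal is recomputed from the reversed
    real (filtered) series, and MI evaluated as usual.
    """
    speech, neural = _select_trials(trials, trial_idx)
    rev = [analytic(np.asarray(s.real, dtype=float)[::-1]).astype(np.complex64) for s in speech]
    reversed_set = AnalyticTrialSet(
        speech=rev, neural=neural, labels=trials.labels, grid=trials.grid,
        band=trials.band, rate=trials.rate,
    )
    return tracking_mi(reversed_set, grid_point, lags_ms, bias_correct=bias_correct)


def surrogate_shuffle_map(
    trials: AnalyticTrialSet,
    lags_ms: list[float] | None = None,
    n_iter: int = 50,
    seed: int | np.random.Generator = 0,
    trial_idx: np.ndarray | None = None,
    points: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorised trial-shuffle surrogate over the whole grid."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    speech, neural = _select_trials(trials, trial_idx)
    n = len(speech)
    if n < 3:
        raise ValueError("need >= 3 trials for shuffle surrogates")
    acc = None
    for _ in range(n_iter):
        perm = _derangement(rng, n)
        pse, pne = [], []
        for i in range(n):
            s, m = speech[perm[i]], neural[i]
            t = min(s.shape[-1], m.shape[-1])
            pse.append(s[:t])
            pne.append(m[:, :t])
        shuffled = AnalyticTrialSet(
            speech=pse, neural=pne, labels=trials.labels, grid=trials.grid,
            band=trials.band, rate=trials.rate,
        )
        vals = tracking_mi_map(shuffled, lags_ms, points=points)
        acc = vals if acc is None else acc + vals
    return acc / n_iter


# ---------------------------------------------------------------------------
# Correct / incorrect contrast


def subsample_size(n_correct: int, n_incorrect: int, frac: float = 0.8) -> int:
    """Equalised per-condition trial count: floor(frac x min of the two)."""
    return int(math.floor(frac * min(n_correct, n_incorrect)))


def condition_contrast(
    trials: AnalyticTrialSet,
    lags_ms: list[float] | None = None,
    frac: float = 0.8,
    n_repeats: int = 20,
    seed: int | np.random.Generator = 0,
    points: np.ndarray | None = None,
) -> tuple[MIMap, MIMap]:
    """Subsampled correct-vs-incorrect MI maps.

    Per repeat, an equal number of trials — floor(frac x the smaller
    condition count) — is drawn without replacement from each condition,
    MI maps computed per condition, and maps averaged over repeats.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lags_ms = lag_grid() if lags_ms is None else lags_ms
    idx_c = trials.label_indices(CORRECT)
    idx_i = trials.label_indices(INCORRECT)
    if idx_c.size < 5 or idx_i.size < 5:
        raise ValueError("need >= 5 trials per condition for the contrast")
    k = subsample_size(idx_c.size, idx_i.size, frac)
    sum_c = sum_i = 0.0
    for _ in range(n_repeats):
        sub_c = rng.choice(idx_c, size=k, replace=False)
        sub_i = rng.choice(idx_i, size=k, replace=False)
        sum_c = sum_c + tracking_mi_map(trials, lags_ms, trial_idx=sub_c, points=points)
        sum_i = sum_i + tracking_mi_map(trials, lags_ms, trial_idx=sub_i, points=points)
    mk = lambda vals, cond: MIMap(
        mi_bits=vals / n_repeats,
        band=trials.band,
        lags_ms=list(lags_ms),
        condition=cond,
        n_trials_used=k,
        n_repeats=n_repeats,
        grid=trials.grid,
    )
    return mk(sum_c, CORRECT), mk(sum_i, INCORRECT)


# ---------------------------------------------------------------------------
# I/O


def write_mimap(mimap: MIMap, path: str | Path) -> None:
    """Write a map as TSV (grid_index, x_mm, y_mm, z_mm, mi_bits) + JSON sidecar."""
    path = Path(path)
    grid = mimap.grid if mimap.grid is not None else np.full((mimap.mi_bits.size, 3), np.nan)
    df = pd.DataFrame(
        {
            "grid_index": np.arange(mimap.mi_bits.size),
            "x_mm": grid[:, 0],
            "y_mm": grid[:, 1],
            "z_mm": grid[:, 2],
            "mi_bits": mimap.mi_bits,
        }
    )
    df.to_csv(path, sep="\t", index=False)
    sidecar = {
        "band": {"name": mimap.band.name, "f_lo": mimap.band.f_lo, "f_hi": mimap.band.f_hi},
        "lags_ms": list(mimap.lags_ms),
        "condition": mimap.condition,
        "n_trials_used": int(mimap.n_trials_used),
        "n_repeats": int(mimap.n_repeats),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
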