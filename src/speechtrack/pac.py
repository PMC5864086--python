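"""Phase-amplitude coupling (PAC) via copula MI.

PAC asks whether the power of a fast rhythm depends on the phase of a
slow one.  Phase is represented as a unit-magnitude complex number
(two real dimensions, cosine and sine) from the analytic signal of the
phase band; power is the squared analytic magnitude of the power band
(one dimension).  Dependence is the 2-D x 1-D Gaussian-copula MI, which
makes the amplitude-vs-power choice immaterial (the copula step is
invariant to monotone marginal transforms).  The canonical pair couples
phrasal delta phase (0.6-1.3 Hz) to beta power (13-30 Hz); alpha, theta
and word-phase pairs serve as frequency controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._dsp import DEFAULT_FILTER_ORDER
from .infotheory import (
    MIValue,
    copula_normalise,
    gaussian_mi,
    mi_bias_bits,
    rank_normalise_rows,
)
from .speech_features import BandSpec
from .tracking import CORRECT, INCORRECT, TrialSet, bandpass_analytic, subsample_size

__all__ = [
    "PACResult",
    "PACTrialSet",
    "phase_power_mi",
    "prepare_pac",
    "pac_mi_map",
    "pac_condition_contrast",
    "pac_wholegrid_contrast",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class PACResult:
    """Region/condition-averaged PAC MI with provenance."""

    mi_bits: float
    phase_band: BandSpec
    power_band: BandSpec
    condition: str
    n_repeats: int

    def __post_init__(self):
        if self.phase_band.f_hi >= self.power_band.f_lo:
            raise ValueError("phase band must lie strictly below the power band")


@dataclass
class PACTrialSet:
    """Per-trial unit phasors (phase band) and power series (power band).

    Filtering and the Hilbert transform are done once per trial here so
    that repeated subsampling only re-ranks cached channels.
    """

    phasor: list[np.ndarray]  # complex64 (P, T) per trial, |z| = 1
    power: list[np.ndarray]  # float32 (P, T) per trial
    labels: np.ndarray
    grid: np.ndarray
    phase_band: BandSpec
    power_band: BandSpec
    rate: float = 150.0

    @property
    def n_trials(self) -> int:
        return len(self.phasor)

    @property
    def n_points(self) -> int:
        return self.grid.shape[0]


def phase_power_mi(
    neural: np.ndarray,
    phase_band: BandSpec,
    power_band: BandSpec,
    rate: float = 150.0,
    order: int = DEFAULT_FILTER_ORDER,
    edge_trim_s: float = 0.5,
    bias_correct: bool = True,
) -> MIValue:
    """PAC MI between slow-band phase and fast-band power of one series.

    The phase channel is the analytic signal of the phase-band-filtered
    series divided by its magnitude (unit phasor -> cos, sin columns);
    the power channel is the squared analytic magnitude of the
    power-band-filtered series.  Filter edges are trimmed before MI.
    """
    if phase_band.f_hi >= power_band.f_lo:
        raise ValueError("phase band must lie strictly below the power band")
    neural = np.asarray(neural, dtype=float)
    ph = bandpass_analytic(neural, phase_band, rate, order)
    pw = bandpass_analytic(neural, power_band, rate, order)
    trim = int(round(edge_trim_s * rate))
    if trim:
        if neural.shape[-1] <= 2 * trim:
            raise ValueError("series shorter than twice the edge trim")
        ph, pw = ph[..., trim:-trim], pw[..., trim:-trim]
    mag = np.abs(ph)
    if np.any(mag == 0):
        raise ValueError("degenerate phase: zero-magnitude analytic sample")
    phasor = ph / mag
    x = np.column_stack([phasor.real, phasor.imag])
    y = np.abs(pw) ** 2
    return gaussian_mi(copula_normalise(x), copula_normalise(y), bias_correct=bias_correct)


def prepare_pac(
    raw: TrialSet,
    phase_band: BandSpec,
    power_band: BandSpec,
    order: int = DEFAULT_FILTER_ORDER,
    edge_trim_s: float = 0.5,
) -> PACTrialSet:
    """Filter + Hilbert every trial into phase/power channels, edges trimmed."""
    if phase_band.f_hi >= power_band.f_lo:
        raise ValueError("phase band must lie strictly below the power band")
    trim = int(round(edge_trim_s * raw.rate))
    phasors, powers = [], []
    for m in raw.neural:
        if m.shape[-1] <= 2 * trim:
            raise ValueError("trial shorter than twice the edge trim")
        sl = slice(trim, m.shape[-1] - trim) if trim else slice(None)
        ph = bandpass_analytic(m, phase_band, raw.rate, order)[..., sl]
        pw = bandpass_analytic(m, power_band, raw.rate, order)[..., sl]
        mag = np.abs(ph)
        if np.any(mag == 0):
            raise ValueError("degenerate phase: zero-magnitude analytic sample")
        phasors.append((ph / mag).astype(np.complex64))
        powers.append((np.abs(pw) ** 2).astype(np.float32))
    return PACTrialSet(
        phasor=phasors, power=powers, labels=raw.labels.copy(), grid=raw.grid.copy(),
        phase_band=phase_band, power_band=power_band, rate=raw.rate,
    )


def pac_mi_map(
    pts: PACTrialSet,
    trial_idx: np.ndarray | None = None,
    points: np.ndarray | None = None,
    bias_correct: bool = True,
) -> np.ndarray:
    """Copula PAC MI (2-D phase x 1-D power) for many grid points at once.

    Trials are concatenated along time; the joint 3x3 determinant is
    evaluated per point via the Schur complement of the phase block.
    """
    points = np.arange(pts.n_points) if points is None else np.asarray(points)
    idx = np.arange(pts.n_trials) if trial_idx is None else np.asarray(trial_idx)
    phas = np.concatenate([pts.phasor[i][points] for i in idx], axis=-1)
    pows = np.concatenate([pts.power[i][points] for i in idx], axis=-1)
    n = phas.shape[-1]
    d = float(n - 1)
    cx0 = rank_normalise_rows(np.ascontiguousarray(phas.real))
    cx1 = rank_normalise_rows(np.ascontiguousarray(phas.imag))
    cy = rank_normalise_rows(pows)

    s00 = np.einsum("pn,pn->p", cx0, cx0) / d
    s11 = np.einsum("pn,pn->p", cx1, cx1) / d
    s01 = np.einsum("pn,pn->p", cx0, cx1) / d
    var_y = np.einsum("pn,pn->p", cy, cy) / d
    c0 = np.einsum("pn,pn->p", cx0, cy) / d
    c1 = np.einsum("pn,pn->p", cx1, cy) / d

    det_sx = s00 * s11 - s01**2
    # Schur complement of the phase block in the joint covariance
    quad = (s11 * c0**2 - 2 * s01 * c0 * c1 + s00 * c1**2) / det_sx
    resid = var_y - quad
    if np.any(det_sx <= 0) or np.any(resid <= 0):
        raise ValueError("singular covariance block: collinear input")
    mi_bits = 0.5 * (np.log(var_y) - np.log(resid)) / _LN2
    if bias_correct:
        mi_bits -= mi_bias_bits(2, 1, n)
    return mi_bits


def _label_pools(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    idx_c = np.flatnonzero(labels == CORRECT)
    idx_i = np.flatnonzero(labels == INCORRECT)
    if idx_c.size == 0 or idx_i.size == 0:
        raise ValueError("both correct and incorrect trials are required")
    return idx_c, idx_i


def pac_condition_contrast(
    raw: TrialSet | PACTrialSet,
    phase_band: BandSpec,
    power_band: BandSpec,
    region: np.ndarray,
    frac: float = 0.8,
    n_repeats: int = 50,
    seed: int | np.random.Generator = 0,
    order: int = DEFAULT_FILTER_ORDER,
    edge_trim_s: float = 0.5,
) -> tuple[PACResult, PACResult]:
    """Region-averaged PAC per condition at equalised trial counts.

    Per repeat and condition, floor(frac x smaller condition count)
    trials are drawn, concatenated, and PAC MI computed for every grid
    point in ``region``; results are averaged over grid points and
    repeats.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    region = np.asarray(region)
    if region.size == 0:
        raise ValueError("empty region")
    pts = (
        raw
        if isinstance(raw, PACTrialSet)
        else prepare_pac(raw, phase_band, power_band, order, edge_trim_s)
    )
    idx_c, idx_i = _label_pools(pts.labels)
    k = subsample_size(idx_c.size, idx_i.size, frac)
    if k < 1:
        raise ValueError("too few trials in the smaller condition")
    acc = {CORRECT: 0.0, INCORRECT: 0.0}
    for _ in range(n_repeats):
        for label, pool in ((CORRECT, idx_c), (INCORRECT, idx_i)):
            sub = rng.choice(pool, size=k, replace=False)
            acc[label] += float(np.mean(pac_mi_map(pts, trial_idx=sub, points=region)))
    mk = lambda label: PACResult(
        mi_bits=acc[label] / n_repeats,
        phase_band=phase_band,
        power_band=power_band,
        condition=label,
        n_repeats=n_repeats,
    )
    return mk(CORRECT), mk(INCORRECT)


def pac_wholegrid_contrast(
    raw: TrialSet | PACTrialSet,
    phase_band: BandSpec,
    power_band: BandSpec,
    frac: float = 0.8,
    n_repeats: int = 20,
    seed: int | np.random.Generator = 0,
    order: int = DEFAULT_FILTER_ORDER,
    edge_trim_s: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-grid-point repeat-averaged PAC for each condition.

    Returns (correct, incorrect) arrays of shape (n_points,), ready for
    a group-level paired t map and one-sided cluster statistics.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pts = (
        raw
        if isinstance(raw, PACTrialSet)
        else prepare_pac(raw, phase_band, power_band, order, edge_trim_s)
    )
    idx_c, idx_i = _label_pools(pts.labels)
    k = subsample_size(idx_c.size, idx_i.size, frac)
    out = {CORRECT: np.zeros(pts.n_points), INCORRECT: np.zeros(pts.n_points)}
    for _ in range(n_repeats):
        for label, pool in ((CORRECT, idx_c), (INCORRECT, idx_i)):
            sub = rng.choice(pool, size=k, replace=False)
            out[label] += pac_mi_map(pts, trial_idx=sub)
    return out[CORRECT] / n_repeats, out[INCORRECT] / n_repeats
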