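"""Shared filtering / analytic-signal helpers (internal)."""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

DEFAULT_FILTER_ORDER = 3


def butter_bandpass_sos(f_lo: float, f_hi: float, rate: float, order: int = DEFAULT_FILTER_ORDER):
    nyq = rate / 2.0
    if not 0 < f_lo < f_hi:
        raise ValueError(f"invalid band ({f_lo}, {f_hi})")
    if f_hi >= nyq:
        raise ValueError(f"band edge {f_hi} Hz at or above Nyquist ({nyq} Hz)")
    return butter(order, [f_lo / nyq, f_hi / nyq], btype="bandpass", output="sos")


def bandpass_zero_phase(
    x: np.ndarray, f_lo: float, f_hi: float, rate: float, order: int = DEFAULT_FILTER_ORDER
) -> np.ndarray:
    """Zero-phase (forward+reverse) Butterworth band-pass along the last axis."""
    sos = butter_bandpass_sos(f_lo, f_hi, rate, order)
    return sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def analytic(x: np.ndarray) -> np.ndarray:
    """Analytic (Hilbert) signal along the last axis."""
    return hilbert(np.asarray(x, dtype=float), axis=-1)
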