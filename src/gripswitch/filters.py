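"""Shared signal helpers: central differences and zero-phase low-pass."""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, filtfilt

__all__ = ["central_difference", "zero_phase_lowpass"]


def central_difference(x: np.ndarray, fs: float) -> np.ndarray:
    """Central-difference derivative, one-sided at the edges."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    d = np.empty_like(x)
    d[1:-1] = (x[2:] - x[:-2]) * (fs / 2.0)
    d[0] = (x[1] - x[0]) * fs
    d[-1] = (x[-1] - x[-2]) * fs
    return d


def zero_phase_lowpass(x: np.ndarray, fs: float, cutoff: float = 20.0,
                       order: int = 4) -> np.ndarray:
    """Forward-backward Butterworth low-pass (zero net phase shift).

    Edge transients are handled by odd-reflection padding, scipy's default
    for :func:`~scipy.signal.filtfilt`.
    """
    b, a = butter(order, cutoff / (fs / 2.0))
    return filtfilt(b, a, np.asarray(x, dtype=float))
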