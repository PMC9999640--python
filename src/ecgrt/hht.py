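"""Hilbert attributes of intrinsic mode functions.

The analytic signal of a well-formed IMF gives a meaningful instantaneous
amplitude and frequency at every sample; the amplitude-squared-weighted
mean frequency is the single number used to check that EMD components come
out ordered from fast to slow.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import hilbert

__all__ = ["instantaneous_attributes", "mean_frequency"]


def instantaneous_attributes(imf: np.ndarray, sampling_rate: float):
    """Instantaneous amplitude (mV) and frequency (Hz) along one IMF.

    Frequency is the phase derivative of the analytic signal, clipped to
    the physical band [0, Nyquist].  A zero IMF yields zero amplitude and,
    by convention, zero frequency.
    """
    x = np.asarray(imf, dtype=float)
    if not np.any(x):
        return np.zeros_like(x), np.zeros_like(x)
    analytic = hilbert(x)
    amplitude = np.abs(analytic)
    phase = np.unwrap(np.angle(analytic))
    freq = np.gradient(phase) * sampling_rate / (2.0 * np.pi)
    return amplitude, np.clip(freq, 0.0, sampling_rate / 2.0)


def mean_frequency(imf: np.ndarray, sampling_rate: float) -> float:
    """Amplitude^2-weighted mean instantaneous frequency; 0 for a zero IMF."""
    amplitude, freq = instantaneous_attributes(imf, sampling_rate)
    w = amplitude ** 2
    total = float(w.sum())
    if total == 0.0:
        return 0.0
    return float((w * freq).sum() / total)
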