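"""Zero-phase Butterworth filtering shared by the channel pipelines."""

from __future__ import annotations

import numpy as np
from scipy import signal

__all__ = ["zero_phase_bandpass", "zero_phase_lowpass"]


def zero_phase_bandpass(
    values: np.ndarray, rate: float, low: float, high: float, order: int = 4
) -> np.ndarray:
    """Bidirectional (forward-backward) Butterworth band-pass.

    ``order`` is the order of the underlying one-directional filter; the
    effective magnitude response is squared by the second pass.  ``high``
    at or above Nyquist degrades to a pure high-pass.
    """
    nyq = rate / 2.0
    x = np.asarray(values, dtype=float)
    if x.size < 3 * (order + 1) * 3:
        raise ValueError(
            "series too short for zero-phase filtering; pad or record longer"
        )
    if high >= nyq * 0.999:
        sos = signal.butter(order, low, btype="high", fs=rate, output="sos")
    else:
        sos = signal.butter(order, [low, high], btype="band", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, x)


def zero_phase_lowpass(
    values: np.ndarray, rate: float, cutoff: float, order: int = 4
) -> np.ndarray:
    nyq = rate / 2.0
    x = np.asarray(values, dtype=float)
    if cutoff >= nyq * 0.999:
        return x.copy()
    sos = signal.butter(order, cutoff, btype="low", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, x)
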