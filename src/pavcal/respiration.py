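"""Respiration-amplitude response (RAR) pipeline.

The belt signal is band-limited, respiration cycles are located at rising
zero-crossings, and each cycle contributes one peak-to-trough amplitude.
Cycle amplitudes are interpolated to a 10-Hz respiration-amplitude series,
band-pass filtered (0.01–2 Hz, zero-phase), and inverted with a
condition-wise convolution GLM using the respiration-amplitude gamma
kernel.  Like the heart-period response, the kernel outlasts the CS–US
interval, so only CS− and nonreinforced CS+ trials are analyzed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import glm
from .cardiac import with_nuisance_labels
from .design import CS_MINUS, CS_PLUS
from .filters import zero_phase_bandpass
from .response_functions import ResponseFunction, get_rf
from .segments import ConditionEstimates
from .timeseries import TimeSeries

__all__ = ["Cycles", "detect_cycles", "rar_timeseries", "estimate_rar_amplitudes"]

RAR_RATE = 10.0
RAR_BAND = (0.01, 2.0)
CYCLE_DURATION_RANGE = (1.0, 15.0)  # plausible breath durations, seconds


@dataclass
class Cycles:
    """Detected respiration cycles: onset/midpoint times and amplitudes."""

    onsets: np.ndarray     # rising zero-crossing opening each cycle
    midpoints: np.ndarray  # centre of each cycle (amplitude timestamp)
    amplitudes: np.ndarray  # peak-to-trough within the cycle, signal units
    peak_times: np.ndarray = None    # time of the within-cycle maximum
    trough_times: np.ndarray = None  # time of the within-cycle minimum


def detect_cycles(
    ts: TimeSeries,
    band: tuple = (0.05, 1.0),
    order: int = 2,
    duration_range: tuple = CYCLE_DURATION_RANGE,
    edge_margin_s: float = None,
) -> Cycles:
    """Zero-crossing cycle detection on the band-limited belt signal.

    Cycles with implausible durations are discarded, as are cycles lying
    within ``edge_margin_s`` of either recording edge, where the
    zero-phase band-pass has not settled and peak-to-trough amplitudes
    are unreliable; the default margin is one period of the high-pass
    corner.  Raises if no cycle is found (flat or disconnected belt).
    """
    if ts.rate < 10.0:
        raise ValueError("respiration signal must be sampled at >= 10 Hz")
    if edge_margin_s is None:
        edge_margin_s = 1.0 / band[0]
    x = zero_phase_bandpass(ts.values, ts.rate, band[0], band[1], order=order)
    sign = x > 0
    rising = np.flatnonzero(~sign[:-1] & sign[1:]) + 1
    if rising.size < 2:
        raise ValueError("no respiration cycles detected")
    t = ts.times()
    onsets, mids, amps, peaks, troughs = [], [], [], [], []
    for a, b in zip(rising[:-1], rising[1:]):
        dur = t[b] - t[a]
        if not duration_range[0] <= dur <= duration_range[1]:
            continue
        if t[a] < t[0] + edge_margin_s or t[b] > t[-1] - edge_margin_s:
            continue
        cyc = x[a:b]
        onsets.append(t[a])
        mids.append((t[a] + t[b]) / 2.0)
        amps.append(float(cyc.max() - cyc.min()))
        peaks.append(t[a + int(np.argmax(cyc))])
        troughs.append(t[a + int(np.argmin(cyc))])
    if not onsets:
        raise ValueError("no plausible respiration cycles detected")
    return Cycles(
        np.asarray(onsets),
        np.asarray(mids),
        np.asarray(amps),
        np.asarray(peaks),
        np.asarray(troughs),
    )


def rar_timeseries(
    cycles: Cycles,
    duration: float,
    rate: float = RAR_RATE,
    band: tuple = RAR_BAND,
    order: int = 2,
    start: float = 0.0,
) -> TimeSeries:
    """Interpolate cycle amplitudes to 10 Hz and band-pass filter.

    The series mean is removed before filtering: the tonic breathing
    amplitude dwarfs the evoked modulation, and pushing that offset
    through the low-cutoff high-pass would leave edge transients far
    larger than the signal of interest.
    """
    if cycles.amplitudes.size < 2:
        raise ValueError("need at least two cycles to build an amplitude series")
    n = int(np.floor((duration - start) * rate))
    grid = start + np.arange(n) / rate
    vals = np.interp(grid, cycles.midpoints, cycles.amplitudes)
    vals = vals - vals.mean()
    filtered = zero_phase_bandpass(vals, rate, band[0], band[1], order=order)
    return TimeSeries(filtered, rate, units="au", start=start)


def _rar_column_filter(rate: float, band=RAR_BAND, order=2):
    def f(col: np.ndarray) -> np.ndarray:
        return zero_phase_bandpass(col - col.mean(), rate, band[0], band[1], order=order)

    return f


def estimate_rar_amplitudes(
    ts: TimeSeries,
    events: pd.DataFrame,
    rf: ResponseFunction | str = "rarf_rew",
    intercept: bool = False,
    cycles: Cycles = None,
) -> ConditionEstimates:
    """Condition-wise convolution GLM on the respiration-amplitude series.

    One regressor per condition (nonreinforced CS+, CS−) plus a nuisance
    regressor for reinforced CS+ trials.  Regressors get the same
    zero-phase band-pass as the data; when ``cycles`` is given the
    observation operator is also mirrored — each predicted time course is
    reduced to one value per breath (the mean of its values at the
    cycle's peak and trough times, matching how a peak-to-trough
    amplitude samples the envelope) and linearly re-interpolated from the
    cycle midpoints, exactly as the data series was, so the once-per-
    breath sampling of the envelope does not attenuate the amplitude
    estimates.  By default this analysis is run for the learning phase
    only (mirroring the reference analysis); recall-phase input is
    accepted but is the caller's choice.
    """
    if isinstance(rf, str):
        rf = get_rf(rf)
    grid = ts.times()
    base_filter = _rar_column_filter(ts.rate)

    def column_filter(col: np.ndarray) -> np.ndarray:
        if cycles is not None:
            if cycles.peak_times is not None and cycles.trough_times is not None:
                per_cycle = 0.5 * (
                    np.interp(cycles.peak_times, grid, col)
                    + np.interp(cycles.trough_times, grid, col)
                )
            else:
                per_cycle = np.interp(cycles.midpoints, grid, col)
            col = np.interp(grid, cycles.midpoints, per_cycle)
        return base_filter(col)

    X = glm.build_design(
        with_nuisance_labels(events),
        rf,
        rate=ts.rate,
        n_samples=ts.n,
        mode="condition",
        intercept=intercept,
        column_filter=column_filter,
        start=ts.start,
    )
    res = glm.invert(ts, X)
    amps = {n: b for n, b in zip(res.names, res.betas) if n in (CS_PLUS, CS_MINUS)}
    return ConditionEstimates(amps, res)
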