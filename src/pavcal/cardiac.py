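"""Heart-period response (HPR) pipeline: beats → filtered series → amplitudes.

Conditioned bradycardia is quantified on heart period (the inter-beat
interval, IBI), not heart rate, because heart period relates linearly to
autonomic input in stimulation studies.  Beat timestamps are converted to
an IBI sequence, implausible intervals (rate outside 50–150 bpm) are
excluded and bridged, the remainder is linearly interpolated at 100 Hz in
chronological time, band-pass filtered (0.015–0.5 Hz, 4th-order
zero-phase Butterworth), and inverted with a condition-wise convolution
GLM using the reward heart-period kernel.  Because the kernel outlasts
the CS–US interval, only CS− trials and nonreinforced CS+ trials enter
the analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import glm
from .design import CS_MINUS, CS_PLUS
from .filters import zero_phase_bandpass
from .response_functions import EmpiricalRFParams, ResponseFunction
from .segments import ConditionEstimates, Segments
from .timeseries import TimeSeries

__all__ = [
    "IBISeries",
    "beats_to_ibi",
    "interpolate_and_filter",
    "extract_segments",
    "condition_mean_difference",
    "estimate_condition_amplitudes",
    "retained_trials_hpr",
]

BPM_MIN, BPM_MAX = 50.0, 150.0
HP_RATE = 100.0  # Hz
BAND = (0.015, 0.5)  # Hz
FILTER_ORDER = 4
MAX_GAP_S = 5.0  # invalid stretches longer than this are flagged missing


@dataclass
class IBISeries:
    """Inter-beat intervals with a plausibility mask.

    ``ibis[k]`` is the interval preceding ``beat_times[k+1]``; ``valid``
    is False where the implied heart rate falls outside 50–150 bpm.
    """

    beat_times: np.ndarray  # all beats, length n
    ibis: np.ndarray        # length n - 1, seconds
    valid: np.ndarray       # length n - 1

    @property
    def ibi_times(self) -> np.ndarray:
        """Timestamp of each interval (the beat that closes it)."""
        return self.beat_times[1:]


def beats_to_ibi(beat_times: Sequence[float]) -> IBISeries:
    """Compute preceding inter-beat intervals and apply the range filter."""
    bt = np.asarray(beat_times, dtype=float)
    if bt.size < 2:
        raise ValueError("need at least two beats")
    if np.any(np.diff(bt) <= 0):
        raise ValueError("beat timestamps must be strictly increasing")
    ibis = np.diff(bt)
    bpm = 60.0 / ibis
    valid = (bpm >= BPM_MIN) & (bpm <= BPM_MAX)
    return IBISeries(bt, ibis, valid)


def interpolate_and_filter(
    ibi: IBISeries,
    duration: Optional[float] = None,
    rate: float = HP_RATE,
    band: tuple = BAND,
    order: int = FILTER_ORDER,
) -> TimeSeries:
    """Grid the valid IBIs at 100 Hz and band-pass to the HPR band.

    Output units are milliseconds.  Invalid IBIs are bridged by linear
    interpolation between neighbouring valid intervals; stretches without
    a valid interval for more than 5 s are additionally flagged in the
    missing mask (values are still interpolated so the zero-phase filter
    has a gap-free input).
    """
    t = ibi.ibi_times[ibi.valid]
    v = ibi.ibis[ibi.valid]
    if t.size < 2:
        raise ValueError("need at least two valid inter-beat intervals")
    if duration is None:
        duration = float(ibi.beat_times[-1])
    n = int(np.floor(duration * rate)) + 1
    grid = np.arange(n) / rate
    hp = np.interp(grid, t, v) * 1000.0  # ms
    filtered = zero_phase_bandpass(hp, rate, band[0], band[1], order=order)

    missing = np.zeros(n, dtype=bool)
    gaps = np.flatnonzero(np.diff(t) > MAX_GAP_S)
    for g in gaps:
        missing |= (grid > t[g]) & (grid < t[g + 1])
    missing |= grid < t[0]
    missing |= grid > t[-1]
    return TimeSeries(filtered, rate, units="ms", missing=missing)


def retained_trials_hpr(events: pd.DataFrame) -> np.ndarray:
    """Trial indices entering HPR analysis: CS− and nonreinforced CS+."""
    keep = (events["condition"] == CS_MINUS) | (
        (events["condition"] == CS_PLUS) & (~events["reinforced"].astype(bool))
    )
    return events.loc[keep, "trial_index"].to_numpy()


def extract_segments(
    ts: TimeSeries,
    events: pd.DataFrame,
    window: float = 25.0,
    baseline_window: float = 5.0,
) -> Segments:
    """Peri-CS segments, baseline-corrected by the pre-CS mean.

    Each retained trial contributes ``[onset, onset + window)`` minus the
    mean over ``[onset - baseline_window, onset)``.  Trials whose window
    leaves the recording are kept but filled with NaN.
    """
    retained = retained_trials_hpr(events)
    tbl = events[events["trial_index"].isin(retained)].reset_index(drop=True)
    n_samp = int(round(window * ts.rate))
    n_base = int(round(baseline_window * ts.rate))
    t_rel = np.arange(n_samp) / ts.rate
    data = np.full((len(tbl), n_samp), np.nan)
    for i, row in tbl.iterrows():
        k = int(round((row["cs_onset"] - ts.start) * ts.rate))
        if k - n_base < 0 or k + n_samp > ts.n:
            warnings.warn(
                f"trial {int(row['trial_index'])} window exceeds recording; flagged missing"
            )
            continue
        seg = ts.values[k : k + n_samp].copy()
        seg[ts.missing[k : k + n_samp]] = np.nan
        base = ts.values[k - n_base : k]
        base_mask = ts.missing[k - n_base : k]
        base = base[~base_mask]
        if base.size == 0:
            continue
        data[i] = seg - base.mean()
    return Segments(data, t_rel, tbl)


def condition_mean_difference(
    participant_segments: Sequence[Segments], rate: float = HP_RATE
) -> EmpiricalRFParams:
    """Grand-mean CS+ − CS− waveform across participants.

    Averaging is within condition within participant first, then across
    participants; participants missing one condition entirely are dropped
    with a warning.
    """
    plus, minus = [], []
    t = participant_segments[0].t
    for i, segs in enumerate(participant_segments):
        means = segs.condition_means()
        if CS_PLUS not in means or CS_MINUS not in means:
            warnings.warn(f"participant {i} lacks a condition; dropped from grand mean")
            continue
        plus.append(means[CS_PLUS])
        minus.append(means[CS_MINUS])
    if not plus:
        raise ValueError("no participant contributes both conditions")
    diff = np.nanmean(np.asarray(plus), axis=0) - np.nanmean(np.asarray(minus), axis=0)
    return EmpiricalRFParams(t, diff, provenance="grand mean CS+ - CS- difference")


def _hpr_column_filter(rate: float, band=BAND, order=FILTER_ORDER):
    def f(col: np.ndarray) -> np.ndarray:
        return zero_phase_bandpass(col, rate, band[0], band[1], order=order)

    return f


def with_nuisance_labels(events: pd.DataFrame) -> pd.DataFrame:
    """Relabel reinforced CS+ trials as a nuisance condition.

    Reinforced CS+ trials are excluded from the reported estimates, but
    their responses still overlap temporally with retained trials when
    the kernel outlasts the inter-trial interval; modelling them as a
    separate regressor keeps them from biasing the CS+/CS− amplitudes.
    """
    tbl = events.copy()
    nuis = (tbl["condition"] == CS_PLUS) & tbl["reinforced"].astype(bool)
    tbl.loc[nuis, "condition"] = "CS+reinforced"
    return tbl


def estimate_condition_amplitudes(
    ts: TimeSeries,
    events: pd.DataFrame,
    rf: ResponseFunction,
    intercept: bool = False,
    ibi: Optional[IBISeries] = None,
) -> ConditionEstimates:
    """Condition-wise convolution GLM on the filtered heart-period series.

    One regressor per condition (nonreinforced CS+, CS−) plus a nuisance
    regressor for reinforced CS+ trials.  Regressor columns receive the
    same zero-phase band-pass as the data.  When the originating
    ``ibi`` series is supplied, the beat-sampling observation operator is
    mirrored as well: each predicted time course is averaged over the
    inter-beat intervals and re-interpolated, exactly as the heart-period
    data were constructed, so the once-per-beat sampling does not
    attenuate the amplitude estimates.  The intercept is optional because
    the band-passed series is already zero-mean.
    """
    grid = ts.times()
    base_filter = _hpr_column_filter(ts.rate)
    if ibi is not None:
        beat_t = ibi.ibi_times[ibi.valid]

        def column_filter(col: np.ndarray) -> np.ndarray:
            integral = np.concatenate([[0.0], np.cumsum(col)]) / ts.rate
            at_beats = np.interp(beat_t, grid, integral[1:])
            avg = np.diff(np.concatenate([[0.0], at_beats])) / np.diff(
                np.concatenate([[grid[0]], beat_t])
            )
            return base_filter(np.interp(grid, beat_t, avg))

    else:
        column_filter = base_filter

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
    amps = {
        n: b
        for n, b in zip(res.names, res.betas)
        if n in (CS_PLUS, CS_MINUS)
    }
    return ConditionEstimates(amps, res)
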