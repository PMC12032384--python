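"""Pupil-size response (PSR) pipeline: preprocessing, model-based and
peak-scored trial amplitudes, and the pupil-specific exclusion rules.

Preprocessing removes implausible samples (diameter outside a biological
range, excessive time-derivative by a median-absolute-deviation speed
criterion, isolated samples, gap edges), removes samples with gaze more
than 5° visual angle from screen centre, applies a first-order cosine
correction for the pupil foreshortening error, interpolates, low-passes
at 50 Hz, resamples to 100 Hz, and z-scores each block.  Trial-wise
amplitudes are estimated by projecting baseline-corrected peri-CS
segments onto a response kernel (RF1–RF6); two peak-scoring baselines
with different windows are provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .design import CS_MINUS, CS_PLUS
from .filters import zero_phase_lowpass
from .glm import trialwise_amplitude_from_segment
from .response_functions import ResponseFunction, get_rf
from .segments import Segments
from .timeseries import TimeSeries

__all__ = [
    "PupilPreprocSpec",
    "PupilExclusionSpec",
    "preprocess_pupil",
    "extract_pupil_segments",
    "psr_amplitudes",
    "peak_score",
    "apply_pupil_exclusions",
]


@dataclass(frozen=True)
class PupilPreprocSpec:
    gaze_limit_deg: float = 5.0
    lowpass_hz: float = 50.0
    out_rate: float = 100.0
    plausible_range_mm: Tuple[float, float] = (1.5, 9.0)
    speed_mad_multiplier: float = 16.0  # MAD-based dilation-speed criterion
    speed_floor_mm_s: float = 1.0  # absolute floor on the speed threshold
    gap_edge_trim_s: float = 0.04
    zscore: bool = True
    sd_floor: float = 1e-6


@dataclass(frozen=True)
class PupilExclusionSpec:
    max_abs_estimate_mm: float = 6.0
    max_missing_fraction_per_trial: float = 0.5
    max_excluded_trials_fraction: float = 0.5


def _speed_outliers(
    v: np.ndarray, rate: float, multiplier: float, floor: float = 1.0
) -> np.ndarray:
    """Dilation-speed filter: flag samples whose neighbouring-sample speed
    exceeds median + multiplier * MAD of the speed distribution.

    The threshold never drops below ``floor`` (mm/s): physiological pupil
    dilation stays well under 1 mm/s while blink and tracking artifacts
    produce speeds orders of magnitude higher, so the floor keeps the
    adaptive criterion from flagging genuine signal when a recording is
    so clean that the MAD collapses toward zero."""
    d = np.abs(np.diff(v)) * rate
    speed = np.zeros_like(v)
    speed[1:-1] = np.maximum(d[:-1], d[1:])
    speed[0], speed[-1] = d[0], d[-1]
    finite = np.isfinite(speed)
    if not finite.any():
        return np.zeros_like(v, dtype=bool)
    med = np.nanmedian(speed[finite])
    mad = np.nanmedian(np.abs(speed[finite] - med))
    thresh = max(med + multiplier * mad, floor)
    return speed > thresh


def _trim_gap_edges(bad: np.ndarray, n_trim: int) -> np.ndarray:
    """Also mark ``n_trim`` samples on each side of every missing span."""
    if n_trim <= 0 or not bad.any():
        return bad
    out = bad.copy()
    idx = np.flatnonzero(bad)
    for k in range(1, n_trim + 1):
        out[np.clip(idx - k, 0, bad.size - 1)] = True
        out[np.clip(idx + k, 0, bad.size - 1)] = True
    return out


def _block_spans(events: Optional[pd.DataFrame], ts: TimeSeries) -> list:
    """Session partition into blocks, split midway between blocks."""
    if events is None or "block" not in events:
        return [(ts.start, ts.end)]
    spans = []
    blocks = sorted(events["block"].unique())
    edges = [ts.start]
    for b0, b1 in zip(blocks[:-1], blocks[1:]):
        last = events.loc[events["block"] == b0, "cs_onset"].max()
        first = events.loc[events["block"] == b1, "cs_onset"].min()
        edges.append((last + first) / 2.0)
    edges.append(ts.end + 1.0 / ts.rate)
    for lo, hi in zip(edges[:-1], edges[1:]):
        spans.append((lo, hi))
    return spans


def preprocess_pupil(
    pupil: TimeSeries,
    gaze_x: np.ndarray,
    gaze_y: np.ndarray,
    events: Optional[pd.DataFrame] = None,
    spec: PupilPreprocSpec = PupilPreprocSpec(),
) -> TimeSeries:
    """Validity filtering, gaze gating, foreshortening correction,
    filtering, resampling to 100 Hz, and per-block z-scoring.

    ``gaze_x``/``gaze_y`` are degrees visual angle from screen centre.
    With ``spec.zscore`` false the output stays in millimetres (used for
    amplitude-recovery checks); z-scoring divides each block by its own
    SD and is the default for real analyses.
    """
    v = pupil.values.copy()
    rate = pupil.rate
    bad = pupil.missing.copy()
    lo, hi = spec.plausible_range_mm
    bad |= (v < lo) | (v > hi)
    bad |= _speed_outliers(
        np.where(bad, np.nan, v), rate, spec.speed_mad_multiplier, spec.speed_floor_mm_s
    )
    # isolated valid samples between missing neighbours are unreliable
    if v.size >= 3:
        isolated = ~bad & np.roll(bad, 1) & np.roll(bad, -1)
        isolated[[0, -1]] = False
        bad |= isolated
    bad = _trim_gap_edges(bad, int(round(spec.gap_edge_trim_s * rate)))

    gaze_dev = np.hypot(np.asarray(gaze_x, float), np.asarray(gaze_y, float))
    bad |= gaze_dev > spec.gaze_limit_deg
    if bad.all():
        raise ValueError("pupil channel entirely missing after validity filtering")

    # first-order geometric foreshortening correction: the camera sees the
    # pupil ellipse minor axis shrink with cos of the gaze deviation
    corr = v / np.cos(np.deg2rad(np.clip(gaze_dev, 0.0, 60.0)))
    work = TimeSeries(corr, rate, "mm", pupil.start, bad).interpolate_missing()
    filtered = zero_phase_lowpass(work.values, rate, spec.lowpass_hz)

    # resample to the output rate
    n_out = int(np.floor(work.duration * spec.out_rate))
    t_out = pupil.start + np.arange(n_out) / spec.out_rate
    t_in = work.times()
    out_vals = np.interp(t_out, t_in, filtered)
    out_bad = np.interp(t_out, t_in, bad.astype(float)) > 0.5
    out = TimeSeries(out_vals, spec.out_rate, "mm", pupil.start, out_bad)

    if spec.zscore:
        for t_lo, t_hi in _block_spans(events, out):
            i = out.index_at(t_lo)
            j = out.index_at(t_hi - 0.5 / out.rate) + 1
            chunk = out.values[i:j]
            keep = ~out.missing[i:j]
            mu = chunk[keep].mean()
            sd = chunk[keep].std(ddof=0)
            if sd < spec.sd_floor:
                import warnings

                warnings.warn("pupil block has (near-)zero variance; z-scoring by SD floor")
                sd = spec.sd_floor
            out.values[i:j] = (chunk - mu) / sd
        out.units = "z"
    return out


def _retained_for_rf(events: pd.DataFrame, rf_name: str) -> pd.DataFrame:
    """RF1 outlasts the CS–US interval: drop reinforced CS+ trials.
    RF2–RF6 finish before US onset: keep all trials."""
    if rf_name == "psr_rf1":
        keep = (events["condition"] == CS_MINUS) | (
            (events["condition"] == CS_PLUS) & (~events["reinforced"].astype(bool))
        )
        return events[keep].reset_index(drop=True)
    return events.reset_index(drop=True)


def extract_pupil_segments(
    ts: TimeSeries,
    events: pd.DataFrame,
    rf: ResponseFunction | str,
    baseline_s: float = 1.0,
) -> Segments:
    """Per-trial segments over the kernel's extraction window.

    Segments are baseline-corrected by the mean over the ``baseline_s``
    pre-CS period so the subsequent single-regressor projection is
    offset-free.  The per-trial fraction of missing samples is recorded
    in the metadata (``missing_fraction``).
    """
    if isinstance(rf, str):
        rf = get_rf(rf)
    if rf.window is None:
        raise ValueError(f"kernel {rf.name} has no extraction window")
    tbl = _retained_for_rf(events, rf.name)
    n_samp = int(round(rf.window * ts.rate))
    n_base = int(round(baseline_s * ts.rate))
    t_rel = np.arange(n_samp) / ts.rate
    data = np.full((len(tbl), n_samp), np.nan)
    missing_frac = np.ones(len(tbl))
    for i, row in tbl.iterrows():
        k = int(round((row["cs_onset"] - ts.start) * ts.rate))
        if k - n_base < 0 or k + n_samp > ts.n:
            continue
        seg = ts.values[k : k + n_samp].copy()
        segbad = ts.missing[k : k + n_samp]
        seg[segbad] = np.nan
        base = ts.values[k - n_base : k][~ts.missing[k - n_base : k]]
        missing_frac[i] = segbad.mean()
        if base.size == 0:
            data[i] = np.nan  # unavailable baseline: trial missing
            missing_frac[i] = 1.0
            continue
        data[i] = seg - base.mean()
    meta = tbl.copy()
    meta["missing_fraction"] = missing_frac
    return Segments(data, t_rel, meta)


def psr_amplitudes(segments: Segments, rf: ResponseFunction | str) -> pd.DataFrame:
    """Trial-wise kernel-projection amplitudes (model-based scoring)."""
    if isinstance(rf, str):
        rf = get_rf(rf)
    rf_vals = rf.normalized().evaluate(segments.t)
    amps = np.array(
        [trialwise_amplitude_from_segment(seg, rf_vals) for seg in segments.data]
    )
    out = segments.meta.copy()
    out["amplitude"] = amps
    out["retained"] = np.isfinite(amps)
    return out


def peak_score(
    ts: TimeSeries,
    events: pd.DataFrame,
    method: str = "finke",
    soa: float = 5.0,
) -> pd.DataFrame:
    """Baseline-corrected maximum dilation per trial.

    ``method='finke'``: baseline = mean over the 1 s before CS onset,
    peak = maximum from CS onset to US onset (0–SOA).
    ``method='pietrock'``: baseline = mean over the 2 s before CS onset,
    peak = maximum during the final second before US onset (SOA−1 to SOA).
    Trials with an all-missing baseline are marked missing.
    """
    if method == "finke":
        base_win, peak_win = 1.0, (0.0, soa)
    elif method == "pietrock":
        base_win, peak_win = 2.0, (soa - 1.0, soa)
    else:
        raise ValueError(f"unknown peak-scoring method {method!r}")
    rows = []
    for _, ev in events.iterrows():
        onset = float(ev["cs_onset"])
        base = ts.slice(onset - base_win, onset)
        peak = ts.slice(onset + peak_win[0], onset + peak_win[1])
        bvals = base.values[~base.missing]
        pvals = peak.values[~peak.missing]
        if bvals.size == 0 or pvals.size == 0:
            score = np.nan
        else:
            score = float(pvals.max() - bvals.mean())
        rows.append(
            {
                "trial_index": int(ev["trial_index"]),
                "condition": ev["condition"],
                "reinforced": bool(ev["reinforced"]),
                "amplitude": score,
                "missing_fraction": float(peak.missing.mean()) if peak.n else 1.0,
                "retained": np.isfinite(score),
            }
        )
    return pd.DataFrame(rows)


def apply_pupil_exclusions(
    estimates: pd.DataFrame, spec: PupilExclusionSpec = PupilExclusionSpec()
) -> Tuple[pd.DataFrame, bool]:
    """Trial- and participant-level exclusion rules.

    Trials are dropped when the amplitude magnitude exceeds ±6 mm or more
    than half the trial's samples are missing; the participant is flagged
    for exclusion when more than half of their trials were dropped.
    Returns ``(retained_trials, participant_excluded)``.
    """
    est = estimates.copy()
    n_total = len(est)
    if n_total == 0:
        raise ValueError("no trial estimates to filter")
    bad = ~np.isfinite(est["amplitude"].to_numpy(dtype=float))
    bad |= np.abs(est["amplitude"].to_numpy(dtype=float)) > spec.max_abs_estimate_mm
    if "missing_fraction" in est:
        bad |= est["missing_fraction"].to_numpy(dtype=float) > spec.max_missing_fraction_per_trial
    kept = est[~bad].reset_index(drop=True)
    participant_excluded = (n_total - len(kept)) / n_total > spec.max_excluded_trials_fraction
    return kept, participant_excluded
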