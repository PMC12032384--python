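"""Skin-conductance response (SCR) pipeline.

Preprocessing marks implausible samples missing (outside 0.05–100 μS, or
absolute slope above 10 μS/s), interpolates them for filtering, applies a
bidirectional 1st-order Butterworth band-pass (0.0159–5 Hz), and
downsamples to 10 Hz.  Trial-wise conditioned and unconditioned response
amplitudes are then estimated with a constrained convolution GLM: one
regressor per trial locked to CS onset and one locked to US delivery /
US omission (CS onset + SOA), both using a canonical bi-exponential SCR
kernel (``estimator=constrained_glm``; this is a linear approximation of
the variational estimator used in the original analysis).  Amplitudes are
normalized per participant by the mean over all CS− trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d

from . import glm
from .design import CS_MINUS
from .filters import zero_phase_bandpass
from .response_functions import ResponseFunction, scr_kernel
from .timeseries import TimeSeries

__all__ = [
    "SCRPreprocSpec",
    "preprocess_scr",
    "estimate_scr_trial_amplitudes",
    "normalize_by_csminus",
]


@dataclass(frozen=True)
class SCRPreprocSpec:
    valid_min: float = 0.05     # μS
    valid_max: float = 100.0    # μS
    max_abs_slope: float = 10.0  # μS/s
    band: tuple = (0.0159, 5.0)  # Hz
    filter_order: int = 1
    out_rate: float = 10.0      # Hz
    max_missing_fraction: float = 0.9


def preprocess_scr(ts: TimeSeries, spec: SCRPreprocSpec = SCRPreprocSpec()) -> TimeSeries:
    """Range/slope artifact rejection, band-pass, downsample to 10 Hz."""
    if ts.rate < spec.out_rate:
        raise ValueError(f"SCR input rate must be >= {spec.out_rate} Hz")
    v = ts.values
    bad = ts.missing | (v < spec.valid_min) | (v > spec.valid_max)
    slope = np.abs(np.gradient(v, 1.0 / ts.rate))
    bad |= slope > spec.max_abs_slope
    if bad.mean() > spec.max_missing_fraction:
        raise ValueError(
            f"{bad.mean():.0%} of SCR samples invalid; channel unusable"
        )
    work = TimeSeries(v, ts.rate, ts.units, ts.start, bad).interpolate_missing()
    filtered = zero_phase_bandpass(
        work.values, ts.rate, spec.band[0], spec.band[1], order=spec.filter_order
    )
    # resample onto the 10-Hz grid (band already limited below Nyquist)
    n_out = int(np.floor(work.duration * spec.out_rate))
    t_out = ts.start + np.arange(n_out) / spec.out_rate
    t_in = work.times()
    out_vals = np.interp(t_out, t_in, filtered)
    # an output sample is missing if any rejected input sample lies within
    # one output period of it; dilate before point-sampling so narrow
    # artifacts cannot fall between output grid points
    width = max(1, int(round(ts.rate / spec.out_rate))) + 1
    bad_dilated = maximum_filter1d(bad.astype(float), size=width)
    out_missing = np.interp(t_out, t_in, bad_dilated) > 0.5
    return TimeSeries(out_vals, spec.out_rate, units="uS", start=ts.start, missing=out_missing)


def _scr_column_filter(rate: float, spec: SCRPreprocSpec):
    def f(col: np.ndarray) -> np.ndarray:
        return zero_phase_bandpass(col, rate, spec.band[0], spec.band[1], order=spec.filter_order)

    return f


def estimate_scr_trial_amplitudes(
    ts: TimeSeries,
    events: pd.DataFrame,
    kernel: ResponseFunction = None,
    spec: SCRPreprocSpec = SCRPreprocSpec(),
    soa: float = 5.0,
) -> pd.DataFrame:
    """Per-trial CS and US/omission amplitudes via a full-session GLM.

    Returns a DataFrame with one row per trial: ``trial_index, condition,
    reinforced, cs_amplitude, us_amplitude, retained, estimator``.
    Amplitudes are in the kernel's units (μS for the unit-peak canonical
    kernel) and are not yet CS−-normalized.
    """
    if kernel is None:
        kernel = scr_kernel()
    # US/omission events are modelled as impulses at cs_onset + soa; build
    # a shifted event table so both regressor sets share build_design.
    us_events = events.copy()
    us_events["cs_onset"] = us_events["cs_onset"] + soa

    col_filter = _scr_column_filter(ts.rate, spec)
    X_cs = glm.build_design(
        events, kernel, ts.rate, ts.n, mode="trial", intercept=False,
        column_filter=col_filter, start=ts.start,
    )
    X_us = glm.build_design(
        us_events, kernel, ts.rate, ts.n, mode="trial", intercept=False,
        column_filter=col_filter, start=ts.start,
    )
    names = (
        [f"cs_{n}" for n in X_cs.names]
        + [f"us_{n}" for n in X_us.names]
        + ["intercept"]
    )
    X = glm.DesignMatrix(
        np.column_stack([X_cs.X, X_us.X, np.ones(ts.n)]), names, ts.rate, True
    )
    res = glm.invert(ts, X)

    rows = []
    for _, ev in events.iterrows():
        ti = int(ev["trial_index"])
        rows.append(
            {
                "trial_index": ti,
                "condition": ev["condition"],
                "reinforced": bool(ev["reinforced"]),
                "cs_amplitude": res[f"cs_trial_{ti}"],
                "us_amplitude": res[f"us_trial_{ti}"],
                "retained": True,
                "estimator": "constrained_glm",
            }
        )
    return pd.DataFrame(rows)


def normalize_by_csminus(est: pd.DataFrame) -> pd.DataFrame:
    """Divide all amplitudes by the participant's mean CS− amplitude.

    If the CS− mean is non-positive the division is skipped and the
    frame is flagged (``normalized=False``) with a warning, since a
    non-positive denominator would flip or explode the estimates.
    """
    out = est.copy()
    cs_minus = out.loc[(out["condition"] == CS_MINUS) & out["retained"], "cs_amplitude"]
    if len(cs_minus) == 0:
        raise ValueError("no valid CS- trial to normalize by")
    denom = float(cs_minus.mean())
    if denom <= 0:
        warnings.warn(
            f"CS- mean amplitude {denom:.4g} is not positive; normalization skipped"
        )
        out.attrs["normalized"] = False
        return out
    out["cs_amplitude"] = out["cs_amplitude"] / denom
    out["us_amplitude"] = out["us_amplitude"] / denom
    out.attrs["normalized"] = True
    return out
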