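"""Convolution design matrices and ordinary least-squares inversion.

The channel models are linear time-invariant: a unit impulse at each event
onset, convolved with the channel's response function, predicts the event's
contribution to the recorded series.  Stacking one such regressor per
condition (condition-wise mode) or per retained trial (trial-wise mode)
gives a design matrix; ordinary least squares then returns one amplitude
estimate per regressor.

When the data series has been band-pass filtered, the same zero-phase
filter must be applied to the regressors (pass ``column_filter``); with
matching filtering, noiseless data in the column span are recovered
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .response_functions import ResponseFunction
from .timeseries import TimeSeries

__all__ = [
    "DesignMatrix",
    "GLMResult",
    "build_design",
    "invert",
    "trialwise_amplitude_from_segment",
    "RankDeficientError",
]

# relative condition-number ceiling above which inversion refuses to proceed
_MAX_CONDITION = 1e10


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix is (numerically) rank deficient."""


@dataclass
class DesignMatrix:
    X: np.ndarray  # (n_samples, n_regressors)
    names: List[str]
    rate: float
    has_intercept: bool
    condition_number: float = field(init=False)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.names):
            raise ValueError("design matrix shape does not match regressor names")
        self.condition_number = float(np.linalg.cond(self.X))

    @property
    def n_regressors(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.names)


@dataclass
class GLMResult:
    betas: np.ndarray
    names: List[str]
    residual_variance: float
    r_squared: float
    dof: int

    def __getitem__(self, name: str) -> float:
        return float(self.betas[self.names.index(name)])

    def amplitudes(self) -> dict:
        return {n: float(b) for n, b in zip(self.names, self.betas)}


def build_design(
    events: pd.DataFrame,
    rf: ResponseFunction,
    rate: float,
    n_samples: int,
    mode: str = "condition",
    retained_trials: Optional[Sequence[int]] = None,
    intercept: bool = True,
    column_filter: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    start: float = 0.0,
) -> DesignMatrix:
    """Convolve unit impulses at CS onsets with ``rf`` into regressors.

    ``mode='condition'`` builds one regressor per condition label present
    among the retained trials; ``mode='trial'`` builds one per retained
    trial.  ``retained_trials`` selects rows by ``trial_index`` (default:
    all).  ``column_filter`` is applied to every convolution column (not
    the intercept) so the design matches filtered data.
    """
    if mode not in ("condition", "trial"):
        raise ValueError(f"mode must be 'condition' or 'trial', got {mode!r}")
    tbl = events
    if retained_trials is not None:
        tbl = events[events["trial_index"].isin(list(retained_trials))]
    if len(tbl) == 0:
        raise ValueError("no retained trials to build a design from")

    kernel = rf.sample(rate)
    kernel_offset = int(round(max(rf.support[0], 0.0) * rate))

    def impulse_column(onsets: np.ndarray) -> np.ndarray:
        col = np.zeros(n_samples)
        stick = np.zeros(n_samples)
        for t in onsets:
            k = int(round((t - start) * rate))
            if 0 <= k < n_samples:
                stick[k] = 1.0
        full = np.convolve(stick, kernel)
        col = full[:n_samples].copy()
        if kernel_offset:  # causal part starting at support[0] > 0
            col = np.roll(col, kernel_offset)
            col[:kernel_offset] = 0.0
        return col

    cols, names = [], []
    if mode == "condition":
        for lab in pd.unique(tbl["condition"]):
            onsets = tbl.loc[tbl["condition"] == lab, "cs_onset"].to_numpy(float)
            cols.append(impulse_column(onsets))
            names.append(str(lab))
    else:
        for _, row in tbl.iterrows():
            cols.append(impulse_column(np.array([row["cs_onset"]])))
            names.append(f"trial_{int(row['trial_index'])}")

    if column_filter is not None:
        cols = [column_filter(c) for c in cols]
    if intercept:
        cols.append(np.ones(n_samples))
        names.append("intercept")

    dm = DesignMatrix(np.column_stack(cols), names, rate, intercept)
    if dm.condition_number > _MAX_CONDITION:
        raise RankDeficientError(
            f"design matrix is rank deficient or near-singular "
            f"(condition number {dm.condition_number:.3g}); "
            "overlapping trial regressors are the usual cause"
        )
    return dm


def invert(ts, X: DesignMatrix) -> GLMResult:
    """Ordinary least squares fit of the design to the data series.

    ``ts`` may be a :class:`TimeSeries` (missing samples are dropped
    listwise from both sides) or a plain array.  Refuses rank-deficient
    designs rather than silently pseudo-inverting.
    """
    if isinstance(ts, TimeSeries):
        y = ts.values
        keep = ~ts.missing
    else:
        y = np.asarray(ts, dtype=float)
        keep = np.isfinite(y)
    if y.size != X.X.shape[0]:
        raise ValueError(
            f"data length {y.size} does not match design length {X.X.shape[0]}"
        )
    A = X.X[keep]
    b = y[keep]
    if A.shape[0] < A.shape[1]:
        raise RankDeficientError("fewer valid samples than regressors")
    if np.linalg.cond(A) > _MAX_CONDITION:
        raise RankDeficientError(
            f"design rank deficient after dropping missing rows "
            f"(condition number {np.linalg.cond(A):.3g})"
        )
    betas, _, _, _ = np.linalg.lstsq(A, b, rcond=None)
    resid = b - A @ betas
    dof = A.shape[0] - A.shape[1]
    residual_variance = float(resid @ resid / dof) if dof > 0 else float("nan")
    tot = float(np.sum((b - b.mean()) ** 2))
    sse = float(resid @ resid)
    r_squared = 1.0 - sse / tot if tot > 0 else (1.0 if sse < 1e-12 else 0.0)
    return GLMResult(betas, list(X.names), residual_variance, r_squared, dof)


def trialwise_amplitude_from_segment(segment: np.ndarray, rf_values: np.ndarray) -> float:
    """Single-regressor projection: ``amp = ⟨seg, rf⟩ / ⟨rf, rf⟩``.

    Missing samples (NaN) are dropped pairwise; an all-missing segment
    returns NaN.  Equivalent to a one-trial GLM without intercept.
    """
    seg = np.asarray(segment, dtype=float)
    rfv = np.asarray(rf_values, dtype=float)
    if seg.shape != rfv.shape:
        raise ValueError("segment and kernel must share a grid")
    keep = np.isfinite(seg)
    if not keep.any():
        return float("nan")
    denom = float(rfv[keep] @ rfv[keep])
    if denom == 0.0:
        return float("nan")
    return float(seg[keep] @ rfv[keep] / denom)
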