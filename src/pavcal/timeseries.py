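"""Uniformly sampled physiological time series with a missing-data mask.

All channels in this package (skin conductance, pupil diameter, respiration
belt, interpolated heart period) are carried as :class:`TimeSeries` objects:
a value array at a fixed sampling rate, a unit string, and a boolean mask
marking samples that are missing or were flagged invalid by preprocessing.
Time is session-relative, in seconds; sample k sits at ``start + k / rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeSeries"]


@dataclass
class TimeSeries:
    values: np.ndarray
    rate: float
    units: str = ""
    start: float = 0.0
    missing: np.ndarray = field(default=None)  # True where sample is missing

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")
        if not np.isfinite(self.rate) or self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if self.missing is None:
            self.missing = ~np.isfinite(self.values)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.values.shape:
                raise ValueError("missing mask must match values in length")
            self.missing = self.missing | ~np.isfinite(self.values)

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n / self.rate

    @property
    def end(self) -> float:
        return self.start + self.duration

    def times(self) -> np.ndarray:
        return self.start + np.arange(self.n) / self.rate

    def copy(self) -> "TimeSeries":
        return TimeSeries(
            self.values.copy(), self.rate, self.units, self.start, self.missing.copy()
        )

    # ------------------------------------------------------------------
    def index_at(self, t: float) -> int:
        """Nearest sample index for session time ``t`` (clipped to range)."""
        k = int(round((t - self.start) * self.rate))
        return min(max(k, 0), self.n - 1)

    def slice(self, t_start: float, t_stop: float) -> "TimeSeries":
        """Samples with ``t_start <= t < t_stop`` as a new series."""
        i = int(np.ceil((t_start - self.start) * self.rate - 1e-9))
        j = int(np.ceil((t_stop - self.start) * self.rate - 1e-9))
        i, j = max(i, 0), min(j, self.n)
        return TimeSeries(
            self.values[i:j],
            self.rate,
            self.units,
            self.start + i / self.rate,
            self.missing[i:j],
        )

    def interpolate_missing(self) -> "TimeSeries":
        """Linearly bridge missing spans (edge values held constant).

        The mask is preserved so downstream estimation can still exclude
        the interpolated stretches; only the values are filled.
        """
        out = self.copy()
        bad = out.missing
        if bad.all():
            raise ValueError("cannot interpolate a fully missing series")
        if bad.any():
            idx = np.arange(out.n)
            out.values[bad] = np.interp(idx[bad], idx[~bad], out.values[~bad])
        return out
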