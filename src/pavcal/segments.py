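"""Per-trial segment and estimate containers shared across channels."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np
import pandas as pd

from .glm import GLMResult

__all__ = ["Segments", "ConditionEstimates"]


@dataclass
class Segments:
    """Stacked per-trial epochs on a common peri-event grid.

    ``data`` is (n_trials, n_samples) with NaN for missing samples;
    ``t`` holds times relative to CS onset; ``meta`` carries one row per
    trial (trial_index, condition, reinforced, ...) aligned with ``data``.
    """

    data: np.ndarray
    t: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self):
        if self.data.shape[0] != len(self.meta):
            raise ValueError("segment rows must match metadata rows")
        if self.data.shape[1] != self.t.size:
            raise ValueError("segment columns must match the time grid")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def for_condition(self, label: str) -> np.ndarray:
        return self.data[(self.meta["condition"] == label).to_numpy()]

    def condition_means(self) -> Dict[str, np.ndarray]:
        return {
            lab: np.nanmean(self.for_condition(lab), axis=0)
            for lab in pd.unique(self.meta["condition"])
        }


@dataclass
class ConditionEstimates:
    """One response amplitude per condition, with the underlying GLM fit."""

    amplitudes: Dict[str, float]
    glm: GLMResult

    def difference(self, plus: str = "CS+", minus: str = "CS-") -> float:
        return self.amplitudes[plus] - self.amplitudes[minus]
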