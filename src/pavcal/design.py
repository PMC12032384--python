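"""Differential-conditioning trial design: generation and validation.

The task is a two-block differential Pavlovian reward-conditioning session.
Each block contains an equal number of CS+ and CS− trials in randomized
order, subject to a run-length constraint (no more than ``max_run_length``
consecutive trials of the same CS, and no more than ``max_run_length``
consecutive reinforced trials).  During learning, CS+ trials are reinforced
with a fruit-juice US at a fixed reinforcement rate and the first CS+ of
every block is always reinforced; CS− is never reinforced.  During recall,
nothing is reinforced.  The US is delivered ``soa`` seconds after CS onset;
inter-trial intervals are random integer durations, and a swallow cue
appears at a random latency inside the ITI.

Event tables are plain :class:`pandas.DataFrame` objects with one row per
trial (columns documented on :func:`generate_trial_sequence`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
import pandas as pd

__all__ = [
    "DesignSpec",
    "Violation",
    "generate_trial_sequence",
    "validate_sequence",
    "max_run_length_of",
    "InfeasibleDesignError",
]

CS_PLUS = "CS+"
CS_MINUS = "CS-"

EVENT_COLUMNS = [
    "trial_index",
    "block",
    "condition",
    "reinforced",
    "cs_onset",
    "us_onset",
    "iti_duration",
    "swallow_onset",
]


class InfeasibleDesignError(RuntimeError):
    """Raised when no sequence satisfying the constraints is found."""


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of one conditioning phase.

    Defaults reproduce the reference task: 2 blocks of 24 CS+ and 24 CS−
    trials (96 trials per phase), 50% reinforcement, runs capped at 3,
    6-s CS, 5-s CS–US interval, integer ITIs of 9–16 s, swallow cue 2–5 s
    after CS offset lasting 2 s.
    """

    n_blocks: int = 2
    trials_per_condition_per_block: int = 24
    reinforcement_rate: float = 0.5
    max_run_length: int = 3
    cs_duration: float = 6.0
    soa: float = 5.0
    iti_min: int = 9
    iti_max: int = 16
    first_csplus_reinforced: bool = True
    swallow_delay_min: float = 2.0
    swallow_delay_max: float = 5.0
    swallow_duration: float = 2.0

    def validate(self) -> None:
        if self.trials_per_condition_per_block < 1:
            raise ValueError("trials_per_condition_per_block must be >= 1")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if not 0.0 <= self.reinforcement_rate <= 1.0:
            raise ValueError("reinforcement_rate must lie in [0, 1]")
        if self.iti_min > self.iti_max:
            raise ValueError("iti_min must not exceed iti_max")
        if self.max_run_length < 1:
            raise ValueError("max_run_length must be >= 1")
        if not self.soa < self.cs_duration:
            raise ValueError("soa must be shorter than cs_duration")

    @property
    def trials_per_block(self) -> int:
        return 2 * self.trials_per_condition_per_block

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def reinforced_per_block(self) -> int:
        return int(round(self.reinforcement_rate * self.trials_per_condition_per_block))


def max_run_length_of(flags: np.ndarray) -> int:
    """Length of the longest run of ``True`` in a boolean array."""
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        return 0
    padded = np.concatenate([[False], flags, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return int((ends - starts).max()) if starts.size else 0


def _has_run_longer_than(flags: np.ndarray, k: int) -> bool:
    """True when a run of ``True`` longer than ``k`` exists (cumsum window)."""
    if flags.size <= k:
        return False
    c = np.zeros(flags.size + 1, dtype=np.intp)
    np.cumsum(flags, out=c[1:])
    return bool((c[k + 1 :] - c[: -k - 1] == k + 1).any())


def _rows_with_long_run(mat: np.ndarray, k: int) -> np.ndarray:
    """Per-row flags: does any run of ``True`` longer than ``k`` exist?"""
    if mat.shape[1] <= k:
        return np.zeros(mat.shape[0], dtype=bool)
    c = np.zeros((mat.shape[0], mat.shape[1] + 1), dtype=np.intp)
    np.cumsum(mat, axis=1, out=c[:, 1:])
    return ((c[:, k + 1 :] - c[:, : -k - 1]) == k + 1).any(axis=1)


def _sample_conditions(
    rng: np.random.Generator, spec: DesignSpec, batch: int = 1
) -> np.ndarray:
    """Boolean is-CS+ flags, one uniformly shuffled block at a time.

    Returns shape ``(batch, n_trials)``; each row is an independent draw.
    """
    per = spec.trials_per_condition_per_block
    template = np.zeros(spec.trials_per_block, dtype=bool)
    template[:per] = True
    blocks = np.tile(template, (batch * spec.n_blocks, 1))
    return rng.permuted(blocks, axis=1).reshape(
        batch, spec.n_blocks * spec.trials_per_block
    )


def _sample_reinforcement(
    rng: np.random.Generator, spec: DesignSpec, isplus: np.ndarray, phase: str
) -> np.ndarray:
    reinforced = np.zeros(isplus.size, dtype=bool)
    if phase == "recall" or spec.reinforcement_rate == 0.0:
        return reinforced
    per_block = spec.trials_per_block
    k = spec.reinforced_per_block
    for b in range(spec.n_blocks):
        off = b * per_block
        plus_idx = np.flatnonzero(isplus[off : off + per_block]) + off
        fixed = 1 if (spec.first_csplus_reinforced and k >= 1 and plus_idx.size) else 0
        if fixed:
            reinforced[plus_idx[0]] = True
        remaining = plus_idx[fixed:]
        extra = k - fixed
        if extra > remaining.size:
            raise InfeasibleDesignError("reinforcement rate exceeds available CS+ trials")
        if extra > 0:
            reinforced[rng.choice(remaining, size=extra, replace=False)] = True
    return reinforced


def generate_trial_sequence(
    spec: DesignSpec, phase: str = "learning", seed: int = 0, max_retries: int = 10_000
) -> pd.DataFrame:
    """Draw one constraint-satisfying event table.

    Rejection sampling: condition orders and reinforcement positions are
    drawn uniformly and the whole sequence is re-drawn until both run
    constraints hold across the full phase (block boundaries included),
    up to ``max_retries`` attempts.

    Returns a DataFrame with columns ``trial_index, block, condition,
    reinforced, cs_onset, us_onset, iti_duration, swallow_onset`` (times in
    seconds; ``us_onset`` is NaN on nonreinforced trials).  Identical
    ``(spec, phase, seed)`` yields an identical table.
    """
    spec.validate()
    if phase not in ("learning", "recall"):
        raise ValueError(f"phase must be 'learning' or 'recall', got {phase!r}")
    rng = np.random.default_rng(seed)

    # Rejection sampling in batches: candidate shuffles are drawn in bulk
    # and scanned in draw order, so the accepted sequence is the same
    # uniform joint-rejection sample as one-at-a-time drawing.  Condition
    # runs are checked before reinforcement is drawn; a rejected attempt
    # redraws both, which leaves the accepted distribution unchanged.
    batch = 256
    conditions = None
    attempts = 0
    while attempts < max_retries and conditions is None:
        n_cand = min(batch, max_retries - attempts)
        cand = _sample_conditions(rng, spec, batch=n_cand)
        attempts += n_cand
        bad = _rows_with_long_run(cand, spec.max_run_length) | _rows_with_long_run(
            ~cand, spec.max_run_length
        )
        for i in np.flatnonzero(~bad):
            isplus = cand[i]
            reinforced = _sample_reinforcement(rng, spec, isplus, phase)
            if not _has_run_longer_than(reinforced, spec.max_run_length):
                conditions = np.where(isplus, CS_PLUS, CS_MINUS).astype(object)
                break
    if conditions is None:
        raise InfeasibleDesignError(
            f"no valid sequence found in {max_retries} attempts; "
            "constraints may be infeasible for this spec"
        )

    n = conditions.size
    itis = rng.integers(spec.iti_min, spec.iti_max + 1, size=n)
    swallow_delay = rng.uniform(spec.swallow_delay_min, spec.swallow_delay_max, size=n)

    cs_onset = np.zeros(n)
    cs_onset[1:] = np.cumsum(spec.cs_duration + itis[:-1].astype(float))
    us_onset = np.where(reinforced, cs_onset + spec.soa, np.nan)
    swallow_onset = cs_onset + spec.cs_duration + swallow_delay

    return pd.DataFrame(
        {
            "trial_index": np.arange(n),
            "block": np.repeat(np.arange(spec.n_blocks), spec.trials_per_block),
            "condition": conditions,
            "reinforced": reinforced,
            "cs_onset": cs_onset,
            "us_onset": us_onset,
            "iti_duration": itis,
            "swallow_onset": swallow_onset,
        }
    )


@dataclass
class Violation:
    rule: str
    rows: List[int]
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] {self.message} (rows {self.rows})"


def validate_sequence(tbl: pd.DataFrame, spec: DesignSpec) -> List[Violation]:
    """Check an event table against every design constraint.

    Returns a (possibly empty) list of :class:`Violation`; tables produced
    by :func:`generate_trial_sequence` always validate clean.
    """
    if len(tbl) == 0:
        raise ValueError("event table is empty")
    out: List[Violation] = []
    conditions = tbl["condition"].to_numpy()
    reinforced = tbl["reinforced"].to_numpy(dtype=bool)
    is_learning = bool(reinforced.any())

    # condition counts per block
    for b, grp in tbl.groupby("block"):
        for lab in (CS_PLUS, CS_MINUS):
            cnt = int((grp["condition"] == lab).sum())
            if cnt != spec.trials_per_condition_per_block:
                out.append(
                    Violation(
                        "condition_count",
                        grp.index.tolist(),
                        f"block {b}: {cnt} {lab} trials, "
                        f"expected {spec.trials_per_condition_per_block}",
                    )
                )
        if is_learning:
            plus = grp[grp["condition"] == CS_PLUS]
            n_reinf = int(plus["reinforced"].sum())
            if n_reinf != spec.reinforced_per_block:
                out.append(
                    Violation(
                        "reinforcement_count",
                        plus.index.tolist(),
                        f"block {b}: {n_reinf} reinforced CS+, "
                        f"expected {spec.reinforced_per_block}",
                    )
                )
            if (
                spec.first_csplus_reinforced
                and len(plus)
                and spec.reinforced_per_block >= 1
                and not bool(plus.iloc[0]["reinforced"])
            ):
                out.append(
                    Violation(
                        "first_csplus_reinforced",
                        [int(plus.index[0])],
                        f"block {b}: first CS+ trial is not reinforced",
                    )
                )

    # reinforced CS− is always invalid
    bad = np.flatnonzero((conditions == CS_MINUS) & reinforced)
    if bad.size:
        out.append(
            Violation("csminus_reinforced", bad.tolist(), "reinforced CS− trial(s)")
        )

    # run-length constraints
    for lab in (CS_PLUS, CS_MINUS):
        flags = conditions == lab
        if max_run_length_of(flags) > spec.max_run_length:
            rows = _long_run_rows(flags, spec.max_run_length)
            out.append(
                Violation(
                    "cs_run_length",
                    rows,
                    f"more than {spec.max_run_length} consecutive {lab} trials",
                )
            )
    if max_run_length_of(reinforced) > spec.max_run_length:
        out.append(
            Violation(
                "us_run_length",
                _long_run_rows(reinforced, spec.max_run_length),
                f"more than {spec.max_run_length} consecutive reinforced trials",
            )
        )

    # timing
    onsets = tbl["cs_onset"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) <= 0):
        rows = (np.flatnonzero(np.diff(onsets) <= 0) + 1).tolist()
        out.append(Violation("onset_order", rows, "trial onsets not strictly increasing"))
    itis = tbl["iti_duration"].to_numpy()
    bad = np.flatnonzero((itis < spec.iti_min) | (itis > spec.iti_max))
    if bad.size:
        out.append(
            Violation(
                "iti_range",
                bad.tolist(),
                f"ITI outside [{spec.iti_min}, {spec.iti_max}] s",
            )
        )
    us = tbl["us_onset"].to_numpy(dtype=float)
    expect = onsets + spec.soa
    bad = np.flatnonzero(reinforced & ~np.isclose(us, expect, atol=1e-9))
    if bad.size:
        out.append(
            Violation("us_onset", bad.tolist(), "us_onset != cs_onset + soa on reinforced trial")
        )
    bad = np.flatnonzero(~reinforced & np.isfinite(us))
    if bad.size:
        out.append(
            Violation("us_onset", bad.tolist(), "us_onset present on nonreinforced trial")
        )
    return out


def _long_run_rows(flags: np.ndarray, max_len: int) -> List[int]:
    """Row indices belonging to runs longer than ``max_len``."""
    flags = np.asarray(flags, dtype=bool)
    padded = np.concatenate([[False], flags, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    rows: List[int] = []
    for s, e in zip(starts, ends):
        if e - s > max_len:
            rows.extend(range(s, e))
    return rows
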