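"""Retrodictive-validity statistics: paired tests, Hedges g, scans, report.

The package's figure of merit for a candidate conditioning index is its
retrodictive validity: the standardized effect size with which the index
recovers the CS+/CS− manipulation that is known to have occurred.  For a
paired design with n participants and paired t statistic t, the
small-sample-corrected Hedges g is

    g = (t / sqrt(n)) * J(n - 1),
    J(df) = Γ(df / 2) / (sqrt(df / 2) * Γ((df - 1) / 2)),

where J is the exact small-sample bias-correction factor (the familiar
approximation is 1 - 3/(4 df - 1)).  Indices are retained when g exceeds
0.5.  Trial-subset scans trace g as a function of how many early trials
enter the condition averages; the halves analysis splits each phase in
two for channels only available condition-wise; Holm–Bonferroni corrects
confirmatory p-values across phases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import special
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .design import CS_MINUS, CS_PLUS

__all__ = [
    "EffectSizeResult",
    "correction_factor",
    "hedges_g",
    "paired_ttest",
    "exclude_outliers_3sd",
    "trial_subset_scan",
    "halves_analysis",
    "holm_bonferroni",
    "calibration_report",
    "paired_test_rejection_rate",
]

G_THRESHOLD = 0.5  # a priori retention criterion on Hedges g


@dataclass
class EffectSizeResult:
    """Paired t with its small-sample-corrected standardized effect."""

    t: float
    df: int
    n: int
    p: float
    g: float
    sides: str = "two"

    def __post_init__(self):
        if self.df != self.n - 1:
            raise ValueError("paired-design df must equal n - 1")


def correction_factor(df: int) -> float:
    """Exact small-sample bias-correction factor J(df), 0 < J < 1."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(
        np.exp(special.gammaln(df / 2.0) - special.gammaln((df - 1) / 2.0))
        / np.sqrt(df / 2.0)
    )


def hedges_g(t: float, n: int) -> float:
    """Hedges g for a paired design from the paired t statistic.

    ``g = (t / sqrt(n)) * J(n - 1)``; sign follows t.
    """
    if n < 2:
        raise ValueError("need n >= 2 participants")
    return float(t / np.sqrt(n) * correction_factor(n - 1))


def paired_ttest(
    cs_plus: Sequence[float], cs_minus: Sequence[float], sides: str = "two"
) -> EffectSizeResult:
    """Classical paired t-test on per-participant condition means.

    ``sides='one'`` tests the directional hypothesis CS+ > CS−.  Hedges g
    is attached via :func:`hedges_g`.
    """
    x = np.asarray(cs_plus, dtype=float)
    y = np.asarray(cs_minus, dtype=float)
    if x.shape != y.shape:
        raise ValueError("condition vectors must be paired (equal length)")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 2:
        raise ValueError("need at least two complete pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero variance of paired differences; t undefined")
    t = float(d.mean() / (sd / np.sqrt(n)))
    df = n - 1
    if sides == "two":
        p = float(2.0 * sps.t.sf(abs(t), df))
    elif sides == "one":
        p = float(sps.t.sf(t, df))
    else:
        raise ValueError("sides must be 'two' or 'one'")
    return EffectSizeResult(t=t, df=df, n=n, p=p, g=hedges_g(t, n), sides=sides)


def exclude_outliers_3sd(
    cs_plus: Sequence[float], cs_minus: Sequence[float]
) -> np.ndarray:
    """Single-pass ±3 SD participant exclusion, condition-wise.

    A participant is masked (False) when either condition estimate falls
    outside mean ± 3 SD of that condition's group distribution.  The SD
    uses the full sample (single pass, not iterated), so the mask is
    invariant to participant order.
    """
    x = np.asarray(cs_plus, dtype=float)
    y = np.asarray(cs_minus, dtype=float)
    if x.size < 3:
        raise ValueError("need at least three participants")
    keep = np.ones(x.size, dtype=bool)
    for v in (x, y):
        mu, sd = np.nanmean(v), np.nanstd(v, ddof=1)
        if sd > 0:
            keep &= np.abs(v - mu) <= 3.0 * sd
    return keep


# ----------------------------------------------------------------------
# trial-subset scan and halves
# ----------------------------------------------------------------------
def _condition_order(trials: pd.DataFrame, label: str, nonreinforced_only: bool) -> pd.DataFrame:
    sel = trials["condition"] == label
    if nonreinforced_only and label == CS_PLUS:
        sel &= ~trials["reinforced"].astype(bool)
    return trials[sel].sort_values("trial_index")


def trial_subset_scan(
    trial_estimates: pd.DataFrame,
    scheme: str = "standard",
    skip_first_pair: bool = False,
    sides: str = "two",
) -> pd.DataFrame:
    """Effect size as a function of the number of early trials averaged.

    ``trial_estimates`` needs columns ``participant, trial_index,
    condition, reinforced, amplitude``.  For ``scheme='standard'`` the
    condition mean at subset size n uses each participant's first n CS+
    and first n CS− trials; for ``scheme='nonreinforced'`` (used when
    reinforced CS+ trials are contaminated by the US response) it uses
    the first n nonreinforced CS+ trials and the first 2n CS− trials.
    ``skip_first_pair`` drops each participant's first CS+ and first CS−
    trial before scanning (the learning-phase variant).  Returns one row
    per subset size with the paired test and Hedges g.
    """
    if scheme not in ("standard", "nonreinforced"):
        raise ValueError("scheme must be 'standard' or 'nonreinforced'")
    nonreinforced_only = scheme == "nonreinforced"

    per_part: Dict[int, Tuple[np.ndarray, np.ndarray]] = {}
    for pid, grp in trial_estimates.groupby("participant"):
        grp = grp[np.isfinite(grp["amplitude"].astype(float))]
        plus = _condition_order(grp, CS_PLUS, nonreinforced_only)["amplitude"].to_numpy(float)
        minus = _condition_order(grp, CS_MINUS, False)["amplitude"].to_numpy(float)
        if skip_first_pair:
            plus, minus = plus[1:], minus[1:]
        per_part[pid] = (plus, minus)

    n_plus_max = min(len(v[0]) for v in per_part.values())
    n_minus_max = min(len(v[1]) for v in per_part.values())
    if nonreinforced_only:
        max_n = min(n_plus_max, n_minus_max // 2)
    else:
        max_n = min(n_plus_max, n_minus_max)
    if max_n < 1:
        raise ValueError("no complete trials available for the scan")

    rows = []
    for n in range(1, max_n + 1):
        xs, ys = [], []
        for plus, minus in per_part.values():
            xs.append(plus[:n].mean())
            ys.append(minus[: (2 * n if nonreinforced_only else n)].mean())
        res = paired_ttest(xs, ys, sides=sides)
        rows.append(
            {
                "n_trials": n,
                "scheme": scheme,
                "t": res.t,
                "df": res.df,
                "n": res.n,
                "p": res.p,
                "g": res.g,
            }
        )
    return pd.DataFrame(rows)


def halves_analysis(
    first_half: pd.DataFrame, second_half: pd.DataFrame, sides: str = "two"
) -> Tuple[EffectSizeResult, EffectSizeResult]:
    """Separate paired tests for the two halves of a phase.

    Each frame needs columns ``participant, cs_plus, cs_minus`` holding
    per-participant condition estimates for that half (condition-wise
    channels re-run their GLM per half upstream).
    """
    out = []
    for half in (first_half, second_half):
        out.append(paired_ttest(half["cs_plus"], half["cs_minus"], sides=sides))
    return out[0], out[1]


def holm_bonferroni(pvals: Sequence[float], alpha: float = 0.05):
    """Step-down Holm–Bonferroni correction.

    Returns ``(adjusted_pvals, reject)`` as arrays aligned with input.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to correct")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return p_adj, reject


# ----------------------------------------------------------------------
# calibration report
# ----------------------------------------------------------------------
def calibration_report(
    channel_estimates: Dict[str, pd.DataFrame],
    sides: str = "two",
    g_threshold: float = G_THRESHOLD,
    exclude_3sd: bool = True,
) -> pd.DataFrame:
    """Per-channel condition summary, paired test, g, and retention flag.

    ``channel_estimates`` maps a channel label (e.g. ``'hpr'`` or
    ``'psr:psr_rf5'``) to a frame with columns ``participant, cs_plus,
    cs_minus``.  Participants outside ±3 SD of either condition group are
    excluded (single pass) before testing.  A channel with fewer than two
    complete pairs is reported with NaN statistics.
    """
    rows = []
    for name, df in channel_estimates.items():
        x = df["cs_plus"].to_numpy(float)
        y = df["cs_minus"].to_numpy(float)
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
        if exclude_3sd and x.size >= 3:
            mask = exclude_outliers_3sd(x, y)
            x, y = x[mask], y[mask]
        if x.size < 2:
            rows.append(
                {
                    "channel": name,
                    "n": int(x.size),
                    "cs_plus_mean": np.nan,
                    "cs_plus_sd": np.nan,
                    "cs_minus_mean": np.nan,
                    "cs_minus_sd": np.nan,
                    "t": np.nan,
                    "df": np.nan,
                    "p": np.nan,
                    "g": np.nan,
                    "retained": False,
                }
            )
            continue
        res = paired_ttest(x, y, sides=sides)
        rows.append(
            {
                "channel": name,
                "n": res.n,
                "cs_plus_mean": float(x.mean()),
                "cs_plus_sd": float(x.std(ddof=1)),
                "cs_minus_mean": float(y.mean()),
                "cs_minus_sd": float(y.std(ddof=1)),
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "g": res.g,
                "retained": bool(res.g > g_threshold),
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# statistical calibration by simulation
# ----------------------------------------------------------------------
def paired_test_rejection_rate(
    n_reps: int,
    n: int,
    effect: float,
    alpha: float = 0.05,
    sides: str = "two",
    seed: int = 0,
) -> float:
    """Monte-Carlo rejection rate of the paired t-test.

    Per-participant paired differences are drawn ``Normal(effect, 1)``,
    so ``effect`` is the true standardized paired effect size;
    ``effect=0`` measures the type-I error rate, ``effect>0`` the power.
    Vectorized over repetitions.
    """
    rng = np.random.default_rng(seed)
    d = rng.standard_normal((n_reps, n)) + effect
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    t = mean / (sd / np.sqrt(n))
    df = n - 1
    if sides == "two":
        p = 2.0 * sps.t.sf(np.abs(t), df)
    elif sides == "one":
        p = sps.t.sf(t, df)
    else:
        raise ValueError("sides must be 'two' or 'one'")
    return float((p < alpha).mean())
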