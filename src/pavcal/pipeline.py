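"""End-to-end analysis of a cohort of recordings, channel by channel.

Ties the channel pipelines together: each participant's raw recordings
are preprocessed and inverted, per-participant condition estimates are
assembled, and the retrodictive-validity report is produced.  Works on
in-memory :class:`~pavcal.synthetic.ParticipantRecording` objects,
whether simulated or loaded from disk.

Condition conventions follow the reference analysis: for kernels that
outlast the CS–US interval (heart period, respiration amplitude, pupil
RF1) and for skin conductance, "CS+" means nonreinforced CS+ trials
only; for the short pupil kernels (RF2–RF6) and peak scoring it means
all CS+ trials.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

from . import cardiac, pupil, respiration, scr, stats
from .design import CS_MINUS, CS_PLUS
from .response_functions import get_rf
from .synthetic import ParticipantRecording

__all__ = [
    "analyze_cardiac",
    "analyze_scr",
    "analyze_pupil",
    "analyze_respiration",
    "condition_means",
    "analyze_cohort",
]


def analyze_cardiac(rec: ParticipantRecording, rf_name: str = "hprf_rew"):
    """Beats → filtered heart period → condition-wise amplitudes (ms)."""
    rf = get_rf(rf_name).normalized()
    ibi = cardiac.beats_to_ibi(rec.beats)
    ts = cardiac.interpolate_and_filter(ibi, duration=rec.scr.duration)
    return cardiac.estimate_condition_amplitudes(ts, rec.events, rf, ibi=ibi)


def analyze_scr(
    rec: ParticipantRecording, normalize: bool = True
) -> pd.DataFrame:
    """Preprocess and estimate trial-wise CS/US amplitudes (μS).

    With ``normalize`` the amplitudes are divided by the participant's
    mean CS− amplitude (the dimensionless units reported downstream).
    """
    ts = scr.preprocess_scr(rec.scr)
    est = scr.estimate_scr_trial_amplitudes(ts, rec.events)
    if normalize:
        est = scr.normalize_by_csminus(est)
    est.insert(0, "participant", rec.participant)
    return est


def analyze_pupil(
    rec: ParticipantRecording,
    rf_name: str = "psr_rf5",
    score: str = "glm",
    units: str = "z",
    apply_exclusions: bool = True,
):
    """Preprocess pupil and score trials by kernel projection or peak.

    ``score`` is ``'glm'`` (model-based, kernel ``rf_name``), ``'peak1'``
    (1-s baseline, max over CS→US) or ``'peak2'`` (2-s baseline, max in
    the final pre-US second).  ``units='mm'`` skips per-block z-scoring
    (used for amplitude-recovery checks).  Returns ``(trial estimates,
    participant_excluded)``.
    """
    spec = pupil.PupilPreprocSpec(zscore=(units == "z"))
    ts = pupil.preprocess_pupil(rec.pupil, rec.gaze_x, rec.gaze_y, rec.events, spec)
    if score == "glm":
        rf = get_rf(rf_name)
        segs = pupil.extract_pupil_segments(ts, rec.events, rf)
        est = pupil.psr_amplitudes(segs, rf)
    elif score in ("peak1", "peak2"):
        method = "finke" if score == "peak1" else "pietrock"
        est = pupil.peak_score(ts, rec.events, method=method)
    else:
        raise ValueError(f"unknown pupil scoring {score!r}")
    excluded = False
    if apply_exclusions:
        est, excluded = pupil.apply_pupil_exclusions(est)
    est.insert(0, "participant", rec.participant)
    return est, excluded


def analyze_respiration(rec: ParticipantRecording, rf_name: str = "rarf_rew"):
    """Belt → cycle amplitudes → RAR series → condition-wise amplitudes."""
    rf = get_rf(rf_name).normalized()
    cycles = respiration.detect_cycles(rec.resp)
    ts = respiration.rar_timeseries(cycles, duration=rec.resp.duration)
    return respiration.estimate_rar_amplitudes(ts, rec.events, rf, cycles=cycles)


def condition_means(
    trial_est: pd.DataFrame, nonreinforced_csplus: bool
) -> pd.DataFrame:
    """Per-participant condition means from trial-wise estimates.

    The amplitude column is ``amplitude`` (pupil) or ``cs_amplitude``
    (skin conductance).  Returns ``participant, cs_plus, cs_minus``.
    """
    col = "amplitude" if "amplitude" in trial_est else "cs_amplitude"
    rows = []
    for pid, grp in trial_est.groupby("participant"):
        grp = grp[grp["retained"]] if "retained" in grp else grp
        plus = grp[grp["condition"] == CS_PLUS]
        if nonreinforced_csplus:
            plus = plus[~plus["reinforced"].astype(bool)]
        minus = grp[grp["condition"] == CS_MINUS]
        rows.append(
            {
                "participant": pid,
                "cs_plus": plus[col].mean() if len(plus) else np.nan,
                "cs_minus": minus[col].mean() if len(minus) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def analyze_cohort(
    recordings: Iterable[ParticipantRecording],
    channels: Optional[List[str]] = None,
    pupil_units: str = "z",
    sides: str = "two",
) -> Dict[str, object]:
    """Run the selected channel analyses over a cohort and report.

    ``channels`` entries: ``'hpr'``, ``'scr'``, ``'rar'``,
    ``'psr:<rf_name>'``, ``'psr_peak1'``, ``'psr_peak2'`` (default: hpr,
    scr, psr:psr_rf5, rar).  Returns a dict with per-channel
    per-participant condition estimates (``'estimates'``), trial-level
    frames where available (``'trials'``), and the retrodictive-validity
    table (``'report'``).
    """
    recordings = list(recordings)
    if channels is None:
        channels = ["hpr", "scr", "psr:psr_rf5", "rar"]
    estimates: Dict[str, pd.DataFrame] = {}
    trials: Dict[str, pd.DataFrame] = {}

    for ch in channels:
        if ch == "hpr":
            rows = []
            for rec in recordings:
                est = analyze_cardiac(rec)
                rows.append(
                    {
                        "participant": rec.participant,
                        "cs_plus": est.amplitudes[CS_PLUS],
                        "cs_minus": est.amplitudes[CS_MINUS],
                    }
                )
            estimates[ch] = pd.DataFrame(rows)
        elif ch == "rar":
            rows = []
            for rec in recordings:
                est = analyze_respiration(rec)
                rows.append(
                    {
                        "participant": rec.participant,
                        "cs_plus": est.amplitudes[CS_PLUS],
                        "cs_minus": est.amplitudes[CS_MINUS],
                    }
                )
            estimates[ch] = pd.DataFrame(rows)
        elif ch == "scr":
            per = [analyze_scr(rec) for rec in recordings]
            trials[ch] = pd.concat(per, ignore_index=True)
            estimates[ch] = condition_means(trials[ch], nonreinforced_csplus=True)
        elif ch.startswith("psr:") or ch in ("psr_peak1", "psr_peak2"):
            per = []
            for rec in recordings:
                if ch.startswith("psr:"):
                    rf_name = ch.split(":", 1)[1]
                    est, excluded = analyze_pupil(
                        rec, rf_name=rf_name, score="glm", units=pupil_units
                    )
                    nonreinf = rf_name == "psr_rf1"
                else:
                    est, excluded = analyze_pupil(
                        rec, score="peak1" if ch.endswith("1") else "peak2",
                        units=pupil_units,
                    )
                    nonreinf = False
                if not excluded:
                    per.append(est)
            trials[ch] = pd.concat(per, ignore_index=True)
            estimates[ch] = condition_means(trials[ch], nonreinforced_csplus=nonreinf)
        else:
            raise ValueError(f"unknown channel {ch!r}")

    report = stats.calibration_report(estimates, sides=sides)
    return {"estimates": estimates, "trials": trials, "report": report}
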