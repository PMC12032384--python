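"""Plain-text file formats and run configuration.

Everything is tab-separated text with a small YAML sidecar for channel
metadata, so fixtures stay diffable and vendor-neutral.  Event tables
use BIDS-events-like columns (``onset, duration, trial_type, reinforced,
block, us_onset, iti_duration, swallow_onset``); times are seconds,
session-relative.  Units are always explicit in the sidecar — no
sniffing.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import yaml

from .design import CS_MINUS, DesignSpec
from .synthetic import CohortSpec, ParticipantRecording
from .timeseries import TimeSeries

__all__ = [
    "write_channel",
    "read_channel",
    "export_events",
    "import_events",
    "write_cohort",
    "read_participant",
    "RunConfig",
]


# ----------------------------------------------------------------------
# channel series
# ----------------------------------------------------------------------
def write_channel(ts: TimeSeries, path, **metadata) -> None:
    """Write a series as TSV (time_s, value, valid) plus a YAML sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        {"time_s": ts.times(), "value": ts.values, "valid": (~ts.missing).astype(int)}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")
    sidecar = {
        "units": ts.units,
        "rate_hz": float(ts.rate),
        "start_s": float(ts.start),
        **metadata,
    }
    path.with_suffix(path.suffix + ".yaml").write_text(yaml.safe_dump(sidecar))


def read_channel(path) -> TimeSeries:
    """Read a channel TSV and its sidecar back into a :class:`TimeSeries`.

    A missing sidecar falls back to the median sampling interval with a
    warning; a non-monotone time column is an error, and a declared rate
    inconsistent with the time column (>1%) is rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    t = df["time_s"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time column not strictly increasing")
    empirical_rate = 1.0 / np.median(np.diff(t))
    sidecar_path = path.with_suffix(path.suffix + ".yaml")
    if sidecar_path.exists():
        meta = yaml.safe_load(sidecar_path.read_text())
        rate = float(meta["rate_hz"])
        if abs(rate - empirical_rate) / rate > 0.01:
            raise ValueError(
                f"{path}: declared rate {rate} Hz inconsistent with "
                f"median interval ({empirical_rate:.4g} Hz)"
            )
        units = meta.get("units", "")
        start = float(meta.get("start_s", t[0]))
    else:
        warnings.warn(f"{path}: no sidecar found; inferring rate from time column")
        rate, units, start = empirical_rate, "", float(t[0])
    missing = None
    if "valid" in df:
        missing = df["valid"].to_numpy(int) == 0
    return TimeSeries(df["value"].to_numpy(float), rate, units, start, missing)


# ----------------------------------------------------------------------
# events
# ----------------------------------------------------------------------
_EVENT_EXPORT = {
    "cs_onset": "onset",
    "condition": "trial_type",
}


def export_events(events: pd.DataFrame, path, cs_duration: float = 6.0) -> None:
    """Write an event table as BIDS-events-like TSV."""
    out = events.rename(columns=_EVENT_EXPORT).copy()
    out.insert(1, "duration", cs_duration)
    cols = [
        "onset",
        "duration",
        "trial_type",
        "reinforced",
        "block",
        "us_onset",
        "iti_duration",
        "swallow_onset",
    ]
    out[cols].to_csv(path, sep="\t", index=False, float_format="%.8g", na_rep="n/a")


def import_events(path) -> pd.DataFrame:
    """Read a BIDS-events-like TSV back to the internal event table.

    Times must be in seconds (the format declares no alternative);
    a reinforced CS− row is rejected.
    """
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    required = {"onset", "trial_type", "reinforced"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing required columns {required - set(df.columns)}")
    out = df.rename(columns={"onset": "cs_onset", "trial_type": "condition"}).copy()
    out["reinforced"] = out["reinforced"].astype(bool)
    if ((out["condition"] == CS_MINUS) & out["reinforced"]).any():
        raise ValueError(f"{path}: reinforced CS- row(s); invalid event table")
    if "trial_index" not in out:
        out.insert(0, "trial_index", np.arange(len(out)))
    out = out.drop(columns=["duration"], errors="ignore")
    return out


# ----------------------------------------------------------------------
# cohort directories
# ----------------------------------------------------------------------
def write_cohort(recordings: List[ParticipantRecording], outdir) -> None:
    """One directory per participant: beats/scr/pupil/resp/events/truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        d = outdir / f"sub-{rec.participant:03d}"
        d.mkdir(exist_ok=True)
        np.savetxt(d / "beats.tsv", rec.beats, fmt="%.6f", header="beat_time_s", comments="")
        write_channel(rec.scr, d / "scr.tsv", channel="scr")
        pupil_df = pd.DataFrame(
            {
                "time_s": rec.pupil.times(),
                "diameter": rec.pupil.values,
                "gaze_x": rec.gaze_x,
                "gaze_y": rec.gaze_y,
                "valid": (~rec.pupil.missing).astype(int),
            }
        )
        pupil_df.to_csv(d / "pupil.tsv", sep="\t", index=False, float_format="%.8g")
        (d / "pupil.tsv.yaml").write_text(
            yaml.safe_dump(
                {"units": "mm", "rate_hz": float(rec.pupil.rate), "start_s": 0.0}
            )
        )
        write_channel(rec.resp, d / "resp.tsv", channel="resp")
        export_events(rec.events, d / "events.tsv")
        rec.truth.to_csv(d / "truth.tsv", sep="\t", index=False, float_format="%.8g")


def read_participant(directory) -> ParticipantRecording:
    """Load one participant directory written by :func:`write_cohort`."""
    d = Path(directory)
    beats = np.loadtxt(d / "beats.tsv", skiprows=1)
    scr = read_channel(d / "scr.tsv")
    pupil_df = pd.read_csv(d / "pupil.tsv", sep="\t")
    meta = yaml.safe_load((d / "pupil.tsv.yaml").read_text())
    pupil_ts = TimeSeries(
        pupil_df["diameter"].to_numpy(float),
        float(meta["rate_hz"]),
        meta.get("units", "mm"),
        float(meta.get("start_s", 0.0)),
        pupil_df["valid"].to_numpy(int) == 0,
    )
    resp = read_channel(d / "resp.tsv")
    events = import_events(d / "events.tsv")
    truth_path = d / "truth.tsv"
    truth = (
        pd.read_csv(truth_path, sep="\t") if truth_path.exists() else pd.DataFrame()
    )
    pid = int(d.name.split("-")[-1]) if "-" in d.name else 0
    return ParticipantRecording(
        participant=pid,
        events=events,
        beats=beats,
        scr=scr,
        pupil=pupil_ts,
        gaze_x=pupil_df["gaze_x"].to_numpy(float),
        gaze_y=pupil_df["gaze_y"].to_numpy(float),
        resp=resp,
        resp_cycle_times=np.array([]),
        truth=truth,
    )


# ----------------------------------------------------------------------
# run configuration
# ----------------------------------------------------------------------
@dataclass
class RunConfig:
    """Validated configuration of one full pipeline run."""

    design: DesignSpec = field(default_factory=DesignSpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    phase: str = "learning"
    channels: List[str] = field(default_factory=lambda: ["hpr", "scr", "psr:psr_rf5", "rar"])
    pupil_units: str = "z"
    sides: str = "two"
    alpha: float = 0.05
    scan: bool = False
    seed: int = 0
    outdir: str = "pavcal_out"

    def __post_init__(self):
        if self.phase not in ("learning", "recall"):
            raise ValueError("phase must be 'learning' or 'recall'")
        if self.sides not in ("one", "two"):
            raise ValueError("sides must be 'one' or 'two'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        self.design.validate()
        self.cohort.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        design = DesignSpec(**raw.pop("design", {}))
        cohort_kwargs = raw.pop("cohort", {})
        for key in ("hpr_noise", "scr_noise", "pupil_noise", "resp_noise"):
            if key in cohort_kwargs and isinstance(cohort_kwargs[key], dict):
                from .synthetic import ChannelNoise

                cohort_kwargs[key] = ChannelNoise(**cohort_kwargs[key])
        cohort = CohortSpec(**cohort_kwargs)
        return cls(design=design, cohort=cohort, **raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


def run_pipeline(config: RunConfig):
    """simulate → analyze → report; writes TSV outputs to ``config.outdir``.

    Returns the analysis dict from :func:`pavcal.pipeline.analyze_cohort`.
    Deterministic: identical config and seed reproduce identical outputs.
    """
    from . import pipeline as pl
    from . import synthetic

    from dataclasses import replace as _replace

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort_spec = _replace(config.cohort, seed=config.seed)
    recordings = synthetic.simulate_cohort(config.design, cohort_spec, phase=config.phase)
    result = pl.analyze_cohort(
        recordings,
        channels=config.channels,
        pupil_units=config.pupil_units,
        sides=config.sides,
    )
    result["report"].to_csv(outdir / "report.tsv", sep="\t", index=False)
    for name, df in result["estimates"].items():
        safe = name.replace(":", "_")
        df.to_csv(outdir / f"estimates_{safe}.tsv", sep="\t", index=False)
    if config.scan:
        from . import stats as st

        for name, df in result["trials"].items():
            scheme = "nonreinforced" if name == "scr" or name.endswith("rf1") else "standard"
            try:
                scan = st.trial_subset_scan(df, scheme=scheme, sides=config.sides)
            except ValueError:
                continue
            scan.to_csv(outdir / f"scan_{name.replace(':', '_')}.tsv", sep="\t", index=False)
    return result
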