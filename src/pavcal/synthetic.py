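"""Forward simulation of a conditioning cohort with known ground truth.

Every analysis stage in this package is validated against synthetic
recordings in which the conditioned responses are injected explicitly.
The statistical structure mirrors the paired design the analysis assumes:
participant *i* carries a standardized CS+/CS− amplitude difference
``d_i ~ Normal(delta, between_sd²)`` per channel, every trial adds
``Normal(0, trial_sd²)`` amplitude jitter, and each channel converts the
standardized amplitude into physical units through a per-channel scale.
Channels are then rendered forward through the same linear
time-invariant kernels the analysis inverts:

* heart period — integral pulse frequency modulation (IPFM): beats fire
  whenever the integral of 1/h(t) reaches the next whole number, where
  h(t) is the instantaneous heart period;
* skin conductance — tonic level plus CS-locked and US/omission-locked
  phasic responses with a canonical bi-exponential kernel;
* pupil — baseline diameter plus kernel responses, blink gaps with fast
  edges, and gaze excursions exercising the 5° filter;
* respiration — a carrier oscillation whose cycle-amplitude envelope
  carries the kernel responses.

Noise is white or spectrally pink (1/f-shaped) Gaussian; physiological
series are autocorrelated, and pink noise keeps the pipeline's precision
estimates honest.  Ground-truth per-trial amplitudes are stored in the
units each analysis stage estimates (ms, μS, mm, peak-to-trough a.u.).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .design import CS_PLUS, DesignSpec, generate_trial_sequence
from .response_functions import ResponseFunction, get_rf, scr_kernel
from .timeseries import TimeSeries

__all__ = [
    "ChannelNoise",
    "CohortSpec",
    "ParticipantRecording",
    "simulate_cohort",
    "simulate_heart_beats",
    "simulate_pupil",
    "simulate_scr",
    "simulate_respiration",
    "pink_noise",
    "noiseless",
]

SOA = 5.0
LEAD_IN_S = 30.0   # recording time before the first CS onset
TAIL_S = 45.0      # recording time after the last CS onset


@dataclass(frozen=True)
class ChannelNoise:
    spectrum: str = "pink"  # 'white' | 'pink'
    sd: float = 0.0

    def __post_init__(self):
        if self.spectrum not in ("white", "pink"):
            raise ValueError("noise spectrum must be 'white' or 'pink'")
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one simulated cohort.

    Defaults emulate the reference study: 34 participants (the powered
    sample size), a standardized CS+/CS− difference of 0.6 (the observed
    heart-period effect range), unit between-participant SD so ``delta``
    is itself the standardized paired effect, and channel baselines and
    noise levels in the physiological range of adult participants at
    rest.
    """

    n_participants: int = 34
    delta: float = 0.6
    between_sd: float = 1.0
    trial_sd: float = 1.0
    seed: int = 0

    # channel scales: physical units per standardized amplitude unit
    hpr_scale_ms: float = 20.0
    scr_scale_uS: float = 0.3
    pupil_scale_mm: float = 0.1
    resp_scale: float = 0.02  # envelope units

    # condition-independent (orienting) response means, standardized units
    hpr_common: float = 0.0
    scr_common: float = 1.0
    pupil_common: float = 2.0
    resp_common: float = 0.5

    # US and US-omission skin-conductance responses, μS
    scr_us_uS: float = 0.8
    scr_omission_uS: float = 0.2

    # per-channel additive noise (units: s, μS, mm, envelope a.u.)
    hpr_noise: ChannelNoise = ChannelNoise("pink", 0.015)
    scr_noise: ChannelNoise = ChannelNoise("pink", 0.02)
    pupil_noise: ChannelNoise = ChannelNoise("pink", 0.03)
    resp_noise: ChannelNoise = ChannelNoise("white", 0.02)

    # pupil missing data and gaze behaviour
    blink_rate_per_min: float = 10.0
    blink_duration_range: tuple = (0.1, 0.4)
    gaze_jitter_deg: float = 0.5
    gaze_excursion_rate_per_min: float = 0.5

    # artifact spikes (rate per minute; magnitudes in channel units)
    artifact_rate_per_min: float = 0.0
    scr_spike_uS: float = 4.0
    pupil_spike_mm: float = 3.0

    # baselines
    heart_period_s: float = 0.85
    scl_uS: float = 5.0
    pupil_mm: float = 3.5
    resp_amp: float = 0.5
    resp_freq_hz: float = 0.25

    # kernels used to render (and later invert) the responses
    hpr_rf: str = "hprf_rew"
    pupil_rf: str = "psr_rf5"
    rar_rf: str = "rarf_rew"

    # simulation sampling rates
    scr_rate: float = 20.0
    pupil_rate: float = 100.0
    resp_rate: float = 20.0
    cardiac_grid_rate: float = 100.0

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        for nm in ("between_sd", "trial_sd"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")
        if not 0.4 <= self.heart_period_s <= 1.2:
            raise ValueError("baseline heart period must lie in [0.4, 1.2] s")


def noiseless(spec: CohortSpec = CohortSpec(), **overrides) -> CohortSpec:
    """Copy of ``spec`` with every stochastic nuisance switched off.

    Trial jitter, between-participant spread, channel noise, blinks,
    gaze excursions, and artifacts are all zeroed, leaving only the
    deterministic injected responses (used by recovery oracles).
    """
    off = ChannelNoise("white", 0.0)
    return replace(
        spec,
        between_sd=0.0,
        trial_sd=0.0,
        hpr_noise=off,
        scr_noise=off,
        pupil_noise=off,
        resp_noise=off,
        blink_rate_per_min=0.0,
        gaze_jitter_deg=0.0,
        gaze_excursion_rate_per_min=0.0,
        artifact_rate_per_min=0.0,
        **overrides,
    )


@dataclass
class ParticipantRecording:
    participant: int
    events: pd.DataFrame
    beats: np.ndarray
    scr: TimeSeries
    pupil: TimeSeries
    gaze_x: np.ndarray
    gaze_y: np.ndarray
    resp: TimeSeries
    resp_cycle_times: np.ndarray  # true carrier cycle onsets (diagnostics)
    truth: pd.DataFrame
    d: Dict[str, float] = field(default_factory=dict)


# ----------------------------------------------------------------------
# noise
# ----------------------------------------------------------------------
def pink_noise(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude-shaped Gaussian noise, normalized to the target SD."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shaping = np.ones_like(f)
    shaping[1:] = 1.0 / np.sqrt(f[1:])
    shaping[0] = 0.0  # no DC drift component
    x = np.fft.irfft(spec * shaping, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _noise(n: int, model: ChannelNoise, rng: np.random.Generator) -> np.ndarray:
    if model.sd == 0.0:
        return np.zeros(n)
    if model.spectrum == "white":
        return rng.standard_normal(n) * model.sd
    return pink_noise(n, model.sd, rng)


def _response_sum(
    grid: np.ndarray, onsets: np.ndarray, amps: np.ndarray, rf: ResponseFunction
) -> np.ndarray:
    out = np.zeros_like(grid)
    for t0, a in zip(onsets, amps):
        if a == 0.0:
            continue
        lo = np.searchsorted(grid, t0 + max(rf.support[0], 0.0))
        hi = np.searchsorted(grid, t0 + rf.support[1])
        out[lo:hi] += a * rf.evaluate(grid[lo:hi] - t0)
    return out


# ----------------------------------------------------------------------
# channel simulators
# ----------------------------------------------------------------------
def simulate_heart_beats(
    events: pd.DataFrame,
    rf: ResponseFunction,
    trial_amps_ms: np.ndarray,
    baseline_s: float,
    noise: ChannelNoise,
    duration: float,
    rng: np.random.Generator,
    grid_rate: float = 100.0,
) -> np.ndarray:
    """Beats from an instantaneous heart-period function via IPFM.

    ``h(t) = baseline + Σ amp·rf(t − onset) + noise`` (seconds); a beat
    fires at t=0 and thereafter whenever ``∫ dt / h(t)`` advances by 1.
    """
    n = int(np.floor(duration * grid_rate)) + 1
    grid = np.arange(n) / grid_rate
    h = baseline_s + _response_sum(
        grid, events["cs_onset"].to_numpy(float), np.asarray(trial_amps_ms) / 1000.0, rf
    )
    h = h + _noise(n, noise, rng)
    if np.any(h <= 0.05):
        raise ValueError("instantaneous heart period reached <= 50 ms; unphysiological spec")
    phase = np.concatenate([[0.0], np.cumsum((1.0 / h)[:-1] + (1.0 / h)[1:]) / (2 * grid_rate)])
    n_beats = int(np.floor(phase[-1]))
    targets = np.arange(0, n_beats + 1, dtype=float)
    beats = np.interp(targets, phase, grid)
    return beats


def simulate_pupil(
    events: pd.DataFrame,
    rf: ResponseFunction,
    trial_amps_mm: np.ndarray,
    baseline_mm: float,
    spec: CohortSpec,
    duration: float,
    rng: np.random.Generator,
):
    """Pupil diameter plus gaze traces with blinks and excursions.

    Returns ``(pupil TimeSeries, gaze_x, gaze_y)``; blink gaps are marked
    missing with fast partial-closure edges so the validity filters have
    realistic input.
    """
    rate = spec.pupil_rate
    n = int(np.floor(duration * rate)) + 1
    grid = np.arange(n) / rate
    v = baseline_mm + _response_sum(
        grid, events["cs_onset"].to_numpy(float), np.asarray(trial_amps_mm), rf
    )
    v = v + _noise(n, spec.pupil_noise, rng)
    missing = np.zeros(n, dtype=bool)

    n_blinks = rng.poisson(spec.blink_rate_per_min * duration / 60.0)
    for t0 in np.sort(rng.uniform(0, duration, n_blinks)):
        dur = rng.uniform(*spec.blink_duration_range)
        i = int(t0 * rate)
        j = min(int((t0 + dur) * rate), n)
        edge = max(int(0.02 * rate), 1)  # ~20-ms lid edges
        lo = max(i - edge, 0)
        v[lo:i] -= np.linspace(0.0, 1.5, i - lo)
        hi = min(j + edge, n)
        v[j:hi] -= np.linspace(1.5, 0.0, hi - j)
        missing[i:j] = True
        v[i:j] = np.nan

    n_spikes = rng.poisson(spec.artifact_rate_per_min * duration / 60.0)
    for t0 in rng.uniform(0, duration, n_spikes):
        i = int(t0 * rate)
        v[i : i + max(int(0.05 * rate), 1)] += spec.pupil_spike_mm

    gaze_x = rng.standard_normal(n) * spec.gaze_jitter_deg
    gaze_y = rng.standard_normal(n) * spec.gaze_jitter_deg
    n_exc = rng.poisson(spec.gaze_excursion_rate_per_min * duration / 60.0)
    for t0 in rng.uniform(0, duration, n_exc):
        i = int(t0 * rate)
        j = min(i + int(0.5 * rate), n)
        gaze_x[i:j] += rng.choice([-1.0, 1.0]) * rng.uniform(6.0, 9.0)

    ts = TimeSeries(v, rate, units="mm", missing=missing)
    return ts, gaze_x, gaze_y


def simulate_scr(
    events: pd.DataFrame,
    trial_amps_cs: np.ndarray,
    trial_amps_us: np.ndarray,
    baseline_uS: float,
    spec: CohortSpec,
    duration: float,
    rng: np.random.Generator,
    kernel: Optional[ResponseFunction] = None,
) -> TimeSeries:
    """Tonic level plus CS-locked and US/omission-locked phasic responses."""
    if kernel is None:
        kernel = scr_kernel()
    rate = spec.scr_rate
    n = int(np.floor(duration * rate)) + 1
    grid = np.arange(n) / rate
    onsets = events["cs_onset"].to_numpy(float)
    v = baseline_uS + _response_sum(grid, onsets, np.asarray(trial_amps_cs), kernel)
    v = v + _response_sum(grid, onsets + SOA, np.asarray(trial_amps_us), kernel)
    v = v + _noise(n, spec.scr_noise, rng)

    n_spikes = rng.poisson(spec.artifact_rate_per_min * duration / 60.0)
    for t0 in rng.uniform(0, duration, n_spikes):
        i = int(t0 * rate)
        v[i : i + max(int(0.1 * rate), 1)] += spec.scr_spike_uS
    if spec.artifact_rate_per_min == 0.0:
        v = np.clip(v, 0.05, 100.0)
    return TimeSeries(v, rate, units="uS")


def simulate_respiration(
    events: pd.DataFrame,
    rf: ResponseFunction,
    trial_amps: np.ndarray,
    base_amp: float,
    base_freq: float,
    spec: CohortSpec,
    duration: float,
    rng: np.random.Generator,
):
    """Carrier oscillation with a kernel-modulated cycle-amplitude envelope.

    Returns ``(belt TimeSeries, cycle_onset_times)``; the envelope never
    goes below 10% of baseline so cycles remain detectable.
    """
    rate = spec.resp_rate
    n = int(np.floor(duration * rate)) + 1
    grid = np.arange(n) / rate
    env = base_amp + _response_sum(
        grid, events["cs_onset"].to_numpy(float), np.asarray(trial_amps), rf
    )
    env = env + _noise(n, spec.resp_noise, rng)
    env = np.maximum(env, 0.1 * base_amp)
    carrier = np.sin(2 * np.pi * base_freq * grid)
    v = env * carrier
    cycle_onsets = np.arange(0.0, duration, 1.0 / base_freq)
    return TimeSeries(v, rate, units="au"), cycle_onsets


# ----------------------------------------------------------------------
# cohort
# ----------------------------------------------------------------------
_CHANNELS = ("hpr", "scr", "pupil", "resp")


def simulate_cohort(
    design: DesignSpec = DesignSpec(),
    spec: CohortSpec = CohortSpec(),
    phase: str = "learning",
) -> List[ParticipantRecording]:
    """Simulate a full cohort; deterministic given ``spec.seed``.

    Event tables are shifted so the first CS onset occurs ``LEAD_IN_S``
    into the recording (giving every trial a pre-CS baseline).  The
    ``truth`` table carries per-trial injected amplitudes in analysis
    units: ``hpr`` (ms at kernel peak), ``scr_cs``/``scr_us`` (μS),
    ``pupil`` (mm), ``resp`` (peak-to-trough envelope units).
    """
    design.validate()
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    out: List[ParticipantRecording] = []

    hpr_rf = get_rf(spec.hpr_rf).normalized()
    pupil_rf = get_rf(spec.pupil_rf).normalized()
    rar_rf = get_rf(spec.rar_rf).normalized()

    for p, child in enumerate(root.spawn(spec.n_participants)):
        rng = np.random.default_rng(child)
        ev_seed = int(rng.integers(0, 2**31 - 1))
        events = generate_trial_sequence(design, phase=phase, seed=ev_seed)
        events = events.copy()
        for col in ("cs_onset", "us_onset", "swallow_onset"):
            events[col] = events[col] + LEAD_IN_S
        duration = float(events["cs_onset"].iloc[-1] + TAIL_S)
        n_trials = len(events)
        isplus = (events["condition"] == CS_PLUS).to_numpy()
        reinforced = events["reinforced"].to_numpy(dtype=bool)

        d = {c: rng.normal(spec.delta, spec.between_sd) for c in _CHANNELS}
        z = {
            c: rng.normal(0.0, spec.trial_sd, size=n_trials) + d[c] * isplus
            for c in _CHANNELS
        }
        amps_hpr = (spec.hpr_common + z["hpr"]) * spec.hpr_scale_ms
        amps_scr = (spec.scr_common + z["scr"]) * spec.scr_scale_uS
        amps_pupil = (spec.pupil_common + z["pupil"]) * spec.pupil_scale_mm
        amps_resp = (spec.resp_common + z["resp"]) * spec.resp_scale
        amps_us = np.where(reinforced, spec.scr_us_uS, spec.scr_omission_uS)

        beats = simulate_heart_beats(
            events, hpr_rf, amps_hpr, spec.heart_period_s, spec.hpr_noise,
            duration, rng, grid_rate=spec.cardiac_grid_rate,
        )
        scr_ts = simulate_scr(events, amps_scr, amps_us, spec.scl_uS, spec, duration, rng)
        pupil_ts, gx, gy = simulate_pupil(
            events, pupil_rf, amps_pupil, spec.pupil_mm, spec, duration, rng
        )
        resp_ts, cyc = simulate_respiration(
            events, rar_rf, amps_resp, spec.resp_amp, spec.resp_freq_hz,
            spec, duration, rng,
        )

        truth = pd.DataFrame(
            {
                "trial_index": events["trial_index"].to_numpy(),
                "condition": events["condition"].to_numpy(),
                "reinforced": reinforced,
                "hpr": amps_hpr,
                "scr_cs": amps_scr,
                "scr_us": amps_us,
                "pupil": amps_pupil,
                "resp": 2.0 * amps_resp,  # analysis observes peak-to-trough
            }
        )
        out.append(
            ParticipantRecording(
                participant=p,
                events=events,
                beats=beats,
                scr=scr_ts,
                pupil=pupil_ts,
                gaze_x=gx,
                gaze_y=gy,
                resp=resp_ts,
                resp_cycle_times=cyc,
                truth=truth,
                d=d,
            )
        )
    return out
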