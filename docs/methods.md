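# Methods

This document describes the measurement model, the channel pipelines and
their parameters, the synthetic cohort generator, the numerical choices
that matter for correctness, and the known limitations.

## 1. Measurement model

Each physiological channel is modelled as a causal linear time-invariant
(LTI) system. For a recording with trial onsets `t_j` and per-trial (or
per-condition) amplitudes `a_j`, the signal on an evenly sampled grid is

    y(t) = Σ_j a_j · k(t − t_j) + drift + noise

where `k` is a fixed channel-specific response kernel ("response
function", RF). Amplitudes are estimated by building one design column
per trial or condition — the kernel placed at the trial onsets — and
solving the ordinary-least-squares normal equations (`pavcal.glm`).
Two invariances keep the estimator unbiased:

1. **Filter mirroring.** Any filter applied to the data (band-pass,
   detrending) is applied identically to every design column, so the
   filter's gain and phase cancel in the regression.
2. **Observation-operator mirroring.** When the data series is not a
   direct sampling of the underlying signal but a derived observation
   (beat-interval averages for heart period, once-per-breath amplitudes
   for respiration), the same derivation is applied to the design
   columns (sections 3 and 6).

All kernels are normalized to unit peak before use, so an estimated
amplitude is the response's value at the kernel peak, in the channel's
measurement units.

## 2. Response kernels

`pavcal.response_functions.registry()` provides the named kernels. The
gamma family is

    k(t) = c · g((t − t0); κ, θ),   g the gamma density,

with the `theta_is_scale` flag recording whether `θ` is the scale
parameter or the rate (inverse scale). Both conventions appear in the
source literature for these kernels, so the parameter object stores the
convention explicitly instead of silently converting, and the two
readings are unit-tested to be equivalent after conversion.

| name | family | parameters | window (s) | support (s) |
|---|---|---|---|---|
| `hprf_rew` | gamma | κ=1.72, θ=0.14 (rate), c=60.1, t0=−17.61 | — | 0–25 |
| `hprf_fear` | gamma | κ=48.5, θ=0.182 (scale), t0=−7.36 | — | 0–25 |
| `rarf_rew` | gamma | κ=40.87, θ=0.29 (scale), c=0.14, t0=2.09 | — | 0–30 |
| `psr_rf1` | gamma | κ=3.534, θ=1.946 (scale), c=−1.183, t0=1.712 | 15.0 | 0–15 |
| `psr_rf2` | gamma | κ=30.781, θ=0.042 (scale), c=0.033, t0=0.506 | 3.5 | 0–3.5 |
| `psr_rf3` | Gaussian | μ=1.784, σ=0.246, c=0.035 | 3.0 | 0–3 |
| `psr_rf4` | empirical | low-pass-smoothed difference waveform, truncated at 2.88 s | 3.0 | 0–2.88 |
| `psr_rf5` | two-gamma | c=12.998, o1=1.355, o2=0.75, d1=0.059, d2=0.178, r=2.715, t0=0.439 | 3.0 | 0–3 |
| `psr_rf6` | empirical | tabulated stand-in with the RF5 shape | 3.5 | 0–3.5 |

A negative `t0` (as in `hprf_rew`) means the gamma shape begins before
the event; only the causal part (t ≥ 0) enters the design, which is why
that kernel's extremum sits at t = 0. `window` is the pupil extraction
window (post-onset seconds used for trial segments); HPR/RAR kernels
have no window — they enter full-length convolution designs. SCR uses a
canonical bi-exponential kernel (`scr_kernel`, rise constant 1.4 s,
decay constant 4.0 s, unit peak).

`fit_rf` fits gamma or Gaussian kernels to a waveform by bounded
least squares (`scipy.optimize.least_squares`) and recovers its own
kernels' parameters from noiseless waveforms to well under 1%.

## 3. Heart period (HPR)

Pipeline: beat times → inter-beat intervals (IBI) → evenly sampled
heart-period series → band-pass → condition-wise convolution GLM.

- IBIs with implied rate outside 50–150 bpm are flagged invalid;
  invalid stretches longer than 5 s are marked missing.
- The IBI sequence is linearly interpolated to a 100 Hz grid in
  milliseconds and band-passed 0.015–0.5 Hz (4th-order zero-phase
  Butterworth, applied forward and backward).
- Design columns: one per condition — nonreinforced CS+, CS−, and a
  nuisance column for reinforced CS+ (US delivery overlaps the CS
  response there) — each the kernel train passed through the identical
  band-pass.
- **Beat-sampling mirror.** The IBI series is not the continuous heart
  period: each IBI is approximately the average of the underlying
  period over one beat interval, re-interpolated from beat times. The
  same operator is applied to each design column (cumulative-integral
  interval averages at the detected beat times, re-interpolated to the
  grid). Without this, the sharp-onset kernel is attenuated in the data
  but not in the regressors, biasing amplitudes by about −7%; with it,
  zero-noise recovery is exact to ~0.03%.

## 4. Skin conductance (SCR)

- Preprocessing: samples outside 0.05–100 μS or with absolute slope
  above 10 μS/s are rejected; the mask is dilated by one output period
  before resampling so single-sample artifacts cannot fall between
  output grid points; 1st-order zero-phase band-pass 0.0159–5 Hz;
  resampled to 10 Hz.
- Estimation: a trial-wise convolution GLM with two regressors per
  trial — one locked to CS onset, one to US delivery/omission (CS onset
  + 5 s) — using the canonical SCR kernel. This is a linear
  approximation of variational model inversion; results carry the
  estimator label `constrained_glm`.
- Amplitudes are optionally normalized per participant by the mean over
  CS− trials (the default for between-participant analysis).

## 5. Pupil size (PSR)

- Preprocessing: plausible-range gating, gaze-deviation gating (> 5°
  from fixation marked missing), foreshortening correction
  (division by the cosine of gaze eccentricity), dilation-speed filter,
  gap-edge trimming, linear interpolation, and per-block z-scoring
  (or mm units on request).
- **Dilation-speed floor.** The speed filter flags samples whose
  absolute velocity exceeds `median + 16·MAD` of the velocity series.
  On clean, low-noise signals the MAD collapses toward zero and the
  unfloored threshold flags essentially everything; the threshold is
  therefore floored at 1 mm/s, a physiologically implausible sustained
  dilation speed, so the filter only ever removes genuine transients.
- Scoring: GLM projection of each trial segment onto the chosen kernel
  (RF1–RF6), or peak scoring (maximum baseline-corrected dilation in
  1–2 s post-onset, or in the final pre-US second).
- Exclusions: trials with |estimate| > 6 mm equivalent or > 50% missing
  samples are dropped; a participant is excluded when more than half of
  their trials drop. Long kernels (RF1) cannot be estimated on
  reinforced CS+ trials (US response overlap), so those trials are
  dropped for kernels whose window crosses the US onset.

## 6. Respiration amplitude (RAR)

- Cycle detection: the belt signal is band-passed 0.05–1 Hz (2nd-order
  zero-phase Butterworth) for zero-crossing cycle segmentation; cycles
  with implausible duration (outside 1–15 s) are discarded; per-cycle
  amplitude is peak-to-trough within the cycle, timestamped at the
  cycle midpoint, with the peak and trough times retained.
- **Edge margin.** Zero-phase filtering has settling transients at the
  recording edges. Cycles whose extent lies within one high-pass-corner
  period (1/0.05 Hz = 20 s) of either edge are discarded; interior
  cycle amplitudes are accurate to ~0.02% on noiseless input while the
  first/last cycles are corrupted by up to ~6%.
- The cycle-amplitude sequence is interpolated to a 10 Hz series,
  demeaned, and band-passed 0.01–2 Hz before the condition-wise GLM.
  Demeaning before filtering avoids the DC edge transient of the
  high-pass stage.
- **Breath-sampling mirror.** The data series samples the amplitude
  envelope once per breath as a peak-to-trough difference — i.e. the
  envelope evaluated near the peak and the trough instants, averaged.
  Each design column is reduced the same way: its values at the
  detected peak and trough times are averaged per cycle and
  re-interpolated from cycle midpoints. Without this the estimates are
  biased about −12%; with it, recovery is within ~0.3%.

## 7. Experimental design generator

The learning phase is 2 blocks × 48 trials (24 CS+, 24 CS− each), 50%
reinforcement of CS+ (12 per block), first CS+ of each block always
reinforced, no more than 3 consecutive trials of the same condition or
of reinforced trials, CS duration 6 s, US at CS onset + 5 s, integer
inter-trial intervals drawn uniformly from 9–16 s, and a swallow cue
2–5 s after CS offset. The recall phase has no reinforcement.

Sequences are drawn by uniform rejection sampling. For speed, candidate
shuffles are drawn in batches of 256 (`Generator.permuted` over tiled
block templates) and the run-length constraint is checked with a
vectorized cumulative-sum window; candidates are scanned in draw order
and a condition-run rejection skips the reinforcement draw. Both are
pure computational reorganizations: each scanned candidate is an
independent fresh draw, so the accepted sequence follows the exact
joint rejection law of one-at-a-time sampling.

## 8. Synthetic cohort generator

`pavcal.synthetic.simulate_cohort` produces four-channel recordings
with known per-trial truth. The design defaults above are the study
conditions; the cohort defaults are n = 34 participants and a
standardized CS+/CS− effect δ = 0.6.

- **Effect injection.** Per channel, per-trial standardized amplitudes
  are `z_j = δ·1[CS+] + trial noise`, plus between-participant
  variation of the per-participant effect; physical amplitudes are
  `z_j` times a channel scale (HPR 20 ms, SCR 0.3 μS, pupil 0.1 mm,
  respiration envelope 0.02 units). US responses on the SCR channel are
  0.8 μS when delivered, 0.2 μS at omission.
- **Cardiac.** Beats are generated by integral pulse frequency
  modulation (IPFM): a beat fires when the integral of the
  instantaneous rate (reciprocal of the kernel-modulated heart period,
  baseline 0.85 s) crosses unity; the integral is accumulated
  trapezoidally on a 100 Hz grid. With a constant period the simulator
  reproduces exactly periodic beats, which is unit-tested.
- **Other channels.** SCR: baseline 5 μS plus CS- and US-locked kernel
  trains, pink (1/f power spectrum) noise. Pupil: baseline 3.5 mm plus
  kernel train, blinks as missing gaps with fast edges, gaze jitter and
  occasional excursions. Respiration: a 0.25 Hz carrier whose envelope
  (baseline 0.5) is modulated by the RAR kernel train and floored at
  10% of baseline so cycles remain detectable; the recorded truth is
  peak-to-trough, i.e. twice the envelope amplitude.
- Recordings include a 30 s lead-in and 45 s tail so every trial has a
  baseline and full response support. All randomness derives from one
  `numpy` `SeedSequence` spawned per participant and channel: identical
  spec and seed reproduce byte-identical cohorts.
- `noiseless(spec)` zeroes every stochastic term (channel noise, trial
  and between-participant variability, blinks, gaze events, artifacts)
  for parameter-recovery testing; at zero noise every channel's
  estimates land within 2% of the injected truth (cardiac and
  respiration residuals are filter edge effects).

## 9. Statistics

- `hedges_g(t, n)` converts a paired t statistic to Hedges g via
  `g = (t/√n)·J(n−1)` with the exact gamma-function correction
  `J(df) = Γ(df/2)/(√(df/2)·Γ((df−1)/2))`, computed with log-gamma for
  numerical stability. `J` is unit-tested against the closed form and
  the common approximation `1 − 3/(4·df − 1)`.
- `paired_ttest` reports t, df = n−1, two- or one-sided p, and g.
  Two-sided is the default: the published p-values this package's
  conversion targets are consistent with two-sided tests.
- Participant exclusion is a single-pass ±3 SD rule per condition; the
  ±3 SD bound uses the full sample's mean and SD, so the mask is order
  invariant and not iterated.
- Trial-subset scans (first n CS+/CS− pairs; variants skipping the
  first pair or comparing nonreinforced CS+ to double CS− counts),
  phase halves, and Holm–Bonferroni correction are provided for
  learning-curve analyses.
- Monte-Carlo calibration (`paired_test_rejection_rate`) simulates
  participant-level paired effects directly: at n = 34, 2000 null
  cohorts reject at 5% ± 1% (two-sided, α = 0.05), and a true
  standardized effect of 0.5 yields power ≈ 0.80.

## 10. Numerical choices (summary)

- Zero-phase (forward–backward) Butterworth filters throughout; the
  same filter object applied to data and design columns.
- OLS via `numpy.linalg.lstsq` with explicit rank checking; a rank
  deficient design (e.g. duplicated onsets) raises instead of silently
  regularizing.
- Linear interpolation for unevenly sampled derived series (IBI, cycle
  amplitudes); no extrapolation beyond observed support.
- Time is seconds, session-relative; CS onset defines trial time zero
  for segment extraction; all file formats are TSV with YAML sidecars.

## 11. Limitations

- The SCR estimator is a linear constrained GLM, not full variational
  inversion; its amplitudes are proportional to, but not numerically
  identical with, those of nonlinear model inversion.
- Kernels are treated as fixed and identical across participants;
  between-participant kernel variability maps into amplitude error.
- The synthetic generator shares its kernels with the estimators, so
  recovery tests validate the inversion, not the kernels' biological
  adequacy; model mismatch must be assessed on real recordings.
- The IPFM simulator uses a deterministic threshold without beat-timing
  jitter beyond the injected period noise.
- Respiration cycle detection assumes a single dominant breathing mode
  in 0.05–1 Hz; apnoea or sighs produce discarded (not modelled)
  cycles.
- Empirical kernel RF6 is a shape-matched stand-in tabulated from the
  two-gamma family, not an independently measured waveform.
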