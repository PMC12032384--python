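"""Response-function kernels for the linear time-invariant channel models.

Each psychophysiological channel is modelled as a linear time-invariant
(LTI) system: an event at time ``t_e`` with amplitude ``a`` adds
``a * h(t - t_e)`` to the recorded series, where ``h`` is the channel's
response function (RF).  This module defines the kernel families used in
the package (shifted gamma densities, a Gaussian bump, a two-gamma
mixture, and tabulated empirical waveforms), a registry of the named
kernels with their published parameters, and least-squares fitting of a
kernel family to an empirical condition-difference waveform.

θ convention
------------
The gamma kernels are printed with θ in inverse seconds, yet a uniform
rate (or uniform scale) reading places some kernels' peaks far outside
their extraction windows.  Each registry kernel therefore carries an
explicit ``theta_is_scale`` flag chosen so that its peak is consistent
with its window; see docs/methods.md for the per-kernel resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import optimize, signal
from scipy import stats as sps

__all__ = [
    "GammaRFParams",
    "GaussianRFParams",
    "TwoGammaRFParams",
    "EmpiricalRFParams",
    "ResponseFunction",
    "evaluate_rf",
    "fit_rf",
    "FitResult",
    "registry",
    "scr_kernel",
    "make_rf4_from_difference",
]


# ----------------------------------------------------------------------
# parameter families
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class GammaRFParams:
    """Shifted, scaled gamma density: ``c * pdfΓ(t - t0; κ, scale)``.

    ``theta`` is interpreted as the gamma SCALE (seconds) when
    ``theta_is_scale`` is true, otherwise as the RATE (1/s).
    """

    kappa: float
    theta: float
    c: float
    t0: float = 0.0
    theta_is_scale: bool = True

    def __post_init__(self):
        if not (self.kappa > 0 and self.theta > 0):
            raise ValueError("gamma kappa and theta must be positive")
        if not np.isfinite(self.c):
            raise ValueError("gamma scale c must be finite")

    @property
    def scale(self) -> float:
        return self.theta if self.theta_is_scale else 1.0 / self.theta

    @property
    def peak_time(self) -> float:
        """Analytic mode of the kernel (t0 for κ <= 1)."""
        if self.kappa <= 1.0:
            return self.t0
        return self.t0 + (self.kappa - 1.0) * self.scale

    def __call__(self, t: np.ndarray) -> np.ndarray:
        x = np.asarray(t, dtype=float) - self.t0
        out = np.zeros_like(x)
        pos = x > 0
        out[pos] = sps.gamma.pdf(x[pos], self.kappa, scale=self.scale)
        return self.c * out


@dataclass(frozen=True)
class GaussianRFParams:
    """Gaussian bump ``c * exp(-(t - mu)^2 / (2 sigma^2))`` (not a pdf)."""

    mu: float
    sigma: float
    c: float

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError("gaussian sigma must be positive")

    @property
    def peak_time(self) -> float:
        return self.mu

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.c * np.exp(-((t - self.mu) ** 2) / (2.0 * self.sigma**2))


@dataclass(frozen=True)
class TwoGammaRFParams:
    """Difference of two gamma densities: ``c * [γ1(t) - r * γ2(t)]``.

    Components are parameterized by their mean ``o`` (seconds) and
    variance ``d`` (s²): shape = o²/d, scale = d/o.  Both are shifted by
    ``t0``.  This combination rule is a package convention (the published
    parameter table does not define one); it is chosen so the positive
    component peaks where the companion Gaussian kernel fitted to the
    same data peaks (~1.8 s).
    """

    c: float
    o1: float
    o2: float
    d1: float
    d2: float
    r: float
    t0: float = 0.0

    def __post_init__(self):
        for name in ("o1", "o2", "d1", "d2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"two-gamma parameter {name} must be positive")

    def _component(self, x: np.ndarray, o: float, d: float) -> np.ndarray:
        shape, scale = o * o / d, d / o
        out = np.zeros_like(x)
        pos = x > 0
        out[pos] = sps.gamma.pdf(x[pos], shape, scale=scale)
        return out

    @property
    def peak_time(self) -> float:
        """Mode of the positive component (t0 + mode of γ1)."""
        shape, scale = self.o1 * self.o1 / self.d1, self.d1 / self.o1
        return self.t0 + max(shape - 1.0, 0.0) * scale

    def __call__(self, t: np.ndarray) -> np.ndarray:
        x = np.asarray(t, dtype=float) - self.t0
        return self.c * (
            self._component(x, self.o1, self.d1)
            - self.r * self._component(x, self.o2, self.d2)
        )


@dataclass(frozen=True)
class EmpiricalRFParams:
    """Tabulated waveform, evaluated by linear interpolation (0 outside)."""

    grid: np.ndarray
    values: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if grid.ndim != 1 or grid.shape != values.shape:
            raise ValueError("empirical RF grid and values must be equal-length 1-D")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("empirical RF grid must be strictly increasing")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)

    @property
    def peak_time(self) -> float:
        return float(self.grid[int(np.argmax(np.abs(self.values)))])

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.interp(t, self.grid, self.values, left=0.0, right=0.0)


# ----------------------------------------------------------------------
# wrapper
# ----------------------------------------------------------------------
_FAMILIES = {
    GammaRFParams: "gamma",
    GaussianRFParams: "gaussian",
    TwoGammaRFParams: "two_gamma",
    EmpiricalRFParams: "empirical",
}


@dataclass(frozen=True)
class ResponseFunction:
    """A named kernel with its evaluation support and extraction window.

    ``support`` bounds the time range (relative to event onset) over which
    the kernel is evaluated when building regressors; ``window`` is the
    per-trial extraction window used by segment-based estimation (pupil).
    """

    name: str
    params: object
    support: Tuple[float, float] = (0.0, 30.0)
    window: Optional[float] = None

    @property
    def family(self) -> str:
        return _FAMILIES[type(self.params)]

    @property
    def peak_time(self) -> float:
        return self.params.peak_time

    def evaluate(self, grid: np.ndarray) -> np.ndarray:
        grid = np.asarray(grid, dtype=float)
        vals = self.params(grid)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"kernel {self.name} produced non-finite values")
        out = np.where((grid >= self.support[0]) & (grid <= self.support[1]), vals, 0.0)
        return out

    def sample(self, rate: float) -> np.ndarray:
        """Kernel values on ``[max(support[0], 0), support[1]]`` at ``rate``.

        Used for convolution with event impulses: causal part only, so a
        regressor never precedes its event.
        """
        t0 = max(self.support[0], 0.0)
        grid = np.arange(t0, self.support[1] + 0.5 / rate, 1.0 / rate)
        return self.evaluate(grid)

    def normalized(self) -> "ResponseFunction":
        """Copy rescaled so the causal-part absolute peak equals 1.

        Amplitude estimates against a unit-peak kernel are in channel
        units at the response peak, which makes simulator ground truth
        directly comparable.
        """
        peak = np.max(np.abs(self.sample(rate=100.0)))
        if peak == 0:
            raise ValueError(f"kernel {self.name} is identically zero on its support")
        p = self.params
        if isinstance(p, EmpiricalRFParams):
            newp = replace(p, values=p.values / peak)
        else:
            newp = replace(p, c=p.c / peak)
        return replace(self, params=newp)


def evaluate_rf(rf: ResponseFunction, grid: np.ndarray) -> np.ndarray:
    """Evaluate a kernel on an arbitrary grid (seconds since event onset)."""
    return rf.evaluate(grid)


# ----------------------------------------------------------------------
# registry of named kernels
# ----------------------------------------------------------------------
def _rf5_like_waveform(rate: float = 100.0, t_end: float = 3.5) -> EmpiricalRFParams:
    """Synthetic pupil difference waveform shaped like the two-gamma kernel.

    Stand-in source for the empirical kernels (RF4/RF6) that can only be
    regenerated from the real recordings; see their docstrings.
    """
    grid = np.arange(0.0, t_end + 0.5 / rate, 1.0 / rate)
    proto = TwoGammaRFParams(
        c=12.998, o1=1.355, o2=0.750, d1=0.059, d2=0.178, r=2.715, t0=0.439
    )
    vals = proto(grid)
    vals = 0.035 * vals / np.max(np.abs(vals))  # Gaussian-kernel amplitude scale
    return EmpiricalRFParams(grid, vals, provenance="synthetic two-gamma-shaped stand-in")


def make_rf4_from_difference(
    grid: np.ndarray, values: np.ndarray, rate: float, truncate_s: float = 2.88,
    cutoff_hz: float = 2.0,
) -> EmpiricalRFParams:
    """Build the low-pass-filtered empirical pupil kernel from a difference wave.

    A bidirectional (zero-phase) 2-Hz Butterworth low-pass is applied to
    the grand-mean CS+ − CS− waveform, which is then truncated at 2.88 s.
    """
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(values, dtype=float)
    sos = signal.butter(2, cutoff_hz, btype="low", fs=rate, output="sos")
    smoothed = signal.sosfiltfilt(sos, values)
    keep = grid <= truncate_s
    return EmpiricalRFParams(grid[keep], smoothed[keep], provenance="rf4 low-pass mean difference")


def _build_registry() -> Dict[str, ResponseFunction]:
    reg: Dict[str, ResponseFunction] = {}

    # Conditioned heart-period (bradycardia) kernel for reward learning.
    # θ read as RATE here: the scale reading (0.14 s with onset −17.61 s)
    # leaves essentially zero kernel mass after CS onset.  Under the rate
    # reading the kernel decays smoothly over tens of seconds, matching
    # the long conditioned bradycardia time course.
    reg["hprf_rew"] = ResponseFunction(
        "hprf_rew",
        GammaRFParams(kappa=1.72, theta=0.14, c=60.10, t0=-17.61, theta_is_scale=False),
        support=(0.0, 25.0),
    )
    # Fear-conditioning heart-period kernel, included for comparison runs.
    reg["hprf_fear"] = ResponseFunction(
        "hprf_fear",
        GammaRFParams(kappa=48.5, theta=0.182, c=1.0, t0=-7.36, theta_is_scale=True),
        support=(0.0, 25.0),
    )
    # Respiration-amplitude kernel.
    reg["rarf_rew"] = ResponseFunction(
        "rarf_rew",
        GammaRFParams(kappa=40.87, theta=0.29, c=0.14, t0=2.09, theta_is_scale=True),
        support=(0.0, 30.0),
    )
    # Pupil-size kernels; extraction windows 15 s (RF1), 3.5 s (RF2, RF6),
    # 3 s (RF3–RF5).
    reg["psr_rf1"] = ResponseFunction(
        "psr_rf1",
        GammaRFParams(kappa=3.534, theta=1.946, c=-1.183, t0=1.712, theta_is_scale=True),
        support=(0.0, 15.0),
        window=15.0,
    )
    reg["psr_rf2"] = ResponseFunction(
        "psr_rf2",
        GammaRFParams(kappa=30.781, theta=0.042, c=0.033, t0=0.506, theta_is_scale=True),
        support=(0.0, 3.5),
        window=3.5,
    )
    reg["psr_rf3"] = ResponseFunction(
        "psr_rf3",
        GaussianRFParams(mu=1.784, sigma=0.246, c=0.035),
        support=(0.0, 3.0),
        window=3.0,
    )
    rf4_src = _rf5_like_waveform(t_end=3.0)
    reg["psr_rf4"] = ResponseFunction(
        "psr_rf4",
        make_rf4_from_difference(rf4_src.grid, rf4_src.values, rate=100.0),
        support=(0.0, 2.88),
        window=3.0,
    )
    reg["psr_rf5"] = ResponseFunction(
        "psr_rf5",
        TwoGammaRFParams(c=12.998, o1=1.355, o2=0.750, d1=0.059, d2=0.178, r=2.715, t0=0.439),
        support=(0.0, 3.0),
        window=3.0,
    )
    reg["psr_rf6"] = ResponseFunction(
        "psr_rf6",
        _rf5_like_waveform(t_end=3.5),
        support=(0.0, 3.5),
        window=3.5,
    )
    return reg


_REGISTRY = _build_registry()


def registry() -> Dict[str, ResponseFunction]:
    """All named kernels, keyed by name.

    ``psr_rf4`` and ``psr_rf6`` are empirical kernels that in the original
    analysis derive from real recordings; here they are shipped as
    synthetic stand-in waveforms (see :func:`make_rf4_from_difference`
    for rebuilding RF4 from data).
    """
    return dict(_REGISTRY)


def get_rf(name: str) -> ResponseFunction:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown response function {name!r}; valid names: {sorted(_REGISTRY)}"
        ) from None


def scr_kernel(tau_rise: float = 1.4, tau_decay: float = 4.0) -> ResponseFunction:
    """Canonical skin-conductance kernel: unit-peak bi-exponential.

    ``h(t) ∝ exp(-t/tau_decay) - exp(-t/tau_rise)``, rise ~1–2 s and decay
    ~3–5 s, standing in for the validated peripheral SCR model.  Peak is
    normalized to 1 so amplitude estimates are in microsiemens.
    """
    if not 0 < tau_rise < tau_decay:
        raise ValueError("require 0 < tau_rise < tau_decay")
    t_peak = np.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)
    peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    grid = np.arange(0.0, 20.0 + 1e-9, 0.01)
    vals = (np.exp(-grid / tau_decay) - np.exp(-grid / tau_rise)) / peak
    return ResponseFunction(
        "scrf", EmpiricalRFParams(grid, vals, provenance="bi-exponential canonical SCR kernel"),
        support=(0.0, 20.0),
    )


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------
@dataclass
class FitResult:
    params: object
    sse: float
    r_squared: float
    converged: bool
    family: str = ""
    message: str = ""


_GAMMA_FIELDS = ("kappa", "theta", "c", "t0")
_GAUSS_FIELDS = ("mu", "sigma", "c")


def fit_rf(
    grid: np.ndarray,
    waveform: np.ndarray,
    family: str,
    init: dict,
    bounds: Optional[dict] = None,
    theta_is_scale: bool = True,
    max_nfev: int = 20_000,
) -> FitResult:
    """Least-squares fit of a kernel family to an empirical waveform.

    ``init`` maps parameter names (gamma: kappa, theta, c, t0; gaussian:
    mu, sigma, c) to starting values; ``bounds`` optionally maps names to
    (lo, hi).  Deterministic given the starting point.  On
    non-convergence the best-so-far parameters are still returned with
    ``converged=False``.
    """
    grid = np.asarray(grid, dtype=float)
    waveform = np.asarray(waveform, dtype=float)
    if family == "gamma":
        names = _GAMMA_FIELDS

        def build(v):
            return GammaRFParams(
                kappa=v[0], theta=v[1], c=v[2], t0=v[3], theta_is_scale=theta_is_scale
            )

        default_bounds = {"kappa": (1e-6, np.inf), "theta": (1e-6, np.inf),
                          "c": (-np.inf, np.inf), "t0": (-np.inf, np.inf)}
    elif family == "gaussian":
        names = _GAUSS_FIELDS

        def build(v):
            return GaussianRFParams(mu=v[0], sigma=v[1], c=v[2])

        default_bounds = {"mu": (-np.inf, np.inf), "sigma": (1e-6, np.inf),
                          "c": (-np.inf, np.inf)}
    else:
        raise ValueError(f"fit_rf supports 'gamma' and 'gaussian' families, got {family!r}")

    x0 = np.array([float(init[k]) for k in names])
    bnd = dict(default_bounds)
    if bounds:
        bnd.update(bounds)
    lo = np.array([bnd[k][0] for k in names])
    hi = np.array([bnd[k][1] for k in names])

    def residuals(v):
        return build(v)(grid) - waveform

    sol = optimize.least_squares(
        residuals, x0, bounds=(lo, hi), max_nfev=max_nfev, xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    fitted = build(sol.x)
    resid = residuals(sol.x)
    sse = float(resid @ resid)
    tot = float(np.sum((waveform - waveform.mean()) ** 2))
    r2 = 1.0 - sse / tot if tot > 0 else (1.0 if sse < 1e-12 else 0.0)
    return FitResult(
        params=fitted, sse=sse, r_squared=r2, converged=bool(sol.success),
        family=family, message=sol.message,
    )
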