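"""Physiologically based heartbeat simulators.

Two classic model families generate synthetic records against which the
mixture decomposition is validated:

**Integral pulse frequency modulation (IPFM).**  A modulating input — a
sinoatrial baseline rate times ``1 + m(t)``, where ``m(t)`` superposes a slow
"sympathetic" and a faster "parasympathetic" oscillator plus Gaussian noise —
is integrated; each time the integral reaches the threshold R a beat is
emitted and the integrator resets.  With constant input the model is exactly
periodic with interval ``R / baseline``.

**Three-input switching model.**  The interbeat interval is a weighted
combination of three inputs (sinoatrial node, parasympathetic and sympathetic
fibres).  Each input relaxes, with feedback strength ``g`` and additive white
noise, toward its own preferred level; the preferred level itself is a random
step function — levels drawn uniformly within a physiological range, dwell
times exponential.  The switching of preferred levels makes the model a
state-space model with switching dynamics and produces the slow regime
changes seen in day-long records.

Both simulators are deterministic under a fixed seed.  A cohort helper draws
per-subject parameter jitter (multiplicative lognormal) around a base
configuration, mimicking between-subject variability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Union

import numpy as np
import numpy.typing as npt
from scipy.signal import lfilter

from .series import BeatEventSeries, HeartRateSeries, RRSeries, beats_to_rr, rr_to_bpm

__all__ = [
    "IPFMParams",
    "SwitchingInput",
    "SwitchingModelParams",
    "simulate_ipfm",
    "switching_trajectory",
    "simulate_switching",
    "synthetic_cohort",
]

logger = logging.getLogger(__name__)

# Clamp window for switching-model interbeat intervals, seconds.
RR_CLAMP = (0.2, 4.0)


@dataclass(frozen=True)
class IPFMParams:
    """IPFM configuration.

    threshold: integrator threshold R (a beat fires when the integral hits it).
    baseline: sinoatrial rate in Hz (1.1 Hz ~ 66 bpm at rest).
    f_s, f_p: sympathetic / parasympathetic oscillator frequencies (Hz); the
        sympathetic branch acts below ~0.1 Hz, the vagal branch up to ~0.4 Hz.
    a_s, a_p: oscillator amplitudes (fraction of baseline).  The sympathetic
        amplitude dominates by default: its slow swing sets the two outer
        bulks of the rate distribution, the vagal oscillator and the noise
        fill the centre.
    noise_sd: stationary standard deviation of the Gaussian noise term of the
        modulation.  The noise is band-limited (Ornstein-Uhlenbeck with
        correlation time ``noise_tau``): autonomic fluctuations act on the
        scale of seconds, and noise faster than a beat would be averaged away
        by the integrator, contributing nothing to rate variability.
    noise_tau: noise correlation time, seconds.
    duration: record length in seconds.
    dt: integration step; must resolve the fastest oscillator.
    """

    threshold: float = 1.0
    baseline: float = 1.1
    f_s: float = 0.1
    f_p: float = 0.25
    a_s: float = 0.25
    a_p: float = 0.05
    noise_sd: float = 0.07
    noise_tau: float = 3.0
    duration: float = 7200.0
    dt: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if self.threshold <= 0 or self.baseline <= 0:
            raise ValueError("threshold and baseline must be positive")
        if self.a_s < 0 or self.a_p < 0 or self.a_s + self.a_p >= 1.0:
            raise ValueError("amplitudes must be non-negative with a_s + a_p < 1")
        if not self.f_s < self.f_p:
            raise ValueError("expected f_s < f_p (sympathetic slower than vagal)")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.noise_tau <= 0:
            raise ValueError("noise correlation time must be positive")
        expected_beats = self.baseline * self.duration / self.threshold
        if expected_beats < 10:
            raise ValueError("duration must cover at least 10 expected beats")

    @property
    def step(self) -> float:
        limit = 1.0 / (50.0 * self.f_p)
        return min(self.dt, limit) if self.dt is not None else min(0.01, limit)


@dataclass(frozen=True)
class SwitchingInput:
    """One autonomic input of the switching model.

    tau_weight: contribution weight of this input to the interbeat interval.
    g: feedback strength (1/s) pulling the input toward its preferred level.
    low, high: range (interval units, s) of the uniformly drawn preferred levels.
    mean_dwell: mean of the exponential dwell time between level switches (s).
    noise_sd: white-noise intensity of the input dynamics.
    """

    tau_weight: float
    g: float = 2.0
    low: float = 0.6
    high: float = 1.2
    mean_dwell: float = 3.0
    noise_sd: float = 0.06

    def __post_init__(self):
        if self.tau_weight <= 0 or self.g <= 0 or self.mean_dwell <= 0:
            raise ValueError("tau_weight, g and mean_dwell must be positive")
        if not self.low < self.high:
            raise ValueError("preferred-level range must satisfy low < high")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


def _default_inputs() -> tuple[SwitchingInput, SwitchingInput, SwitchingInput]:
    # The sinoatrial range is wide (it carries most of the interval swing),
    # the autonomic ranges narrower and offset against each other: the
    # parasympathetic input lengthens intervals, the sympathetic one shortens
    # them.  Combined, the per-beat rate spans roughly 55-100 bpm and its
    # distribution decomposes into a central bulk and two shoulders.
    return (
        SwitchingInput(tau_weight=0.5, low=0.60, high=1.20),   # sinoatrial
        SwitchingInput(tau_weight=0.3, low=0.80, high=1.30),   # parasympathetic
        SwitchingInput(tau_weight=0.2, low=0.45, high=0.75),   # sympathetic
    )


@dataclass(frozen=True)
class SwitchingModelParams:
    """Three-input switching model configuration.

    inputs: (sinoatrial, parasympathetic, sympathetic) input parameters.
    rr_init: initial interbeat interval (s); only the transient depends on it.
    duration: record length in seconds.
    dt: Euler grid step for the input dynamics (exact exponential updates are
        used on this grid, so the step only limits the switching resolution).
    """

    inputs: tuple[SwitchingInput, SwitchingInput, SwitchingInput] = field(
        default_factory=_default_inputs
    )
    rr_init: float = 0.8
    duration: float = 7200.0
    dt: float = 0.05
    seed: Optional[int] = None

    def __post_init__(self):
        if len(self.inputs) != 3:
            raise ValueError("the switching model has exactly three inputs")
        if self.rr_init <= 0 or self.duration <= 0 or self.dt <= 0:
            raise ValueError("rr_init, duration and dt must be positive")

    @property
    def weights(self) -> npt.NDArray[np.float64]:
        w = np.array([inp.tau_weight for inp in self.inputs], dtype=float)
        return w / w.sum()


# ---------------------------------------------------------------------------
# IPFM


def simulate_ipfm(p: IPFMParams) -> BeatEventSeries:
    """Integrate-and-fire beat generation.

    The modulating signal ``v(t) = baseline * (1 + m(t))`` with
    ``m(t) = a_s sin(2 pi f_s t) + a_p sin(2 pi f_p t) + noise`` is integrated
    by the trapezoidal rule on a fixed grid; a beat is emitted whenever the
    running integral crosses a multiple of the threshold R, with the crossing
    time refined by linear interpolation inside the step.  The noise term is
    an Ornstein-Uhlenbeck path (stationary sd ``noise_sd``, correlation time
    ``noise_tau``), simulated by its exact discretization on the grid.
    """
    rng = np.random.default_rng(p.seed)
    dt = p.step
    n_steps = int(np.ceil(p.duration / dt))
    t = np.arange(n_steps + 1) * dt
    m = p.a_s * np.sin(2.0 * np.pi * p.f_s * t) + p.a_p * np.sin(2.0 * np.pi * p.f_p * t)
    if p.noise_sd > 0:
        decay = np.exp(-dt / p.noise_tau)
        shocks = rng.normal(0.0, p.noise_sd * np.sqrt(1.0 - decay**2), size=t.size - 1)
        x0 = rng.normal(0.0, p.noise_sd)
        tail, _ = lfilter([1.0], [1.0, -decay], shocks, zi=np.array([decay * x0]))
        m = m + np.concatenate([[x0], tail])
    v = p.baseline * (1.0 + m)

    nonpos = float((v <= 0).mean())
    if nonpos > 0.10:
        raise ValueError(
            f"modulating input non-positive for {100 * nonpos:.1f}% of the record; "
            "amplitudes/noise too large for this baseline"
        )

    # cumulative trapezoidal integral of v; strictly increasing wherever v > 0
    increments = 0.5 * (v[1:] + v[:-1]) * dt
    cum = np.concatenate([[0.0], np.cumsum(increments)])
    n_beats = int(np.floor(cum[-1] / p.threshold))
    if n_beats < 2:
        raise ValueError("fewer than two beats generated; lengthen the record")
    levels = p.threshold * np.arange(1, n_beats + 1)
    idx = np.searchsorted(cum, levels)  # cum[idx-1] < level <= cum[idx]
    frac = (levels - cum[idx - 1]) / (cum[idx] - cum[idx - 1])
    beat_times = t[idx - 1] + frac * dt
    return BeatEventSeries(times=beat_times)


# ---------------------------------------------------------------------------
# switching model


def _exact_ou_path(
    pref: npt.NDArray, g: float, dt: float, x0: float, shocks: npt.NDArray
) -> npt.NDArray[np.float64]:
    """Exact discretization of dx/dt = -g (x - pref(t)) + noise on the grid.

    ``pref`` is zero-order-held over each step, so the exponential update
    x[i] = pref[i-1] + (x[i-1] - pref[i-1]) exp(-g dt) + shock[i-1]
    solves the ODE exactly between grid points.  The linear recurrence is
    evaluated with an IIR filter.
    """
    decay = np.exp(-g * dt)
    u = (1.0 - decay) * pref[:-1] + shocks
    out, _ = lfilter([1.0], [1.0, -decay], u, zi=np.array([decay * x0]))
    return np.concatenate([[x0], out])


def switching_trajectory(
    p: SwitchingModelParams,
) -> tuple[npt.NDArray, npt.NDArray, npt.NDArray, npt.NDArray]:
    """Grid-level simulation of the switching model.

    Returns ``(t_grid, prefs, inputs, rr)`` where ``prefs`` and ``inputs`` are
    (n_steps, 3) arrays of preferred levels and input trajectories and ``rr``
    is the interbeat-interval trajectory.  Preferred levels are zero-order-held
    on the grid; with that convention every update below is the exact solution
    of the continuous dynamics over each step, including the forcing of RR by
    the exponentially relaxing inputs (matched-exponential convolution terms),
    so the zero-noise trajectory agrees with a high-resolution ODE solve to
    integrator precision.
    """
    rng = np.random.default_rng(p.seed)
    n_steps = int(np.ceil(p.duration / p.dt)) + 1
    t_grid = np.arange(n_steps) * p.dt
    w = p.weights

    prefs = np.empty((n_steps, 3))
    inputs = np.empty((n_steps, 3))
    for j, inp in enumerate(p.inputs):
        pref = _step_process(inp, p.duration, p.dt, n_steps, rng)
        if inp.noise_sd > 0:
            decay = np.exp(-inp.g * p.dt)
            scale = inp.noise_sd * np.sqrt((1.0 - decay**2) / (2.0 * inp.g))
            shocks = rng.normal(0.0, scale, size=n_steps - 1)
        else:
            shocks = np.zeros(n_steps - 1)
        prefs[:, j] = pref
        inputs[:, j] = _exact_ou_path(pref, inp.g, p.dt, float(pref[0]), shocks)

    # RR relaxes toward the tau-weighted combination of the inputs with the
    # mean feedback rate.  Within a step the combined input is
    # sum_j w_j [pref_j + (x_j - pref_j) e^{-g_j s}]; the exact response of RR
    # to each exponential forcing term is a matched-exponential convolution.
    g_rr = float(np.mean([inp.g for inp in p.inputs]))
    decay_rr = np.exp(-g_rr * p.dt)
    kernels = np.empty(3)
    for j, inp in enumerate(p.inputs):
        if abs(g_rr - inp.g) < 1e-12 * max(g_rr, inp.g):
            kernels[j] = g_rr * p.dt * decay_rr
        else:
            kernels[j] = g_rr * (np.exp(-inp.g * p.dt) - decay_rr) / (g_rr - inp.g)
    t_seg = prefs[:-1] @ w  # combined preferred level per step
    forcing = (1.0 - decay_rr) * t_seg + ((inputs[:-1] - prefs[:-1]) * w) @ kernels
    rr_tail, _ = lfilter(
        [1.0], [1.0, -decay_rr], forcing, zi=np.array([decay_rr * p.rr_init])
    )
    rr = np.concatenate([[p.rr_init], rr_tail])
    return t_grid, prefs, inputs, rr


def simulate_switching(p: SwitchingModelParams) -> RRSeries:
    """Simulate the three-input switching model and sample the interval per beat.

    Each input follows an Ornstein-Uhlenbeck relaxation
    ``dI/dt = -g (I - P(t)) + noise`` toward its piecewise-constant preferred
    level ``P(t)`` (levels uniform in [low, high], exponential dwell times);
    the interbeat interval relaxes toward the tau-weighted combination
    ``sum_j w_j I_j(t)``.  Beats are emitted sequentially: each interval is
    read off the RR trajectory at the beat's onset time.

    Intervals outside the physiological window (0.2, 4.0) s are clamped and
    counted; more than 5% clamped raises an error (model misuse).
    """
    t_grid, _, _, rr_grid = switching_trajectory(p)
    lo, hi = RR_CLAMP
    beat_times = []
    intervals = []
    clamped = 0
    t = 0.0
    while t < p.duration:
        rr = float(np.interp(t, t_grid, rr_grid))
        if rr < lo or rr > hi:
            rr = min(max(rr, lo), hi)
            clamped += 1
        beat_times.append(t)
        intervals.append(rr)
        t += rr
    if clamped:
        logger.info("switching model clamped %d of %d intervals", clamped, len(intervals))
    if len(intervals) and clamped / len(intervals) > 0.05:
        raise ValueError(
            f"{clamped} of {len(intervals)} intervals left the physiological window; "
            "parameters are inconsistent with a plausible heart"
        )
    return RRSeries(intervals=np.array(intervals), onsets=np.array(beat_times))


def _step_process(
    inp: SwitchingInput, duration: float, dt: float, n_steps: int, rng: np.random.Generator
) -> npt.NDArray[np.float64]:
    """Piecewise-constant preferred level: uniform levels, exponential dwells.

    Switch times are aligned to the integration grid so the exponential input
    update stays exact within each step.
    """
    times = [0.0]
    while times[-1] < duration:
        times.append(times[-1] + rng.exponential(inp.mean_dwell))
    n_segments = len(times) - 1
    levels = rng.uniform(inp.low, inp.high, size=n_segments)
    grid = np.arange(n_steps) * dt
    seg = np.searchsorted(times, grid, side="right") - 1
    seg = np.clip(seg, 0, n_segments - 1)
    return levels[seg]


# ---------------------------------------------------------------------------
# cohorts


def _jitter_ipfm(base: IPFMParams, factor_of, seed: int) -> IPFMParams:
    return replace(
        base,
        baseline=base.baseline * factor_of("baseline"),
        a_s=min(base.a_s * factor_of("a_s"), 0.45),
        a_p=min(base.a_p * factor_of("a_p"), 0.45),
        noise_sd=base.noise_sd * factor_of("noise_sd"),
        seed=seed,
    )


def _jitter_switching(base: SwitchingModelParams, factor_of, seed: int) -> SwitchingModelParams:
    new_inputs = []
    for j, inp in enumerate(base.inputs):
        scale = factor_of(f"level_{j}")
        new_inputs.append(
            replace(inp, low=inp.low * scale, high=inp.high * scale,
                    g=inp.g * factor_of(f"g_{j}"))
        )
    return replace(base, inputs=tuple(new_inputs), seed=seed)


def synthetic_cohort(
    n_subjects: int,
    model: Literal["ipfm", "switching"] = "ipfm",
    base_params: Optional[Union[IPFMParams, SwitchingModelParams]] = None,
    jitter: float = 0.05,
    seed: Optional[int] = None,
) -> list[HeartRateSeries]:
    """Simulate a cohort of heart-rate series with between-subject variability.

    Per-subject parameters are jittered multiplicatively around the base
    configuration with lognormal factors of standard deviation ``jitter``
    (jitter = 0 reproduces the base parameters for every subject).  Subject
    seeds derive deterministically from the master seed and the subject index.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    if model not in ("ipfm", "switching"):
        raise ValueError(f"unknown model {model!r}")
    if base_params is None:
        base_params = IPFMParams() if model == "ipfm" else SwitchingModelParams()
    master = np.random.default_rng(seed)
    subject_seeds = master.integers(0, 2**31 - 1, size=n_subjects)
    series: list[HeartRateSeries] = []
    sigma = np.sqrt(np.log1p(jitter**2))  # lognormal with sd ~ jitter around 1
    for s in range(n_subjects):
        sub_rng = np.random.default_rng(int(subject_seeds[s]))

        def factor_of(_name: str) -> float:
            if jitter == 0:
                return 1.0
            return float(np.exp(sub_rng.normal(-0.5 * sigma**2, sigma)))

        sim_seed = int(sub_rng.integers(0, 2**31 - 1))
        if model == "ipfm":
            params = _jitter_ipfm(base_params, factor_of, sim_seed)
            rr = beats_to_rr(simulate_ipfm(params))
        else:
            params = _jitter_switching(base_params, factor_of, sim_seed)
            rr = simulate_switching(params)
        series.append(rr_to_bpm(rr))
    return series
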