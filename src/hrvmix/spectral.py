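"""Frequency-domain analysis of heart-rate series.

A tachogram is irregularly sampled (one value per beat), so FFT-based
estimation first resamples it on a uniform grid — cubic interpolation at 4 Hz
by default, safely above the Nyquist requirement of the 0.15-0.40 Hz
high-frequency band.  The power spectral density is then estimated by Welch's
averaged periodogram (Hann window, 50% overlap, per-segment linear detrend,
one-sided density normalization so the integral over frequency recovers the
variance of the detrended signal).

Band powers follow the conventional short-term HRV bands: VLF 0.003-0.04 Hz,
LF 0.04-0.15 Hz (mixed sympathetic/parasympathetic), HF 0.15-0.40 Hz
(parasympathetic).  Long records additionally show an approximate 1/f^beta
decay of power at low frequency; ``fit_loglog_slope`` estimates beta by least
squares on the log-log spectrum.

A Lomb-Scargle periodogram is offered for irregular series without
resampling, as an alternative diagnostic only: it is not a consistent
estimator and is never the default route.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import numpy.typing as npt
from scipy import signal
from scipy.interpolate import CubicSpline

from .series import HeartRateSeries

__all__ = [
    "PowerSpectrum",
    "BandPowers",
    "SlopeFit",
    "DEFAULT_BANDS",
    "resample_uniform",
    "power_spectrum",
    "lomb_periodogram",
    "band_powers",
    "fit_loglog_slope",
]

logger = logging.getLogger(__name__)

#: Conventional short-term HRV analysis bands, Hz.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "vlf": (0.003, 0.04),
    "lf": (0.04, 0.15),
    "hf": (0.15, 0.40),
}

DEFAULT_RESAMPLE_HZ = 4.0
DEFAULT_SLOPE_RANGE = (0.003, 0.1)


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided power spectral density: frequencies (Hz) and power (bpm^2/Hz)."""

    frequencies: npt.NDArray[np.float64]
    power: npt.NDArray[np.float64]
    method: str = "welch"
    fs: Optional[float] = None

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        p = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "power", p)
        if f.shape != p.shape:
            raise ValueError("frequencies and power must have equal length")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if not np.all(np.isfinite(p)) or np.any(p < 0):
            raise ValueError("power must be finite and non-negative")

    def total_power(self) -> float:
        """Integral of the density over all estimated frequencies."""
        return float(np.trapezoid(self.power, self.frequencies))


@dataclass(frozen=True)
class BandPowers:
    """Integrated band powers (bpm^2) and derived sympathovagal indices."""

    vlf: float
    lf: float
    hf: float

    @property
    def lf_hf_ratio(self) -> Optional[float]:
        """LF/HF ratio; ``None`` (undefined) when the HF power vanishes."""
        return self.lf / self.hf if self.hf > 0 else None

    @property
    def lf_normalized(self) -> Optional[float]:
        total = self.lf + self.hf
        return self.lf / total if total > 0 else None

    @property
    def hf_normalized(self) -> Optional[float]:
        total = self.lf + self.hf
        return self.hf / total if total > 0 else None

    def to_dict(self) -> dict:
        return {
            "vlf": self.vlf,
            "lf": self.lf,
            "hf": self.hf,
            "lf_hf_ratio": self.lf_hf_ratio,
            "lf_normalized": self.lf_normalized,
            "hf_normalized": self.hf_normalized,
        }


@dataclass(frozen=True)
class SlopeFit:
    """Least-squares line on (log10 f, log10 P): P ~ c * f^beta."""

    beta: float
    intercept: float
    f_min: float
    f_max: float
    n_points: int
    residual_rms: float


def resample_uniform(hr: HeartRateSeries, fs: float = DEFAULT_RESAMPLE_HZ) -> HeartRateSeries:
    """Cubic-spline interpolation of a beat-aligned series onto a uniform grid.

    The grid runs from the first to the last native sample with step ``1/fs``.
    """
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    if len(hr) < 4:
        raise ValueError("need at least 4 samples for cubic interpolation")
    spline = CubicSpline(hr.times, hr.values)
    t = hr.times[0] + np.arange(int(np.floor(hr.duration * fs)) + 1) / fs
    values = spline(t)
    # cubic overshoot cannot produce physical (positive) rates below tiny floor
    values = np.maximum(values, np.finfo(float).tiny)
    return HeartRateSeries(times=t, values=values)


def power_spectrum(
    series: HeartRateSeries,
    fs: Optional[float] = None,
    segment_length: Optional[int] = None,
    detrend: str = "linear",
    window: str = "hann",
) -> PowerSpectrum:
    """Welch-averaged one-sided PSD of a uniformly sampled series.

    ``fs`` defaults to the grid rate inferred from the time axis (which must
    be uniform); ``segment_length`` defaults to ``min(N, 2**12)``.  Density
    scaling: integrating the returned power over frequency approximates the
    variance of the detrended signal.
    """
    steps = np.diff(series.times)
    inferred = float(np.median(steps))
    if np.max(np.abs(steps - inferred)) > 1e-6 * inferred:
        raise ValueError("series is not uniformly sampled; resample first")
    if fs is None:
        fs = 1.0 / inferred
    n = len(series)
    if segment_length is None:
        segment_length = min(n, 4096)
    if segment_length > n:
        raise ValueError(f"segment length {segment_length} exceeds series length {n}")
    f, p = signal.welch(
        series.values,
        fs=fs,
        window=window,
        nperseg=segment_length,
        noverlap=segment_length // 2,
        detrend=detrend,
        scaling="density",
        return_onesided=True,
    )
    # drop the zero-frequency bin: log-log slope fitting needs f > 0 and the
    # DC term carries no variance after detrending
    return PowerSpectrum(frequencies=f[1:], power=p[1:], method="welch", fs=fs)


def lomb_periodogram(
    hr: HeartRateSeries, frequencies: Optional[npt.NDArray] = None
) -> PowerSpectrum:
    """Lomb-Scargle periodogram of an irregularly sampled series.

    Alternative diagnostic for series that cannot be resampled; not a
    consistent PSD estimator, so Welch on the resampled series stays the
    default everywhere else in the package.
    """
    if frequencies is None:
        duration = hr.duration
        f_min = max(1.0 / duration, 1e-4)
        mean_dt = duration / (len(hr) - 1)
        f_max = 0.5 / mean_dt
        frequencies = np.linspace(f_min, f_max, 1 << 10)
    x = hr.values - hr.values.mean()
    pgram = signal.lombscargle(hr.times, x, 2.0 * np.pi * frequencies)
    # rescale to an approximate one-sided density: integral over the evaluated
    # grid equals the sample variance (Parseval-style normalization)
    raw_integral = float(np.trapezoid(pgram, frequencies))
    scale = x.var() / raw_integral if raw_integral > 0 else 0.0
    return PowerSpectrum(frequencies=frequencies, power=pgram * scale, method="lomb")


def band_powers(
    ps: PowerSpectrum, bands: Optional[dict[str, tuple[float, float]]] = None
) -> BandPowers:
    """Trapezoidal integration of the PSD over the VLF/LF/HF bands."""
    bands = DEFAULT_BANDS if bands is None else bands
    out = {}
    for name in ("vlf", "lf", "hf"):
        lo, hi = bands[name]
        out[name] = _integrate_band(ps, lo, hi)
    return BandPowers(**out)


def _integrate_band(ps: PowerSpectrum, lo: float, hi: float) -> float:
    """Integral of the density over [lo, hi] with linear interpolation at the edges."""
    f, p = ps.frequencies, ps.power
    lo = max(lo, float(f[0]))
    hi = min(hi, float(f[-1]))
    if hi <= lo:
        return 0.0
    grid = np.unique(np.concatenate([[lo, hi], f[(f > lo) & (f < hi)]]))
    vals = np.interp(grid, f, p)
    return float(np.trapezoid(vals, grid))


def fit_loglog_slope(
    ps: PowerSpectrum,
    f_min: float = DEFAULT_SLOPE_RANGE[0],
    f_max: float = DEFAULT_SLOPE_RANGE[1],
) -> SlopeFit:
    """Least-squares power-law exponent beta of P(f) ~ c * f^beta on [f_min, f_max].

    Points with zero power are excluded (logged); at least five usable points
    are required.
    """
    f, p = ps.frequencies, ps.power
    in_range = (f >= f_min) & (f <= f_max)
    usable = in_range & (p > 0)
    n_zero = int(in_range.sum() - usable.sum())
    if n_zero:
        logger.info("slope fit: excluded %d zero-power points", n_zero)
    if usable.sum() < 5:
        raise ValueError(
            f"need at least 5 positive-power points in [{f_min}, {f_max}] Hz, "
            f"found {int(usable.sum())}"
        )
    lx, ly = np.log10(f[usable]), np.log10(p[usable])
    beta, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (beta * lx + intercept)
    return SlopeFit(
        beta=float(beta),
        intercept=float(intercept),
        f_min=f_min,
        f_max=f_max,
        n_points=int(usable.sum()),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )
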