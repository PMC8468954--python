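"""Velocity autocorrelation functions and vibrational power spectra.

The power spectrum of a set of atomic velocities is obtained the classical
MD way: the normalized velocity autocorrelation function (VACF)

    C(k) = < v(t) . v(t + k dt) > / < v(t) . v(t) >

is estimated by averaging over time origins and selected atoms, tapered
with a lag window, and cosine-transformed.  Because the true VACF is even
in the lag, the windowed one-sided estimate is extended symmetrically to
N = 2 L - 2 samples before the FFT, which makes the transform exactly real;
the wavenumber axis is j / (c N dt) with resolution 1 / (c N dt).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .constants import C_CM_PER_FS

logger = logging.getLogger(__name__)

__all__ = [
    "Vacf",
    "Spectrum",
    "velocity_autocorrelation",
    "power_spectrum",
    "band_regions",
    "WINDOWS",
]


@dataclass
class Vacf:
    """Normalized velocity autocorrelation function, C(0) = 1."""

    lags: np.ndarray     # fs
    values: np.ndarray   # dimensionless

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, float)
        self.values = np.asarray(self.values, float)
        if self.lags.shape != self.values.shape:
            raise ValueError("lags and values must have equal length")

    def __len__(self) -> int:
        return len(self.lags)


@dataclass
class Spectrum:
    """One-sided vibrational power spectrum on a wavenumber axis (cm^-1)."""

    wavenumber: np.ndarray
    intensity: np.ndarray
    resolution: float           # cm^-1 per bin
    window: str = "hann"
    metadata: dict = field(default_factory=dict)

    def peak_wavenumber(self) -> float:
        return float(self.wavenumber[int(np.argmax(self.intensity))])


def _lag_window(name: str, length: int) -> np.ndarray:
    """One-sided lag windows: w_0 = 1, tapering toward the last lag."""
    k = np.arange(length)
    if length == 1:
        return np.ones(1)
    x = np.pi * k / (length - 1)
    if name == "hann":
        return 0.5 * (1.0 + np.cos(x))
    if name == "hamming":
        return 0.54 + 0.46 * np.cos(x)
    if name in ("boxcar", "rect", "none"):
        return np.ones(length)
    raise ValueError(f"unknown window {name!r}; choose from {sorted(WINDOWS)}")


WINDOWS = ("hann", "hamming", "boxcar")


def velocity_autocorrelation(velocities: np.ndarray,
                             max_lag: int) -> Vacf:
    """VACF of one or more velocity components, normalized to C(0) = 1.

    ``velocities`` may be (n_frames,), (n_frames, k) or
    (n_frames, n_atoms, 3); trailing axes are treated as independent
    components whose correlations are summed (the dot product in
    < v(t) . v(t+k dt) >).  All available time origins are used per lag
    (FFT-based estimator, normalization by the number of origins).

    ``lags`` are reported in frame units times dt=1; multiply by the frame
    spacing or pass them straight to :func:`power_spectrum` together with
    ``dt``.  Raises on zero-variance input (normalization undefined).
    """
    v = np.asarray(velocities, float)
    if v.ndim == 1:
        v = v[:, None]
    else:
        v = v.reshape(v.shape[0], -1)
    n = v.shape[0]
    if max_lag < 1 or max_lag > n:
        raise ValueError(f"max_lag must be in [1, {n}], got {max_lag}")
    # FFT autocorrelation, summed over components
    n_fft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(v, n=n_fft, axis=0)
    acf = np.fft.irfft((spec * spec.conj()).real.sum(axis=1), n=n_fft)[:max_lag]
    origins = n - np.arange(max_lag)
    acf = acf / origins
    if acf[0] <= 0:
        raise ValueError("zero-variance velocities: VACF normalization undefined")
    return Vacf(lags=np.arange(max_lag, dtype=float), values=acf / acf[0])


def power_spectrum(vacf: Vacf, dt: float, window: str = "hann") -> Spectrum:
    """Cosine-transform a windowed VACF into a one-sided power spectrum.

    The windowed VACF g_k (k = 0 .. L-1) is extended evenly to
    N = 2 L - 2 points and transformed with a real FFT; the result is real
    by construction.  Tiny negative values from the lag-window estimate are
    clipped to zero and logged.  Wavenumbers: j / (c N dt), cm^-1.
    """
    if len(vacf) == 0:
        raise ValueError("empty VACF")
    if dt <= 0:
        raise ValueError("dt must be positive")
    g = vacf.values * _lag_window(window, len(vacf))
    L = len(g)
    if L >= 2:
        h = np.concatenate([g, g[-2:0:-1]])
    else:
        h = g
    n_full = len(h)
    raw = np.fft.rfft(h).real * dt
    neg = raw < 0
    if np.any(neg):
        worst = float(raw.min())
        scale = float(np.abs(raw).max())
        if scale > 0 and -worst > 1e-9 * scale:
            logger.info(
                "power_spectrum: clipped %d negative bins "
                "(worst %.3g of max %.3g)", int(neg.sum()), worst, scale,
            )
        raw = np.where(neg, 0.0, raw)
    resolution = 1.0 / (C_CM_PER_FS * n_full * dt)
    wavenumber = resolution * np.arange(len(raw))
    return Spectrum(
        wavenumber=wavenumber,
        intensity=raw,
        resolution=resolution,
        window=window,
        metadata={"max_lag": L, "dt_fs": dt, "n_full": n_full},
    )


def band_regions(spec: Spectrum, rel_threshold: float = 0.05,
                 merge_gap: float = 50.0) -> list[tuple[float, float]]:
    """Contiguous wavenumber regions with intensity >= rel_threshold * max.

    Runs separated by sub-threshold gaps no wider than ``merge_gap`` (cm^-1)
    are merged; regions are returned ascending as (lo, hi) wavenumbers.  An
    all-zero spectrum yields an empty list.
    """
    if not 0.0 < rel_threshold < 1.0:
        raise ValueError("rel_threshold must be in (0, 1)")
    peak = float(spec.intensity.max(initial=0.0))
    if peak <= 0.0:
        return []
    above = spec.intensity >= rel_threshold * peak
    idx = np.flatnonzero(above)
    if len(idx) == 0:
        return []
    # split into contiguous runs of bins
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    regions = [(float(spec.wavenumber[s]), float(spec.wavenumber[e]))
               for s, e in zip(starts, ends)]
    merged = [regions[0]]
    for lo, hi in regions[1:]:
        if lo - merged[-1][1] <= merge_gap:
            merged[-1] = (merged[-1][0], hi)
        else:
            merged.append((lo, hi))
    return merged
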