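"""Spectral and envelope observables, applied identically to simulated and
empirical signals.

Band-limited filtering uses zero-phase (forward-backward) 3rd-order Bessel
band-pass filters; envelopes are Hilbert magnitudes high-pass filtered at
0.5 Hz with a zero-phase 3rd-order Butterworth; spectra use Welch's method
with 2 s Hann windows and 50% overlap (0.5 Hz resolution); relative band
power normalizes by the total power between 0.5 and 30 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import signal as sps

__all__ = [
    "BandDefinition",
    "CANONICAL_BANDS",
    "bandpass",
    "envelope",
    "welch_psd",
    "normalized_psd",
    "relative_band_power",
    "peak_frequency",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [lo, hi) in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError("band edges must satisfy 0 < lo < hi")


CANONICAL_BANDS: Tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 40.0),
)


def _as_2d(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return x[None, :], True
    if x.ndim == 2:
        return x, False
    raise ValueError("signal must be 1-D or 2-D (channels x time)")


def bandpass(signal: np.ndarray, fs: float, band: BandDefinition) -> np.ndarray:
    """Zero-phase 3rd-order Bessel band-pass along the last axis."""
    if band.hi >= fs / 2:
        raise ValueError(f"band {band.name} upper edge {band.hi} Hz at/above Nyquist")
    sos = sps.bessel(3, [band.lo, band.hi], btype="bandpass", fs=fs, output="sos")
    x, squeeze = _as_2d(signal)
    out = sps.sosfiltfilt(sos, x, axis=-1)
    return out[0] if squeeze else out


def envelope(signal: np.ndarray, fs: float) -> np.ndarray:
    """Hilbert amplitude envelope, high-passed at 0.5 Hz (zero-phase
    3rd-order Butterworth) to keep only envelope fluctuations."""
    x, squeeze = _as_2d(signal)
    if x.shape[-1] / fs < 10.0:
        warnings.warn("signal shorter than 10 s: envelope estimate is unreliable")
    env = np.abs(sps.hilbert(x, axis=-1))
    sos = sps.butter(3, 0.5, btype="highpass", fs=fs, output="sos")
    out = sps.sosfiltfilt(sos, env, axis=-1)
    return out[0] if squeeze else out


def welch_psd(
    signal: np.ndarray, fs: float, window_sec: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density with ``window_sec`` Hann windows and 50%
    overlap; returns (frequencies, density) with density along the last axis."""
    x, squeeze = _as_2d(signal)
    nperseg = int(round(window_sec * fs))
    if x.shape[-1] < nperseg:
        raise ValueError("signal shorter than one Welch window")
    freqs, psd = sps.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2,
        detrend="constant", axis=-1,
    )
    return freqs, (psd[0] if squeeze else psd)


def normalized_psd(psd: np.ndarray) -> np.ndarray:
    """PSD divided by its maximum (scale-invariant spectral shape)."""
    psd = np.asarray(psd, dtype=float)
    top = psd.max(axis=-1, keepdims=True)
    if np.any(top <= 0):
        raise ValueError("cannot normalize an all-zero spectrum")
    return psd / top


def relative_band_power(
    freqs: np.ndarray,
    psd: np.ndarray,
    bands: Sequence[BandDefinition],
    total_lo: float = 0.5,
    total_hi: float = 30.0,
) -> np.ndarray:
    """Per-band integrated power divided by total power in [total_lo, total_hi].

    Integration is trapezoidal on the PSD grid; for 2-D input the band axis
    is prepended (bands x channels).
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    sel = (freqs >= total_lo) & (freqs <= total_hi)
    total = np.trapezoid(psd[..., sel], freqs[sel], axis=-1)
    if np.any(total <= 0):
        raise ValueError("zero total power in the normalization range")
    out = []
    for band in bands:
        bsel = (freqs >= band.lo) & (freqs <= band.hi)
        out.append(np.trapezoid(psd[..., bsel], freqs[bsel], axis=-1) / total)
    return np.stack(out, axis=0) if psd.ndim > 1 else np.array(out)


def peak_frequency(
    freqs: np.ndarray,
    psd: np.ndarray,
    search_range: tuple[float, float] = (0.5, 60.0),
) -> float:
    """Frequency of maximal density within ``search_range``; ties (within
    floating tolerance) break toward the lower frequency."""
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    if psd.ndim != 1:
        raise ValueError("peak_frequency expects a single spectrum")
    lo, hi = search_range
    sel = (freqs >= lo) & (freqs <= hi)
    if not np.any(sel):
        raise ValueError("empty search range for this PSD grid")
    f, d = freqs[sel], psd[sel]
    # np.argmax already returns the first (lowest-frequency) maximum
    return float(f[int(np.argmax(d))])
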