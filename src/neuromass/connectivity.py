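"""Functional-connectivity matrices.

EEG FC is the amplitude-envelope correlation: band-pass the signals,
take Hilbert envelopes (high-passed at 0.5 Hz), and correlate all region
pairs.  BOLD FC band-passes the signals at 0.01-0.08 Hz (3rd-order Bessel)
before the pairwise Pearson correlation.  Diagonals are zeroed by
convention so matrix comparisons are not inflated by the trivial self-
correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .signals import BandDefinition, bandpass, envelope

__all__ = ["FCMatrix", "pearson_fc", "eeg_band_fc", "bold_fc", "load_fc", "save_fc"]


@dataclass
class FCMatrix:
    """Symmetric correlation matrix with zero diagonal; band records the
    originating frequency band name (or "bold")."""

    values: np.ndarray
    band: str
    n_samples: int

    def mean_offdiagonal(self) -> float:
        n = self.values.shape[0]
        mask = ~np.eye(n, dtype=bool)
        return float(self.values[mask].mean())


def pearson_fc(series: np.ndarray, band: str = "raw") -> FCMatrix:
    """Pairwise Pearson correlation of rows; constant rows give zero
    correlations (with a warning) rather than NaN."""
    x = np.atleast_2d(np.asarray(series, dtype=float))
    sd = x.std(axis=1)
    flat = sd == 0
    if np.any(flat):
        warnings.warn(f"{int(flat.sum())} constant series: their FC rows set to 0")
        x = x.copy()
        x[flat] += np.random.default_rng(0).normal(size=(int(flat.sum()), x.shape[1]))
    fc = np.corrcoef(x)
    fc[flat, :] = 0.0
    fc[:, flat] = 0.0
    np.fill_diagonal(fc, 0.0)
    return FCMatrix(values=fc, band=band, n_samples=x.shape[1])


def eeg_band_fc(signals: np.ndarray, band: BandDefinition, fs: float) -> FCMatrix:
    """Amplitude-envelope correlation FC for one EEG band."""
    x = np.atleast_2d(np.asarray(signals, dtype=float))
    if x.shape[1] / fs < 10.0:
        raise ValueError("need at least 10 s of signal for envelope FC")
    env = envelope(bandpass(x, fs, band), fs)
    return pearson_fc(env, band=band.name)


def bold_fc(
    bold: np.ndarray, fs: float, lo: float = 0.01, hi: float = 0.08
) -> FCMatrix:
    """Pearson FC of band-passed (0.01-0.08 Hz, 3rd-order Bessel) BOLD."""
    x = np.atleast_2d(np.asarray(bold, dtype=float))
    duration = x.shape[1] / fs
    if duration < 200.0:
        raise ValueError("need at least 200 s of BOLD for 0.01 Hz filtering")
    sos = sps.bessel(3, [lo, hi], btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, x, axis=-1)
    return pearson_fc(filt, band="bold")


def save_fc(fc: FCMatrix, path: str | Path, labels: list[str] | None = None) -> None:
    cols = labels if labels else [str(i) for i in range(fc.values.shape[0])]
    pd.DataFrame(fc.values, columns=cols).to_csv(path, index=False)


def load_fc(path: str | Path, band: str = "loaded") -> FCMatrix:
    """Read a delimited-text FC matrix; the zero-diagonal convention is
    enforced on load."""
    df = pd.read_csv(path)
    vals = df.to_numpy(dtype=float)
    if vals.shape[0] != vals.shape[1]:
        raise ValueError("FC matrix must be square")
    np.fill_diagonal(vals, 0.0)
    return FCMatrix(values=vals, band=band, n_samples=0)
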