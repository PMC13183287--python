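"""Deterministic synthetic test-signal generators.

These stand in for recorded EEG/fMRI data in the test suite: multivariate
Gaussian series with a prescribed correlation structure, and pairs of
amplitude-modulated carriers with a controllable shared-envelope fraction
(exercising the envelope-correlation pipeline end to end).  Connectome
fixtures are generated by :func:`neuromass.network.synthetic_connectome`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["make_gaussian_fc_series", "make_am_pair"]


def make_gaussian_fc_series(
    target_fc: np.ndarray, n_samples: int, seed: int
) -> np.ndarray:
    """Gaussian N x T series whose sample correlation converges to
    ``target_fc`` (unit diagonal assumed) as T grows.

    Built by a Cholesky (or eigen, for semidefinite targets) factor applied
    to i.i.d. standard normals; the target must be positive semidefinite.
    """
    target = np.asarray(target_fc, dtype=float)
    if target.ndim != 2 or target.shape[0] != target.shape[1]:
        raise ValueError("target correlation matrix must be square")
    target = 0.5 * (target + target.T)
    eigval, eigvec = np.linalg.eigh(target)
    if eigval.min() < -1e-10:
        raise ValueError("target correlation matrix is not positive semidefinite")
    factor = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0.0, None)))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((target.shape[0], int(n_samples)))
    return factor @ z


def make_am_pair(
    carrier_hz: float,
    env_hz: float,
    shared_fraction: float,
    fs: float,
    n_samples: int,
    seed: int,
) -> np.ndarray:
    """Two sinusoidal carriers with partially shared slow amplitude
    modulation; the expected envelope correlation grows with
    ``shared_fraction`` in [0, 1].

    The two envelopes mix one shared sinusoidal component with a private
    component whose frequency is randomly detuned (so private envelopes
    decorrelate over the record instead of correlating as cos of a phase
    offset); carriers get independent random phases.  Requires
    env_hz < carrier_hz / 4 and carrier below Nyquist.
    """
    if not (0.0 <= shared_fraction <= 1.0):
        raise ValueError("shared_fraction must lie in [0, 1]")
    if env_hz >= carrier_hz / 4.0:
        raise ValueError("envelope must be much slower than the carrier")
    if carrier_hz >= fs / 2.0:
        raise ValueError("carrier at/above Nyquist")
    rng = np.random.default_rng(seed)
    t = np.arange(int(n_samples)) / fs
    shared = np.sin(2 * np.pi * env_hz * t + rng.uniform(0, 2 * np.pi))
    out = np.empty((2, t.size))
    w = np.sqrt(shared_fraction)
    wp = np.sqrt(1.0 - shared_fraction)
    for k in range(2):
        f_priv = env_hz * rng.uniform(0.6, 1.4)
        private = np.sin(2 * np.pi * f_priv * t + rng.uniform(0, 2 * np.pi))
        env = 1.0 + 0.5 * (w * shared + wp * private)
        out[k] = env * np.sin(2 * np.pi * carrier_hz * t + rng.uniform(0, 2 * np.pi))
    return out
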