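"""Balloon-Windkessel hemodynamic forward model.

Pyramidal firing rates drive, per region, a vasodilatory signal s, blood
inflow f, venous volume v and deoxyhemoglobin content q:

    ds/dt = z(t) - s/tau_s - (f - 1)/tau_f
    df/dt = s
    dv/dt = (f - v^(1/kappa)) / tau_v
    dq/dt = ( f (1 - (1-E0)^(1/f)) / E0 - q v^(1/kappa - 1) ) / tau_q

and the BOLD observable is

    B = V0 [ k1 (1 - q) + k2 (1 - q/v) + k3 (1 - v) ].

The venous outflow term in dq/dt uses the standard Balloon form
q * v^(1/kappa) / v, following the generalized hemodynamic formulation the
constants are taken from.  Integration is explicit Euler at 10 ms, then the
BOLD series is anti-alias filtered and resampled to the repetition time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import downsample

__all__ = ["HemodynamicParams", "HemoState", "balloon_derivatives", "simulate_bold"]


@dataclass(frozen=True)
class HemodynamicParams:
    tau_s: float = 0.65  # signal decay, s
    tau_f: float = 0.41  # blood inflow, s
    tau_v: float = 0.98  # blood volume, s
    tau_q: float = 0.98  # deoxyhemoglobin, s
    kappa: float = 0.32  # vessel stiffness exponent
    E0: float = 0.4  # resting oxygen extraction fraction
    V0: float = 0.04  # resting venous blood volume fraction
    k1: float = 2.77
    k2: float = 0.2
    k3: float = 0.5
    dt_h: float = 0.01  # integration step, s
    TR: float = 2.08  # output repetition time, s

    def __post_init__(self) -> None:
        if min(self.tau_s, self.tau_f, self.tau_v, self.tau_q, self.dt_h, self.TR) <= 0:
            raise ValueError("time constants must be strictly positive")
        if not (0 < self.E0 < 1):
            raise ValueError("E0 must lie in (0, 1)")
        if not (0 < self.kappa <= 1):
            raise ValueError("kappa must lie in (0, 1]")


@dataclass
class HemoState:
    """Per-region hemodynamic state; resting point is (s, f, v, q) = (0, 1, 1, 1)."""

    s: np.ndarray
    f: np.ndarray
    v: np.ndarray
    q: np.ndarray

    @classmethod
    def resting(cls, n_nodes: int) -> "HemoState":
        return cls(
            s=np.zeros(n_nodes),
            f=np.ones(n_nodes),
            v=np.ones(n_nodes),
            q=np.ones(n_nodes),
        )


def balloon_derivatives(
    h: HemoState, drive: np.ndarray, hp: HemodynamicParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Time derivatives (ds, df, dv, dq) for the given neural drive (1/s)."""
    if np.any(h.f <= 0) or np.any(h.v <= 0):
        raise ValueError("inflow f and volume v must stay positive")
    drive = np.asarray(drive, dtype=float)
    ds = drive - h.s / hp.tau_s - (h.f - 1.0) / hp.tau_f
    df = h.s.copy()
    v_out = h.v ** (1.0 / hp.kappa)
    dv = (h.f - v_out) / hp.tau_v
    extraction = (1.0 - (1.0 - hp.E0) ** (1.0 / h.f)) / hp.E0
    dq = (h.f * extraction - h.q * v_out / h.v) / hp.tau_q
    return ds, df, dv, dq


def bold_signal(h: HemoState, hp: HemodynamicParams) -> np.ndarray:
    """Instantaneous BOLD observable from (q, v)."""
    return hp.V0 * (
        hp.k1 * (1.0 - h.q) + hp.k2 * (1.0 - h.q / h.v) + hp.k3 * (1.0 - h.v)
    )


def simulate_bold(
    zeta_pyr: np.ndarray, fs_in: float, hp: HemodynamicParams = HemodynamicParams()
) -> tuple[np.ndarray, float]:
    """Transform pyramidal-rate traces (n_nodes x T at ``fs_in``) into BOLD.

    The drive is consumed on the hemodynamic time grid dt_h by zero-order
    hold (fs_in and 1/dt_h must be integer multiples of one another); Euler
    integration starts from the resting state, and the output is resampled
    to 1/TR Hz.  Returns (bold, fs_out).
    """
    z = np.atleast_2d(np.asarray(zeta_pyr, dtype=float))
    if fs_in * hp.dt_h < 1.0 - 1e-9 and not np.isclose(
        round(1.0 / (fs_in * hp.dt_h)), 1.0 / (fs_in * hp.dt_h)
    ):
        raise ValueError("1/dt_h must be an integer multiple of fs_in")
    if fs_in * hp.dt_h >= 1.0 and abs(
        fs_in * hp.dt_h - round(fs_in * hp.dt_h)
    ) > 1e-9:
        raise ValueError("fs_in must be an integer multiple of 1/dt_h")
    n = z.shape[0]
    t = int(round(z.shape[1] / (fs_in * hp.dt_h)))
    h = HemoState.resting(n)
    out = np.empty((n, t))
    for k in range(t):
        out[:, k] = bold_signal(h, hp)
        # zero-order hold of the drive on the hemodynamic time grid
        idx = min(int(k * hp.dt_h * fs_in), z.shape[1] - 1)
        ds, df, dv, dq = balloon_derivatives(h, z[:, idx], hp)
        h.s += hp.dt_h * ds
        h.f += hp.dt_h * df
        h.v += hp.dt_h * dv
        h.q += hp.dt_h * dq
        if not (np.all(np.isfinite(h.v)) and np.all(h.v > 0) and np.all(h.f > 0)):
            bad = int(np.argmax(~(np.isfinite(h.v) & (h.v > 0) & (h.f > 0))))
            raise FloatingPointError(f"hemodynamic divergence at node {bad}")
    fs_h = 1.0 / hp.dt_h
    factor = int(round(fs_h * hp.TR))
    if abs(fs_h * hp.TR - factor) > 1e-6:
        raise ValueError("TR must be an integer multiple of dt_h")
    bold = downsample(out, fs_h, fs_h / factor)
    return bold, fs_h / factor
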