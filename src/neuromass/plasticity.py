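"""Homeostatic inhibitory synaptic plasticity (ISP) on the feedback inhibition C4.

The inhibitory-to-pyramidal gain c4 of each region evolves so that the
time-averaged pyramidal firing rate is clamped to a target rho:

    tau * dc4/dt = zeta_inh * (zeta_pyr - rho) * ((c4 - c4_min)/C)^beta

With beta = 1 this is a soft lower bound at c4_min: the multiplicative
factor vanishes as c4 approaches c4_min, and the derivative vanishes at the
homeostatic fixed point zeta_pyr = rho.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import NodeParams

__all__ = ["PlasticityParams", "isp_derivative", "convergence_time"]


@dataclass(frozen=True)
class PlasticityParams:
    """ISP constants: target rate rho (1/s), inverse learning rate tau (s),
    bounding exponent beta, and lower bound c4_min."""

    rho: float = 2.5
    tau: float = 2.0
    beta_exp: float = 1.0
    c4_min: float = 0.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be strictly positive")
        if self.rho < 0 or self.c4_min < 0:
            raise ValueError("rho and c4_min must be nonnegative")


def isp_derivative(
    c4: float,
    zeta_pyr: float,
    zeta_inh: float,
    node: NodeParams,
    pp: PlasticityParams,
) -> float:
    """dc4/dt of the plasticity rule; zero at zeta_pyr = rho or c4 = c4_min."""
    if c4 < pp.c4_min:
        raise ValueError(f"c4 = {c4} below the lower bound c4_min = {pp.c4_min}")
    bound = ((c4 - pp.c4_min) / node.C) ** pp.beta_exp
    return (1.0 / pp.tau) * zeta_inh * (zeta_pyr - pp.rho) * bound


def convergence_time(
    c4_trace: np.ndarray,
    dt: float,
    baseline_window: float = 2.0,
    steady_window: float = 10.0,
    tol: float = 1e-9,
) -> float:
    """First time the (ROI-averaged) c4 trace covers 63.2% of its total change.

    The initial level c4_0 is the mean over the first ``baseline_window``
    seconds and the steady level c4_inf the mean over the last
    ``steady_window`` seconds; the returned time is the first crossing of
    c4_0 + (1 - 1/e) * (c4_inf - c4_0).

    Raises ``ValueError`` for traces shorter than the two windows or with a
    total change below ``tol`` (degenerate flat trace).
    """
    trace = np.asarray(c4_trace, dtype=float)
    if trace.ndim != 1:
        raise ValueError("c4_trace must be one-dimensional (ROI-averaged)")
    n_base = int(round(baseline_window / dt))
    n_steady = int(round(steady_window / dt))
    if trace.size <= n_base + n_steady:
        raise ValueError("trace shorter than baseline_window + steady_window")
    c4_0 = trace[:n_base].mean()
    c4_inf = trace[-n_steady:].mean()
    change = c4_inf - c4_0
    if abs(change) < tol:
        raise ValueError("degenerate trace: total c4 change below tolerance")
    target = c4_0 + (1.0 - np.exp(-1.0)) * change
    crossed = trace >= target if change > 0 else trace <= target
    idx = np.flatnonzero(crossed)
    if idx.size == 0:
        raise ValueError("trace never crosses the 63.2% level")
    return float(idx[0] * dt)
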