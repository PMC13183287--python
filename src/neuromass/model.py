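"""Single-region Jansen-Rit dynamics with two rhythm-generating subpopulations.

Each brain region is modelled by two Jansen-Rit neural masses: an "alpha"
subpopulation tuned around 10 Hz and a "gamma" subpopulation whose synaptic
rate constants are 5.5 times faster.  Every mass consists of a pyramidal
population with excitatory and inhibitory interneuron feedback loops; the
second-order synaptic kernels turn firing rates into post-synaptic potentials
(PSPs), and a sigmoid turns membrane potentials back into firing rates.

The regional EEG-like observable is ``x1 - x2`` of the *combined* mixture
variables, where the mixture weight ``r_alpha`` sets the proportion of
alpha- versus gamma-tuned neurons:

    x_k = r_alpha * x_k_alpha - (1 - r_alpha) * x_k_gamma

Node-level firing rates (the EEG observable, the pyramidal output sent to
other regions, and the rates driving plasticity) are computed from these
combined variables.  Each mass's internal loops, by default, use its own
state variables inside the sigmoid, so the two masses are independent
oscillators mixed at the output; ``combined_sigmoid_args=True`` switches to
feeding the combined variables into every sigmoid instead (in that variant
the gain-matched masses mirror each other and their mixture largely
cancels, collapsing the EEG for intermediate ``r_alpha``).  Both
subpopulations share a single (possibly plastic) feedback-inhibition
constant ``c4``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

__all__ = [
    "SigmoidParams",
    "SubpopulationParams",
    "NodeParams",
    "NodeState",
    "sigmoid",
    "sigmoid_derivative",
    "combine_states",
    "firing_rates",
    "subpop_derivatives",
]


@dataclass(frozen=True)
class SigmoidParams:
    """Potential-to-rate sigmoid: S(v) = zeta_max / (1 + exp(-slope_r (v - v_th)))."""

    zeta_max: float = 5.0  # maximal firing rate, 1/s
    slope_r: float = 0.56  # slope, 1/mV
    v_th: float = 6.0  # threshold potential, mV

    def __post_init__(self) -> None:
        if not (self.zeta_max > 0 and self.slope_r > 0):
            raise ValueError("zeta_max and slope_r must be strictly positive")


@dataclass(frozen=True)
class SubpopulationParams:
    """Synaptic kernel constants of one Jansen-Rit mass.

    A, B are the maximal EPSP/IPSP amplitudes (mV); a, b the inverse
    characteristic time constants (1/s) of the excitatory and inhibitory
    kernels h(t) = A a t exp(-a t).
    """

    A: float
    B: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if min(self.A, self.B, self.a, self.b) <= 0:
            raise ValueError("all kernel constants must be strictly positive")

    @classmethod
    def alpha_preset(cls) -> "SubpopulationParams":
        """Slow subpopulation (~10 Hz limit cycle)."""
        return cls(A=3.9, B=26.4, a=120.0, b=60.0)

    @classmethod
    def gamma_preset(cls) -> "SubpopulationParams":
        """Fast subpopulation; amplitudes tied to the rate constants."""
        a, b = 660.0, 330.0
        return cls(A=32.5 * a / 1000.0, B=440.0 * b / 1000.0, a=a, b=b)


def _default_alpha() -> SubpopulationParams:
    return SubpopulationParams.alpha_preset()


def _default_gamma() -> SubpopulationParams:
    return SubpopulationParams.gamma_preset()


@dataclass(frozen=True)
class NodeParams:
    """All constants of one brain region.

    The local connectivity constants follow the classical Jansen-Rit ratios
    c1 = C, c2 = 0.8 C, c3 = 0.25 C, c4_init = 0.25 C; ``r_alpha`` is the
    proportion of alpha-tuned neurons in the mixture.
    """

    alpha: SubpopulationParams = field(default_factory=_default_alpha)
    gamma: SubpopulationParams = field(default_factory=_default_gamma)
    sigmoid: SigmoidParams = field(default_factory=SigmoidParams)
    C: float = 135.0
    c1: float | None = None
    c2: float | None = None
    c3: float | None = None
    c4_init: float | None = None
    r_alpha: float = 0.5
    combined_sigmoid_args: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "c1", self.C if self.c1 is None else self.c1)
        object.__setattr__(self, "c2", 0.8 * self.C if self.c2 is None else self.c2)
        object.__setattr__(self, "c3", 0.25 * self.C if self.c3 is None else self.c3)
        object.__setattr__(
            self, "c4_init", 0.25 * self.C if self.c4_init is None else self.c4_init
        )
        if not (0.0 <= self.r_alpha <= 1.0):
            raise ValueError("r_alpha must lie in [0, 1]")
        if min(self.c1, self.c2, self.c3, self.c4_init) < 0:
            raise ValueError("connectivity constants must be nonnegative")

    def with_r_alpha(self, r_alpha: float) -> "NodeParams":
        return replace(self, r_alpha=r_alpha)


@dataclass
class NodeState:
    """State of one region: six PSP variables per subpopulation plus c4.

    ``x`` holds PSP outputs (mV) and ``y`` their rates of change (mV/s);
    index order is (x0, x1, x2) for each of the alpha and gamma masses.
    """

    x_alpha: np.ndarray
    y_alpha: np.ndarray
    x_gamma: np.ndarray
    y_gamma: np.ndarray
    c4: float

    @classmethod
    def zeros(cls, node: NodeParams) -> "NodeState":
        return cls(
            x_alpha=np.zeros(3),
            y_alpha=np.zeros(3),
            x_gamma=np.zeros(3),
            y_gamma=np.zeros(3),
            c4=float(node.c4_init),
        )


def sigmoid(v, sp: SigmoidParams = SigmoidParams()):
    """Firing rate S(v) in 1/s for membrane potential v in mV."""
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("sigmoid input must be finite")
    out = sp.zeta_max / (1.0 + np.exp(-sp.slope_r * (v - sp.v_th)))
    return float(out) if out.ndim == 0 else out


def sigmoid_derivative(v, sp: SigmoidParams = SigmoidParams()):
    """dS/dv = slope_r * S * (1 - S/zeta_max)."""
    s = sigmoid(v, sp)
    return sp.slope_r * s * (1.0 - s / sp.zeta_max)


def combine_states(
    alpha_triplet: Tuple[float, float, float],
    gamma_triplet: Tuple[float, float, float],
    r_alpha: float,
) -> np.ndarray:
    """Mixture variables x_k = r_alpha x_k^alpha - (1 - r_alpha) x_k^gamma."""
    if not (0.0 <= r_alpha <= 1.0):
        raise ValueError("r_alpha must lie in [0, 1]")
    a = np.asarray(alpha_triplet, dtype=float)
    g = np.asarray(gamma_triplet, dtype=float)
    return r_alpha * a - (1.0 - r_alpha) * g


def firing_rates(
    combined: Tuple[float, float, float], node: NodeParams
) -> Tuple[float, float, float]:
    """Node-level firing rates (zeta_pyr, zeta_exc, zeta_inh) from combined PSPs.

    zeta_pyr = S(x1 - x2), zeta_exc = S(c1 x0), zeta_inh = S(c3 x0).
    """
    x0, x1, x2 = (float(c) for c in combined)
    sp = node.sigmoid
    return (
        sigmoid(x1 - x2, sp),
        sigmoid(node.c1 * x0, sp),
        sigmoid(node.c3 * x0, sp),
    )


def subpop_derivatives(
    state: NodeState,
    subpop: str,
    combined: Tuple[float, float, float],
    p_input: float,
    coupling: float,
    node: NodeParams,
) -> np.ndarray:
    """Time derivatives (dx0, dy0, dx1, dy1, dx2, dy2) of one subpopulation.

    By default each mass's sigmoids see its own state variables; with
    ``node.combined_sigmoid_args`` they see the node-level combined mixture
    instead.  The external drive ``p_input`` (1/s) enters the
    pyramidal-output loop scaled by A*a, while the network ``coupling``
    (1/s) is added unscaled, matching the placement of the long-range term
    outside the parenthesis.  The node's current c4 multiplies the
    inhibitory loop of both masses.
    """
    if subpop == "alpha":
        sp, x, y = node.alpha, state.x_alpha, state.y_alpha
    elif subpop == "gamma":
        sp, x, y = node.gamma, state.x_gamma, state.y_gamma
    else:
        raise ValueError(f"unknown subpopulation {subpop!r}")
    if coupling < 0:
        raise ValueError("coupling must be nonnegative")
    args = combined if node.combined_sigmoid_args else (x[0], x[1], x[2])
    zeta_pyr, zeta_exc, zeta_inh = firing_rates(args, node)
    A, B, a, b = sp.A, sp.B, sp.a, sp.b
    dy0 = A * a * zeta_pyr - 2.0 * a * y[0] - a * a * x[0]
    dy1 = (
        A * a * (p_input + node.c2 * zeta_exc)
        + coupling
        - 2.0 * a * y[1]
        - a * a * x[1]
    )
    dy2 = B * b * state.c4 * zeta_inh - 2.0 * b * y[2] - b * b * x[2]
    return np.array([y[0], dy0, y[1], dy1, y[2], dy2])
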