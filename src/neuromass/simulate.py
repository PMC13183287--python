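"""Stochastic network integration (Euler-Maruyama, 1 ms step).

Every region carries 12 Jansen-Rit states (6 per subpopulation) plus one
plastic c4.  The external drive p_i(t) is redrawn independently per region
and per step from Normal(p_mean, p_sd) and held constant over the step
(input-noise convention, no sqrt(dt) scaling; an ``sde_scaling`` flag
switches to the Wiener-increment convention).  Long-range coupling
K*C*sum_j M_ij*zeta_pyr_j enters the pyramidal-output loop of both
subpopulations like the external input, i.e. scaled by each mass's A*a
(``coupling_scaled_by_aa=False`` switches to adding it unscaled, in which
case it is a sub-percent perturbation of the drive).

Traces are stored only after anti-alias filtering and decimation to
``output_fs`` (200 Hz default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from numba import njit
from scipy import signal as sps

from .model import NodeParams
from .network import Connectome
from .plasticity import PlasticityParams

__all__ = [
    "SimulationProtocol",
    "SimulationResult",
    "draw_input",
    "simulate",
    "downsample",
]


@dataclass(frozen=True)
class SimulationProtocol:
    """Integration and input settings for one run."""

    t_total: float = 180.0  # total simulated time, s
    t_discard: float = 60.0  # discarded transient, s
    dt: float = 1e-3  # integration step, s
    p_mean: float = 220.0  # external input mean, 1/s
    p_sd: float = 31.0  # external input SD, 1/s
    K: float = 0.0  # global coupling
    seed: int = 0
    noise_enabled: bool = True
    output_fs: float = 200.0  # stored sampling rate, Hz
    sde_scaling: bool = False  # scale noise by 1/sqrt(dt) (Wiener convention)
    coupling_scaled_by_aa: bool = True  # coupling enters like p, scaled by A*a

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (0 <= self.t_discard < self.t_total):
            raise ValueError("need 0 <= t_discard < t_total")
        if self.p_sd < 0:
            raise ValueError("p_sd must be nonnegative")
        factor = 1.0 / (self.dt * self.output_fs)
        if abs(factor - round(factor)) > 1e-9:
            raise ValueError("output_fs must divide the integration rate 1/dt")


@dataclass
class SimulationResult:
    """Downsampled traces shaped (n_nodes, n_samples): the EEG-like
    observable x1-x2 of the combined mixture variables (mV), the node
    pyramidal rate r_alpha*S(v_alpha) + (1-r_alpha)*S(v_gamma) (1/s, the
    quantity ISP clamps and the hemodynamic drive), and the plastic c4."""

    eeg: np.ndarray
    zeta_pyr: np.ndarray
    c4_trace: np.ndarray
    fs: float
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.eeg.shape[1]) / self.fs


def draw_input(
    n_nodes: int, proto: SimulationProtocol, rng: np.random.Generator
) -> np.ndarray:
    """One step's external drive: i.i.d. Normal(p_mean, p_sd) per region
    (constant p_mean when noise is disabled)."""
    if not proto.noise_enabled or proto.p_sd == 0:
        return np.full(n_nodes, proto.p_mean)
    return rng.normal(proto.p_mean, proto.p_sd, size=n_nodes)


@njit(cache=True)
def _euler_kernel(
    xa, ya, xg, yg, c4,  # states, modified in place
    p_chunk,  # (steps, N) external drive
    M, KC,  # connectome weights, K*C
    Aa, Ba, aa, ba, Ag, Bg, ag, bg,  # subpopulation constants
    zmax, slope, vth, c1, c2, c3,  # sigmoid + local connectivity
    r_alpha, dt,
    isp_on, inv_tau, rho, beta, c4_min, Cloc,
    scale_coup_aa, combined_args,
    eeg_out, zpyr_out, c4_out,  # (steps, N) outputs
):
    n_steps = p_chunk.shape[0]
    n = xa.shape[0]
    ra, rg = r_alpha, 1.0 - r_alpha
    for t in range(n_steps):
        # per-mass rates, node-level rate mixtures, EEG observable
        zpyr = np.empty(n)
        zinh = np.empty(n)
        zpa = np.empty(n)
        zea = np.empty(n)
        zia = np.empty(n)
        zpg = np.empty(n)
        zeg = np.empty(n)
        zig = np.empty(n)
        for i in range(n):
            x0 = ra * xa[i, 0] - rg * xg[i, 0]
            x1 = ra * xa[i, 1] - rg * xg[i, 1]
            x2 = ra * xa[i, 2] - rg * xg[i, 2]
            v = x1 - x2
            if combined_args:
                zpa[i] = zpg[i] = zmax / (1.0 + np.exp(-slope * (v - vth)))
                zea[i] = zeg[i] = zmax / (1.0 + np.exp(-slope * (c1 * x0 - vth)))
                zia[i] = zig[i] = zmax / (1.0 + np.exp(-slope * (c3 * x0 - vth)))
                zpyr[i] = zpa[i]
                zinh[i] = zia[i]
            else:
                va = xa[i, 1] - xa[i, 2]
                zpa[i] = zmax / (1.0 + np.exp(-slope * (va - vth)))
                zea[i] = zmax / (1.0 + np.exp(-slope * (c1 * xa[i, 0] - vth)))
                zia[i] = zmax / (1.0 + np.exp(-slope * (c3 * xa[i, 0] - vth)))
                vg = xg[i, 1] - xg[i, 2]
                zpg[i] = zmax / (1.0 + np.exp(-slope * (vg - vth)))
                zeg[i] = zmax / (1.0 + np.exp(-slope * (c1 * xg[i, 0] - vth)))
                zig[i] = zmax / (1.0 + np.exp(-slope * (c3 * xg[i, 0] - vth)))
                zpyr[i] = ra * zpa[i] + rg * zpg[i]
                # inhibitory rate as printed: S of the combined x0 mixture
                zinh[i] = zmax / (1.0 + np.exp(-slope * (c3 * x0 - vth)))
            eeg_out[t, i] = v
            zpyr_out[t, i] = zpyr[i]
            c4_out[t, i] = c4[i]
        coup = KC * (M @ zpyr)
        for i in range(n):
            p = p_chunk[t, i]
            ca = coup[i]
            cg = coup[i]
            if scale_coup_aa:
                ca = Aa * aa * ca
                cg = Ag * ag * cg
            zp_a, ze_a, zi_a = zpa[i], zea[i], zia[i]
            zp_g, ze_g, zi_g = zpg[i], zeg[i], zig[i]
            dy0 = Aa * aa * zp_a - 2.0 * aa * ya[i, 0] - aa * aa * xa[i, 0]
            dy1 = (
                Aa * aa * (p + c2 * ze_a) + ca
                - 2.0 * aa * ya[i, 1] - aa * aa * xa[i, 1]
            )
            dy2 = (
                Ba * ba * c4[i] * zi_a
                - 2.0 * ba * ya[i, 2] - ba * ba * xa[i, 2]
            )
            for k in range(3):
                xa[i, k] += dt * ya[i, k]
            ya[i, 0] += dt * dy0
            ya[i, 1] += dt * dy1
            ya[i, 2] += dt * dy2
            # gamma subpopulation
            dy0 = Ag * ag * zp_g - 2.0 * ag * yg[i, 0] - ag * ag * xg[i, 0]
            dy1 = (
                Ag * ag * (p + c2 * ze_g) + cg
                - 2.0 * ag * yg[i, 1] - ag * ag * xg[i, 1]
            )
            dy2 = (
                Bg * bg * c4[i] * zi_g
                - 2.0 * bg * yg[i, 2] - bg * bg * xg[i, 2]
            )
            for k in range(3):
                xg[i, k] += dt * yg[i, k]
            yg[i, 0] += dt * dy0
            yg[i, 1] += dt * dy1
            yg[i, 2] += dt * dy2
            if isp_on:
                dc4 = (
                    inv_tau * zinh[i] * (zpyr[i] - rho)
                    * ((c4[i] - c4_min) / Cloc) ** beta
                )
                c4[i] += dt * dc4
                if c4[i] < c4_min:  # hard clip guards finite-dt overshoot
                    c4[i] = c4_min
        if not np.isfinite(xa).all() or not np.isfinite(xg).all():
            return t
    return -1


def simulate(
    connectome: Connectome | None,
    node: NodeParams,
    plasticity: PlasticityParams | None = None,
    proto: SimulationProtocol = SimulationProtocol(),
) -> SimulationResult:
    """Integrate the whole-brain (or single-node) system and return
    downsampled EEG-like, pyramidal-rate, and c4 traces.

    ``connectome=None`` runs one isolated region.  Initial conditions are
    all-zero states with c4(0) = c4_init.  Deterministic given
    (seed, protocol).
    """
    pp = plasticity if plasticity is not None else PlasticityParams(enabled=False)
    if connectome is None:
        M = np.zeros((1, 1))
        n = 1
    else:
        M = connectome.weights
        n = connectome.n_nodes
    dt = proto.dt
    n_steps = int(round(proto.t_total / dt))
    rng = np.random.default_rng(proto.seed)

    xa = np.zeros((n, 3))
    ya = np.zeros((n, 3))
    xg = np.zeros((n, 3))
    yg = np.zeros((n, 3))
    c4 = np.full(n, float(node.c4_init))

    eeg = np.empty((n_steps, n))
    zpyr = np.empty((n_steps, n))
    c4_tr = np.empty((n_steps, n))

    sd = proto.p_sd if proto.noise_enabled else 0.0
    if proto.sde_scaling and sd > 0:
        sd = sd / np.sqrt(dt)

    chunk = 20000
    start = 0
    while start < n_steps:
        stop = min(start + chunk, n_steps)
        if sd > 0:
            p_chunk = rng.normal(proto.p_mean, sd, size=(stop - start, n))
        else:
            p_chunk = np.full((stop - start, n), proto.p_mean)
        bad = _euler_kernel(
            xa, ya, xg, yg, c4, p_chunk, M, proto.K * node.C,
            node.alpha.A, node.alpha.B, node.alpha.a, node.alpha.b,
            node.gamma.A, node.gamma.B, node.gamma.a, node.gamma.b,
            node.sigmoid.zeta_max, node.sigmoid.slope_r, node.sigmoid.v_th,
            node.c1, node.c2, node.c3,
            node.r_alpha, dt,
            pp.enabled, 1.0 / pp.tau, pp.rho, pp.beta_exp, pp.c4_min, node.C,
            proto.coupling_scaled_by_aa, node.combined_sigmoid_args,
            eeg[start:stop], zpyr[start:stop], c4_tr[start:stop],
        )
        if bad >= 0:
            step = start + bad
            node_idx = int(np.argmax(~np.isfinite(np.concatenate([xa, xg], 1)).all(1)))
            raise FloatingPointError(
                f"divergence at step {step} (t = {step * dt:.3f} s), node {node_idx}"
            )
        start = stop

    n_drop = int(round(proto.t_discard / dt))
    fs_in = 1.0 / dt
    factor = int(round(fs_in / proto.output_fs))
    out = []
    for tr in (eeg, zpyr, c4_tr):
        kept = tr[n_drop:].T  # (n, samples) at full rate
        out.append(downsample(kept, fs_in, proto.output_fs) if factor > 1 else kept)
    meta = {
        "protocol": proto,
        "node": node,
        "plasticity": pp,
        "n_nodes": n,
    }
    return SimulationResult(
        eeg=out[0], zeta_pyr=out[1], c4_trace=out[2], fs=proto.output_fs, meta=meta
    )


def downsample(signal: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Anti-alias low-pass then keep every (fs_in/fs_out)-th sample.

    The factor must be an integer; the anti-alias filter is a zero-phase
    8th-order Butterworth at 0.8 of the output Nyquist (maximally flat, so
    DC and in-band amplitudes are preserved), applied in stages of at most
    13 for large factors.
    """
    factor = fs_in / fs_out
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(f"fs_in/fs_out = {factor} is not an integer")
    q = int(round(factor))
    x = np.asarray(signal, dtype=float)
    while q > 1:
        step = q if q <= 13 else min(8, q)
        while q % step:
            step -= 1
        sos = sps.butter(8, 0.8 / step, btype="lowpass", output="sos")
        x = sps.sosfiltfilt(sos, x, axis=-1)[..., ::step]
        q //= step
    return x
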