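"""Numerical bifurcation toolkit for the deterministic single-node model.

Replaces interactive continuation software with an in-repo implementation:

* analytic vector field and Jacobian of one region (pure-subpopulation
  reduced 6/7-state form, or the full 12/13-state mixture),
* Newton location of equilibria and pseudo-arclength continuation over the
  external input p with stability labels,
* codim-1 event classification (saddle-node at folds via a zero real
  eigenvalue, Hopf via a complex pair crossing the imaginary axis),
* periodic orbits by single shooting with monodromy matrices from the
  variational equations, Floquet multipliers, and pseudo-arclength cycle
  continuation detecting folds of cycles (a real multiplier through +1)
  and torus/Neimark-Sacker points (a complex pair through the unit circle).

With plasticity enabled, c4 is carried as an extra state of the extended
system, so equilibria satisfy either zeta_pyr = rho or c4 = c4_min.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model import NodeParams
from .plasticity import PlasticityParams

__all__ = [
    "SingleNodeField",
    "Branch",
    "BifurcationEvent",
    "CycleBranch",
    "equilibria",
    "jacobian_eigenvalues",
    "continue_branch",
    "classify_events",
    "limit_cycle_floquet",
    "continue_cycle",
    "find_periodic_orbit",
]


# --------------------------------------------------------------------------
# vector field
# --------------------------------------------------------------------------


class SingleNodeField:
    """Deterministic field f(x, p) and Jacobian of one isolated region.

    For r_alpha exactly 1 (or 0) only the alpha (gamma) subpopulation is
    carried, with the mixture sign folded into a weight of +1 (-1) for the
    node-level combined variables; for intermediate r_alpha both 6-state
    blocks are kept.  Each mass's internal sigmoids see its own states
    unless ``node.combined_sigmoid_args`` is set.  With ``isp`` the plastic
    c4 is appended as the last state (its rate driven by the combined
    node-level firing rates); otherwise c4 is frozen at ``node.c4_init``.
    """

    def __init__(
        self,
        node: NodeParams,
        isp: bool = False,
        plasticity: PlasticityParams | None = None,
    ):
        self.node = node
        self.isp = isp
        self.pp = plasticity if plasticity is not None else PlasticityParams()
        ra = node.r_alpha
        if ra == 1.0:
            self.subpops = [node.alpha]
            self.weights = [1.0]
        elif ra == 0.0:
            self.subpops = [node.gamma]
            self.weights = [-1.0]
        else:
            self.subpops = [node.alpha, node.gamma]
            self.weights = [ra, -(1.0 - ra)]
        self.n_sub = len(self.subpops)
        # positive mixture weights for node-level firing rates
        self.rate_weights = [abs(w) for w in self.weights]
        self.dim = 6 * self.n_sub + (1 if isp else 0)

    # sigmoid helpers
    def _S(self, v):
        sp = self.node.sigmoid
        return sp.zeta_max / (1.0 + np.exp(-sp.slope_r * (v - sp.v_th)))

    def _Sd(self, v):
        sp = self.node.sigmoid
        s = self._S(v)
        return sp.slope_r * s * (1.0 - s / sp.zeta_max)

    def _combined(self, x: np.ndarray):
        c0 = sum(w * x[6 * s + 0] for s, w in enumerate(self.weights))
        c1 = sum(w * x[6 * s + 2] for s, w in enumerate(self.weights))
        c2 = sum(w * x[6 * s + 4] for s, w in enumerate(self.weights))
        return c0, c1, c2

    def _c4(self, x: np.ndarray) -> float:
        return x[-1] if self.isp else float(self.node.c4_init)

    def _node_rates(self, x: np.ndarray) -> tuple[float, float]:
        """Node pyramidal and inhibitory firing rates.

        The pyramidal rate is the subpopulation rate mixture
        sum_s |w_s| S(x1_s - x2_s); the inhibitory rate is S(C3 x0) of the
        combined mixture variable, as printed.  In the literal-equation
        variant both come from the combined potentials."""
        nd = self.node
        c0, c1, c2 = self._combined(x)
        if nd.combined_sigmoid_args:
            return self._S(c1 - c2), self._S(nd.c3 * c0)
        zp = 0.0
        for s, w in enumerate(self.rate_weights):
            o = 6 * s
            zp += w * self._S(x[o + 2] - x[o + 4])
        return zp, self._S(nd.c3 * c0)

    def _local_args(self, x: np.ndarray, s: int):
        """Sigmoid arguments of subpopulation s's internal loops."""
        if self.node.combined_sigmoid_args:
            c0, c1, c2 = self._combined(x)
            return c1 - c2, self.node.c1 * c0, self.node.c3 * c0
        o = 6 * s
        return (
            x[o + 2] - x[o + 4],
            self.node.c1 * x[o + 0],
            self.node.c3 * x[o + 0],
        )

    def f(self, x: np.ndarray, p: float) -> np.ndarray:
        nd = self.node
        out = np.empty(self.dim)
        c4 = self._c4(x)
        for s, sp in enumerate(self.subpops):
            o = 6 * s
            A, B, a, b = sp.A, sp.B, sp.a, sp.b
            vp, ve, vi = self._local_args(x, s)
            out[o + 0] = x[o + 1]
            out[o + 1] = A * a * self._S(vp) - 2 * a * x[o + 1] - a * a * x[o + 0]
            out[o + 2] = x[o + 3]
            out[o + 3] = (
                A * a * (p + nd.c2 * self._S(ve))
                - 2 * a * x[o + 3] - a * a * x[o + 2]
            )
            out[o + 4] = x[o + 5]
            out[o + 5] = (
                B * b * c4 * self._S(vi) - 2 * b * x[o + 5] - b * b * x[o + 4]
            )
        if self.isp:
            pp = self.pp
            zp, zi = self._node_rates(x)
            bound = ((c4 - pp.c4_min) / nd.C) ** pp.beta_exp
            out[-1] = (1.0 / pp.tau) * zi * (zp - pp.rho) * bound
        return out

    def jac(self, x: np.ndarray, p: float) -> np.ndarray:
        nd = self.node
        J = np.zeros((self.dim, self.dim))
        c4 = self._c4(x)
        combined = nd.combined_sigmoid_args
        for s, sp in enumerate(self.subpops):
            o = 6 * s
            A, B, a, b = sp.A, sp.B, sp.a, sp.b
            vp, ve, vi = self._local_args(x, s)
            dzp, dze, dzi = self._Sd(vp), self._Sd(ve), self._Sd(vi)
            zi = self._S(vi)
            J[o + 0, o + 1] = 1.0
            J[o + 1, o + 1] = -2 * a
            J[o + 1, o + 0] = -a * a
            J[o + 2, o + 3] = 1.0
            J[o + 3, o + 3] = -2 * a
            J[o + 3, o + 2] += -a * a
            J[o + 4, o + 5] = 1.0
            J[o + 5, o + 5] = -2 * b
            J[o + 5, o + 4] += -b * b
            if combined:
                for t, w in enumerate(self.weights):
                    ot = 6 * t
                    J[o + 1, ot + 2] += A * a * dzp * w
                    J[o + 1, ot + 4] += -A * a * dzp * w
                    J[o + 3, ot + 0] += A * a * nd.c2 * dze * nd.c1 * w
                    J[o + 5, ot + 0] += B * b * c4 * dzi * nd.c3 * w
            else:
                J[o + 1, o + 2] += A * a * dzp
                J[o + 1, o + 4] += -A * a * dzp
                J[o + 3, o + 0] += A * a * nd.c2 * dze * nd.c1
                J[o + 5, o + 0] += B * b * c4 * dzi * nd.c3
            if self.isp:
                J[o + 5, self.dim - 1] = B * b * zi
        if self.isp:
            pp = self.pp
            zp, zi = self._node_rates(x)
            bound = ((c4 - pp.c4_min) / nd.C) ** pp.beta_exp
            if pp.beta_exp == 1.0:
                dbound = 1.0 / nd.C
            else:
                base = max(c4 - pp.c4_min, 1e-300) / nd.C
                dbound = pp.beta_exp * base ** (pp.beta_exp - 1.0) / nd.C
            i4 = self.dim - 1
            if combined:
                c0, c1, c2 = self._combined(x)
                dzp = self._Sd(c1 - c2)
                dzi = self._Sd(nd.c3 * c0)
                for t, w in enumerate(self.weights):
                    ot = 6 * t
                    J[i4, ot + 0] += (
                        (1.0 / pp.tau) * (zp - pp.rho) * bound * dzi * nd.c3 * w
                    )
                    J[i4, ot + 2] += (1.0 / pp.tau) * zi * bound * dzp * w
                    J[i4, ot + 4] += -(1.0 / pp.tau) * zi * bound * dzp * w
            else:
                c0, _, _ = self._combined(x)
                dzi_c = self._Sd(nd.c3 * c0)
                for t, w in enumerate(self.weights):
                    ot = 6 * t
                    J[i4, ot + 0] += (
                        (1.0 / pp.tau) * (zp - pp.rho) * bound * dzi_c * nd.c3 * w
                    )
                for t, w in enumerate(self.rate_weights):
                    ot = 6 * t
                    dzp_t = self._Sd(x[ot + 2] - x[ot + 4])
                    J[i4, ot + 2] += (1.0 / pp.tau) * zi * bound * w * dzp_t
                    J[i4, ot + 4] += -(1.0 / pp.tau) * zi * bound * w * dzp_t
            J[i4, i4] = (1.0 / pp.tau) * zi * (zp - pp.rho) * dbound
        return J

    def df_dp(self, x: np.ndarray) -> np.ndarray:
        out = np.zeros(self.dim)
        for s, sp in enumerate(self.subpops):
            out[6 * s + 3] = sp.A * sp.a
        return out


# --------------------------------------------------------------------------
# equilibria and equilibrium continuation
# --------------------------------------------------------------------------


@dataclass
class Branch:
    """Continuation output: states, parameter values, eigenvalues, stability,
    and the tangent p-component per accepted point."""

    states: list[np.ndarray] = dc_field(default_factory=list)
    params: list[float] = dc_field(default_factory=list)
    eigvals: list[np.ndarray] = dc_field(default_factory=list)
    stable: list[bool] = dc_field(default_factory=list)
    tangent_p: list[float] = dc_field(default_factory=list)
    truncated: bool = False


@dataclass
class BifurcationEvent:
    kind: str  # saddle-node | hopf | fold-of-cycles | torus
    param: float
    state: np.ndarray
    diagnostic: complex


def equilibria(
    field: SingleNodeField,
    p: float,
    guesses: Sequence[np.ndarray] | None = None,
    residual_tol: float = 1e-10,
) -> list[np.ndarray]:
    """Roots of f(., p) from the given initial guesses, duplicates merged."""
    if guesses is None:
        guesses = [np.zeros(field.dim)]
    found: list[np.ndarray] = []
    for g in guesses:
        sol = root(lambda x: field.f(x, p), g, jac=lambda x: field.jac(x, p),
                   method="hybr", tol=1e-13)
        if not sol.success:
            continue
        x = sol.x
        if np.linalg.norm(field.f(x, p)) > residual_tol:
            continue
        if field.isp and x[-1] < field.pp.c4_min - 1e-9:
            continue
        if not any(np.linalg.norm(x - h) < 1e-6 * (1 + np.linalg.norm(h)) for h in found):
            found.append(x)
    return found


def jacobian_eigenvalues(
    field: SingleNodeField, x: np.ndarray, p: float
) -> np.ndarray:
    """Eigenvalues of the analytic Jacobian, sorted by descending real part."""
    ev = np.linalg.eigvals(field.jac(x, p))
    return ev[np.argsort(-ev.real)]


def _tangent(field, x, p, prev=None):
    """Unit tangent of the equilibrium curve in (x, p) space."""
    J = field.jac(x, p)
    fp = field.df_dp(x)
    n = field.dim
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = J
    A[:n, n] = fp
    if prev is None:
        A[n, n] = 1.0
    else:
        A[n, :] = prev
    rhs = np.zeros(n + 1)
    rhs[n] = 1.0
    t, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    t /= np.linalg.norm(t)
    if prev is not None and np.dot(t, prev) < 0:
        t = -t
    return t


def continue_branch(
    field: SingleNodeField,
    x0: np.ndarray,
    p0: float,
    p_range: tuple[float, float],
    direction: float = 1.0,
    ds: float = 0.5,
    ds_min: float = 1e-6,
    ds_max: float = 2.0,
    max_points: int = 2000,
    newton_tol: float = 1e-10,
) -> Branch:
    """Pseudo-arclength continuation of an equilibrium branch over p.

    Follows the curve through folds; stability is recomputed at every
    accepted point.  Stops when p leaves ``p_range``, the point budget is
    exhausted, or the step collapses below ``ds_min`` (branch flagged
    truncated).
    """
    n = field.dim
    branch = Branch()
    x, p = np.array(x0, dtype=float), float(p0)
    t = _tangent(field, x, p)
    if t[n] * direction < 0:
        t = -t

    def accept(x, p, t):
        ev = jacobian_eigenvalues(field, x, p)
        branch.states.append(x.copy())
        branch.params.append(float(p))
        branch.eigvals.append(ev)
        branch.stable.append(bool(np.all(ev.real < 0)))
        branch.tangent_p.append(float(t[n]))

    accept(x, p, t)
    step = ds
    while len(branch.params) < max_points:
        pred = np.concatenate([x, [p]]) + step * t
        xi, pi = pred[:n].copy(), float(pred[n])
        ok = False
        for _ in range(8):
            F = np.concatenate([
                field.f(xi, pi),
                [np.dot(t, np.concatenate([xi, [pi]]) - pred)],
            ])
            if np.linalg.norm(F) < newton_tol:
                ok = True
                break
            A = np.zeros((n + 1, n + 1))
            A[:n, :n] = field.jac(xi, pi)
            A[:n, n] = field.df_dp(xi)
            A[n, :] = t
            delta = np.linalg.solve(A, -F)
            xi += delta[:n]
            pi += delta[n]
        if not ok:
            step *= 0.5
            if step < ds_min:
                branch.truncated = True
                break
            continue
        x, p = xi, pi
        t = _tangent(field, x, p, prev=t)
        accept(x, p, t)
        step = min(step * 1.3, ds_max)
        if not (p_range[0] <= p <= p_range[1]):
            break
    return branch


def _refine_fold(field: SingleNodeField, x: np.ndarray, p: float) -> tuple[np.ndarray, float]:
    """Solve the fold (saddle-node) extended system f=0, J v=0, ||v||=1."""
    n = field.dim
    ev, vec = np.linalg.eig(field.jac(x, p))
    v0 = np.real(vec[:, np.argmin(np.abs(ev))])
    v0 /= np.linalg.norm(v0)

    def G(u):
        xx, vv, pp = u[:n], u[n:2 * n], u[2 * n]
        return np.concatenate([
            field.f(xx, pp),
            field.jac(xx, pp) @ vv,
            [vv @ vv - 1.0],
        ])

    sol = root(G, np.concatenate([x, v0, [p]]), method="hybr", tol=1e-12)
    if not sol.success:
        raise RuntimeError("fold refinement did not converge")
    return sol.x[:n], float(sol.x[2 * n])


def _refine_hopf(field, branch: Branch, i: int, tol: float = 1e-3):
    """Bisect the Re-crossing of a complex eigenvalue pair between points
    i and i+1 of the branch (no fold in between)."""

    def mu(p, x_guess):
        sol = root(lambda x: field.f(x, p), x_guess,
                   jac=lambda x: field.jac(x, p), method="hybr", tol=1e-13)
        ev = jacobian_eigenvalues(field, sol.x, p)
        cplx = ev[np.abs(ev.imag) > 1e-8]
        return (cplx.real.max() if cplx.size else -np.inf), sol.x, ev

    p_lo, p_hi = branch.params[i], branch.params[i + 1]
    x_lo = branch.states[i].copy()
    m_lo, x_lo, _ = mu(p_lo, x_lo)
    while abs(p_hi - p_lo) > tol:
        p_mid = 0.5 * (p_lo + p_hi)
        m_mid, x_mid, ev_mid = mu(p_mid, x_lo)
        if np.sign(m_mid) == np.sign(m_lo):
            p_lo, x_lo, m_lo = p_mid, x_mid, m_mid
        else:
            p_hi = p_mid
    _, x_fin, ev_fin = mu(0.5 * (p_lo + p_hi), x_lo)
    cplx = ev_fin[np.abs(ev_fin.imag) > 1e-8]
    pair = cplx[np.argmax(cplx.real)]
    return 0.5 * (p_lo + p_hi), x_fin, pair


def classify_events(
    field: SingleNodeField, branch: Branch, p_tol: float = 1e-3
) -> list[BifurcationEvent]:
    """Detect and refine codim-1 events along an equilibrium branch.

    Saddle-nodes are folds (sign change of dp/ds) refined with the extended
    fold system; Hopf points are real-part zero crossings of a complex pair
    refined by bisection to ``p_tol``.
    """
    events: list[BifurcationEvent] = []
    for i in range(len(branch.params) - 1):
        tp0, tp1 = branch.tangent_p[i], branch.tangent_p[i + 1]
        if tp0 * tp1 < 0:  # fold
            x_f, p_f = _refine_fold(field, branch.states[i], branch.params[i])
            ev = jacobian_eigenvalues(field, x_f, p_f)
            diag = ev[np.argmin(np.abs(ev))]
            events.append(BifurcationEvent("saddle-node", p_f, x_f, diag))
            continue
        ev0, ev1 = branch.eigvals[i], branch.eigvals[i + 1]
        c0 = ev0[np.abs(ev0.imag) > 1e-8]
        c1 = ev1[np.abs(ev1.imag) > 1e-8]
        if c0.size and c1.size and c0.real.max() * c1.real.max() < 0:
            p_h, x_h, pair = _refine_hopf(field, branch, i, tol=p_tol)
            events.append(BifurcationEvent("hopf", p_h, x_h, pair))
    return events


# --------------------------------------------------------------------------
# periodic orbits: shooting, Floquet, cycle continuation
# --------------------------------------------------------------------------


def _flow(field, x0, T, p, rtol=1e-10, atol=1e-12, sens_p=False):
    """Integrate state + variational matrix (+ optional dphi/dp) over [0, T].

    Returns (x(T), monodromy, dx(T)/dp or None).
    """
    n = field.dim

    def rhs(_, z):
        x = z[:n]
        J = field.jac(x, p)
        phi = z[n:n + n * n].reshape(n, n)
        out = [field.f(x, p), (J @ phi).ravel()]
        if sens_p:
            psi = z[n + n * n:]
            out.append(J @ psi + field.df_dp(x))
        return np.concatenate(out)

    z0 = [x0, np.eye(n).ravel()]
    if sens_p:
        z0.append(np.zeros(n))
    sol = solve_ivp(rhs, (0.0, T), np.concatenate(z0), method="DOP853",
                    rtol=rtol, atol=atol, dense_output=False)
    if not sol.success:
        raise RuntimeError(f"orbit integration failed: {sol.message}")
    zT = sol.y[:, -1]
    M = zT[n:n + n * n].reshape(n, n)
    psi = zT[n + n * n:] if sens_p else None
    return zT[:n], M, psi


def limit_cycle_floquet(
    field: SingleNodeField,
    p: float,
    x_guess: np.ndarray,
    T_guess: float,
    newton_tol: float = 1e-9,
    max_iter: int = 15,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Refine a periodic orbit by single shooting and return
    (period, orbit point, Floquet multipliers).

    The phase condition anchors the orbit on the hyperplane through the
    initial guess orthogonal to the flow; the multipliers are the
    eigenvalues of the monodromy matrix (the trivial one is ~1).
    """
    n = field.dim
    x = np.array(x_guess, dtype=float)
    T = float(T_guess)
    anchor = x.copy()
    f_anchor = field.f(anchor, p)
    scale = max(1.0, np.linalg.norm(x))
    for _ in range(max_iter):
        xT, M, _ = _flow(field, x, T, p)
        R = np.concatenate([xT - x, [f_anchor @ (x - anchor)]])
        if np.linalg.norm(R) < newton_tol * scale:
            mult = np.linalg.eigvals(M)
            return T, x, mult[np.argsort(-np.abs(mult))]
        A = np.zeros((n + 1, n + 1))
        A[:n, :n] = M - np.eye(n)
        A[:n, n] = field.f(xT, p)
        A[n, :n] = f_anchor
        delta, *_ = np.linalg.lstsq(A, -R, rcond=None)
        x = x + delta[:n]
        T = T + delta[n]
        if T <= 0:
            raise RuntimeError("shooting produced a nonpositive period")
    raise RuntimeError(f"shooting Newton failed; last residual {np.linalg.norm(R):.2e}")


def find_periodic_orbit(
    field: SingleNodeField,
    p: float,
    x_init: np.ndarray | None = None,
    t_transient: float = 60.0,
    t_probe: float = 2.0,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Locate an attracting cycle by forward integration, then refine it.

    Integrates past the transient, estimates the period from mean-crossings
    of the first state variable over ``t_probe``, and polishes with
    shooting.  Returns (period, orbit point, multipliers).
    """
    n = field.dim
    if x_init is None:
        x_init = np.zeros(n)
        if field.isp:
            x_init[-1] = field.node.c4_init
    sol = solve_ivp(lambda _, x: field.f(x, p), (0.0, t_transient), x_init,
                    method="LSODA", jac=lambda _, x: field.jac(x, p),
                    rtol=1e-9, atol=1e-11)
    x_end = sol.y[:, -1]
    probe = solve_ivp(lambda _, x: field.f(x, p), (0.0, t_probe), x_end,
                      method="DOP853", rtol=1e-10, atol=1e-12,
                      dense_output=True, max_step=1e-3)
    tt = np.linspace(0.0, t_probe, int(t_probe * 20000))
    xx = probe.sol(tt)[0]
    mid = 0.5 * (xx.max() + xx.min())
    if xx.max() - xx.min() < 1e-8:
        raise RuntimeError(f"no oscillation detected at p = {p}")
    up = np.flatnonzero((xx[:-1] < mid) & (xx[1:] >= mid))
    if up.size < 3:
        raise RuntimeError("too few oscillation cycles in the probe window")
    T0 = float(np.mean(np.diff(tt[up])))
    x0 = probe.sol(tt[up[1]])
    return limit_cycle_floquet(field, p, x0, T0)


@dataclass
class CycleBranch:
    """Cycle continuation output: orbit anchor points, periods, parameter
    values, Floquet multipliers, and tangent p-components."""

    states: list[np.ndarray] = dc_field(default_factory=list)
    periods: list[float] = dc_field(default_factory=list)
    params: list[float] = dc_field(default_factory=list)
    multipliers: list[np.ndarray] = dc_field(default_factory=list)
    tangent_p: list[float] = dc_field(default_factory=list)
    truncated: bool = False


def _nontrivial(mult: np.ndarray) -> np.ndarray:
    """Drop the trivial multiplier (the one closest to +1)."""
    i = int(np.argmin(np.abs(mult - 1.0)))
    return np.delete(mult, i)


def continue_cycle(
    field: SingleNodeField,
    p0: float,
    x0: np.ndarray,
    T0: float,
    p_range: tuple[float, float],
    direction: float = -1.0,
    ds: float = 0.5,
    ds_min: float = 1e-4,
    ds_max: float = 1.5,
    max_points: int = 400,
    newton_tol: float = 1e-8,
    p_scale: float = 5.0,
) -> CycleBranch:
    """Pseudo-arclength continuation of a periodic orbit over p.

    Unknowns are (orbit point, period, p); the shooting residual, a phase
    hyperplane through the previous orbit point, and the arclength
    condition close the system.  Arclength is measured in scaled
    coordinates (state components by the orbit amplitude, period by T0,
    p by ``p_scale``) so a unit step makes comparable progress in every
    direction.  Follows the branch through folds of cycles; Floquet
    multipliers are recorded at every accepted point.
    """
    n = field.dim
    branch = CycleBranch()
    T, x, mult = limit_cycle_floquet(field, p0, x0, T0)
    p = float(p0)
    # scaled coordinates: v = u / scale
    scale = np.concatenate([np.maximum(np.abs(x), 1.0), [T, p_scale]])

    def bordered(x, T, p, anchor_f, last_row, M, fT, psi):
        """Bordered Jacobian in scaled coordinates (columns times scale)."""
        A = np.zeros((n + 2, n + 2))
        A[:n, :n] = M - np.eye(n)
        A[:n, n] = fT
        A[:n, n + 1] = psi
        A[n, :n] = anchor_f
        A[:n + 1, :] *= scale[None, :]
        A[n + 1, :] = last_row
        return A

    anchor = x.copy()
    anchor_f = field.f(anchor, p)
    xT0, M0, psi0 = _flow(field, x, T, p, sens_p=True)
    e = np.zeros(n + 2)
    e[n + 1] = 1.0
    A = bordered(x, T, p, anchor_f, e, M0, field.f(xT0, p), psi0)
    t_vec, *_ = np.linalg.lstsq(A, e, rcond=None)  # tangent in v-space
    t_vec /= np.linalg.norm(t_vec)
    if t_vec[n + 1] * direction < 0:
        t_vec = -t_vec

    def accept(x, T, p, mult, t_vec):
        branch.states.append(x.copy())
        branch.periods.append(float(T))
        branch.params.append(float(p))
        branch.multipliers.append(mult)
        branch.tangent_p.append(float(t_vec[n + 1]))

    accept(x, T, p, mult, t_vec)
    step = ds
    while len(branch.params) < max_points:
        v_pred = np.concatenate([x, [T, p]]) / scale + step * t_vec
        u = v_pred * scale
        xi, Ti, pi = u[:n].copy(), float(u[n]), float(u[n + 1])
        anchor = x.copy()
        anchor_f = field.f(anchor, p)
        ok = False
        M_last = fT_last = psi_last = None
        for _ in range(10):
            xT, M_last, psi_last = _flow(field, xi, Ti, pi, sens_p=True)
            fT_last = field.f(xT, pi)
            v = np.concatenate([xi, [Ti, pi]]) / scale
            R = np.concatenate([
                xT - xi,
                [anchor_f @ (xi - anchor)],
                [t_vec @ (v - v_pred)],
            ])
            if np.linalg.norm(R) < newton_tol * max(1.0, np.linalg.norm(xi)):
                ok = True
                break
            A = bordered(xi, Ti, pi, anchor_f, t_vec, M_last, fT_last, psi_last)
            dv, *_ = np.linalg.lstsq(A, -R, rcond=None)
            du = dv * scale
            xi += du[:n]
            Ti += du[n]
            pi += du[n + 1]
            if Ti <= 0:
                break
        if not ok:
            step *= 0.4
            if step < ds_min:
                branch.truncated = True
                break
            continue
        x, T, p = xi, Ti, pi
        mult = np.linalg.eigvals(M_last)
        mult = mult[np.argsort(-np.abs(mult))]
        # new tangent reuses the converged flow quantities
        A = bordered(x, T, p, anchor_f, t_vec, M_last, fT_last, psi_last)
        rhs = np.zeros(n + 2)
        rhs[n + 1] = 1.0
        t_new, *_ = np.linalg.lstsq(A, rhs, rcond=None)
        t_new /= np.linalg.norm(t_new)
        if np.dot(t_new, t_vec) < 0:
            t_new = -t_new
        t_vec = t_new
        accept(x, T, p, mult, t_vec)
        step = min(step * 1.25, ds_max)
        if not (p_range[0] <= p <= p_range[1]):
            break
    return branch


def detect_cycle_fold(branch: CycleBranch) -> BifurcationEvent | None:
    """Fold of cycles: sign change of dp/ds along the cycle branch; the
    fold parameter is interpolated at the tangent zero-crossing."""
    for i in range(len(branch.params) - 1):
        tp0, tp1 = branch.tangent_p[i], branch.tangent_p[i + 1]
        if tp0 * tp1 < 0:
            w = abs(tp0) / (abs(tp0) + abs(tp1))
            p_f = (1 - w) * branch.params[i] + w * branch.params[i + 1]
            mult = branch.multipliers[i]
            nt = _nontrivial(mult)
            diag = nt[np.argmin(np.abs(nt - 1.0))] if nt.size else 1.0
            return BifurcationEvent("fold-of-cycles", p_f, branch.states[i], diag)
    return None


def _cycle_at(field, p_target, x, T, p_from, max_halvings=8):
    """Walk a converged cycle from p_from to p_target with step halving on
    shooting failures; returns (T, x, multipliers) at p_target."""
    p_cur, x_cur, T_cur = p_from, np.array(x, dtype=float), float(T)
    step = p_target - p_cur
    halvings = 0
    mult = None
    while abs(p_target - p_cur) > 1e-12:
        step = np.sign(p_target - p_cur) * min(abs(step), abs(p_target - p_cur))
        try:
            T_new, x_new, mult = limit_cycle_floquet(
                field, p_cur + step, x_cur, T_cur
            )
        except RuntimeError:
            step *= 0.5
            halvings += 1
            if halvings > max_halvings:
                raise
            continue
        p_cur += step
        x_cur, T_cur = x_new, T_new
    if mult is None:
        T_cur, x_cur, mult = limit_cycle_floquet(field, p_cur, x_cur, T_cur)
    return T_cur, x_cur, mult


def detect_torus(
    field: SingleNodeField, branch: CycleBranch, p_tol: float = 1e-2
) -> BifurcationEvent | None:
    """Torus (Neimark-Sacker) point: a complex Floquet pair crossing the
    unit circle, bisected in p between bracketing branch points."""

    def gap(mult):
        cplx = _nontrivial(mult)
        cplx = cplx[np.abs(cplx.imag) > 1e-6]
        return np.abs(cplx).max() - 1.0 if cplx.size else -np.inf

    for i in range(len(branch.params) - 1):
        g0, g1 = gap(branch.multipliers[i]), gap(branch.multipliers[i + 1])
        if not (np.isfinite(g0) and np.isfinite(g1)) or g0 * g1 >= 0:
            continue
        p_lo, p_hi = branch.params[i], branch.params[i + 1]
        x_lo, T_lo = branch.states[i].copy(), branch.periods[i]
        g_lo = g0
        best = (branch.params[i], branch.states[i], branch.multipliers[i])
        while abs(p_hi - p_lo) > p_tol:
            p_mid = 0.5 * (p_lo + p_hi)
            T_mid, x_mid, mult = _cycle_at(field, p_mid, x_lo, T_lo, p_lo)
            g_mid = gap(mult)
            if np.isfinite(g_mid):
                best = (p_mid, x_mid, mult)
            if np.sign(g_mid) == np.sign(g_lo):
                p_lo, x_lo, T_lo, g_lo = p_mid, x_mid, T_mid, g_mid
            else:
                p_hi = p_mid
        p_t = 0.5 * (p_lo + p_hi)
        cplx = _nontrivial(best[2])
        cplx = cplx[np.abs(cplx.imag) > 1e-6]
        diag = cplx[np.argmax(np.abs(cplx))]
        return BifurcationEvent("torus", p_t, best[1], diag)
    return None
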