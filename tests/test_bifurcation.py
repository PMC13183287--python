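"""Continuation and Floquet machinery: analytic oracles, residual
invariants, and classical Jansen-Rit structure."""

import numpy as np
import pytest

from neuromass import (
    NodeParams,
    PlasticityParams,
    SigmoidParams,
    SingleNodeField,
    classify_events,
    continue_branch,
    equilibria,
    find_periodic_orbit,
    jacobian_eigenvalues,
    limit_cycle_floquet,
)
from neuromass.bifurcation import _flow


@pytest.fixture(scope="module")
def alpha_field():
    return SingleNodeField(NodeParams(r_alpha=1.0), isp=False)


@pytest.fixture(scope="module")
def isp_field():
    return SingleNodeField(
        NodeParams(r_alpha=1.0), isp=True, plasticity=PlasticityParams(rho=2.5)
    )


class HopfNormalForm:
    """dx = mu x - w y - x r^2 ; dy = w x + mu y - y r^2 (analytic oracle):
    limit cycle of radius sqrt(mu), period 2 pi / w, nontrivial Floquet
    multiplier exp(-2 mu T)."""

    dim = 2

    def __init__(self, mu=0.5, w=3.0):
        self.mu, self.w = mu, w

    def f(self, x, p):
        r2 = x[0] ** 2 + x[1] ** 2
        return np.array([
            self.mu * x[0] - self.w * x[1] - x[0] * r2,
            self.w * x[0] + self.mu * x[1] - x[1] * r2,
        ])

    def jac(self, x, p):
        r2 = x[0] ** 2 + x[1] ** 2
        return np.array([
            [self.mu - r2 - 2 * x[0] ** 2, -self.w - 2 * x[0] * x[1]],
            [self.w - 2 * x[0] * x[1], self.mu - r2 - 2 * x[1] ** 2],
        ])

    def df_dp(self, x):
        return np.zeros(2)


class TestField:
    @pytest.mark.parametrize("r_alpha", [1.0, 0.0, 0.4])
    @pytest.mark.parametrize("isp", [False, True])
    def test_jacobian_matches_finite_differences(self, r_alpha, isp):
        fld = SingleNodeField(
            NodeParams(r_alpha=r_alpha), isp=isp,
            plasticity=PlasticityParams(rho=2.5),
        )
        rng = np.random.default_rng(5)
        x = rng.normal(2, 3, fld.dim)
        if isp:
            x[-1] = 30.0
        J = fld.jac(x, 150.0)
        eps = 1e-6
        Jn = np.column_stack([
            (fld.f(x + eps * e, 150.0) - fld.f(x - eps * e, 150.0)) / (2 * eps)
            for e in np.eye(fld.dim)
        ])
        assert np.abs(J - Jn).max() < 1e-5 * max(1.0, np.abs(Jn).max())

    def test_silenced_sigmoid_gives_damped_blocks(self):
        """With zeta_max ~ 0 the Jacobian is block-diagonal with the damped
        oscillator eigenvalues -a (double) and -b (double)."""
        node = NodeParams(
            sigmoid=SigmoidParams(zeta_max=1e-300), r_alpha=1.0
        )
        fld = SingleNodeField(node, isp=False)
        ev = np.sort(jacobian_eigenvalues(fld, np.zeros(6), 0.0).real)
        a, b = node.alpha.a, node.alpha.b
        assert np.allclose(ev, sorted([-a, -a, -a, -a, -b, -b]), rtol=1e-6)


class TestEquilibria:
    def test_residual_invariant(self, alpha_field):
        eqs = equilibria(alpha_field, 50.0)
        assert eqs
        for e in eqs:
            assert np.linalg.norm(alpha_field.f(e, 50.0)) < 1e-10

    def test_low_input_equilibrium_matches_forward_integration(self, alpha_field):
        """At small p the stable node equals the long-time limit of the
        damped deterministic flow (independent oracle)."""
        from scipy.integrate import solve_ivp

        sol = solve_ivp(
            lambda t, x: alpha_field.f(x, 3.0), (0, 30.0), np.zeros(6),
            method="LSODA", rtol=1e-12, atol=1e-12,
        )
        eqs = equilibria(alpha_field, 3.0, [sol.y[:, -1]])
        assert np.allclose(eqs[0], sol.y[:, -1], atol=1e-5)
        ev = jacobian_eigenvalues(alpha_field, eqs[0], 3.0)
        assert ev.real.max() < 0

    def test_isp_interior_equilibrium_clamps_rate(self):
        """On the interior branch the extended system's root forces the
        node pyramidal rate exactly to rho."""
        node = NodeParams(r_alpha=1.0)
        pp = PlasticityParams(rho=2.5)
        fld = SingleNodeField(node, isp=True, plasticity=pp)
        # analytic construction: zeta_pyr = rho  =>  x1 - x2 = v_th
        A_over_a = node.alpha.A / node.alpha.a
        x0 = A_over_a * pp.rho
        p = 100.0
        from neuromass import sigmoid

        x1 = A_over_a * (p + node.c2 * sigmoid(node.c1 * x0))
        x2 = x1 - node.sigmoid.v_th
        c4 = (
            x2 * node.alpha.b
            / (node.alpha.B * sigmoid(node.c3 * x0))
        )
        guess = np.array([x0, 0, x1, 0, x2, 0, c4])
        eqs = equilibria(fld, p, [guess])
        assert eqs
        zp, _ = fld._node_rates(eqs[0])
        assert zp == pytest.approx(2.5, abs=1e-9)


class TestContinuation:
    def test_branch_residuals_and_fold(self, isp_field):
        eqs = equilibria(isp_field, 0.0)
        branch = continue_branch(isp_field, eqs[0], 0.0, (-5.0, 60.0), ds=0.3)
        for x, p in zip(branch.states, branch.params):
            assert np.linalg.norm(isp_field.f(x, p)) < 1e-9
        events = classify_events(isp_field, branch)
        folds = [e for e in events if e.kind == "saddle-node"]
        assert folds
        # defining condition: a near-zero real eigenvalue at the fold
        assert abs(folds[0].diagnostic) < 1e-6
        assert 5.0 < folds[0].param < 8.5

    def test_classical_lower_branch_folds(self, alpha_field):
        """The plasticity-free equilibrium curve is S-shaped: continuing
        the low-activity branch upward in p reaches a saddle-node."""
        eqs = equilibria(alpha_field, 0.0)
        branch = continue_branch(alpha_field, eqs[0], 0.0, (-40.0, 400.0), ds=1.0)
        events = classify_events(alpha_field, branch)
        folds = [e for e in events if e.kind == "saddle-node"]
        assert folds
        assert abs(folds[0].diagnostic) < 1e-6  # zero eigenvalue at the fold

    def test_classical_upper_branch_hopf(self, alpha_field):
        """The high-activity equilibrium restabilizes at large p through a
        Hopf bifurcation; continuation from p = 400 downward detects it."""
        from neuromass import sigmoid
        from scipy.optimize import brentq

        node = alpha_field.node
        A, a = node.alpha.A, node.alpha.a
        B, b = node.alpha.B, node.alpha.b
        c4 = node.c4_init

        def closure(u, p):  # scalar reduction of the equilibrium system
            x0 = (A / a) * sigmoid(u)
            x1 = (A / a) * (p + node.c2 * sigmoid(node.c1 * x0))
            x2 = (B / b) * c4 * sigmoid(node.c3 * x0)
            return x1 - x2 - u

        u = brentq(closure, -10.0, 40.0, args=(400.0,))
        x0 = (A / a) * sigmoid(u)
        x1 = (A / a) * (400.0 + node.c2 * sigmoid(node.c1 * x0))
        guess = np.array([x0, 0.0, x1, 0.0, x1 - u, 0.0])
        eqs = equilibria(alpha_field, 400.0, [guess])
        assert eqs
        branch = continue_branch(
            alpha_field, eqs[0], 400.0, (150.0, 410.0), direction=-1.0, ds=1.0
        )
        hopfs = [e for e in classify_events(alpha_field, branch)
                 if e.kind == "hopf"]
        assert hopfs
        # defining condition: imaginary pair, |Re| ~ 0, finite frequency
        assert abs(hopfs[0].diagnostic.real) < 1e-2
        assert abs(hopfs[0].diagnostic.imag) > 1.0


class TestCycles:
    def test_hopf_normal_form_shooting(self):
        nf = HopfNormalForm(mu=0.5, w=3.0)
        r = np.sqrt(nf.mu)
        T, x, mult = limit_cycle_floquet(
            nf, 0.0, np.array([r * 1.05, 0.0]), 2 * np.pi / nf.w * 1.02
        )
        assert T == pytest.approx(2 * np.pi / nf.w, rel=1e-8)
        assert np.linalg.norm(x) == pytest.approx(r, rel=1e-8)
        mult = sorted(np.abs(mult))
        assert mult[1] == pytest.approx(1.0, abs=1e-6)  # trivial
        assert mult[0] == pytest.approx(np.exp(-2 * nf.mu * T), rel=1e-5)

    def test_alpha_cycle_trivial_multiplier(self, alpha_field):
        T, x, mult = find_periodic_orbit(alpha_field, 220.0, t_transient=15.0)
        assert 10.0 < 1.0 / T < 15.0  # fast alpha-band limit cycle
        assert min(np.abs(mult - 1.0)) < 1e-4  # trivial multiplier at +1
        assert np.sort(np.abs(mult))[-2] < 1.0  # attracting cycle

    def test_multipliers_match_perturbation_decay(self, alpha_field):
        """The leading nontrivial multiplier equals the per-period decay of
        a perturbation along its Floquet direction, measured by integrating
        the full nonlinear flow (independent of the eigenvalue solve)."""
        T, x, mult_and = find_periodic_orbit(alpha_field, 220.0, t_transient=15.0)
        _, M, _ = _flow(alpha_field, x, T, 220.0)
        lam_all, vecs = np.linalg.eig(M)
        order = np.argsort(-np.abs(lam_all))
        # leading nontrivial multiplier (trivial one is closest to +1)
        idx = order[0] if abs(lam_all[order[0]] - 1) > 1e-3 else order[1]
        lam = lam_all[idx].real
        v = np.real(vecs[:, idx])
        v /= np.linalg.norm(v)
        eps = 1e-6 * np.linalg.norm(x)
        for k in (1, 3):
            xT, _, _ = _flow(alpha_field, x + eps * v, k * T, 220.0)
            decay = (np.linalg.norm(xT - x) / eps) ** (1.0 / k)
            assert decay == pytest.approx(abs(lam), rel=1e-3)
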