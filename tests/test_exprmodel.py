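"""Expression SDE: parameter sampling, stepping, steady states, stability."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.optimize import fsolve
from scipy.special import expit

from grnsim import (
    ExpressionParams,
    SimulationConfig,
    find_steady_state,
    generate_network,
    GeneratorParams,
    is_stable,
    jacobian,
    sample_expression_params,
    simulate_trajectory,
    step,
)


class TestSampleExpressionParams:
    def test_edge_weights_have_minimum_strength(self, small_grn, rng):
        params = sample_expression_params(small_grn, rng)
        assert np.all(np.abs(params.beta.data) >= 1.0)
        assert params.beta.nnz == small_grn.n_edges

    def test_activator_fraction(self, rng):
        """Each regulator's sign is shared by all its outgoing edges, ~80% positive."""
        grn = generate_network(GeneratorParams(n=400, p=0.2, seed=3))
        fracs = []
        for i in range(30):
            p = sample_expression_params(grn, np.random.default_rng(i))
            b = p.beta.tocoo()
            # one sign per regulator
            for j in np.unique(b.row):
                signs = np.sign(b.data[b.row == j])
                assert len(set(signs.tolist())) == 1
            regs = np.unique(b.row)
            sign_of = {int(j): np.sign(b.data[b.row == j][0]) for j in regs}
            fracs.append(np.mean([s > 0 for s in sign_of.values()]))
        assert np.mean(fracs) == pytest.approx(0.8, abs=0.03)

    def test_baseline_expression_distribution(self, rng):
        """sigma(alpha) ~ Beta(2, 8): mean 0.2 over many draws."""
        grn = generate_network(GeneratorParams(n=200, p=0.5, seed=4))
        draws = np.concatenate(
            [expit(sample_expression_params(grn, np.random.default_rng(i)).alpha)
             for i in range(50)]
        )
        assert draws.mean() == pytest.approx(2 / (2 + 8), abs=0.01)

    def test_decay_floor_bounds_isolated_steady_state(self, rng):
        """ell >= e^{-alpha} keeps isolated-gene steady states below one."""
        grn = generate_network(GeneratorParams(n=500, p=0.5, seed=5))
        p = sample_expression_params(grn, rng)
        assert np.all(p.ell >= np.exp(-p.alpha) - 1e-12)
        x_iso = expit(p.alpha) / p.ell
        # analytic bound: x* <= sigma(alpha) e^alpha = sigma^2/(1 - sigma)
        assert np.all(x_iso <= expit(p.alpha) * np.exp(p.alpha) + 1e-12)
        assert np.median(x_iso) < 0.2


class TestStep:
    def test_fixed_point_is_invariant(self, edgeless_params):
        """Without regulators and noise, x = sigma(alpha)/ell is unchanged."""
        x = expit(edgeless_params.alpha) / edgeless_params.ell
        x2 = step(x, edgeless_params)
        assert np.allclose(x2, x, atol=1e-12)

    def test_from_zero_edgeless(self, edgeless_params):
        x2 = step(np.zeros(edgeless_params.n), edgeless_params)
        assert np.allclose(x2, edgeless_params.dt * expit(edgeless_params.alpha))

    def test_matches_scalar_oracle(self, rng):
        """Vectorized update equals an independent scalar-by-scalar evaluation."""
        n = 5
        edges = [(0, 1), (1, 2), (3, 2), (2, 4), (4, 0)]
        data = [1.5, -2.0, 1.2, 3.0, -1.1]
        beta = sp.csr_matrix((data, tuple(zip(*[(s, t) for s, t in edges]))), shape=(n, n))
        params = ExpressionParams(
            alpha=rng.normal(-1, 0.5, n), ell=rng.uniform(0.5, 1, n), beta=beta, s=0.0
        )
        x = rng.uniform(0, 1, n)
        got = step(x, params)
        want = np.empty(n)
        B = beta.toarray()
        for i in range(n):
            u = params.alpha[i] + sum(B[j, i] * x[j] for j in range(n))
            want[i] = max(x[i] + params.dt * (1 / (1 + np.exp(-u)) - params.ell[i] * x[i]), 0)
        assert np.allclose(got, want, atol=1e-12)

    def test_nonfinite_input_raises(self, edgeless_params):
        with pytest.raises(FloatingPointError):
            step(np.array([np.nan] * edgeless_params.n), edgeless_params)


class TestFindSteadyState:
    def test_edgeless_reaches_closed_form(self, edgeless_params):
        st = find_steady_state(edgeless_params)
        assert st.converged
        want = expit(edgeless_params.alpha) / edgeless_params.ell
        assert np.allclose(st.xbar, want, atol=1e-3)

    def test_mutual_activation_satisfies_fixed_point(self):
        """Two-gene mutual activation matches a root-finder on x = sigma(a+b x)/ell."""
        beta = sp.csr_matrix(([2.0, 2.0], ([0, 1], [1, 0])), shape=(2, 2))
        params = ExpressionParams(
            alpha=np.array([-1.0, -1.5]), ell=np.array([0.8, 0.9]), beta=beta, s=0.0
        )
        st = find_steady_state(params)
        B = beta.toarray()

        def resid(x):
            return expit(params.alpha + B.T @ x) / params.ell - x

        root = fsolve(resid, st.xbar)
        assert np.max(np.abs(st.xbar - root) / root) < 1e-3

    def test_default_protocol(self):
        cfg = SimulationConfig()
        assert (cfg.burn_in, cfg.check_every, cfg.t_max, cfg.tolerance) == (
            5000, 1000, 20000, 1e-3,
        )

    def test_residual_small_at_convergence(self, small_system):
        """||sigma(alpha + beta^T xbar) - ell xbar||_inf stays below 10x tolerance."""
        _, params = small_system
        cfg = SimulationConfig()
        st = find_steady_state(params, cfg)
        resid = expit(params.alpha + params.beta.T @ st.xbar) - params.ell * st.xbar
        assert st.converged
        assert np.max(np.abs(resid)) < 10 * cfg.tolerance

    def test_expression_bounded(self, small_system, rng):
        """Trajectories stay within [0, max(1/ell)] up to noise slack."""
        _, params = small_system
        p = params.copy()
        p.s = 1e-3
        traj = simulate_trajectory(p, np.zeros(p.n), 3000, rng=rng)
        assert traj.min() >= 0
        assert traj.max() <= (1 / p.ell).max() * 1.05

    def test_permutation_equivariance(self, small_system):
        """Relabeling genes permutes the steady state but nothing else."""
        _, params = small_system
        n = params.n
        perm = np.random.default_rng(3).permutation(n)
        st = find_steady_state(params)
        # gene i of the permuted system is gene perm[i] of the original
        alpha_p = params.alpha[perm]
        ell_p = params.ell[perm]
        beta_p = sp.csr_matrix(params.beta.toarray()[np.ix_(perm, perm)])
        st_p = find_steady_state(
            ExpressionParams(alpha=alpha_p, ell=ell_p, beta=beta_p, s=0.0, dt=params.dt)
        )
        assert st_p.converged == st.converged
        assert st_p.iterations_used == st.iterations_used
        assert np.allclose(st_p.xbar, st.xbar[perm], atol=1e-9)


class TestJacobianStability:
    def test_edgeless_jacobian_is_minus_decay(self, edgeless_params):
        x = expit(edgeless_params.alpha) / edgeless_params.ell
        J = jacobian(edgeless_params, x)
        assert np.allclose(J, -np.diag(edgeless_params.ell))

    def test_matches_finite_differences(self, rng):
        """Analytic Jacobian agrees with central differences of the drift to 1e-6."""
        n = 6
        grn = generate_network(GeneratorParams(n=n, p=0.6, seed=11))
        params = sample_expression_params(grn, rng, s=0.0)
        x = rng.uniform(0.1, 1.0, n)
        J = jacobian(params, x)
        B = params.beta.toarray()

        def drift(x):
            return expit(params.alpha + B.T @ x) - params.ell * x

        h = 1e-6
        for j in range(n):
            e = np.zeros(n)
            e[j] = h
            col = (drift(x + e) - drift(x - e)) / (2 * h)
            assert np.allclose(J[:, j], col, atol=1e-6)

    def test_sparsity_pattern(self, small_system):
        grn, params = small_system
        x = np.random.default_rng(0).uniform(0, 1, grn.n)
        J = jacobian(params, x)
        edge_set = set(grn.edges)
        for i in range(grn.n):
            for j in range(grn.n):
                if i != j and (j, i) not in edge_set:
                    assert J[i, j] == 0.0

    def test_edgeless_is_stable(self, edgeless_params):
        st = find_steady_state(edgeless_params)
        stable, leading = is_stable(edgeless_params, st)
        assert stable
        assert leading == pytest.approx(-edgeless_params.ell.min(), abs=1e-9)

    def test_strong_positive_feedback_is_unstable(self):
        """A 2-cycle with sigma' * beta > ell at the origin-side fixed point.

        With alpha = 0 (sigma' = 1/4 at u near 0), beta = 8 and ell = 1 the
        analytic eigenvalues at x near the symmetric fixed point include a
        positive real part, so the flag must be unstable.
        """
        beta = sp.csr_matrix(([8.0, 8.0], ([0, 1], [1, 0])), shape=(2, 2))
        params = ExpressionParams(
            alpha=np.array([-4.0, -4.0]), ell=np.array([1.0, 1.0]), beta=beta, s=0.0
        )
        # evaluate stability at the unstable middle fixed point x = (0.5, 0.5):
        # u = -4 + 8*0.5 = 0, sigma(u) = 0.5 = ell*x, so it is a fixed point;
        # J = [[-1, 2], [2, -1]] has leading eigenvalue +1.
        from grnsim import SteadyState

        st = SteadyState(xbar=np.array([0.5, 0.5]), converged=True, iterations_used=0)
        stable, leading = is_stable(params, st)
        assert not stable
        assert leading == pytest.approx(1.0, abs=1e-9)

    def test_stability_flag_predicts_return_to_equilibrium(self):
        """On random small networks, the eigenvalue test agrees with dynamics.

        Perturb the converged state multiplicatively by 1% and evolve the
        deterministic system: stable states return, unstable ones do not.
        """
        agree = 0
        total = 0
        for seed in range(20):
            n = 30
            grn = generate_network(GeneratorParams(n=n, p=0.15, k=1, seed=seed))
            params = sample_expression_params(grn, np.random.default_rng(seed), s=0.0)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                st = find_steady_state(params)
            stable, _ = is_stable(params, st)
            if not st.converged:
                continue
            x = st.xbar * (1 + 0.01 * np.where(np.arange(n) % 2 == 0, 1, -1))
            for _ in range(4000):
                x = step(x, params)
            returned = np.max(np.abs(x - st.xbar) / np.maximum(st.xbar, 1e-12)) < 0.005
            total += 1
            agree += int(returned == stable)
        assert total >= 10
        assert agree == total
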