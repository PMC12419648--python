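"""Stochastic differential-equation model of gene expression on a network.

For gene i with baseline transcription log-odds alpha_i, decay rate ell_i and
signed regulator weights beta_ji (nonzero exactly on network edges), one
Euler-Maruyama step of size dt is

    x' = x + dt * (sigma(alpha + beta^T x) - ell * x) + N(0, dt * s^2 * diag(x))

with sigma the logistic sigmoid.  Transcription saturates through the sigmoid
and expression is clipped to stay non-negative, so trajectories live in
[0, 1/ell] up to noise.  Steady states satisfy x* = sigma(alpha + beta^T x*) / ell
and are found by forward simulation with a running-mean convergence check;
their local stability follows from the eigenvalues of the Jacobian

    J[i, j] = beta_ji * sigma'(u_i) - 1{i == j} * ell_i,   u = alpha + beta^T x.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.special import expit

from .netgen import Grn

__all__ = [
    "ExpressionParams",
    "SimulationConfig",
    "SteadyState",
    "sample_expression_params",
    "step",
    "find_steady_state",
    "simulate_batch",
    "simulate_trajectory",
    "knockout_params",
    "jacobian",
    "is_stable",
]

_TINY = np.finfo(np.float64).tiny


@dataclass
class ExpressionParams:
    """Per-gene and per-edge parameters of the expression SDE.

    ``beta`` is a sparse (n, n) matrix with ``beta[j, i]`` the signed weight
    of regulator j on target i; its sparsity pattern is the network edge set.
    """

    alpha: np.ndarray
    ell: np.ndarray
    beta: sp.csr_matrix
    s: float = 1e-4
    dt: float = 0.01

    @property
    def n(self) -> int:
        return len(self.alpha)

    def validate(self) -> None:
        n = self.n
        if self.beta.shape != (n, n) or len(self.ell) != n:
            raise ValueError("alpha, ell and beta shapes disagree")
        if (self.ell <= 0).any():
            raise ValueError("decay rates must be positive")
        if self.beta.nnz and np.abs(self.beta.data).min() < 1.0 - 1e-12:
            raise ValueError("edge weights must satisfy |beta| >= 1")
        if self.s < 0 or self.dt <= 0:
            raise ValueError("need s >= 0 and dt > 0")

    def copy(self) -> "ExpressionParams":
        return ExpressionParams(
            alpha=self.alpha.copy(),
            ell=self.ell.copy(),
            beta=self.beta.copy(),
            s=self.s,
            dt=self.dt,
        )

    # -- serialization --------------------------------------------------------
    def write(self, json_path: str | Path, weights_path: str | Path) -> None:
        Path(json_path).write_text(
            json.dumps(
                {
                    "alpha": self.alpha.tolist(),
                    "ell": self.ell.tolist(),
                    "s": self.s,
                    "dt": self.dt,
                },
            )
            + "\n"
        )
        coo = self.beta.tocoo()
        with open(weights_path, "w") as fh:
            fh.write("source\ttarget\tbeta\n")
            for j, i, b in zip(coo.row, coo.col, coo.data):
                fh.write(f"{j}\t{i}\t{float(b)!r}\n")

    @classmethod
    def read(cls, json_path: str | Path, weights_path: str | Path) -> "ExpressionParams":
        d = json.loads(Path(json_path).read_text())
        alpha = np.asarray(d["alpha"], dtype=np.float64)
        n = len(alpha)
        raw = np.loadtxt(weights_path, skiprows=1, ndmin=2)
        if raw.size:
            beta = sp.csr_matrix(
                (raw[:, 2], (raw[:, 0].astype(int), raw[:, 1].astype(int))), shape=(n, n)
            )
        else:
            beta = sp.csr_matrix((n, n))
        return cls(
            alpha=alpha,
            ell=np.asarray(d["ell"], dtype=np.float64),
            beta=beta,
            s=d["s"],
            dt=d["dt"],
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Forward-simulation protocol: burn-in, convergence checks, iteration cap.

    After ``burn_in`` iterations, running means of expression are accumulated
    and checked every ``check_every`` iterations; the system has converged when
    the largest |log2 ratio| of running means between consecutive checks, over
    genes whose running mean exceeds the noise magnitude, falls below
    ``tolerance``.  Simulation stops at convergence or at ``t_max`` total
    iterations.
    """

    burn_in: int = 5000
    check_every: int = 1000
    t_max: int = 20000
    tolerance: float = 1e-3
    seed: int | None = None

    def validate(self) -> None:
        if self.burn_in < 0 or self.check_every <= 0 or self.t_max <= self.burn_in:
            raise ValueError("need burn_in >= 0, check_every > 0, t_max > burn_in")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class SteadyState:
    """Running-mean equilibrium expression with convergence/stability flags."""

    xbar: np.ndarray
    converged: bool
    iterations_used: int
    stable: bool | None = None
    leading_eigenvalue_real_part: float | None = None

    def expressed_mask(self, s: float) -> np.ndarray:
        """Genes whose equilibrium expression exceeds the noise magnitude."""
        return self.xbar > s

    def write_tsv(self, path: str | Path, s: float = 1e-4) -> None:
        mask = self.expressed_mask(s)
        with open(path, "w") as fh:
            fh.write("gene\txbar\texpressed\n")
            for i, (x, m) in enumerate(zip(self.xbar, mask)):
                fh.write(f"{i}\t{float(x)!r}\t{int(m)}\n")


def sample_expression_params(
    grn: Grn,
    rng: np.random.Generator,
    activator_prob: float = 0.8,
    s: float = 1e-4,
    dt: float = 0.01,
) -> ExpressionParams:
    """Draw expression parameters for a network.

    Baseline transcription: sigma(alpha_i) ~ Beta(2, 8), i.e. low but nonzero
    innate expression.  Decay: ell_i ~ Beta(8, 2), hard-clipped from below at
    e^{-alpha_i}; the clip prevents excessively large steady-state expression
    (the isolated-gene steady state sigma(alpha_i)/ell_i is then at most
    sigma(alpha_i) e^{alpha_i} < 1) and, by keeping expression small, leaves
    regulatory inputs in the responsive range of the sigmoid rather than its
    saturated tails.  Each regulator j is an activator with probability
    ``activator_prob`` (sign 2 p_j - 1 applied to all its outgoing edges);
    per-edge magnitudes are 1 + |Normal(0, 1)|, so every interaction has
    strength at least 1.
    """
    n = grn.n
    sig_alpha = rng.beta(2.0, 8.0, size=n)
    alpha = np.log(sig_alpha) - np.log1p(-sig_alpha)  # logit
    ell = rng.beta(8.0, 2.0, size=n)
    ell = np.maximum(ell, np.exp(-alpha))

    signs = np.where(rng.random(n) < activator_prob, 1.0, -1.0)
    e = grn.edge_array()
    if len(e):
        mags = 1.0 + np.abs(rng.standard_normal(len(e)))
        data = signs[e[:, 0]] * mags
        beta = sp.csr_matrix((data, (e[:, 0], e[:, 1])), shape=(n, n))
    else:
        beta = sp.csr_matrix((n, n))
    return ExpressionParams(alpha=alpha, ell=ell, beta=beta, s=s, dt=dt)


def step(
    x: np.ndarray, params: ExpressionParams, rng: np.random.Generator | None = None
) -> np.ndarray:
    """One Euler-Maruyama update of the expression vector."""
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite expression input")
    u = params.alpha + params.beta.T @ x
    drift = expit(u) - params.ell * x
    x_new = x + params.dt * drift
    if params.s > 0:
        if rng is None:
            raise ValueError("rng required when s > 0")
        x_new = x_new + params.s * np.sqrt(params.dt * x) * rng.standard_normal(len(x))
    np.clip(x_new, 0.0, None, out=x_new)
    if not np.all(np.isfinite(x_new)):
        raise FloatingPointError("numerical blow-up during simulation")
    return x_new


def simulate_batch(
    params: ExpressionParams,
    config: SimulationConfig,
    x0: np.ndarray,
    rng: np.random.Generator | None = None,
    ko_genes: np.ndarray | None = None,
    dtype=np.float64,
):
    """Simulate ``m`` independent systems sharing the step loop.

    ``x0`` has shape (m, n) (or (n,) for a single system).  When ``ko_genes``
    is given, system r evolves with row ``ko_genes[r]`` of beta zeroed — its
    outgoing regulation nullified — which is numerically equivalent to
    simulating each knockout independently.  Systems whose running means have
    converged are frozen and dropped from the active batch.

    Returns ``(xbar, converged, iterations)`` arrays over systems.
    """
    config.validate()
    params.validate()
    n = params.n
    X = np.atleast_2d(np.asarray(x0, dtype=dtype)).T.copy()  # (n, m) column-major systems
    m = X.shape[1]
    if X.shape[0] != n:
        raise ValueError("x0 shape does not match parameter dimension")

    alpha = params.alpha.astype(dtype)[:, None]
    ell = params.ell.astype(dtype)[:, None]
    BT = params.beta.T.tocsr().astype(dtype)
    s, dt = dtype(params.s), dtype(params.dt)
    noise_scale = dtype(params.s * np.sqrt(params.dt))
    if params.s > 0 and rng is None:
        raise ValueError("rng required when s > 0")

    if ko_genes is not None:
        ko_genes = np.asarray(ko_genes)
        if len(ko_genes) != m:
            raise ValueError("one knocked-out gene per system required")
        # outgoing-weight rows of the knocked-out genes; dense (n, m)
        R = np.asarray(params.beta[ko_genes].todense(), dtype=dtype).T.copy()
        g_idx = ko_genes.copy()
    else:
        R = None
        g_idx = None

    active = np.arange(m)
    xbar_out = np.zeros((m, n))
    converged = np.zeros(m, dtype=bool)
    iters_out = np.full(m, config.t_max)
    S = np.zeros((n, m))  # running sums (float64 accumulators)
    prev_mean = None
    colix = np.arange(m)

    tmp = np.empty_like(X)
    t = 0
    while t < config.t_max and X.shape[1] > 0:
        t += 1
        if tmp.shape != X.shape:
            tmp = np.empty_like(X)
        U = BT @ X
        if R is not None:
            np.multiply(R, X[g_idx, colix], out=tmp)
            U -= tmp
        U += alpha
        expit(U, out=U)
        np.multiply(ell, X, out=tmp)
        U -= tmp  # U now holds the drift
        U *= dt
        if s > 0:
            np.sqrt(X, out=tmp)
            tmp *= noise_scale
            tmp *= rng.standard_normal(X.shape, dtype=dtype)
            X += U
            X += tmp
        else:
            X += U
        np.clip(X, 0.0, None, out=X)
        if not np.all(np.isfinite(X)):
            bad = active[~np.isfinite(X).all(axis=0)]
            raise FloatingPointError(f"numerical blow-up in systems {bad.tolist()}")
        if t > config.burn_in:
            S += X
            since = t - config.burn_in
            if since % config.check_every == 0:
                mean = S / since
                if prev_mean is not None:
                    num = np.maximum(mean, _TINY)
                    den = np.maximum(prev_mean, _TINY)
                    crit = np.abs(np.log2(num / den))
                    crit[mean <= params.s] = 0.0  # lowly expressed genes excluded
                    ok = crit.max(axis=0) < config.tolerance
                    if ok.any():
                        done = active[ok]
                        xbar_out[done] = mean[:, ok].T
                        converged[done] = True
                        iters_out[done] = t
                        keep = ~ok
                        X = X[:, keep].copy()
                        S = S[:, keep].copy()
                        mean = mean[:, keep]
                        active = active[keep]
                        if R is not None:
                            R = R[:, keep].copy()
                            g_idx = g_idx[keep]
                        colix = np.arange(X.shape[1])
                prev_mean = mean
    if X.shape[1] > 0:
        since = max(t - config.burn_in, 1)
        mean = S / since
        xbar_out[active] = mean.T
        warnings.warn(
            f"{X.shape[1]} system(s) did not converge by t_max={config.t_max}; "
            "running mean taken as approximate equilibrium",
            RuntimeWarning,
            stacklevel=2,
        )
    return xbar_out, converged, iters_out


def simulate_trajectory(
    params: ExpressionParams,
    x0: np.ndarray,
    n_steps: int,
    rng: np.random.Generator | None = None,
    ko_gene: int | None = None,
) -> np.ndarray:
    """Forward-simulate one system and record every step.

    Returns an (n_steps, n) array: row t is the expression vector after t + 1
    updates from ``x0``.  With ``ko_gene`` set, the gene's outgoing weights
    are nullified for the whole trajectory.
    """
    p = params
    if ko_gene is not None:
        p = knockout_params(params, ko_gene)
    x = np.asarray(x0, dtype=np.float64).copy()
    out = np.empty((n_steps, p.n))
    for t in range(n_steps):
        x = step(x, p, rng)
        out[t] = x
    return out


def knockout_params(params: ExpressionParams, gene: int) -> ExpressionParams:
    """Copy of ``params`` with the gene's outgoing weights (beta row) zeroed."""
    if not (0 <= gene < params.n):
        raise ValueError(f"gene index {gene} out of range")
    beta = params.beta.tolil(copy=True)
    beta[gene, :] = 0
    return ExpressionParams(
        alpha=params.alpha.copy(),
        ell=params.ell.copy(),
        beta=beta.tocsr(),
        s=params.s,
        dt=params.dt,
    )


def find_steady_state(
    params: ExpressionParams,
    config: SimulationConfig | None = None,
    x0: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> SteadyState:
    """Forward-simulate from ``x0`` (default zeros) to a steady state.

    Non-convergence at ``t_max`` produces a warning, not an error: the final
    running mean is returned as an approximate equilibrium.
    """
    if config is None:
        config = SimulationConfig()
    if x0 is None:
        x0 = np.zeros(params.n)
    if rng is None and params.s > 0:
        rng = np.random.default_rng(config.seed)
    xbar, conv, iters = simulate_batch(params, config, x0[None, :], rng=rng)
    return SteadyState(xbar=xbar[0], converged=bool(conv[0]), iterations_used=int(iters[0]))


def jacobian(params: ExpressionParams, x: np.ndarray) -> np.ndarray:
    """Jacobian of the deterministic drift at expression ``x`` (dense)."""
    x = np.asarray(x, dtype=np.float64)
    u = params.alpha + params.beta.T @ x
    sig = expit(u)
    dsig = sig * (1.0 - sig)  # sigma'(u_i)
    # J[i, j] = beta_ji * sigma'(u_i); beta[j, i] stored as (row=regulator, col=target)
    J = np.asarray(params.beta.T.todense()) * dsig[:, None]
    J[np.diag_indices_from(J)] -= params.ell
    return J


def is_stable(params: ExpressionParams, state: SteadyState) -> tuple[bool, float]:
    """Linear stability of the deterministic system at the steady state.

    Stable iff every eigenvalue of the Jacobian at ``xbar`` has negative real
    part.  Updates the ``stable`` and ``leading_eigenvalue_real_part`` fields
    of ``state`` and returns them.
    """
    J = jacobian(params, state.xbar)
    eigs = np.linalg.eigvals(J)
    leading = float(eigs.real.max())
    state.stable = leading < 0
    state.leading_eigenvalue_real_part = leading
    return state.stable, leading
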