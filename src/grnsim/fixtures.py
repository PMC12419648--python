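"""Small synthetic inputs with hand-checkable structure.

These generators produce the tiny objects used in examples and tests:
minimal networks with known analytics, empirical-style p-value tables with a
configurable significant-pair rate, and constructed effect matrices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .exprmodel import ExpressionParams, SteadyState
from .netgen import GeneratorParams, Grn
from .perturb import EffectMatrix

__all__ = ["make_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("chain3", "star10", "small_random", "emp_table", "effects")


def make_fixture(kind: str, seed: int = 0, **kwargs):
    """Build a named fixture; the same seed yields an identical object.

    kinds:
      ``chain3``       3-gene activating chain 0 -> 1 -> 2, one group.
      ``star10``       10-node star, node 0 regulating nodes 1..9.
      ``small_random`` a generated network with n <= 50 (kwargs: n, p, k, w).
      ``emp_table``    perturbation x gene p-value DataFrame (kwargs:
                       n_genes, rate — fraction of off-diagonal pairs
                       significant at p < 0.05).
      ``effects``      EffectMatrix with one constructed hub row (kwargs:
                       n_genes, hub_targets, hub_lfc).
    """
    rng = np.random.default_rng(seed)
    if kind == "chain3":
        grn = Grn(n=3, edges=[(0, 1), (1, 2)], group_of=np.zeros(3, dtype=np.int64))
        beta = sp.csr_matrix(([1.5, 1.5], ([0, 1], [1, 2])), shape=(3, 3))
        params = ExpressionParams(
            alpha=np.full(3, -1.0), ell=np.full(3, 0.8), beta=beta, s=0.0
        )
        return grn, params
    if kind == "star10":
        edges = [(0, i) for i in range(1, 10)]
        return Grn(n=10, edges=edges, group_of=np.zeros(10, dtype=np.int64))
    if kind == "small_random":
        gp = GeneratorParams(
            n=kwargs.get("n", 30),
            p=kwargs.get("p", 0.5),
            k=kwargs.get("k", 3),
            w=kwargs.get("w", 5.0),
            delta_in=kwargs.get("delta_in", 5.0),
            delta_out=kwargs.get("delta_out", 5.0),
            seed=seed,
        )
        from .netgen import generate_network

        return generate_network(gp, rng)
    if kind == "emp_table":
        n = kwargs.get("n_genes", 40)
        rate = kwargs.get("rate", 0.0316)
        genes = [f"G{i:03d}" for i in range(n)]
        P = rng.uniform(0.05, 1.0, size=(n, n))
        off = ~np.eye(n, dtype=bool)
        idx = np.argwhere(off)
        n_sig = int(round(rate * len(idx)))
        chosen = idx[rng.choice(len(idx), size=n_sig, replace=False)]
        P[chosen[:, 0], chosen[:, 1]] = rng.uniform(0.0, 0.05, size=n_sig)
        np.fill_diagonal(P, 0.0)
        return pd.DataFrame(P, index=genes, columns=genes)
    if kind == "effects":
        n = kwargs.get("n_genes", 20)
        hub_targets = kwargs.get("hub_targets", 10)
        hub_lfc = kwargs.get("hub_lfc", 0.2)
        lfc = np.zeros((n, n))
        lfc[0, 1 : hub_targets + 1] = hub_lfc
        lfc[np.diag_indices(n)] = np.nan
        baseline = SteadyState(xbar=np.ones(n), converged=True, iterations_used=0)
        return EffectMatrix(
            lfc=lfc,
            ko_genes=np.arange(n),
            expressed_mask=np.ones(n, dtype=bool),
            baseline=baseline,
        )
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
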