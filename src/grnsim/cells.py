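"""Sampling single-"cell" expression profiles and coexpression statistics.

Cells are consecutive steps of the stochastic expression model at steady
state: after the system equilibrates, each additional forward step yields one
cell, so the intrinsic noise of the SDE produces the cell-to-cell
variability.  Cells are therefore autocorrelated, which is intentional — the
sampler emulates natural expression fluctuation around equilibrium, not
independent draws.  Perturbed "experiments" mix baseline cells with cells
drawn from per-knockout equilibria, mimicking the composition of a pooled
single-cell knockout screen.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import spearmanr
from sklearn.metrics import average_precision_score

from dataclasses import dataclass

from .exprmodel import (
    ExpressionParams,
    SimulationConfig,
    SteadyState,
    simulate_batch,
    simulate_trajectory,
)
from .netgen import Grn
from .perturb import EffectMatrix

__all__ = [
    "CellMatrix",
    "BASELINE",
    "sample_baseline_cells",
    "sample_experiment_cells",
    "coexpression",
    "edge_enrichment",
    "EdgeEnrichment",
]

#: Condition label for unperturbed cells.
BASELINE = -1


@dataclass
class CellMatrix:
    """Cells x genes expression with a per-cell condition label.

    ``condition_of[c]`` is the knocked-out gene id for cell c, or
    ``BASELINE`` (-1) for unperturbed cells.
    """

    values: np.ndarray
    condition_of: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        if (self.values < 0).any():
            raise ValueError("expression must be non-negative")
        if len(self.condition_of) != self.n_cells:
            raise ValueError("one condition label per cell required")
        bad = (self.condition_of < BASELINE) | (self.condition_of >= self.n_genes)
        if bad.any():
            raise ValueError("condition labels must be gene ids or the baseline sentinel")

    def write_tsv(self, values_path, labels_path) -> None:
        np.savetxt(values_path, self.values, delimiter="\t")
        np.savetxt(labels_path, self.condition_of, fmt="%d")


def sample_baseline_cells(
    params: ExpressionParams,
    state: SteadyState,
    n_cells: int = 10000,
    rng: np.random.Generator | None = None,
) -> CellMatrix:
    """Sample cells from forward steps at the baseline steady state.

    One cell per step, starting from the equilibrium ``state.xbar``; with
    s = 0 every cell equals the steady state exactly.
    """
    if rng is None and params.s > 0:
        rng = np.random.default_rng()
    values = simulate_trajectory(params, state.xbar, n_cells, rng=rng)
    return CellMatrix(values=values, condition_of=np.full(n_cells, BASELINE))


def sample_experiment_cells(
    grn: Grn,
    params: ExpressionParams,
    config: SimulationConfig | None = None,
    n_cells: int = 75328,
    baseline_fraction: float = 0.081,
    rng: np.random.Generator | None = None,
    baseline: SteadyState | None = None,
) -> CellMatrix:
    """Sample a mixed baseline + knockout experiment.

    A fraction ``baseline_fraction`` of cells comes from baseline conditions;
    the rest are assigned uniformly at random to a knockout of one of the n
    genes (for the default 75,328 cells over 2,000 genes this is about 35
    cells per knockout).  Cells for each knockout are consecutive forward
    steps after re-equilibration under that knockout.  Lowly expressed genes
    are not filtered.
    """
    if config is None:
        config = SimulationConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if baseline is None:
        baseline = _baseline_state(params, config, rng)

    n_base = int(round(n_cells * baseline_fraction))
    ko_of_cell = rng.integers(0, grn.n, size=n_cells - n_base)
    ko_ids, counts = np.unique(ko_of_cell, return_counts=True)

    values = np.empty((n_cells, grn.n))
    labels = np.empty(n_cells, dtype=np.int64)
    base_cells = sample_baseline_cells(params, baseline, n_base, rng)
    values[:n_base] = base_cells.values
    labels[:n_base] = BASELINE

    if len(ko_ids):
        x0 = np.broadcast_to(baseline.xbar, (len(ko_ids), grn.n))
        ko_xbar, _, _ = simulate_batch(
            params, config, x0, rng=rng, ko_genes=ko_ids, dtype=np.float32
        )
        pos = n_base
        for ko, cnt, xeq in zip(ko_ids, counts, ko_xbar):
            traj = simulate_trajectory(params, xeq, cnt, rng=rng, ko_gene=int(ko))
            values[pos : pos + cnt] = traj
            labels[pos : pos + cnt] = ko
            pos += cnt
    return CellMatrix(values=values, condition_of=labels)


def _baseline_state(params, config, rng) -> SteadyState:
    from .exprmodel import find_steady_state

    return find_steady_state(params, config, rng=rng)


def coexpression(cells: CellMatrix) -> np.ndarray:
    """Gene x gene Pearson correlation across cells.

    Symmetric with unit diagonal; genes with zero variance get correlation 0
    off-diagonal.  Population (divide-by-m) moments are used — immaterial at
    the default cell counts.
    """
    X = cells.values
    if X.shape[0] < 2:
        raise ValueError("need at least two cells")
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    zero = sd == 0
    denom = np.where(zero, 1.0, sd)
    Z = Xc / denom
    r = (Z.T @ Z) / X.shape[0]
    r[zero, :] = 0.0
    r[:, zero] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


@dataclass(frozen=True)
class EdgeEnrichment:
    """Edge-recovery performance of perturbation effects vs coexpression.

    ``ap_lfc``/``ap_coex``: average precision when ranking unordered gene
    pairs by |log2FC| (max over the two directions) or |r| against undirected
    edge membership.  ``rho_*_beta``: Spearman correlation of each statistic
    with |beta| over directed edges.  ``rho_coex_lfc_all``/``_edges``:
    Spearman correlation between |r| and |lfc| over all ordered pairs and
    over edge pairs.
    """

    ap_lfc: float
    ap_coex: float
    edge_density: float
    rho_lfc_beta: float
    rho_coex_beta: float
    rho_coex_lfc_all: float
    rho_coex_lfc_edges: float


def edge_enrichment(
    effects: EffectMatrix,
    coex: np.ndarray,
    grn: Grn,
    params: ExpressionParams | None = None,
) -> EdgeEnrichment:
    """Score |log2FC| and |coexpression| as rankers of network edges.

    Requires a full screen (one row per gene) so both directions of every
    pair are available.  Pass ``params`` to also compute rank correlations
    with the true edge weights |beta|.
    """
    n = grn.n
    if len(effects.ko_genes) != n or not np.array_equal(np.sort(effects.ko_genes), np.arange(n)):
        raise ValueError("edge_enrichment requires a full screen over all genes")
    order = np.argsort(effects.ko_genes)
    L = np.abs(effects.lfc[order])  # L[j, i] = |lfc| of KO j on gene i

    e = grn.edge_array()
    adj = np.zeros((n, n), dtype=bool)
    if len(e):
        adj[e[:, 0], e[:, 1]] = True

    iu = np.triu_indices(n, k=1)
    undirected_edge = (adj | adj.T)[iu]
    pair_lfc = np.fmax(L, L.T)[iu]  # fmax ignores the NaN diagonal
    pair_coex = np.abs(coex)[iu]

    ap_lfc = float(average_precision_score(undirected_edge, pair_lfc))
    ap_coex = float(average_precision_score(undirected_edge, pair_coex))

    # per-directed-edge statistics vs |beta|
    rho_lfc_beta = rho_coex_beta = rho_edges = float("nan")
    if len(e):
        lfc_e = L[e[:, 0], e[:, 1]]
        coex_e = np.abs(coex)[e[:, 0], e[:, 1]]
        rho_edges = _spearman(coex_e, lfc_e)
        if params is not None:
            beta = np.abs(np.asarray(params.beta[e[:, 0], e[:, 1]]).ravel())
            rho_lfc_beta = _spearman(lfc_e, beta)
            rho_coex_beta = _spearman(coex_e, beta)

    offdiag = ~np.eye(n, dtype=bool)
    rho_all = _spearman(np.abs(coex)[offdiag], L[offdiag])
    return EdgeEnrichment(
        ap_lfc=ap_lfc,
        ap_coex=ap_coex,
        edge_density=float(undirected_edge.mean()),
        rho_lfc_beta=rho_lfc_beta,
        rho_coex_beta=rho_coex_beta,
        rho_coex_lfc_all=rho_all,
        rho_coex_lfc_edges=rho_edges,
    )


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3 or np.ptp(a[ok]) == 0 or np.ptp(b[ok]) == 0:
        return float("nan")  # undefined for constant input
    return float(spearmanr(a[ok], b[ok]).statistic)
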