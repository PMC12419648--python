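"""Systematic in-silico knockout screens and effect-matrix summaries.

A knockout of gene j nullifies its outgoing regulatory weights (beta row j).
Starting from the baseline steady state, the perturbed system re-equilibrates
under the same burn-in/convergence protocol, and the effect on every other
gene i is the log2 fold-change of its steady-state expression,

    log2FC_ji = log2(x_i | do(x_j = 0)) - log2(x_i).

Hub statistics count genes that induce (hub KO) or receive (hub target)
|log2FC| > 0.1 in at least 100 other genes; genes whose baseline expression
is below the noise magnitude are excluded, since their expression varies
across conditions through noise alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exprmodel import (
    ExpressionParams,
    SimulationConfig,
    SteadyState,
    knockout_params,
    simulate_batch,
)
from .netgen import Grn, shortest_path_distances

__all__ = ["EffectMatrix", "HubSummary", "knockout", "ko_screen", "hub_summary", "stratify_effects"]

_TINY = np.finfo(np.float64).tiny


def knockout(params: ExpressionParams, j: int) -> ExpressionParams:
    """Expression parameters with gene j's outgoing effects nullified."""
    return knockout_params(params, j)


@dataclass
class EffectMatrix:
    """Knockout log2 fold-change effects: one row per perturbed gene.

    ``lfc[r, i]`` is the effect of knocking out ``ko_genes[r]`` on gene i;
    entries where target equals the perturbed gene are NaN and excluded from
    all summaries.  ``expressed_mask`` flags genes with baseline expression
    above the noise magnitude.
    """

    lfc: np.ndarray
    ko_genes: np.ndarray
    expressed_mask: np.ndarray
    baseline: SteadyState
    ko_converged: np.ndarray = field(default=None)

    @property
    def n_genes(self) -> int:
        return self.lfc.shape[1]

    def offdiag_mask(self) -> np.ndarray:
        """Boolean mask of (perturbation, target) pairs with target != KO gene."""
        mask = np.ones_like(self.lfc, dtype=bool)
        mask[np.arange(len(self.ko_genes)), self.ko_genes] = False
        return mask

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("perturbed\ttarget\tlfc\n")
            for r, j in enumerate(self.ko_genes):
                for i in range(self.n_genes):
                    if i == j:
                        continue
                    fh.write(f"{j}\t{i}\t{float(self.lfc[r, i])!r}\n")

    def write_hdf5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("lfc", data=self.lfc, compression="gzip")
            fh.create_dataset("ko_genes", data=self.ko_genes)
            fh.create_dataset("expressed_mask", data=self.expressed_mask)
            fh.create_dataset("baseline_xbar", data=self.baseline.xbar)

    @classmethod
    def read_hdf5(cls, path: str | Path) -> "EffectMatrix":
        import h5py

        with h5py.File(path, "r") as fh:
            baseline = SteadyState(
                xbar=fh["baseline_xbar"][:], converged=True, iterations_used=-1
            )
            return cls(
                lfc=fh["lfc"][:],
                ko_genes=fh["ko_genes"][:],
                expressed_mask=fh["expressed_mask"][:],
                baseline=baseline,
            )


def ko_screen(
    grn: Grn,
    params: ExpressionParams,
    baseline: SteadyState,
    config: SimulationConfig | None = None,
    ko_genes: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    dtype=np.float64,
) -> EffectMatrix:
    """Knock out each gene (or a subset) and measure re-equilibrated effects.

    All knockouts start from the baseline steady state and follow the same
    burn-in/convergence protocol as the baseline run.  Knockouts are batched
    through a shared step loop but evolve independently (no cross-talk), which
    at s = 0 is numerically equivalent to one-at-a-time simulation.  ``dtype``
    selects the state precision of the batch (running means accumulate in
    float64 either way).
    """
    if config is None:
        config = SimulationConfig()
    if ko_genes is None:
        ko_genes = np.arange(grn.n)
    ko_genes = np.asarray(ko_genes, dtype=np.int64)
    if rng is None and params.s > 0:
        rng = np.random.default_rng(config.seed)
    m = len(ko_genes)
    x0 = np.broadcast_to(baseline.xbar, (m, grn.n))
    xbar, conv, _ = simulate_batch(
        params, config, x0, rng=rng, ko_genes=ko_genes, dtype=dtype
    )
    base = np.maximum(baseline.xbar, _TINY)
    lfc = np.log2(np.maximum(xbar, _TINY)) - np.log2(base)
    lfc[np.arange(m), ko_genes] = np.nan
    return EffectMatrix(
        lfc=lfc,
        ko_genes=ko_genes,
        expressed_mask=baseline.expressed_mask(params.s),
        baseline=baseline,
        ko_converged=conv,
    )


@dataclass(frozen=True)
class HubSummary:
    """Counts of hub knockouts and hub target genes at fixed thresholds."""

    n_hub_ko: int
    n_hub_target: int
    hub_lfc: float = 0.1
    hub_count: int = 100

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1) + "\n")


def hub_summary(
    effects: EffectMatrix, hub_lfc: float = 0.1, hub_count: int = 100
) -> HubSummary:
    """Count hub knockouts and hub targets among expressed genes.

    A hub KO changes at least ``hub_count`` other genes by |log2FC| >
    ``hub_lfc``; a hub target is so changed by at least ``hub_count``
    knockouts.  Lowly expressed genes are excluded on both axes.
    """
    expressed = effects.expressed_mask
    row_ok = expressed[effects.ko_genes]
    big = np.abs(np.nan_to_num(effects.lfc, nan=0.0)) > hub_lfc
    big &= expressed[None, :]  # expressed targets only
    out_counts = big[row_ok].sum(axis=1)
    n_hub_ko = int((out_counts >= hub_count).sum())
    in_counts = big[row_ok].sum(axis=0)
    n_hub_target = int(((in_counts >= hub_count) & expressed).sum())
    return HubSummary(n_hub_ko, n_hub_target, hub_lfc, hub_count)


def stratify_effects(
    effects: EffectMatrix,
    grn: Grn,
    distances: np.ndarray | None = None,
    include_masked: bool = True,
) -> dict:
    """Stratified |log2FC| distributions over (perturbed, target) pairs.

    Returns a dict with per-distance samples (integer distances, with
    ``inf`` for unreachable pairs), a within/between-group split, and a
    direct / mediated / null split (direct: distance 1; mediated: finite
    distance > 1; null: no directed path).  ``include_masked=False``
    restricts to pairs where both genes are expressed.
    """
    if distances is None:
        distances = shortest_path_distances(grn, sources=effects.ko_genes)
    offdiag = effects.offdiag_mask()
    if not include_masked:
        offdiag = offdiag & effects.expressed_mask[effects.ko_genes][:, None]
        offdiag = offdiag & effects.expressed_mask[None, :]
    alfc = np.abs(effects.lfc)
    d = distances
    by_distance: dict[float, np.ndarray] = {}
    finite = d[offdiag][np.isfinite(d[offdiag])]
    max_d = int(finite.max()) if finite.size else 0
    for dist in range(1, max_d + 1):
        sel = offdiag & (d == dist)
        if sel.any():
            by_distance[dist] = alfc[sel]
    null_sel = offdiag & np.isinf(d)
    if null_sel.any():
        by_distance[np.inf] = alfc[null_sel]

    same_group = grn.group_of[effects.ko_genes][:, None] == grn.group_of[None, :]
    within = alfc[offdiag & same_group]
    between = alfc[offdiag & ~same_group]

    direct = alfc[offdiag & (d == 1)]
    mediated = alfc[offdiag & (d > 1) & np.isfinite(d)]
    null = alfc[null_sel]
    return {
        "by_distance": by_distance,
        "within_group": within,
        "between_group": between,
        "direct": direct,
        "mediated": mediated,
        "null": null,
    }
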