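"""Matching simulated knockout screens against empirical perturbation data.

A screen (simulated or experimental) is reduced to two per-gene samples: the
fraction of analyzed genes a gene affects when perturbed (outgoing effect
degree) and the fraction of perturbations that affect it (incoming effect
degree).  Experimental significance calls use FDR-corrected p-values at a
fixed cutoff; simulated |log2FC| values are thresholded so that the overall
discovery rate matches the experimental one (3.16% by default), which puts
both data sources on a common footing despite imperfect statistical power in
experiments.  Two-sample Kolmogorov-Smirnov tests on the outgoing and
incoming samples then rank candidate networks by similarity to the data.

Also here: the regression of logit hub fractions on generator parameters, and
the master-regulator p-value reweighting p'_ij = p_ij / n_i used to bias pair
rankings toward putative master regulators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import ks_2samp

from .netgen import GeneratorParams
from .perturb import EffectMatrix

__all__ = [
    "EffectDegreeDistribution",
    "EmpiricalEffects",
    "RegressionResult",
    "effect_degrees",
    "empirical_effect_degrees",
    "ks_match",
    "rank_networks",
    "fit_param_regression",
    "reweight_pvalues",
]


@dataclass
class EffectDegreeDistribution:
    """Per-gene incoming/outgoing significant-effect fractions.

    Fractions are normalized by ``n_analyzed``, the number of
    non-lowly-expressed genes included in the analysis, so that screens with
    different numbers of analyzed genes are comparable.
    """

    outgoing: np.ndarray
    incoming: np.ndarray
    n_analyzed: int
    threshold: float

    @property
    def discovery_rate(self) -> float:
        """Overall fraction of analyzed ordered pairs called significant."""
        total = self.n_analyzed * (self.n_analyzed - 1)
        if total == 0:
            return float("nan")
        return float(self.outgoing.sum() * self.n_analyzed / total)


def effect_degrees(
    effects: EffectMatrix, discovery_rate: float = 0.0316
) -> EffectDegreeDistribution:
    """Threshold |log2FC| at a fixed discovery rate and compute effect degrees.

    The cutoff k is the (1 - discovery_rate) quantile of off-diagonal |log2FC|
    over expressed-by-expressed pairs; pairs strictly above k are significant
    (ties at the quantile are not called, so the realized rate can fall one
    pair short).  Requires a full screen over the expressed genes.
    """
    expressed = effects.expressed_mask
    row_ok = expressed[effects.ko_genes]
    sub = effects.lfc[np.ix_(row_ok, expressed)]
    kos = effects.ko_genes[row_ok]
    alfc = np.abs(sub)
    offdiag = ~np.isnan(sub)
    vals = alfc[offdiag]
    if vals.size == 0:
        raise ValueError("no analyzable pairs (all genes lowly expressed?)")
    if np.allclose(vals, vals[0]):
        raise ValueError("degenerate effect matrix: all |log2FC| equal")
    k = float(np.quantile(vals, 1.0 - discovery_rate))
    sig = (alfc > k) & offdiag
    n_analyzed = int(expressed.sum())
    outgoing = sig.sum(axis=1) / n_analyzed
    incoming = sig.sum(axis=0) / n_analyzed
    if len(kos) != n_analyzed:
        # partial screens still yield valid per-row outgoing fractions, but
        # incoming fractions would be on a different scale; normalize by rows
        incoming = sig.sum(axis=0) / max(len(kos), 1)
    return EffectDegreeDistribution(
        outgoing=np.asarray(outgoing, dtype=float),
        incoming=np.asarray(incoming, dtype=float),
        n_analyzed=n_analyzed,
        threshold=k,
    )


@dataclass
class EmpiricalEffects:
    """Perturbation x gene matrix of FDR-corrected p-values.

    ``table`` rows are perturbations, columns measured genes, both labeled by
    identifier.  The reader accepts delimited text (gzip transparently) with
    a header row of gene identifiers and one labeled row per perturbation.
    """

    table: pd.DataFrame
    cutoff: float = 0.05

    @classmethod
    def read_csv(cls, path: str | Path, cutoff: float = 0.05, sep: str = ",") -> "EmpiricalEffects":
        df = pd.read_csv(path, sep=sep, index_col=0)
        return cls(table=df, cutoff=cutoff)

    def aligned(self) -> pd.DataFrame:
        """Subset to perturbations that are also measured, in matching order."""
        common = [g for g in self.table.index if g in set(self.table.columns)]
        if not common:
            raise ValueError("no perturbation identifiers match measured gene identifiers")
        return self.table.loc[common, common]


def empirical_effect_degrees(
    emp: EmpiricalEffects, cutoff: float | None = None
) -> EffectDegreeDistribution:
    """Per-gene significant-effect fractions from an empirical p-value table."""
    if cutoff is None:
        cutoff = emp.cutoff
    sub = emp.aligned()
    P = sub.to_numpy(dtype=float)
    np.fill_diagonal(P, np.nan)
    sig = P < cutoff
    n = P.shape[0]
    outgoing = sig.sum(axis=1) / n
    incoming = sig.sum(axis=0) / n
    return EffectDegreeDistribution(
        outgoing=outgoing.astype(float),
        incoming=incoming.astype(float),
        n_analyzed=n,
        threshold=cutoff,
    )


def ks_match(
    synth: EffectDegreeDistribution, emp: EffectDegreeDistribution
) -> tuple[float, float, float, float]:
    """Two-sample KS comparison of outgoing and incoming effect degrees.

    Returns (stat_out, p_out, stat_in, p_in).
    """
    r_out = ks_2samp(synth.outgoing, emp.outgoing)
    r_in = ks_2samp(synth.incoming, emp.incoming)
    return (
        float(r_out.statistic),
        float(r_out.pvalue),
        float(r_in.statistic),
        float(r_in.pvalue),
    )


@dataclass
class NetworkRanking:
    """Ranking of candidate networks by similarity to the data.

    ``by_rank_sum``: network indices ordered by the sum of their per-
    distribution p-value ranks (rank 1 = largest KS p-value; best first).
    ``top_by_joint``: the ``top_k`` networks found at the smallest rank r such
    that ``top_k`` networks are in the top r for both distributions.
    ``joint_rank_r``: that smallest r.
    """

    by_rank_sum: list[int]
    top_by_joint: list[int]
    joint_rank_r: int


def rank_networks(results: list[tuple[float, float, float, float]], top_k: int = 1) -> NetworkRanking:
    """Rank networks from their (stat_out, p_out, stat_in, p_in) KS results.

    Both ranking modes are computed; ties are broken by summed rank, then by
    network index.
    """
    if not results:
        raise ValueError("need at least one network")
    arr = np.asarray(results, dtype=float)
    p_out, p_in = arr[:, 1], arr[:, 3]
    # rank 1 = largest p-value (closest match)
    rank_out = np.argsort(np.argsort(-p_out)) + 1
    rank_in = np.argsort(np.argsort(-p_in)) + 1
    ranksum = rank_out + rank_in
    order = sorted(range(len(arr)), key=lambda i: (ranksum[i], i))

    top_k = min(top_k, len(arr))
    r = top_k
    while True:
        joint = [i for i in range(len(arr)) if rank_out[i] <= r and rank_in[i] <= r]
        if len(joint) >= top_k:
            joint.sort(key=lambda i: (ranksum[i], i))
            return NetworkRanking(
                by_rank_sum=order, top_by_joint=joint[:top_k], joint_rank_r=r
            )
        r += 1


@dataclass
class RegressionResult:
    """OLS fit of logit hub fractions on the generator parameters."""

    params: pd.Series
    pvalues: pd.Series
    r_squared: float
    response: str
    model: object = field(repr=False, default=None)


def fit_param_regression(
    gen_params: list[GeneratorParams],
    fractions: np.ndarray,
    response: str = "hub_ko_fraction",
) -> RegressionResult:
    """Regress logit(fraction) on 1/p, k', w, delta_in, delta_out.

    ``fractions`` holds the per-network fraction of genes that are hub
    knockouts (or hub targets).  Covariates enter on their natural scales;
    k' recodes k = 1 as k = n (a single group and one-group-per-gene are the
    same dissolution of modular structure).  Boundary fractions are nudged to
    1/(2n) and 1 - 1/(2n) before the logit.
    """
    fractions = np.asarray(fractions, dtype=float)
    if len(gen_params) != len(fractions):
        raise ValueError("one fraction per parameter set required")
    n_genes = gen_params[0].n
    lo, hi = 1.0 / (2 * n_genes), 1.0 - 1.0 / (2 * n_genes)
    frac = np.clip(fractions, lo, hi)
    y = np.log(frac / (1.0 - frac))
    X = pd.DataFrame(
        {
            "inv_p": [1.0 / gp.p for gp in gen_params],
            "k_prime": [gp.n if gp.k == 1 else gp.k for gp in gen_params],
            "w": [gp.w for gp in gen_params],
            "delta_in": [gp.delta_in for gp in gen_params],
            "delta_out": [gp.delta_out for gp in gen_params],
        }
    )
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design: vary every generator parameter")
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        params=fit.params,
        pvalues=fit.pvalues,
        r_squared=float(fit.rsquared),
        response=response,
        model=fit,
    )


def reweight_pvalues(
    emp: EmpiricalEffects,
    truth_pairs: list[tuple[str, str]] | None = None,
    directed: bool = True,
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Rank perturbation-target pairs by raw p and master-regulator-scaled p'.

    p'_ij = p_ij / n_i where n_i counts the genome-wide significant outgoing
    effects of perturbation i; the scaling promotes pairs whose perturbation
    is a putative master regulator.  Perturbations with n_i = 0 are excluded.
    Only pairs significant at the genome-wide FDR cutoff are evaluated against
    ``truth_pairs`` (the ``in_truth`` column; undirected truth matches either
    orientation).
    """
    P = emp.table
    sig = P.to_numpy(dtype=float) < fdr_cutoff
    n_i = sig.sum(axis=1)
    keep_rows = n_i > 0
    rows = []
    pert_ids = P.index.to_numpy()
    gene_ids = P.columns.to_numpy()
    truth = set()
    if truth_pairs is not None:
        for a, b in truth_pairs:
            truth.add((a, b))
            if not directed:
                truth.add((b, a))
    for r in np.where(keep_rows)[0]:
        cols = np.where(sig[r])[0]
        for c in cols:
            i, j = pert_ids[r], gene_ids[c]
            if i == j:
                continue
            p = float(P.iat[r, c])
            rows.append(
                {
                    "perturbed": i,
                    "target": j,
                    "p": p,
                    "p_prime": p / n_i[r],
                    "in_truth": (i, j) in truth if truth_pairs is not None else np.nan,
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        df["rank_p"] = df["p"].rank(method="first").astype(int)
        df["rank_p_prime"] = df["p_prime"].rank(method="first").astype(int)
        df = df.sort_values("rank_p_prime", ignore_index=True)
    return df
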