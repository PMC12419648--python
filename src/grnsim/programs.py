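"""Gene programs from truncated SVD of cell-by-gene expression.

Each gene is z-normalized across cells, the top ``n_components`` singular
vectors are computed, and every component defines a "program": the
``program_size`` genes with the largest squared loadings on that component.
Programs from two datasets are compared by maximum intersection size, and
their loading spaces by canonical correlation — the singular values of
V^T V', which for orthonormal loading matrices lie in [0, 1] and measure the
alignment of the two low-rank representations irrespective of rotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import svdvals
from sklearn.decomposition import TruncatedSVD

from .cells import CellMatrix

__all__ = ["ProgramSet", "compute_programs", "program_overlap", "canonical_correlations"]


@dataclass
class ProgramSet:
    """Orthonormal gene loadings, singular values, and derived programs."""

    gene_loadings: np.ndarray  # genes x n_components, orthonormal columns
    singular_values: np.ndarray
    programs: list[np.ndarray]  # per component, sorted gene-id arrays
    program_size: int

    @property
    def n_components(self) -> int:
        return self.gene_loadings.shape[1]

    def validate(self) -> None:
        V = self.gene_loadings
        g = V.T @ V
        if not np.allclose(g, np.eye(V.shape[1]), atol=1e-6):
            raise ValueError("gene loading columns are not orthonormal")
        for p in self.programs:
            if len(np.unique(p)) != self.program_size:
                raise ValueError("each program must have program_size distinct genes")

    def write_programs_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for p in self.programs:
                fh.write("\t".join(str(int(g)) for g in p) + "\n")


def compute_programs(
    cells: CellMatrix | np.ndarray,
    n_components: int = 200,
    program_size: int = 200,
    random_state: int = 0,
) -> ProgramSet:
    """z-normalize genes, run truncated SVD, and derive gene programs.

    Zero-variance genes contribute all-zero columns and can never enter a
    program.  Ties at the program-size boundary break toward the lower gene
    id.  The randomized solver is seeded for reproducibility; programs are
    insensitive to the sign ambiguity of singular vectors since membership
    depends on squared loadings.
    """
    X = cells.values if isinstance(cells, CellMatrix) else np.asarray(cells, dtype=float)
    m, n = X.shape
    if m < 2:
        raise ValueError("need at least two cells")
    if n < program_size:
        raise ValueError(f"need at least program_size={program_size} genes, got {n}")
    if m < n_components:
        raise ValueError("need at least n_components cells")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    # constant columns can carry tiny rounding-induced deviations
    zero = sd <= 1e-12 * np.maximum(1.0, np.abs(mu))
    Z = (X - mu) / np.where(zero, 1.0, sd)
    Z[:, zero] = 0.0

    svd = TruncatedSVD(n_components=n_components, random_state=random_state)
    svd.fit(Z)
    V = svd.components_.T  # genes x k
    # zero-variance genes carry no signal; the randomized solver can leave
    # them with small spurious loadings, so force them out explicitly
    V[zero, :] = 0.0
    # re-orthonormalize: randomized TSVD columns are orthonormal to solver
    # tolerance already; clean up residual drift for the CCA contract
    # (QR column operations preserve the zeroed rows)
    q, r = np.linalg.qr(V)
    V = q * np.sign(np.diag(r))

    programs = []
    ids = np.arange(n)
    for c in range(n_components):
        sq = V[:, c] ** 2
        # sort by (-squared loading, gene id): lower id wins ties
        order = np.lexsort((ids, -sq))
        programs.append(np.sort(order[:program_size]))
    return ProgramSet(
        gene_loadings=V,
        singular_values=svd.singular_values_.copy(),
        programs=programs,
        program_size=program_size,
    )


def program_overlap(ref: ProgramSet, other: ProgramSet) -> np.ndarray:
    """Max intersection of each reference program with any other-set program.

    Returns an array of counts, one per reference program, each in
    [0, program_size].
    """
    other_sets = [set(p.tolist()) for p in other.programs]
    out = np.zeros(len(ref.programs), dtype=np.int64)
    for i, p in enumerate(ref.programs):
        ps = set(p.tolist())
        out[i] = max(len(ps & q) for q in other_sets) if other_sets else 0
    return out


def canonical_correlations(V: np.ndarray, Vprime: np.ndarray) -> np.ndarray:
    """Singular values of V^T V', sorted descending.

    For orthonormal-column inputs these are the canonical correlations
    between the two loading spaces, all in [0, 1]; invariant to orthogonal
    rotation of either input.
    """
    V = np.asarray(V, dtype=float)
    Vprime = np.asarray(Vprime, dtype=float)
    if V.shape != Vprime.shape:
        raise ValueError(f"shape mismatch: {V.shape} vs {Vprime.shape}")
    vals = svdvals(V.T @ Vprime)
    return np.clip(vals, 0.0, 1.0)
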