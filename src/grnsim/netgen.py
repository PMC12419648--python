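"""Directed scale-free network generation with group structure.

Networks grow by preferential attachment: at each step either a new node is
added (becoming the target of one new edge) or a new edge is drawn between
existing nodes.  Targets are chosen with probability proportional to
in-degree plus an additive constant ``delta_in``; sources proportionally to
out-degree plus ``delta_out``.  Each node belongs to one of ``k`` groups, and
the source of every new edge is drawn from the target's own group with
affinity ``w`` (relative to weight 1 for each other group), so the expected
fraction of within-group edges is ``w / (w + k - 1)``.

The five structural knobs:

``p``         node-addition probability; the mean number of regulators per
              gene is approximately ``1/p`` (``r`` denotes ``1/p``).
``k``         number of groups.
``w``         within-group affinity (modularity); ``w = 1`` (or ``k = 1``)
              dissolves group structure.
``delta_in``  in-degree uniformity; larger values flatten the in-degree
              distribution (smaller CV).
``delta_out`` out-degree uniformity, analogously for out-degree.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

__all__ = [
    "GeneratorParams",
    "Grn",
    "DegreeSummary",
    "generate_network",
    "degree_summary",
    "shortest_path_distances",
    "PARAM_GRID",
    "grid_preset",
    "stratified_grid_sample",
]

#: Parameter levels of the full factorial study grid (4 x 5 x 6 x 4 x 4 = 1,920).
PARAM_GRID = {
    "p": (1 / 2, 1 / 4, 1 / 8, 1 / 16),
    "k": (1, 5, 10, 50, 100),
    "w": (1, 9, 40, 90, 400, 900),
    "delta_in": (10, 30, 100, 300),
    "delta_out": (1, 3, 10, 30),
}

# Sentinel reported when a CV is undefined (zero mean degree).
CV_UNDEFINED = float("nan")


@dataclass(frozen=True)
class GeneratorParams:
    """Structural parameters of the network generator."""

    n: int
    p: float
    k: int = 1
    w: float = 1.0
    delta_in: float = 10.0
    delta_out: float = 10.0
    seed: int | None = None

    def validate(self) -> None:
        if not (self.n >= self.k >= 1):
            raise ValueError(f"need n >= k >= 1, got n={self.n}, k={self.k}")
        if not (0 < self.p <= 1):
            raise ValueError(f"p must be in (0, 1], got {self.p}")
        if self.w < 1:
            raise ValueError(f"w must be >= 1, got {self.w}")
        if self.delta_in < 0 or self.delta_out < 0:
            raise ValueError("delta_in and delta_out must be >= 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorParams":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class Grn:
    """A directed network over genes 0..n-1 with a group label per gene.

    Edges are ordered (source, target) pairs: source regulates target.
    """

    n: int
    edges: list[tuple[int, int]]
    group_of: np.ndarray
    params: GeneratorParams | None = field(default=None, repr=False)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def k(self) -> int:
        return int(self.group_of.max()) + 1 if self.n else 0

    def edge_array(self) -> np.ndarray:
        """Edges as an (m, 2) integer array of (source, target)."""
        if not self.edges:
            return np.empty((0, 2), dtype=np.int64)
        return np.asarray(self.edges, dtype=np.int64)

    def adjacency(self) -> sp.csr_matrix:
        """Sparse adjacency A with A[source, target] = 1."""
        e = self.edge_array()
        data = np.ones(len(e))
        return sp.csr_matrix((data, (e[:, 0], e[:, 1])), shape=(self.n, self.n))

    def in_degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=np.int64)
        e = self.edge_array()
        if len(e):
            np.add.at(deg, e[:, 1], 1)
        return deg

    def out_degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=np.int64)
        e = self.edge_array()
        if len(e):
            np.add.at(deg, e[:, 0], 1)
        return deg

    def validate(self) -> None:
        e = self.edge_array()
        if len(e):
            if (e[:, 0] == e[:, 1]).any():
                raise ValueError("self-loop present")
            if len({(int(a), int(b)) for a, b in e}) != len(e):
                raise ValueError("duplicate directed edge present")
            if e.min() < 0 or e.max() >= self.n:
                raise ValueError("edge endpoint out of range")
        if len(self.group_of) != self.n:
            raise ValueError("every node needs a group label")

    # -- plain-text round trip -------------------------------------------------
    def write_tsv(self, edges_path: str | Path, groups_path: str | Path) -> None:
        with open(edges_path, "w") as fh:
            fh.write("source\ttarget\n")
            for s, t in self.edges:
                fh.write(f"{s}\t{t}\n")
        with open(groups_path, "w") as fh:
            fh.write("node\tgroup\n")
            for i, g in enumerate(self.group_of):
                fh.write(f"{i}\t{g}\n")

    @classmethod
    def read_tsv(cls, edges_path: str | Path, groups_path: str | Path) -> "Grn":
        e = np.loadtxt(edges_path, skiprows=1, dtype=np.int64, ndmin=2)
        g = np.loadtxt(groups_path, skiprows=1, dtype=np.int64, ndmin=2)
        order = np.argsort(g[:, 0])
        groups = g[order, 1]
        edges = [(int(a), int(b)) for a, b in e] if e.size else []
        return cls(n=len(groups), edges=edges, group_of=groups)


@dataclass(frozen=True)
class DegreeSummary:
    mean_in: float
    cv_in: float
    cv_out: float
    within_fraction: float


def _cv(deg: np.ndarray) -> float:
    mu = deg.mean()
    if mu == 0:
        return CV_UNDEFINED
    return float(deg.std() / mu)


def degree_summary(grn: Grn) -> DegreeSummary:
    """Mean in-degree, degree CVs, and the within-group edge fraction."""
    if grn.n == 0:
        raise ValueError("empty network")
    din, dout = grn.in_degrees(), grn.out_degrees()
    e = grn.edge_array()
    if len(e):
        within = float(np.mean(grn.group_of[e[:, 0]] == grn.group_of[e[:, 1]]))
    else:
        within = float("nan")
    return DegreeSummary(
        mean_in=float(din.mean()),
        cv_in=_cv(din),
        cv_out=_cv(dout),
        within_fraction=within,
    )


def shortest_path_distances(grn: Grn, sources: np.ndarray | None = None) -> np.ndarray:
    """Directed shortest-path length d(j -> i) along edges.

    Returns a (len(sources), n) float matrix with ``inf`` for unreachable
    pairs; ``sources=None`` uses all nodes (an n x n matrix).
    """
    adj = grn.adjacency()
    kwargs = {} if sources is None else {"indices": np.asarray(sources)}
    d = _csgraph_shortest_path(adj, method="D", directed=True, unweighted=True, **kwargs)
    return np.atleast_2d(d)


class GraphSaturatedError(RuntimeError):
    """Raised when no legal (non-duplicate, non-loop) edge can be drawn."""


def generate_network(params: GeneratorParams, rng: np.random.Generator | None = None) -> Grn:
    """Grow a directed scale-free network with groups.

    The seed graph has one node per group connected in a directed cycle
    (a single isolated node for ``k = 1``).  The growth loop then repeats
    until ``n`` nodes exist: with probability ``p`` a new node is added
    (uniform random group; it becomes the target of one new edge whose
    source is drawn by group-biased out-degree preferential attachment),
    otherwise an edge is added between existing nodes (target by in-degree
    preferential attachment, then source as above, biased toward the
    target's group).  Self-loops and duplicate edges are rejected and
    resampled, up to ``100 * n`` attempts per event.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n, k, w = params.n, params.k, float(params.w)
    din_c, dout_c = float(params.delta_in), float(params.delta_out)

    group_of = np.zeros(n, dtype=np.int64)
    group_of[:k] = np.arange(k)
    in_deg = np.zeros(n, dtype=np.float64)
    out_deg = np.zeros(n, dtype=np.float64)
    edges: list[tuple[int, int]] = []
    edge_set: set[tuple[int, int]] = set()
    preds: list[set[int]] = [set() for _ in range(n)]  # existing sources per target

    def add_edge(src: int, tgt: int) -> None:
        edges.append((src, tgt))
        edge_set.add((src, tgt))
        preds[tgt].add(src)
        out_deg[src] += 1
        in_deg[tgt] += 1

    # seed: directed cycle over one node per group
    n_nodes = k
    if k > 1:
        for i in range(k):
            add_edge(i, (i + 1) % k)

    max_attempts = 100 * n
    group_w = np.empty(k)

    def pick_weighted(weights: np.ndarray) -> int:
        total = weights.sum()
        if total <= 0:
            return -1
        c = np.cumsum(weights)
        return int(np.searchsorted(c, rng.random() * total, side="right"))

    def pick_source(target_group: int, n_cur: int, target: int | None = None) -> int:
        """Group-biased out-degree preferential attachment among existing nodes.

        The partner group is drawn first (weight w for the target's own
        group, 1 for each other), then the node within that group, excluding
        sources that would create a self-loop or a duplicate edge — so
        duplicate avoidance never distorts the within-group edge fraction.
        """
        group_w.fill(1.0)
        group_w[target_group] = w
        grp = pick_weighted(group_w)
        weights = (out_deg[:n_cur] + dout_c) * (group_of[:n_cur] == grp)
        if target is not None:
            weights[target] = 0.0
            if preds[target]:
                weights[list(preds[target])] = 0.0
        return pick_weighted(weights)

    while n_nodes < n:
        # a single-node graph (k = 1 seed) admits no legal edge event
        if rng.random() < params.p or n_nodes < 2:
            # node event: new node is the target of one new edge
            new = n_nodes
            grp = int(rng.integers(k))
            attempts = 0
            while True:
                src = pick_source(grp, n_nodes)
                if src >= 0:
                    break
                attempts += 1
                if attempts > max_attempts:
                    raise GraphSaturatedError("no source with positive weight")
            group_of[new] = grp
            n_nodes += 1
            add_edge(src, new)
        else:
            # edge event between existing nodes; in the early phase of dense
            # growth (small p) the existing graph can be complete, in which
            # case no legal edge exists and the event is skipped
            if len(edge_set) >= n_nodes * (n_nodes - 1):
                continue
            attempts = 0
            while True:
                tgt = pick_weighted(in_deg[:n_nodes] + din_c)
                src = -1 if tgt < 0 else pick_source(int(group_of[tgt]), n_nodes, target=tgt)
                if src >= 0:
                    break
                attempts += 1
                if attempts > max_attempts:
                    raise GraphSaturatedError(
                        f"could not draw a legal edge after {max_attempts} attempts"
                    )
            add_edge(src, tgt)

    grn = Grn(n=n, edges=edges, group_of=group_of, params=params)
    return grn


def grid_preset(n: int = 2000, seed: int = 0) -> list[GeneratorParams]:
    """The full factorial study grid of 1,920 parameter sets.

    Order is the lexicographic product over (p, k, w, delta_in, delta_out)
    levels; each set gets a distinct derived seed.
    """
    out = []
    combos = itertools.product(*PARAM_GRID.values())
    for i, (p, k, w, di, do) in enumerate(combos):
        out.append(
            GeneratorParams(n=n, p=p, k=k, w=w, delta_in=di, delta_out=do, seed=seed + i)
        )
    return out


def stratified_grid_sample(
    n_networks: int = 10, n: int = 2000, seed: int = 0
) -> list[GeneratorParams]:
    """A small deterministic subsample of the study grid.

    Cycles through the sorted levels of each parameter independently so every
    level of every parameter appears at least once for ``n_networks >= 6``
    (the largest number of levels).  Seeds are derived from ``seed``.
    """
    levels = {name: vals for name, vals in PARAM_GRID.items()}
    out = []
    for i in range(n_networks):
        combo = {name: vals[i % len(vals)] for name, vals in levels.items()}
        out.append(GeneratorParams(n=n, seed=seed + i, **combo))
    return out
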