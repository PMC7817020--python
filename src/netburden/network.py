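"""Weighted gene-interaction networks: loading, binarization, normalization,
degree-preserving randomization, and neighbourhood queries.

A :class:`GeneNetwork` is an undirected, weighted graph over gene identifiers
with edge weights in [0, 1] (e.g. posterior interaction probabilities from a
tissue-specific functional network). The propagation operator is derived from
it by :func:`degree_normalize`, which divides each row of the similarity
matrix by the node strength, yielding a row-stochastic matrix.
"""

from __future__ import annotations

import difflib
import gzip
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "GeneNetwork",
    "NormalizedOperator",
    "load_network",
    "write_network",
    "binarize_top_edges",
    "degree_normalize",
    "randomize_preserving_degree",
    "neighbourhood",
]


@dataclass
class GeneNetwork:
    """Undirected weighted gene graph.

    Parameters
    ----------
    genes : ndarray of str
        Unique gene identifiers, fixed order (length M).
    weights : scipy.sparse matrix, shape (M, M)
        Symmetric similarity matrix with entries in [0, 1].
    is_binary : bool
        True once the network has been binarized (weights in {0, 1}).
    allow_self_loops : bool
        If False (default) the diagonal must be zero.
    """

    genes: np.ndarray
    weights: sp.spmatrix
    is_binary: bool = False
    allow_self_loops: bool = False
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        self.genes = np.asarray(self.genes, dtype=object)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers in network")
        self.weights = sp.csr_matrix(self.weights, dtype=float)
        m = len(self.genes)
        if self.weights.shape != (m, m):
            raise ValueError(
                f"weights shape {self.weights.shape} does not match {m} genes"
            )
        if (abs(self.weights - self.weights.T) > 1e-12).nnz:
            raise ValueError("weight matrix must be symmetric")
        data = self.weights.data
        if data.size and (data.min() < 0 or data.max() > 1):
            raise ValueError("edge weights must lie in [0, 1]")
        if self.is_binary and data.size and not np.all(np.isin(data, (0.0, 1.0))):
            raise ValueError("binary network must have weights in {0, 1}")
        if not self.allow_self_loops and self.weights.diagonal().any():
            raise ValueError("self-loops present but allow_self_loops is False")
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        """Number of nonzero undirected edges (self-loops counted once)."""
        off = self.weights.nnz - np.count_nonzero(self.weights.diagonal())
        return off // 2 + np.count_nonzero(self.weights.diagonal())

    def strengths(self) -> np.ndarray:
        """Node strengths (weighted degrees)."""
        return np.asarray(self.weights.sum(axis=1)).ravel()

    def index_of(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            close = difflib.get_close_matches(gene, list(self.genes), n=3)
            raise KeyError(
                f"gene {gene!r} not in network"
                + (f"; close matches: {close}" if close else "")
            ) from None

    def edge_list(self) -> list[tuple[str, str, float]]:
        """Undirected edges as (geneA, geneB, weight), A < B, sorted."""
        coo = sp.triu(self.weights, k=0 if self.allow_self_loops else 1).tocoo()
        edges = [
            (self.genes[i], self.genes[j], w)
            for i, j, w in zip(coo.row, coo.col, coo.data)
        ]
        return sorted(edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.genes)
        g.add_weighted_edges_from(self.edge_list())
        return g


@dataclass
class NormalizedOperator:
    """Row-stochastic propagation operator D.N (D = diag(1/strength)).

    Rows of genes with zero strength (isolated genes) are left all-zero so
    gene indices stay aligned with the burden matrix.
    """

    genes: np.ndarray
    matrix: sp.spmatrix

    def __post_init__(self):
        self.genes = np.asarray(self.genes, dtype=object)
        self.matrix = sp.csr_matrix(self.matrix, dtype=float)
        if self.matrix.data.size and self.matrix.data.min() < 0:
            raise ValueError("operator entries must be nonnegative")
        rowsum = np.asarray(self.matrix.sum(axis=1)).ravel()
        nz = rowsum > 0
        if nz.any() and np.abs(rowsum[nz] - 1.0).max() > 1e-9:
            raise ValueError("nonzero rows of operator must sum to 1")


def _open_maybe_gzip(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def load_network(
    path,
    name_map: dict | None = None,
    allow_self_loops: bool = False,
) -> GeneNetwork:
    """Load a 3-column edge list (geneA, geneB, weight) into a GeneNetwork.

    Lines starting with ``#`` are skipped. If an undirected edge appears more
    than once with different weights, the maximum is kept and a warning is
    logged. ``name_map`` optionally translates identifiers (e.g. Entrez to
    symbol); unmapped identifiers are kept as-is. Gene order is lexicographic.
    """
    edges: dict[tuple[str, str], float] = {}
    n_conflicts = 0
    n_loops_dropped = 0
    with _open_maybe_gzip(path) as fh:
        n_lines = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >=3 columns, got {len(parts)}"
                )
            a, b = parts[0], parts[1]
            try:
                w = float(parts[2])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: weight {parts[2]!r} is not a number"
                ) from None
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"{path}:{lineno}: weight {w} outside [0, 1]")
            if name_map is not None:
                a = name_map.get(a, a)
                b = name_map.get(b, b)
            if a == b and not allow_self_loops:
                n_loops_dropped += 1
                continue
            key = (a, b) if a <= b else (b, a)
            if key in edges:
                if edges[key] != w:
                    n_conflicts += 1
                    edges[key] = max(edges[key], w)
            else:
                edges[key] = w
            n_lines += 1
    if not edges:
        raise ValueError(f"{path}: no edges found")
    if n_conflicts:
        logger.warning(
            "%d duplicate edges with conflicting weights; kept the maximum",
            n_conflicts,
        )
    if n_loops_dropped:
        logger.info("dropped %d self-loop edges", n_loops_dropped)
    genes = np.array(sorted({g for pair in edges for g in pair}), dtype=object)
    index = {g: i for i, g in enumerate(genes)}
    rows, cols, vals = [], [], []
    for (a, b), w in edges.items():
        i, j = index[a], index[b]
        rows.append(i)
        cols.append(j)
        vals.append(w)
        if i != j:
            rows.append(j)
            cols.append(i)
            vals.append(w)
    m = len(genes)
    weights = sp.csr_matrix((vals, (rows, cols)), shape=(m, m))
    return GeneNetwork(genes, weights, allow_self_loops=allow_self_loops)


def write_network(net: GeneNetwork, path) -> None:
    """Write a network as a 3-column edge list (gzipped if path ends .gz)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for a, b, w in net.edge_list():
            fh.write(f"{a}\t{b}\t{w:g}\n")


def binarize_top_edges(net: GeneNetwork, top_pct: float = 1.0) -> GeneNetwork:
    """Keep the top ``top_pct`` percent highest-weight edges as an adjacency.

    Exactly ``k = ceil(top_pct/100 * E)`` edges are retained, where E is the
    number of nonzero undirected edges. Ties at the cut weight are broken by
    lexicographic (geneA, geneB) order so the result is deterministic.
    """
    if net.is_binary:
        raise ValueError("network is already binary")
    if not 0 < top_pct <= 100:
        raise ValueError(f"top_pct must be in (0, 100], got {top_pct}")
    edges = net.edge_list()
    n_keep = int(np.ceil(top_pct / 100.0 * len(edges)))
    # highest weight first; ties resolved by gene-pair lexicographic order
    edges.sort(key=lambda e: (-e[2], e[0], e[1]))
    kept = edges[:n_keep]
    m = net.n_genes
    rows, cols = [], []
    for a, b, _ in kept:
        i, j = net.index_of(a), net.index_of(b)
        rows.append(i)
        cols.append(j)
        if i != j:
            rows.append(j)
            cols.append(i)
    adj = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(m, m), dtype=float
    )
    return GeneNetwork(
        net.genes.copy(), adj, is_binary=True, allow_self_loops=net.allow_self_loops
    )


def degree_normalize(net: GeneNetwork) -> NormalizedOperator:
    """Row-normalize the similarity matrix by node strength.

    Returns the row-stochastic operator D.N where D holds the inverse node
    strengths. Isolated genes (strength 0) keep all-zero rows.
    """
    s = net.strengths()
    inv = np.zeros_like(s)
    nz = s > 0
    inv[nz] = 1.0 / s[nz]
    d = sp.diags(inv)
    return NormalizedOperator(net.genes.copy(), d @ net.weights)


def randomize_preserving_degree(
    net: GeneNetwork, n_swaps: int | None = None, seed: int | None = None
) -> GeneNetwork:
    """Degree-preserving randomization of a binary network via double edge swaps.

    Two edges (a, b), (c, d) are repeatedly rewired to (a, d), (c, b) when
    this creates no self-loop or duplicate edge; every node keeps its exact
    degree. ``n_swaps`` defaults to 10x the edge count (a common mixing
    heuristic). Reproducible given ``seed``.
    """
    if not net.is_binary:
        raise ValueError("degree-preserving randomization expects a binary network")
    if net.n_edges < 2:
        raise ValueError("need at least 2 edges to swap")
    if n_swaps is None:
        n_swaps = 10 * net.n_edges
    if n_swaps < 1:
        raise ValueError("n_swaps must be >= 1")
    g = net.to_networkx()
    try:
        nx.double_edge_swap(g, nswap=n_swaps, max_tries=100 * n_swaps, seed=seed)
    except nx.NetworkXAlgorithmError:
        logger.warning("edge-swap attempt budget exhausted before %d swaps", n_swaps)
    m = net.n_genes
    rows, cols = [], []
    for a, b in g.edges():
        i, j = net.index_of(a), net.index_of(b)
        rows.extend((i, j))
        cols.extend((j, i))
    adj = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(m, m), dtype=float
    )
    return GeneNetwork(
        net.genes.copy(), adj, is_binary=True, allow_self_loops=net.allow_self_loops
    )


def neighbourhood(
    net: GeneNetwork, gene: str, radius: int = 1, include_seed: bool = False
) -> set[str]:
    """Genes within shortest-path distance ``radius`` of ``gene``.

    The seed itself is excluded unless ``include_seed``. Edge weights are
    ignored (hop distance on the nonzero support).
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    net.index_of(gene)  # raises with close matches if unknown
    g = net.to_networkx()
    dist = nx.single_source_shortest_path_length(g, gene, cutoff=radius)
    out = set(dist)
    if not include_seed:
        out.discard(gene)
    return out
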