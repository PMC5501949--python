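"""Weighted gene networks: co-expression aggregation, PPI extension, degrees.

Networks are stored densely (symmetric non-negative weight matrix, zero
diagonal) over an explicit node order.  Co-expression networks are built
from expression matrices by Spearman correlation and rank-standardized to
(0, 1]; aggregates are element-wise means of standardized weights,
re-standardized.  Binary protein-interaction networks are extended to
weighted ones by the inverse shortest-path length up to a hop cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


__all__ = [
    "WeightedGeneNetwork",
    "DegreeProfile",
    "build_coexpression_network",
    "aggregate_networks",
    "extend_ppi",
    "degree_profile",
    "assortativity",
    "read_edge_list",
    "read_expression",
]


@dataclass
class WeightedGeneNetwork:
    """Symmetric non-negative weighted network over named genes.

    ``validate=False`` skips the O(n^2) symmetry check for matrices that
    are symmetric by construction (aggregation, simulation).
    """

    nodes: tuple[str, ...]
    weights: np.ndarray
    validate: bool = True

    def __post_init__(self) -> None:
        self.nodes = tuple(self.nodes)
        w = np.asarray(self.weights)
        if not np.issubdtype(w.dtype, np.floating):
            w = w.astype(float)
        n = len(self.nodes)
        if len(set(self.nodes)) != n:
            raise ValueError("node identifiers must be unique")
        if w.shape != (n, n):
            raise ValueError(f"weight matrix shape {w.shape} != ({n}, {n})")
        if self.validate:
            if not np.allclose(w, w.T, atol=1e-12):
                raise ValueError("weight matrix must be symmetric")
            if (w < 0).any():
                raise ValueError("weights must be non-negative")
        np.fill_diagonal(w, 0.0)
        self.weights = w
        self._index = {g: i for i, g in enumerate(self.nodes)}

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def indices(self, genes: Iterable[str]) -> np.ndarray:
        """Indices of the given genes that are present, in sorted gene order."""
        return np.array(
            [self._index[g] for g in sorted(genes) if g in self._index], dtype=int
        )

    def global_degree(self) -> np.ndarray:
        """Per-node sum of all incident edge weights (row sums)."""
        return self.weights.sum(axis=1)

    def weight(self, a: str, b: str) -> float:
        return float(self.weights[self._index[a], self._index[b]])

    def to_edge_list(self, path) -> None:
        """Write nonzero upper-triangle edges as TSV (geneA, geneB, weight)."""
        iu, ju = np.triu_indices(len(self.nodes), k=1)
        mask = self.weights[iu, ju] > 0
        df = pd.DataFrame(
            {
                "geneA": [self.nodes[i] for i in iu[mask]],
                "geneB": [self.nodes[j] for j in ju[mask]],
                "weight": self.weights[iu[mask], ju[mask]],
            }
        )
        df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class DegreeProfile:
    """Global vs within-set node degrees for the genes of a candidate set."""

    genes: tuple[str, ...]
    global_degree: np.ndarray
    internal_degree: np.ndarray

    def __post_init__(self) -> None:
        if not (self.internal_degree <= self.global_degree + 1e-9).all():
            raise ValueError("internal degree cannot exceed global degree")


def _rank_standardize(values: np.ndarray) -> np.ndarray:
    """Map values to (0, 1] by mid-ranked standardized rank."""
    ranks = stats.rankdata(values, method="average")
    return ranks / len(values)


def _standardize_weights(corr: np.ndarray) -> np.ndarray:
    """Rank-standardize the off-diagonal entries of a symmetric matrix."""
    n = corr.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    std = _rank_standardize(corr[iu, ju])
    out = np.zeros_like(corr)
    out[iu, ju] = std
    out[ju, iu] = std
    return out


def build_coexpression_network(expr: pd.DataFrame) -> WeightedGeneNetwork:
    """Build a co-expression network from a genes x samples expression table.

    Edge weights are Spearman correlations (signed, ties mid-ranked)
    rank-standardized over all gene pairs to (0, 1].  Genes with constant
    expression correlate 0 with everything and so receive the mid rank.
    Requires at least 3 samples and 2 genes; NaN values are rejected.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples to build a co-expression network")
    if expr.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    values = expr.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("expression matrix contains NaN")
    nodes = tuple(expr.index.astype(str))

    ranks = np.apply_along_axis(stats.rankdata, 1, values)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((centered ** 2).sum(axis=1))
    constant = norm == 0
    norm[constant] = 1.0
    corr = (centered / norm[:, None]) @ (centered / norm[:, None]).T
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)
    # round so analytically-equal correlations tie exactly under mid-ranking
    np.round(corr, 12, out=corr)
    return WeightedGeneNetwork(nodes, _standardize_weights(corr))


def aggregate_networks(
    networks: Sequence[WeightedGeneNetwork],
) -> WeightedGeneNetwork:
    """Aggregate rank-standardized networks by element-wise mean, re-ranked.

    All networks must share an identical node list.  The mean weight matrix
    is rank-standardized again so the aggregate is on the same (0, 1] scale.
    """
    if not networks:
        raise ValueError("need at least one network to aggregate")
    nodes = networks[0].nodes
    for net in networks[1:]:
        if net.nodes != nodes:
            raise ValueError("all networks must share an identical node list")
    mean = np.mean([net.weights for net in networks], axis=0)
    return WeightedGeneNetwork(nodes, _standardize_weights(mean))


def extend_ppi(
    binary_edges: Iterable[tuple[str, str]],
    max_hops: int = 6,
) -> WeightedGeneNetwork:
    """Extend a binary interaction network by inverse shortest-path length.

    ``weight(a, b) = 1 / d(a, b)`` where ``d`` is the unweighted shortest
    path length, as long as ``d <= max_hops``; unreachable or farther pairs
    get weight 0.  Direct interactions keep weight 1.  Self-loops are
    dropped; edges are undirected.
    """
    if max_hops < 1:
        raise ValueError("max_hops must be >= 1")
    g = nx.Graph()
    for a, b in binary_edges:
        if a != b:
            g.add_edge(a, b)
    nodes = tuple(sorted(g.nodes))
    index = {v: i for i, v in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)))
    for src, lengths in nx.all_pairs_shortest_path_length(g, cutoff=max_hops):
        i = index[src]
        for dst, d in lengths.items():
            if d > 0:
                w[i, index[dst]] = 1.0 / d
    return WeightedGeneNetwork(nodes, w)


def degree_profile(
    network: WeightedGeneNetwork,
    gene_set: Iterable[str],
) -> DegreeProfile:
    """Global and within-set degrees for the set's genes present in the network."""
    idx = network.indices(gene_set)
    if idx.size == 0:
        raise ValueError("gene set does not intersect the network")
    sub = network.weights[np.ix_(idx, idx)]
    return DegreeProfile(
        genes=tuple(network.nodes[i] for i in idx),
        global_degree=network.weights[idx].sum(axis=1),
        internal_degree=sub.sum(axis=1),
    )


def assortativity(
    network: WeightedGeneNetwork,
    *,
    weighted: bool = False,
) -> float:
    """Degree assortativity: Pearson correlation of edge-endpoint degrees.

    By default the network is binarized at weight > 0 and binary degrees are
    correlated over the symmetrized edge list; with ``weighted=True`` the
    weighted degrees are used instead (edges still enumerated as binary).
    Returns NaN for degenerate inputs (fewer than 2 edges, or zero degree
    variance as in regular graphs).
    """
    adj = network.weights > 0
    iu, ju = np.nonzero(np.triu(adj, k=1))
    if iu.size < 2:
        return float("nan")
    deg = network.global_degree() if weighted else adj.sum(axis=1).astype(float)
    x = np.concatenate([deg[iu], deg[ju]])
    y = np.concatenate([deg[ju], deg[iu]])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def read_edge_list(path) -> WeightedGeneNetwork:
    """Read a TSV edge list (geneA, geneB, weight) into a dense network."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected 3 columns (geneA, geneB, weight)")
    nodes = tuple(sorted(set(df.iloc[:, 0]) | set(df.iloc[:, 1])))
    index = {g: i for i, g in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)))
    for a, b, wt in df.itertuples(index=False):
        i, j = index[a], index[b]
        w[i, j] = w[j, i] = float(wt)
    return WeightedGeneNetwork(nodes, w)


def read_expression(path) -> pd.DataFrame:
    """Read a TSV expression matrix: first column gene id, header = samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df
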