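"""Jaccard similarity of kinase substrate sets, within and between algorithms.

A kinase's "set" is the collection of substrates connected to it at or above
a stringency level. Within one algorithm the pairwise Jaccard matrix is
symmetric and measures discriminability between kinases; between two
algorithms the matrix is non-symmetric (rows from algorithm A, columns from
B) and measures agreement. Significance uses the tabulated critical value
J >= 0.49 for sets of at least 100 elements (p = 0.001); between-algorithm
matrices flag cells in the top 1% of all cells instead. Rank CDFs summarize
whether a kinase's best match in the other algorithm is its namesake, and a
degree-preserving randomizer provides the null expectation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from .stringency import ThresholdedNetwork

logger = logging.getLogger(__name__)

JACCARD_SIGNIFICANCE = 0.49  # critical value at p = 0.001 for N >= 100
MIN_SET_SIZE = 100


def jaccard(set_a: set, set_b: set) -> float:
    """|A ∩ B| / |A ∪ B|; two empty sets score 0 (with a warning)."""
    union = len(set_a | set_b)
    if union == 0:
        logger.warning("Jaccard of two empty sets defined as 0")
        return 0.0
    return len(set_a & set_b) / union


@dataclass
class JaccardMatrix:
    row_kinases: list[str]
    col_kinases: list[str]
    values: np.ndarray
    symmetric: bool
    levels: tuple[str, str]
    row_set_sizes: dict[str, int] = field(default_factory=dict)
    col_set_sizes: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_kinases,
                            columns=self.col_kinases)

    def value(self, row: str, col: str) -> float:
        return float(
            self.values[self.row_kinases.index(row), self.col_kinases.index(col)]
        )


def within_matrix(
    network: ThresholdedNetwork, kinases: list[str] | None = None
) -> JaccardMatrix:
    """Symmetric all-pairs Jaccard matrix of one network's kinase sets."""
    names = kinases if kinases is not None else sorted(network.kinase_sets)
    sets = [network.kinase_sets.get(k, set()) for k in names]
    n = len(names)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            v = jaccard(sets[i], sets[j]) if sets[i] or sets[j] else 0.0
            vals[i, j] = vals[j, i] = v
    sizes = {k: len(s) for k, s in zip(names, sets)}
    return JaccardMatrix(names, list(names), vals, True,
                         (network.level, network.level), sizes, dict(sizes))


def between_matrix(
    net_a: ThresholdedNetwork, net_b: ThresholdedNetwork,
    kinases: list[str] | None = None,
) -> JaccardMatrix:
    """Non-symmetric Jaccard matrix between two algorithms' kinase sets.

    Rows and columns are restricted to the kinases predicted by both
    algorithms (before thresholding); a kinase with an empty set at this
    level keeps its row/column with J = 0.
    """
    if kinases is None:
        kinases = sorted(set(net_a.kinase_sets) & set(net_b.kinase_sets))
    a_sets = [net_a.kinase_sets.get(k, set()) for k in kinases]
    b_sets = [net_b.kinase_sets.get(k, set()) for k in kinases]
    n = len(kinases)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if a_sets[i] or b_sets[j]:
                vals[i, j] = jaccard(a_sets[i], b_sets[j])
    return JaccardMatrix(
        list(kinases), list(kinases), vals, False,
        (net_a.level, net_b.level),
        {k: len(s) for k, s in zip(kinases, a_sets)},
        {k: len(s) for k, s in zip(kinases, b_sets)},
    )


def significant_pairs(
    matrix: JaccardMatrix,
    threshold: float = JACCARD_SIGNIFICANCE,
    min_n: int = MIN_SET_SIZE,
) -> tuple[np.ndarray, dict[str, bool], float]:
    """Flag kinase pairs whose overlap is significant.

    A pair is flagged iff J >= threshold AND both sets hold at least
    ``min_n`` substrates (the tabulated critical value assumes N >= 100);
    smaller sets are untested, never significant. The diagonal is excluded
    for symmetric matrices. Returns (flag matrix, per-kinase any-significant
    flags, fraction of kinases with at least one significant partner).
    """
    v = matrix.values
    flags = v >= threshold
    row_ok = np.array([matrix.row_set_sizes[k] >= min_n for k in matrix.row_kinases])
    col_ok = np.array([matrix.col_set_sizes[k] >= min_n for k in matrix.col_kinases])
    flags &= row_ok[:, None] & col_ok[None, :]
    if matrix.symmetric:
        np.fill_diagonal(flags, False)
    per_kinase = {
        k: bool(flags[i].any() or (matrix.symmetric and flags[:, i].any()))
        for i, k in enumerate(matrix.row_kinases)
    }
    frac = sum(per_kinase.values()) / len(per_kinase) if per_kinase else 0.0
    return flags, per_kinase, frac


def order_matrix(matrix: JaccardMatrix) -> JaccardMatrix:
    """Permute rows/columns by average-linkage clustering on distance 1 - J.

    Symmetric matrices get one leaf order applied to both axes; a
    non-symmetric input is ordered by row-wise clustering only (flagged).
    """
    v = matrix.values
    n = len(matrix.row_kinases)
    if n <= 2:
        return matrix
    if matrix.symmetric:
        d = 1.0 - v
        np.fill_diagonal(d, 0.0)
        order = leaves_list(average(squareform(d, checks=False)))
        names = [matrix.row_kinases[i] for i in order]
        return JaccardMatrix(
            names, list(names), v[np.ix_(order, order)], True, matrix.levels,
            matrix.row_set_sizes, matrix.col_set_sizes,
        )
    logger.warning("non-symmetric matrix: ordering rows only")
    from scipy.spatial.distance import pdist

    order = leaves_list(average(pdist(v)))
    names = [matrix.row_kinases[i] for i in order]
    return JaccardMatrix(
        names, list(matrix.col_kinases), v[order], False, matrix.levels,
        matrix.row_set_sizes, matrix.col_set_sizes,
    )


def overlap_graph(
    matrix: JaccardMatrix, threshold: float = JACCARD_SIGNIFICANCE,
    min_n: int = MIN_SET_SIZE,
) -> nx.Graph:
    """Weighted graph of significantly overlapping kinases (symmetric case)."""
    flags, per_kinase, _ = significant_pairs(matrix, threshold, min_n)
    g = nx.Graph()
    names = matrix.row_kinases
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if flags[i, j]:
                g.add_edge(names[i], names[j], weight=float(matrix.values[i, j]))
    return g


def top_percent_flags(matrix: JaccardMatrix, percent: float = 1.0) -> np.ndarray:
    """Boolean mask of cells in the top ``percent`` % of all cells.

    At least ``ceil(percent% of cells)`` cells are flagged; ties at the
    boundary value are all flagged (deterministic, order-independent).
    """
    v = matrix.values
    n_cells = v.size
    k = max(1, math.ceil(n_cells * percent / 100.0))
    boundary = np.sort(v, axis=None)[::-1][k - 1]
    return v >= boundary


@dataclass
class RankCDF:
    direction: str
    ranks: dict[str, int]
    K: int
    n_candidates: int
    truncated: bool = False

    def cdf(self, k: int) -> float:
        """Fraction of kinases whose self-match rank is <= k."""
        if not self.ranks:
            return 0.0
        return sum(r <= k for r in self.ranks.values()) / len(self.ranks)

    def random_expectation(self, k: int) -> float:
        return min(1.0, k / self.n_candidates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "k": range(1, self.K + 1),
            "cdf": [self.cdf(k) for k in range(1, self.K + 1)],
            "expectation": [self.random_expectation(k)
                            for k in range(1, self.K + 1)],
        })


def rank_cdf(matrix: JaccardMatrix, K: int, direction: str = "") -> RankCDF:
    """Self-match rank CDF of a between-algorithm matrix.

    For each shared kinase, the rank of J(k_A, k_B) among all J(k_A, j_B) in
    its row; rank 1 is the largest value and ties take the worst (maximum)
    rank, which never inflates apparent agreement. The random expectation at
    depth k is k / N_B for N_B candidate kinases in the column algorithm.
    """
    names = matrix.row_kinases
    n_b = len(matrix.col_kinases)
    truncated = n_b < K
    if truncated:
        logger.warning("only %d candidates; CDF truncated below K=%d", n_b, K)
        K = n_b
    ranks = {}
    col_index = {k: j for j, k in enumerate(matrix.col_kinases)}
    for i, k in enumerate(names):
        j = col_index.get(k)
        if j is None:
            continue
        row = matrix.values[i]
        self_val = row[j]
        # worst-rank tie policy: everything >= self counts, including self
        ranks[k] = int((row >= self_val).sum())
    return RankCDF(direction, ranks, K, n_b, truncated)


def randomize_network(
    network: ThresholdedNetwork, seed, method: str = "resample"
) -> ThresholdedNetwork:
    """Degree-aware randomization null for a thresholded network.

    ``resample`` replaces each kinase's substrate set by a uniform sample
    (without replacement, same size) from the network's substrate universe —
    kinase degrees are preserved exactly, substrate degrees are not.
    ``swap`` additionally preserves substrate degrees via repeated
    double-edge swaps on the bipartite edge set.
    """
    rng = np.random.default_rng(seed)
    universe = sorted(network.substrates)
    if method == "resample":
        sets = {}
        for k in sorted(network.kinase_sets):
            size = len(network.kinase_sets[k])
            if size > len(universe):
                raise ValueError(f"set size {size} exceeds universe "
                                 f"{len(universe)} for kinase {k}")
            sets[k] = set(rng.choice(universe, size=size, replace=False))
        return ThresholdedNetwork(network.algorithm_id, network.level, sets)
    if method == "swap":
        edges = sorted(network.edges())
        n = len(edges)
        sets = {k: set(v) for k, v in network.kinase_sets.items()}
        n_swaps, attempts = 0, 0
        while n_swaps < 10 * n and attempts < 100 * n:
            attempts += 1
            i, j = rng.integers(0, n, size=2)
            (k1, s1), (k2, s2) = edges[i], edges[j]
            if k1 == k2 or s1 == s2:
                continue
            if s2 in sets[k1] or s1 in sets[k2]:
                continue
            sets[k1].discard(s1); sets[k1].add(s2)
            sets[k2].discard(s2); sets[k2].add(s1)
            edges[i], edges[j] = (k1, s2), (k2, s1)
            n_swaps += 1
        return ThresholdedNetwork(network.algorithm_id, network.level, sets)
    raise ValueError(f"unknown randomization method {method!r}")


def graph_edge_list(g: nx.Graph) -> pd.DataFrame:
    return pd.DataFrame(
        [(u, v, d["weight"]) for u, v, d in g.edges(data=True)],
        columns=["kinase_a", "kinase_b", "jaccard"],
    )
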