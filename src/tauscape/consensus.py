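"""Tau gradient consensus: order-conserved region sequences across samples.

A *consensus sequence* is a list of regions whose descending order of tau
density is identical in every sample — exactly a common subsequence of the
k per-sample rankings (each a permutation of a shared region set).  The
maximal consensus is found as the longest path in the precedence DAG whose
edge u -> v exists iff u precedes v in *every* sample; since the DAG is a
subgraph of the first sample's total order, a single O(k n^2) dynamic
programming pass over that order suffices.  This is equivalent to the
incremental extension search (grow length-n chains from length n-1 chains).

Significance is assessed empirically: permute every sample's ranking
uniformly at random, record the maximal consensus length, and take the
smallest length whose tail proportion falls below alpha (an empirical
false-discovery threshold).  Retained sequences are assembled into a
directed network whose edge weights are adjacency counts plus one,
normalized to a fixed total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io import TauscapeError, ValidationError, logger
from .regions import RankingSet

__all__ = [
    "ConsensusSequence",
    "NullDistribution",
    "ConsensusGraph",
    "EnumerationCapExceeded",
    "max_consensus",
    "enumerate_sequences",
    "unique_patterns",
    "is_subsequence",
    "permutation_null",
    "build_graph",
    "layout_graph",
]


class EnumerationCapExceeded(TauscapeError):
    """Sequence enumeration aborted: more sequences than the configured cap."""


@dataclass(frozen=True)
class ConsensusSequence:
    """An ordered region list conserved in every sample's ranking."""

    region_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        ids = tuple(int(r) for r in self.region_ids)
        if len(set(ids)) != len(ids):
            raise ValidationError("consensus sequence ids must be distinct")
        object.__setattr__(self, "region_ids", ids)

    def __len__(self) -> int:
        return len(self.region_ids)


# --------------------------------------------------------------------------
# Precedence DAG and longest chain
# --------------------------------------------------------------------------

def _position_matrix(rankings: RankingSet) -> np.ndarray:
    """(k, n) matrix of each region's rank per sample, regions in id order."""
    ids = rankings.region_ids
    index = {r: i for i, r in enumerate(ids)}
    k, n = rankings.k_samples, rankings.n_regions
    pos = np.empty((k, n), dtype=np.int64)
    for s, order in enumerate(rankings.orderings):
        for rank, rid in enumerate(order):
            pos[s, index[rid]] = rank
    return pos


def _chain_dp(pos: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """DP over the first sample's order.

    Returns (order, dp, parent): ``order`` lists region indices sorted by
    the first sample's ranking; ``dp[i]`` is the longest consensus chain
    ending at ``order[i]``; ``parent[i]`` the predecessor position or -1.
    """
    k, n = pos.shape
    order = np.argsort(pos[0], kind="stable")
    q = pos[:, order]                         # (k, n), q[0] = 0..n-1
    # edge j -> i (j before i in every sample); j < i guaranteed via sample 0
    edge = np.ones((n, n), dtype=bool)
    for s in range(1, k):
        edge &= q[s][:, None] < q[s][None, :]
    dp = np.ones(n, dtype=np.int64)
    parent = np.full(n, -1, dtype=np.int64)
    for i in range(1, n):
        preds = np.nonzero(edge[:i, i])[0]
        if preds.size:
            best = preds[np.argmax(dp[preds])]
            dp[i] = dp[best] + 1
            parent[i] = best
    return order, dp, parent


def _max_chain_length(pos: np.ndarray) -> int:
    """Longest common subsequence length of k permutations given as ranks."""
    k, n = pos.shape
    if n == 0:
        return 0
    if k == 1:
        return n
    _, dp, _ = _chain_dp(pos)
    return int(dp.max())


def max_consensus(rankings: RankingSet) -> tuple[int, ConsensusSequence]:
    """Length of the maximal order-conserved sequence plus one witness."""
    pos = _position_matrix(rankings)
    if rankings.k_samples == 0:
        raise ValidationError("at least one sample required")
    order, dp, parent = _chain_dp(pos)
    end = int(np.argmax(dp))
    length = int(dp[end])
    chain = []
    i = end
    while i >= 0:
        chain.append(rankings.region_ids[order[i]])
        i = int(parent[i])
    chain.reverse()
    return length, ConsensusSequence(region_ids=tuple(chain))


# --------------------------------------------------------------------------
# Exhaustive enumeration at a fixed length
# --------------------------------------------------------------------------

def enumerate_sequences(
    rankings: RankingSet, length: int, cap: int = 1_000_000
) -> list[ConsensusSequence]:
    """All consensus sequences of exactly ``length``, lexicographic order.

    Depth-first search over the precedence DAG, pruned by the longest chain
    still reachable from each node.  Aborts with
    :class:`EnumerationCapExceeded` beyond ``cap`` sequences.
    """
    if length < 1:
        raise ValidationError("length must be >= 1")
    pos = _position_matrix(rankings)
    k, n = pos.shape
    order = np.argsort(pos[0], kind="stable")
    q = pos[:, order]
    edge = np.ones((n, n), dtype=bool)
    for s in range(1, k):
        edge &= q[s][:, None] < q[s][None, :]
    np.fill_diagonal(edge, False)
    edge &= np.triu(np.ones((n, n), dtype=bool), 1)
    # longest chain starting at each node, for pruning
    tail = np.ones(n, dtype=np.int64)
    for i in range(n - 2, -1, -1):
        succ = np.nonzero(edge[i, i + 1:])[0]
        if succ.size:
            tail[i] = 1 + tail[i + 1 + succ].max()
    ids = [rankings.region_ids[order[i]] for i in range(n)]
    results: list[tuple[int, ...]] = []
    stack: list[int] = []

    def dfs(i: int, remaining: int) -> None:
        stack.append(ids[i])
        if remaining == 1:
            if len(results) >= cap:
                stack.pop()
                raise EnumerationCapExceeded(f"more than {cap} sequences at length {length}")
            results.append(tuple(stack))
        else:
            for j in np.nonzero(edge[i])[0]:
                if tail[j] >= remaining - 1:
                    dfs(int(j), remaining - 1)
        stack.pop()

    for i in range(n):
        if tail[i] >= length:
            dfs(i, length)
    results.sort()
    return [ConsensusSequence(region_ids=r) for r in results]


def is_subsequence(short: ConsensusSequence, long: ConsensusSequence) -> bool:
    """True if ``short`` appears in order (not necessarily contiguously)."""
    it = iter(long.region_ids)
    return all(x in it for x in short.region_ids)


def unique_patterns(
    rankings: RankingSet,
    max_length: int | None = None,
    min_length: int = 2,
    containment: str = "subsequence",
    cap: int = 1_000_000,
) -> dict[int, list[ConsensusSequence]]:
    """Per-length consensus sequences not contained in longer retained ones.

    Working from the maximal length down to ``min_length``, a sequence is
    retained iff it is not a subsequence of any already-retained longer
    sequence (``containment='exact'`` relaxes this to exact equality, which
    never triggers across different lengths and so retains everything).
    Partially overlapping sequences are kept.
    """
    if containment not in ("subsequence", "exact"):
        raise ValidationError("containment must be 'subsequence' or 'exact'")
    top = max_consensus(rankings)[0]
    if max_length is None:
        max_length = top
    max_length = min(max_length, top)
    retained: dict[int, list[ConsensusSequence]] = {}
    longer: list[ConsensusSequence] = []
    for length in range(max_length, min_length - 1, -1):
        keep = []
        for seq in enumerate_sequences(rankings, length, cap=cap):
            if containment == "subsequence" and any(is_subsequence(seq, w) for w in longer):
                continue
            keep.append(seq)
        retained[length] = keep
        longer.extend(keep)
        logger.info("patterns: length %d -> %d unique sequence(s)", length, len(keep))
    return retained


# --------------------------------------------------------------------------
# Permutation null
# --------------------------------------------------------------------------

@dataclass
class NullDistribution:
    """Empirical null of the maximal consensus length under random rankings.

    ``p_at[L]`` is the raw tail proportion #{replicates with length >= L} /
    n_perm; ``threshold_length`` the smallest L with ``p_at[L] < alpha``.
    """

    n_regions: int
    k_samples: int
    n_perm: int
    alpha: float
    seed: int | None
    max_lengths: np.ndarray
    p_at: dict[int, float] = field(default_factory=dict)
    threshold_length: int | None = None

    def __post_init__(self) -> None:
        lengths = np.asarray(self.max_lengths, dtype=np.int64)
        self.max_lengths = lengths
        if not self.p_at:
            self.p_at = {
                L: float(np.mean(lengths >= L)) for L in range(1, self.n_regions + 1)
            }
        if self.threshold_length is None:
            for L in range(1, self.n_regions + 1):
                if self.p_at[L] < self.alpha:
                    self.threshold_length = L
                    break


def permutation_null(
    n_regions: int,
    k_samples: int,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> NullDistribution:
    """Null distribution of the maximal consensus length.

    Each replicate draws ``k_samples`` independent uniform permutations of
    ``n_regions`` labels and records the longest common subsequence length.
    Permuting the samples' orderings is distribution-equivalent to permuting
    region labels of real rankings, so uniform permutations are drawn
    directly.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if n_regions < 1 or k_samples < 1:
        raise ValidationError("n_regions and k_samples must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = np.empty(n_perm, dtype=np.int64)
    for r in range(n_perm):
        pos = np.stack([rng.permutation(n_regions) for _ in range(k_samples)])
        lengths[r] = _max_chain_length(pos)
    null = NullDistribution(
        n_regions=n_regions,
        k_samples=k_samples,
        n_perm=n_perm,
        alpha=alpha,
        seed=seed,
        max_lengths=lengths,
    )
    logger.info(
        "null: n=%d k=%d perms=%d -> threshold length %s (alpha %.3g)",
        n_regions, k_samples, n_perm, null.threshold_length, alpha,
    )
    return null


# --------------------------------------------------------------------------
# Consensus network graph
# --------------------------------------------------------------------------

@dataclass
class ConsensusGraph:
    """Directed consensus network with weights normalized to a fixed total."""

    graph: nx.DiGraph
    weight_total: float

    @property
    def total_weight(self) -> float:
        return float(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))


def build_graph(
    sequences: list[ConsensusSequence],
    mean_density_ranks: dict[int, int] | None = None,
    weight_total: float = 250.0,
) -> ConsensusGraph:
    """Assemble retained sequences into the consensus network.

    Every ordered adjacent pair within a sequence contributes 1 to its
    edge's adjacency count; the edge weight is count + 1, and all weights
    are rescaled by a common factor so they sum to ``weight_total``.  Node
    attribute ``rank`` carries the region's mean-density rank (descending)
    when supplied.
    """
    if not sequences:
        raise ValidationError("cannot build a graph from an empty sequence list")
    counts: dict[tuple[int, int], int] = {}
    nodes: list[int] = []
    seen = set()
    for seq in sequences:
        for rid in seq.region_ids:
            if rid not in seen:
                seen.add(rid)
                nodes.append(rid)
        for u, v in zip(seq.region_ids, seq.region_ids[1:]):
            counts[(u, v)] = counts.get((u, v), 0) + 1
    pre = {e: c + 1 for e, c in counts.items()}
    scale = weight_total / sum(pre.values())
    g = nx.DiGraph()
    for rid in nodes:
        rank = None if mean_density_ranks is None else mean_density_ranks.get(rid)
        g.add_node(rid, rank=rank)
    for (u, v), w in pre.items():
        g.add_edge(u, v, adjacency=counts[(u, v)], weight=w * scale)
    return ConsensusGraph(graph=g, weight_total=float(weight_total))


def layout_graph(graph: ConsensusGraph, seed: int = 0) -> dict[int, np.ndarray]:
    """Deterministic Fruchterman–Reingold positions (positions only)."""
    if graph.graph.number_of_nodes() == 0:
        return {}
    return nx.spring_layout(graph.graph, seed=seed)
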