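"""Betweenness preference of nodes in a temporal network.

For a node v, every time stamp t where an in-edge (w1, v; t) is immediately
followed by an out-edge (v, w2; t+1) records one traversal (w1, w2).  The
time-aggregated betweenness preference matrix B^v counts these traversals; the
betweenness preference score I^v is the mutual information (in bits) between
the source and destination of the two-step time-respecting paths through v.
I^v = 0 means v routes flows independently of where they came from; I^v > 0
means preferential routing.  A node that is never traversed (sum B^v = 0) is
degenerate and carries no score.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np

from .state_space import GridPartition
from .temporal_graph import TemporalNetwork, aggregate

__all__ = [
    "NodeBetweenness",
    "BetweennessPreferenceResult",
    "betweenness_matrix",
    "betweenness_preference",
    "bp_distribution",
    "bp_spatial_map",
    "mutual_information_bits",
]


def _traversals(gt: TemporalNetwork) -> dict[int, Counter]:
    """Per-node counts of (in-neighbor, out-neighbor) traversal pairs."""
    s = gt.symbols.tolist()
    trav: dict[int, Counter] = defaultdict(Counter)
    for i in range(1, len(s) - 1):
        trav[s[i]][(s[i - 1], s[i + 1])] += 1
    return trav


def mutual_information_bits(counts: np.ndarray, base: float = 2.0) -> float:
    """Mutual information of a non-negative joint count matrix (default bits)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("count matrix is empty")
    p = counts / total
    p1 = p.sum(axis=1)
    p2 = p.sum(axis=0)
    mi = 0.0
    for i, j in zip(*np.nonzero(p)):
        mi += p[i, j] * math.log(p[i, j] / (p1[i] * p2[j]))
    return mi / math.log(base)


@dataclass
class NodeBetweenness:
    """Betweenness preference data for a single node."""

    node: int
    in_labels: list[int]
    out_labels: list[int]
    counts: np.ndarray  # B^v, rows = in-neighbors, cols = out-neighbors
    i_score: float
    total: int  # sum of B^v = number of traversals of the node


@dataclass
class BetweennessPreferenceResult:
    """All per-node scores plus the set of degenerate (never-traversed) nodes."""

    per_node: dict[int, NodeBetweenness]
    degenerate: set[int]

    def scores(self) -> list[tuple[int, float]]:
        return sorted((v, nb.i_score) for v, nb in self.per_node.items())


def betweenness_matrix(
    gt: TemporalNetwork, v: int
) -> tuple[list[int], list[int], np.ndarray]:
    """Time-aggregated betweenness preference matrix B^v.

    Rows/columns are indexed by v's observed in-/out-neighbors in the
    aggregate network G^(0) (so a neighbor whose transition is never part of a
    two-step path still gets a zero row/column).  Returns
    ``(in_labels, out_labels, counts)``.  A never-traversed v yields an
    all-zero matrix (degenerate), not an exception.
    """
    if v not in gt.nodes:
        raise ValueError(f"node {v} does not occur in the temporal network")
    agg = aggregate(gt)
    in_labels = agg.in_neighbors(v)
    out_labels = agg.out_neighbors(v)
    counts = np.zeros((len(in_labels), len(out_labels)), dtype=int)
    row = {u: i for i, u in enumerate(in_labels)}
    col = {w: j for j, w in enumerate(out_labels)}
    for (w1, w2), c in _traversals(gt).get(v, {}).items():
        counts[row[w1], col[w2]] = c
    return in_labels, out_labels, counts


def betweenness_preference(
    gt: TemporalNetwork,
    v: int,
    base: float = 2.0,
    normalized: bool = False,
) -> float:
    """Betweenness preference score I^v in bits (mutual information of B^v).

    ``normalized=True`` divides by min(H(P1), H(P2)); this variant is an
    extra convenience, not part of the reference analysis, and returns 0 for
    deterministic marginals.
    """
    _in, _out, counts = betweenness_matrix(gt, v)
    total = counts.sum()
    if total == 0:
        raise ValueError(f"node {v} is degenerate (never traversed)")
    mi = mutual_information_bits(counts, base=base)
    if not normalized:
        return mi
    p = counts / total
    h1 = -sum(q * math.log(q, base) for q in p.sum(axis=1) if q > 0)
    h2 = -sum(q * math.log(q, base) for q in p.sum(axis=0) if q > 0)
    hmin = min(h1, h2)
    return 0.0 if hmin <= 0 else mi / hmin


def bp_distribution(
    gt: TemporalNetwork, base: float = 2.0
) -> BetweennessPreferenceResult:
    """I^v for every non-degenerate node of the temporal network.

    Nodes with at least one traversal are scored (forced-zero cases such as a
    single in- or out-neighbor simply give I = 0); never-traversed nodes are
    reported in ``degenerate``.
    """
    trav = _traversals(gt)
    agg = aggregate(gt)
    per_node: dict[int, NodeBetweenness] = {}
    degenerate: set[int] = set()
    for v in sorted(gt.nodes):
        pairs = trav.get(v)
        if not pairs:
            degenerate.add(v)
            continue
        in_labels = agg.in_neighbors(v)
        out_labels = agg.out_neighbors(v)
        counts = np.zeros((len(in_labels), len(out_labels)), dtype=int)
        row = {u: i for i, u in enumerate(in_labels)}
        col = {w: j for j, w in enumerate(out_labels)}
        for (w1, w2), c in pairs.items():
            counts[row[w1], col[w2]] = c
        per_node[v] = NodeBetweenness(
            node=v,
            in_labels=in_labels,
            out_labels=out_labels,
            counts=counts,
            i_score=mutual_information_bits(counts, base=base),
            total=int(counts.sum()),
        )
    return BetweennessPreferenceResult(per_node=per_node, degenerate=degenerate)


def bp_spatial_map(
    result: BetweennessPreferenceResult, partition: GridPartition
) -> np.ndarray:
    """Cell-center coordinates and I^v for every scored node.

    Returns an array with one row per non-degenerate node: the m center
    coordinates of the node's cell followed by its score.
    """
    nodes = sorted(result.per_node)
    if nodes and nodes[-1] >= partition.n_cells:
        raise ValueError(
            f"node {nodes[-1]} outside the partition's {partition.n_cells} cells"
        )
    if not nodes:
        return np.empty((0, partition.m + 1))
    centers = partition.cell_center(np.array(nodes))
    scores = np.array([result.per_node[v].i_score for v in nodes])
    return np.column_stack([centers, scores])
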