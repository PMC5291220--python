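"""Temporal network construction and aggregation.

A symbol sequence of length n induces a temporal network G^T with exactly one
time-stamped edge per consecutive sample pair: edge (u, w; t) records the
transition from cell u to cell w at time stamp t (1-based, t = 1..n-1).  The
mapping sequence <-> temporal network is one-to-one.  Time-aggregating the
stamped edges gives the weighted directed null aggregate network G^(0), whose
weight w(u, w) counts how many times the transition u -> w occurred.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .state_space import SymbolSequence

__all__ = [
    "TemporalNetwork",
    "AggregateNetwork",
    "build_temporal_network",
    "aggregate",
    "write_temporal_edges",
    "read_temporal_edges",
]


@dataclass
class TemporalNetwork:
    """A temporal network stored as its underlying symbol sequence.

    The time-stamped edge list is derived on demand: edge t is
    ``(symbols[t-1], symbols[t]; t)`` for t = 1..n-1.
    """

    symbols: np.ndarray

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.int64)
        if self.symbols.size < 2:
            raise ValueError(
                "a temporal network needs at least 2 samples (one transition)"
            )

    @property
    def n(self) -> int:
        return self.symbols.size

    @property
    def n_edges(self) -> int:
        return self.symbols.size - 1

    @property
    def sources(self) -> np.ndarray:
        return self.symbols[:-1]

    @property
    def targets(self) -> np.ndarray:
        return self.symbols[1:]

    @property
    def times(self) -> np.ndarray:
        return np.arange(1, self.symbols.size)

    @property
    def nodes(self) -> set[int]:
        return set(int(s) for s in np.unique(self.symbols))

    def edges(self) -> Iterator[tuple[int, int, int]]:
        """Yield time-stamped edges ``(u, w, t)`` in temporal order."""
        s = self.symbols
        for t in range(1, s.size):
            yield int(s[t - 1]), int(s[t]), t


@dataclass
class AggregateNetwork:
    """The null aggregate network G^(0): weighted directed transition counts."""

    weights: dict[tuple[int, int], int]
    nodes: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.nodes:
            for u, w in self.weights:
                self.nodes.add(u)
                self.nodes.add(w)

    @property
    def total_weight(self) -> int:
        return sum(self.weights.values())

    def weight(self, u: int, w: int) -> int:
        return self.weights.get((u, w), 0)

    def out_neighbors(self, v: int) -> list[int]:
        return sorted(w for (u, w) in self.weights if u == v)

    def in_neighbors(self, v: int) -> list[int]:
        return sorted(u for (u, w) in self.weights if w == v)


def build_temporal_network(
    symbols: SymbolSequence | np.ndarray,
    collapse_repeats: bool = False,
) -> TemporalNetwork:
    """Build G^T from a symbol sequence.

    Consecutive identical symbols produce self time-stamped edges (one
    transition happens at every sample step).  ``collapse_repeats`` instead
    removes consecutive duplicates before construction — useful for flow data
    sampled faster than the typical cell-crossing time.
    """
    s = symbols.symbols if isinstance(symbols, SymbolSequence) else np.asarray(symbols)
    s = np.asarray(s, dtype=np.int64)
    if collapse_repeats and s.size:
        keep = np.concatenate(([True], s[1:] != s[:-1]))
        s = s[keep]
    return TemporalNetwork(s)


def aggregate(gt: TemporalNetwork) -> AggregateNetwork:
    """Time-aggregate G^T into the weighted directed network G^(0)."""
    pairs = Counter(zip(gt.sources.tolist(), gt.targets.tolist()))
    return AggregateNetwork(dict(pairs), nodes=gt.nodes)


def write_temporal_edges(gt: TemporalNetwork, path) -> None:
    """Write the time-stamped edge list as TSV (``source  target  time``)."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\ttime\n")
        for u, w, t in gt.edges():
            fh.write(f"{u}\t{w}\t{t}\n")


def read_temporal_edges(path) -> TemporalNetwork:
    """Read a TSV time-stamped edge list back into a temporal network.

    The file must contain the consecutive transitions of a single symbol
    sequence: timestamps 1..n-1 in order, with each edge's source equal to the
    previous edge's target (this is what makes the mapping invertible).
    Malformed rows raise with their line number.
    """
    symbols: list[int] = []
    expected_t = 1
    with open(path) as fh:
        header = fh.readline()
        if header.strip().split("\t") != ["source", "target", "time"]:
            raise ValueError(f"{path}: line 1: expected header 'source\\ttarget\\ttime'")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 tab-separated fields")
            try:
                u, w, t = (int(p) for p in parts)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer field") from exc
            if t != expected_t:
                raise ValueError(
                    f"{path}: line {lineno}: expected timestamp {expected_t}, got {t}"
                )
            if not symbols:
                symbols.append(u)
            elif symbols[-1] != u:
                raise ValueError(
                    f"{path}: line {lineno}: source {u} does not chain onto previous "
                    f"target {symbols[-1]}"
                )
            symbols.append(w)
            expected_t += 1
    if len(symbols) < 2:
        raise ValueError(f"{path}: no edges found")
    return TemporalNetwork(np.array(symbols, dtype=np.int64))
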