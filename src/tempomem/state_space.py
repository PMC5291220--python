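"""Phase-space handling: delay embedding, grid partitioning, symbolization.

A trajectory in m-dimensional phase space is coarse-grained by an axis-aligned
grid of equal-size cells; each sample is replaced by the index of the cell it
falls in, producing the symbol sequence from which temporal networks are built.
Cells are half-open ``[low, high)`` with a closed top edge so the maximal point
is never lost.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .signal_models import TimeSeries

__all__ = [
    "PhaseTrajectory",
    "GridPartition",
    "SymbolSequence",
    "trajectory_from_series",
    "delay_embed",
    "nonlinear_transform",
    "fit_grid",
    "fit_grid_occupancy",
    "symbolize",
]

log = logging.getLogger(__name__)


@dataclass
class PhaseTrajectory:
    """An ordered sequence of m-dimensional phase-space points."""

    points: np.ndarray  # (n, m)
    source: str = "raw"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2:
            raise ValueError("points must be a 2-D array (n samples x m dims)")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("trajectory contains non-finite coordinates")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def m(self) -> int:
        return self.points.shape[1]


def trajectory_from_series(series: TimeSeries | np.ndarray) -> PhaseTrajectory:
    """Interpret a time series as a native phase-space trajectory.

    Scalar series become 1-D trajectories; vector series keep their
    coordinates (the original phase-space points of the generating system).
    """
    values = series.values if isinstance(series, TimeSeries) else np.asarray(series, float)
    if values.ndim == 1:
        values = values[:, None]
    return PhaseTrajectory(values, source="raw")


def delay_embed(
    series: TimeSeries | np.ndarray, m: int, l: int = 1
) -> PhaseTrajectory:
    """Takens delay embedding of a scalar series.

    Point i is ``(s_i, s_{i+l}, ..., s_{i+(m-1)l})``; the embedded trajectory
    has ``n - (m-1) l`` points.  ``m = 1`` is the identity mapping to 1-D
    points.
    """
    values = series.values if isinstance(series, TimeSeries) else np.asarray(series, float)
    if values.ndim != 1:
        raise ValueError("delay embedding applies to scalar series")
    if m < 1:
        raise ValueError("embedding dimension m must be >= 1")
    if m > 1 and l < 1:
        raise ValueError("delay l must be >= 1")
    n_pts = values.size - (m - 1) * l
    if n_pts < 1:
        raise ValueError(
            f"series too short for embedding: need at least {(m - 1) * l + 1} "
            f"samples, got {values.size}"
        )
    points = np.column_stack([values[j * l : j * l + n_pts] for j in range(m)])
    return PhaseTrajectory(points, source=f"embedded(m={m},l={l})")


def nonlinear_transform(traj: PhaseTrajectory, kind: str) -> PhaseTrajectory:
    """Apply a componentwise strictly monotone polynomial map.

    ``quadratic`` maps x -> x|x| (a sign-preserving square) and ``cubic`` maps
    x -> x^3.  Both are injective, so distinct points stay distinct; they are
    used to probe invariance of the memory exponent under smooth phase-space
    deformations.
    """
    if kind == "quadratic":
        pts = traj.points * np.abs(traj.points)
    elif kind == "cubic":
        pts = traj.points**3
    else:
        raise ValueError(f"unknown transform kind {kind!r}")
    return PhaseTrajectory(pts, source=f"transformed({kind})")


@dataclass
class GridPartition:
    """An axis-aligned grid of equal-size cells over a bounding box.

    Cell indices are flattened row-major over dimensions; cells are half-open
    with the top edge of each dimension closed.
    """

    lows: np.ndarray
    highs: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.lows = np.asarray(self.lows, dtype=float)
        self.highs = np.asarray(self.highs, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if not (self.lows.shape == self.highs.shape == self.counts.shape):
            raise ValueError("lows, highs and counts must have matching shapes")
        if np.any(self.counts < 1):
            raise ValueError("every dimension needs at least one cell")
        if np.any(self.highs <= self.lows):
            raise ValueError("highs must exceed lows in every dimension")

    @property
    def m(self) -> int:
        return self.lows.size

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.counts))

    @property
    def widths(self) -> np.ndarray:
        return (self.highs - self.lows) / self.counts

    def cell_of(self, points: np.ndarray) -> np.ndarray:
        """Flattened cell index of each point; raises if any point is outside."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.shape[1] != self.m:
            raise ValueError(
                f"point dimension {pts.shape[1]} does not match partition dimension {self.m}"
            )
        if np.any(pts < self.lows) or np.any(pts > self.highs):
            bad = int(np.argmax(np.any((pts < self.lows) | (pts > self.highs), axis=1)))
            raise ValueError(f"point {bad} lies outside the partition bounds")
        idx = np.floor((pts - self.lows) / self.widths).astype(int)
        np.clip(idx, 0, self.counts - 1, out=idx)  # closed top edge
        return np.ravel_multi_index(idx.T, self.counts)

    def cell_center(self, cells: np.ndarray | int) -> np.ndarray:
        """Coordinates of the center of each (flattened) cell index."""
        cells = np.atleast_1d(np.asarray(cells, dtype=int))
        multi = np.column_stack(np.unravel_index(cells, self.counts))
        return self.lows + (multi + 0.5) * self.widths

    def to_dict(self) -> dict:
        return {
            "lows": self.lows.tolist(),
            "highs": self.highs.tolist(),
            "counts": self.counts.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridPartition":
        return cls(np.array(d["lows"]), np.array(d["highs"]), np.array(d["counts"]))

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load_json(cls, path) -> "GridPartition":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SymbolSequence:
    """The cell-index sequence of a coarse-grained trajectory."""

    symbols: np.ndarray
    partition: GridPartition | None = None

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.int64)
        if self.symbols.ndim != 1:
            raise ValueError("symbols must be a flat sequence")
        if self.partition is not None and self.symbols.size:
            if self.symbols.min() < 0 or self.symbols.max() >= self.partition.n_cells:
                raise ValueError("symbol outside the partition's cell range")

    @property
    def n(self) -> int:
        return self.symbols.size

    @property
    def alphabet(self) -> set[int]:
        return set(int(s) for s in np.unique(self.symbols))


def fit_grid(
    traj: PhaseTrajectory,
    n_cells_total: int | None = None,
    per_dim: tuple[int, ...] | None = None,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> GridPartition:
    """Fit an equal-size grid partition to a trajectory.

    Exactly one of ``n_cells_total`` or ``per_dim`` must be given.  With a
    total N, each dimension gets ``k = round(N^(1/m))`` cells and the
    effective cell count ``k^m`` is logged (exact for square numbers in 2-D).
    Bounds default to the componentwise data min/max expanded by 1e-9 of the
    range; an explicit ``bounds`` override supports reproducible partitions
    across noise realisations.
    """
    if (n_cells_total is None) == (per_dim is None):
        raise ValueError("give exactly one of n_cells_total or per_dim")
    m = traj.m
    if per_dim is not None:
        if len(per_dim) != m:
            raise ValueError(f"per_dim has {len(per_dim)} entries for a {m}-D trajectory")
        counts = np.asarray(per_dim, dtype=int)
    else:
        k = max(1, round(n_cells_total ** (1.0 / m)))
        counts = np.full(m, k, dtype=int)
        if k**m != n_cells_total:
            log.info(
                "requested %d cells in %d-D: using %d per dimension (effective N = %d)",
                n_cells_total, m, k, k**m,
            )
    if bounds is not None:
        lows = np.asarray(bounds[0], dtype=float)
        highs = np.asarray(bounds[1], dtype=float)
    else:
        lows = traj.points.min(axis=0)
        highs = traj.points.max(axis=0)
        span = highs - lows
        flat = np.nonzero(span <= 0)[0]
        if flat.size:
            raise ValueError(
                f"trajectory is degenerate (constant) in dimension {int(flat[0])}"
            )
        lows = lows - 1e-9 * span
        highs = highs + 1e-9 * span
    return GridPartition(lows, highs, counts)


def fit_grid_occupancy(
    traj: PhaseTrajectory,
    n_occupied: int,
    k_max: int = 4096,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> GridPartition:
    """Fit a grid whose resolution makes the trajectory occupy ~``n_occupied`` cells.

    The partition cell count N is read as the number of distinguishable states
    of the attractor: a bounding-box grid over a thin (fractal) attractor
    leaves most cells empty, so the per-dimension resolution ``k`` is found by
    bisection such that the number of *visited* cells is closest to
    ``n_occupied``.  For a space-filling 1-D trajectory this reduces to a
    plain ``n_occupied``-cell grid.  If even ``k_max`` cells per dimension
    cannot reach the target (e.g. a periodic orbit visiting a fixed handful of
    cells), the ``k_max`` grid is returned and the shortfall logged.
    """
    if n_occupied < 1:
        raise ValueError("n_occupied must be positive")

    def occupied(k: int) -> tuple[int, GridPartition]:
        part = fit_grid(traj, per_dim=(k,) * traj.m, bounds=bounds)
        return np.unique(part.cell_of(traj.points)).size, part

    lo, hi = 1, k_max
    n_hi, part_hi = occupied(hi)
    if n_hi < n_occupied:
        log.info(
            "occupancy target %d unreachable: %d cells occupied at resolution %d "
            "per dimension (orbit visits too few distinct states)",
            n_occupied, n_hi, k_max,
        )
        return part_hi
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if occupied(mid)[0] < n_occupied:
            lo = mid
        else:
            hi = mid
    n_lo, part_lo = occupied(lo)
    n_hi, part_hi = occupied(hi)
    return part_lo if abs(n_lo - n_occupied) <= abs(n_hi - n_occupied) else part_hi


def symbolize(traj: PhaseTrajectory, part: GridPartition) -> SymbolSequence:
    """Map every trajectory point to its cell index."""
    if traj.m != part.m:
        raise ValueError(
            f"trajectory dimension {traj.m} does not match partition dimension {part.m}"
        )
    return SymbolSequence(part.cell_of(traj.points), partition=part)
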