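"""Memory entropy analysis of temporal networks.

The consecutive memory network G^(tau) lifts the aggregate network to path
states: its nodes are the tau-step paths of G^(0) observed in G^T (windows of
tau+1 consecutive cells of the symbol sequence), and its weighted edges count
how often one path is continued by another.  The entropy growth rate H(tau) is
the conditional entropy (in nats) of the next jump given the current path
state, weighted by the empirical stationary distribution.  For chaotic signals
H(tau) decays approximately exponentially, H(tau) ~ exp(-rho * tau); the decay
rate rho is the memory exponent and tracks the largest Lyapunov exponent.

Two edge constructions are available:

* ``overlapping`` (default): an edge joins path a to path b when b is the
  one-step shift of a, with weight the number of (tau+2)-cell windows that
  realise the continuation.  This is the higher-order (memory) network
  construction; H(tau) then equals the conditional block entropy of the
  symbol sequence exactly.
* ``concatenated``: an edge joins two disjoint consecutive (tau+1)-cell
  windows (a path of 2*tau+1 edges in G^(0)), an alternative literal reading
  of the path-pair definition.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .temporal_graph import AggregateNetwork, TemporalNetwork

__all__ = [
    "MemoryNetwork",
    "EntropyProfile",
    "MemoryExponentFit",
    "build_memory_network",
    "entropy_growth_rate",
    "entropy_profile",
    "fit_memory_exponent",
]

Path = tuple[int, ...]


@dataclass
class MemoryNetwork:
    """The consecutive memory network G^(tau) with weighted path-to-path edges."""

    tau: int
    nodes: set[Path]
    weights: dict[tuple[Path, Path], int]
    mode: str = "overlapping"

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def total_weight(self) -> int:
        return sum(self.weights.values())

    def to_aggregate(self) -> AggregateNetwork:
        """For tau = 0 the memory network is exactly the aggregate network."""
        if self.tau != 0:
            raise ValueError("only the tau=0 memory network reduces to G^(0)")
        return AggregateNetwork(
            {(a[0], b[0]): w for (a, b), w in self.weights.items()},
            nodes={p[0] for p in self.nodes},
        )


def _windows(seq: np.ndarray, k: int) -> list[Path]:
    s = seq.tolist()
    return list(zip(*(s[i:] for i in range(k))))


def build_memory_network(
    gt: TemporalNetwork, tau: int, mode: str = "overlapping"
) -> MemoryNetwork:
    """Construct G^(tau) from a temporal network.

    Nodes are the distinct (tau+1)-cell windows of the symbol sequence.  In
    overlapping mode the edge a -> b (b the shift of a) is weighted by the
    count of (tau+2)-cell windows; in concatenated mode a -> b joins disjoint
    adjacent windows, weighted by the count of 2(tau+1)-cell windows.
    tau = 0 reduces to the aggregate network in both modes.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    if mode not in ("overlapping", "concatenated"):
        raise ValueError(f"unknown mode {mode!r}")
    seq = gt.symbols
    if seq.size <= tau + 1:
        raise ValueError(
            f"sequence of length {seq.size} too short for memory order tau={tau}"
        )
    nodes = set(_windows(seq, tau + 1))
    weights: Counter[tuple[Path, Path]] = Counter()
    if mode == "overlapping":
        for win in _windows(seq, tau + 2):
            weights[(win[:-1], win[1:])] += 1
    else:
        span = 2 * (tau + 1)
        if seq.size < span:
            raise ValueError(
                f"sequence of length {seq.size} too short for concatenated tau={tau}"
            )
        for win in _windows(seq, span):
            weights[(win[: tau + 1], win[tau + 1 :])] += 1
    return MemoryNetwork(tau=tau, nodes=nodes, weights=dict(weights), mode=mode)


def entropy_growth_rate(mn: MemoryNetwork) -> float:
    """Entropy growth rate H (nats) of a memory network.

    H = -sum_a pi_a sum_b T_ab ln T_ab with T_ab the out-weight-normalised
    transition probability and pi the empirical edge marginal
    (pi_a = out-weight of a / total weight).  Nodes without out-edges
    contribute nothing.  Computed in the numerically convenient form
    H = (sum_a c_a ln c_a - sum_ab c_ab ln c_ab) / total.
    """
    if not mn.weights:
        raise ValueError("memory network has no edges")
    out: Counter[Path] = Counter()
    for (a, _b), w in mn.weights.items():
        out[a] += w
    total = sum(out.values())
    s_out = sum(c * math.log(c) for c in out.values())
    s_edge = sum(w * math.log(w) for w in mn.weights.values())
    return (s_out - s_edge) / total


@dataclass
class EntropyProfile:
    """H(tau) for tau = 0..tau_max, with path-node counts as a diagnostic."""

    taus: np.ndarray
    h: np.ndarray
    n_nodes: np.ndarray
    log_base: str = "e"

    def __post_init__(self) -> None:
        self.taus = np.asarray(self.taus, dtype=int)
        self.h = np.asarray(self.h, dtype=float)
        self.n_nodes = np.asarray(self.n_nodes, dtype=int)


def entropy_profile(
    gt: TemporalNetwork, tau_max: int, mode: str = "overlapping"
) -> EntropyProfile:
    """Compute H(tau) for tau = 0..tau_max."""
    if tau_max < 0:
        raise ValueError("tau_max must be non-negative")
    hs, counts = [], []
    for tau in range(tau_max + 1):
        mn = build_memory_network(gt, tau, mode=mode)
        hs.append(entropy_growth_rate(mn))
        counts.append(mn.n_nodes)
    return EntropyProfile(np.arange(tau_max + 1), np.array(hs), np.array(counts))


@dataclass
class MemoryExponentFit:
    """Least-squares fit of ln H(tau) on tau; rho = -slope."""

    rho: float
    intercept: float
    fit_taus: tuple[int, ...]
    r_squared: float


def _ols_loglinear(taus: np.ndarray, hs: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and R^2 of ln H regressed on tau."""
    y = np.log(hs)
    slope, intercept = np.polyfit(taus, y, 1)
    resid = y - (slope * taus + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return float(slope), float(intercept), r2


def fit_memory_exponent(
    profile: EntropyProfile,
    h_floor: float = 1e-12,
    tau_fit_max: int = 6,
    select: str = "range",
    min_window: int = 5,
) -> MemoryExponentFit:
    """Fit the memory exponent rho from an entropy profile.

    ``select="range"`` (default): ordinary least squares of ln H(tau) on tau
    over the points with tau <= tau_fit_max and H(tau) > h_floor.

    ``select="best"``: the profile of a finite series is exponential only over
    a limited stretch (a resolution-limited plateau precedes it and an
    estimator floor follows it), so the fit is taken over the contiguous
    window of at least ``min_window`` points, all above ``h_floor``, that
    maximises R^2 of the log-linear fit — ties broken toward longer, then
    earlier, windows.  ``tau_fit_max`` is ignored; compute the profile out to
    the tau range of interest.

    Degenerate rule (both modes): with fewer than two usable points, or a
    profile constant to within h_floor (the periodic case, H identically 0),
    rho = 0.
    """
    if select not in ("range", "best"):
        raise ValueError(f"unknown fit selection {select!r}")
    if select == "range":
        sel = (profile.taus <= tau_fit_max) & (profile.h > h_floor)
        in_range = profile.h[profile.taus <= tau_fit_max]
    else:
        sel = profile.h > h_floor
        in_range = profile.h
    taus = profile.taus[sel]
    hs = profile.h[sel]
    if taus.size < 2 or (in_range.size and np.ptp(in_range) <= h_floor):
        return MemoryExponentFit(0.0, float("nan"), (), float("nan"))

    if select == "best" and taus.size >= min_window:
        usable = profile.h > h_floor
        best = None  # (r2, length, -lo, slope, intercept, window)
        n_tau = profile.taus.size
        for lo in range(n_tau):
            for hi in range(lo + min_window - 1, n_tau):
                if not usable[lo : hi + 1].all():
                    continue
                t = profile.taus[lo : hi + 1]
                slope, intercept, r2 = _ols_loglinear(t, profile.h[lo : hi + 1])
                key = (r2, hi - lo, -lo)
                if best is None or key > best[0]:
                    best = (key, slope, intercept, t)
        if best is not None:
            _key, slope, intercept, t = best
            return MemoryExponentFit(
                rho=-slope,
                intercept=intercept,
                fit_taus=tuple(int(x) for x in t),
                r_squared=_key[0],
            )
    slope, intercept, r2 = _ols_loglinear(taus, hs)
    return MemoryExponentFit(
        rho=-slope,
        intercept=intercept,
        fit_taus=tuple(int(t) for t in taus),
        r_squared=r2,
    )
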