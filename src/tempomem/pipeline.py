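"""End-to-end composition: series -> trajectory -> symbols -> networks -> scores.

Also houses the run configuration (serialisable, replayable), the named system
presets with the partition sizes used throughout the analyses, and small
text fixtures for tests and demos.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import signal_models as sm
from .betweenness_preference import BetweennessPreferenceResult, bp_distribution
from .memory_entropy import (
    EntropyProfile,
    MemoryExponentFit,
    entropy_profile,
    fit_memory_exponent,
)
from .state_space import (
    GridPartition,
    delay_embed,
    fit_grid,
    fit_grid_occupancy,
    symbolize,
    trajectory_from_series,
)
from .temporal_graph import TemporalNetwork, build_temporal_network, write_temporal_edges

__all__ = [
    "RunConfig",
    "PipelineResult",
    "PRESETS",
    "ECG_PRESET",
    "generate",
    "series_to_network",
    "memory_exponent_of_series",
    "run_pipeline",
    "make_fixtures",
]

log = logging.getLogger(__name__)

#: Study presets: generator arguments plus the partition used in the reference
#: analyses.  Maps keep n = 2e4 after a 4000-step transient.  Deterministic
#: systems use their native (original) phase-space coordinates with the
#: partition size N read as the number of distinguishable attractor cells
#: (``n_occupied``: grid resolution calibrated so the orbit visits ~N cells;
#: for the 1-D logistic interval this is simply a 900-cell grid).  Scalar
#: random processes (white, 1/f, AR(3)) have no attractor and are symbolised
#: directly in 1-D with 100 equal cells.
PRESETS: dict[str, dict] = {
    "logistic": {"gen": "gen_logistic", "params": {"mu": 4.0, "n": 20_000, "n_transient": 4000},
                 "n_occupied": 900},
    "henon": {"gen": "gen_henon", "params": {"a": 1.4, "b": 0.3, "n": 20_000, "n_transient": 4000},
              "n_occupied": 2500},
    "henon_periodic": {"gen": "gen_henon",
                       "params": {**sm.HENON_PERIODIC, "n": 20_000, "n_transient": 4000},
                       "n_cells": 2500},
    "ikeda": {"gen": "gen_ikeda", "params": {"n": 20_000, "n_transient": 4000},
              "n_occupied": 1600},
    "rossler": {"gen": "gen_rossler", "params": {"n_samples": 20_000, "sample_stride": 1.0},
                "n_occupied": 100},
    "ar3": {"gen": "gen_ar3", "params": {"n": 20_000, "n_transient": 4000}, "n_cells": 100},
    "white": {"gen": "gen_white_noise", "params": {"n": 20_000}, "n_cells": 100},
    "pink": {"gen": "gen_pink_noise", "params": {"n": 20_000}, "n_cells": 100},
}

#: Embedding/partition preset for short noisy physiological recordings
#: (e.g. 10^4-point ECG traces): m=2, l=15, N=300.
ECG_PRESET = {"embed": (2, 15), "n_cells": 300}


def generate(system: str, seed: int | None = None, **overrides) -> sm.TimeSeries:
    """Generate a preset benchmark series, with keyword overrides."""
    if system not in PRESETS:
        raise ValueError(f"unknown system {system!r}; choose from {sorted(PRESETS)}")
    preset = PRESETS[system]
    params = {**preset["params"], **overrides}
    fn = getattr(sm, preset["gen"])
    if preset["gen"] == "gen_rossler":
        return fn(**params)  # deterministic flow, no seed argument
    return fn(seed=seed, **params)


@dataclass
class RunConfig:
    """A fully serialisable pipeline run description."""

    system: str = "logistic"
    params: dict = field(default_factory=dict)
    seed: int | None = None
    embed: tuple[int, int] | None = None  # (m, l); None = native coordinates
    n_cells: int | None = None
    per_dim: tuple[int, ...] | None = None
    n_occupied: int | None = None
    tau_max: int = 6
    mode: str = "overlapping"
    h_floor: float = 1e-12
    tau_fit_max: int = 6
    fit_select: str = "range"
    snr_db: float | None = None
    collapse_repeats: bool = False

    @classmethod
    def from_preset(cls, system: str, seed: int | None = None, **overrides) -> "RunConfig":
        preset = PRESETS[system]
        cfg = cls(
            system=system,
            params=dict(preset["params"]),
            seed=seed,
            embed=preset.get("embed"),
            n_cells=preset.get("n_cells"),
            per_dim=preset.get("per_dim"),
            n_occupied=preset.get("n_occupied"),
        )
        for key, val in overrides.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config field {key!r}")
            setattr(cfg, key, val)
        return cfg

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        for key in ("embed", "per_dim"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def series_to_network(
    series: sm.TimeSeries,
    embed: tuple[int, int] | None = None,
    n_cells: int | None = None,
    per_dim: tuple[int, ...] | None = None,
    n_occupied: int | None = None,
    bounds=None,
    collapse_repeats: bool = False,
) -> tuple[TemporalNetwork, GridPartition]:
    """Coarse-grain a series and build its temporal network.

    Scalar series are delay-embedded when ``embed=(m, l)`` is given, otherwise
    treated as 1-D trajectories; vector series always use their native
    coordinates.  The partition comes from exactly one of ``n_cells`` (total
    grid cells), ``per_dim`` (cells per dimension) or ``n_occupied``
    (resolution calibrated so the orbit occupies ~that many cells).
    """
    if series.is_scalar and embed is not None:
        m, l = embed
        traj = delay_embed(series, m, l)
    else:
        traj = trajectory_from_series(series)
    if n_occupied is not None:
        if n_cells is not None or per_dim is not None:
            raise ValueError("give only one partition specification")
        part = fit_grid_occupancy(traj, n_occupied, bounds=bounds)
    else:
        part = fit_grid(traj, n_cells_total=n_cells, per_dim=per_dim, bounds=bounds)
    symbols = symbolize(traj, part)
    gt = build_temporal_network(symbols, collapse_repeats=collapse_repeats)
    return gt, part


def memory_exponent_of_series(
    series: sm.TimeSeries,
    embed: tuple[int, int] | None = None,
    n_cells: int | None = None,
    per_dim: tuple[int, ...] | None = None,
    n_occupied: int | None = None,
    tau_max: int = 6,
    mode: str = "overlapping",
    h_floor: float = 1e-12,
    tau_fit_max: int = 6,
    select: str = "range",
    bounds=None,
) -> tuple[EntropyProfile, MemoryExponentFit]:
    """Full memory-entropy analysis of one series: H(tau) profile and rho."""
    gt, _part = series_to_network(
        series, embed=embed, n_cells=n_cells, per_dim=per_dim,
        n_occupied=n_occupied, bounds=bounds,
    )
    profile = entropy_profile(gt, tau_max, mode=mode)
    fit = fit_memory_exponent(
        profile, h_floor=h_floor, tau_fit_max=tau_fit_max, select=select
    )
    return profile, fit


def attractor_analysis(
    system: str,
    seed: int | None = None,
    tau_max: int = 14,
    **overrides,
) -> tuple[TemporalNetwork, GridPartition, EntropyProfile, MemoryExponentFit]:
    """The reference memory-exponent experiment for a preset system.

    Generates the preset series, symbolises the native phase-space trajectory
    on its preset partition, computes H(tau) out to ``tau_max`` and fits rho
    over the best exponential window (see
    :func:`~tempomem.memory_entropy.fit_memory_exponent` with
    ``select="best"``).
    """
    preset = PRESETS[system]
    series = generate(system, seed=seed, **overrides)
    gt, part = series_to_network(
        series,
        n_cells=preset.get("n_cells"),
        per_dim=preset.get("per_dim"),
        n_occupied=preset.get("n_occupied"),
    )
    profile = entropy_profile(gt, tau_max)
    fit = fit_memory_exponent(profile, select="best")
    return gt, part, profile, fit


@dataclass
class PipelineResult:
    config: RunConfig
    series: sm.TimeSeries
    network: TemporalNetwork
    partition: GridPartition
    profile: EntropyProfile
    fit: MemoryExponentFit
    betweenness: BetweennessPreferenceResult


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute generate -> embed -> partition -> G^T -> {H(tau), rho, I^v}.

    With ``outdir`` set, writes the edge list, entropy profile, betweenness
    scores and the effective config next to each other so the run can be
    replayed exactly.
    """
    stage = "generate"
    try:
        series = generate(config.system, seed=config.seed, **config.params)
        if config.snr_db is not None:
            stage = "noise"
            noise_seed = None if config.seed is None else config.seed + 1
            series = sm.add_noise_snr(series, config.snr_db, seed=noise_seed)
        stage = "transform"
        gt, part = series_to_network(
            series,
            embed=config.embed,
            n_cells=config.n_cells,
            per_dim=config.per_dim,
            n_occupied=config.n_occupied,
            collapse_repeats=config.collapse_repeats,
        )
        log.info("run %s: %d samples, %d occupied cells of %d",
                 config.system, series.n, len(gt.nodes), part.n_cells)
        stage = "entropy"
        profile = entropy_profile(gt, config.tau_max, mode=config.mode)
        fit = fit_memory_exponent(
            profile, h_floor=config.h_floor, tau_fit_max=config.tau_fit_max,
            select=config.fit_select,
        )
        stage = "betweenness"
        bp = bp_distribution(gt)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    result = PipelineResult(config, series, gt, part, profile, fit, bp)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_temporal_edges(gt, outdir / "edges.tsv")
        part.save_json(outdir / "partition.json")
        with open(outdir / "profile.tsv", "w") as fh:
            fh.write("tau\tH\tn_nodes\n")
            for t, h, c in zip(profile.taus, profile.h, profile.n_nodes):
                fh.write(f"{t}\t{h:.12g}\t{c}\n")
        with open(outdir / "rho.tsv", "w") as fh:
            fh.write("rho\tr_squared\tfit_taus\n")
            fh.write(f"{fit.rho:.12g}\t{fit.r_squared:.12g}\t"
                     f"{','.join(map(str, fit.fit_taus))}\n")
        with open(outdir / "betweenness.tsv", "w") as fh:
            fh.write("node\tI\ttotal\n")
            for v, nb in sorted(bp.per_node.items()):
                fh.write(f"{v}\t{nb.i_score:.12g}\t{nb.total}\n")
        config.to_json(outdir / "config.json")
    return result


# --- tiny text fixtures -----------------------------------------------------

#: Schematic 8-cell example: a short walk whose first transitions are
#: c -> e -> d (cells labelled a..h = 0..7).  No transition pair repeats, so
#: every aggregate weight is 1.
_TOY_LABELS = "abcdefgh"
_TOY_SYMBOLS = [2, 4, 3, 1, 2, 0, 4, 5]  # c e d b c a e f


def make_fixtures(outdir: str | Path) -> list[Path]:
    """Write small deterministic fixtures: the 8-cell toy walk and its
    temporal/aggregate/one-step-memory networks, plus short seeded samples of
    every generator.  Regeneration is byte-identical."""
    from .memory_entropy import build_memory_network
    from .temporal_graph import aggregate as _aggregate

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, text: str) -> None:
        path = outdir / name
        path.write_text(text)
        written.append(path)

    emit("toy_symbols.csv", "".join(f"{s}\n" for s in _TOY_SYMBOLS))
    emit("toy_labels.txt",
         "".join(f"{i}\t{c}\n" for i, c in enumerate(_TOY_LABELS)))

    gt = build_temporal_network(np.array(_TOY_SYMBOLS))
    lines = ["source\ttarget\ttime\n"]
    lines += [f"{u}\t{w}\t{t}\n" for u, w, t in gt.edges()]
    emit("toy_gt.tsv", "".join(lines))

    agg = _aggregate(gt)
    lines = ["source\ttarget\tweight\n"]
    lines += [f"{u}\t{w}\t{c}\n" for (u, w), c in sorted(agg.weights.items())]
    emit("toy_g0.tsv", "".join(lines))

    g1 = build_memory_network(gt, tau=1)
    lines = ["source\ttarget\tweight\n"]
    for (a, b), c in sorted(g1.weights.items()):
        lines.append(f"{'-'.join(map(str, a))}\t{'-'.join(map(str, b))}\t{c}\n")
    emit("toy_g1.tsv", "".join(lines))

    for system in ("logistic", "henon", "ikeda", "ar3", "white", "pink"):
        series = generate(system, seed=7, n=64, n_transient=16) \
            if system not in ("white", "pink") else generate(system, seed=7, n=64)
        vals = np.atleast_2d(series.values.T).T
        text = "".join(",".join(f"{v:.10g}" for v in row) + "\n" for row in vals)
        emit(f"sample_{system}.csv", text)
    series = generate("rossler", n_samples=64, n_transient_time=50.0)
    text = "".join(",".join(f"{v:.10g}" for v in row) + "\n" for row in series.values)
    emit("sample_rossler.csv", text)
    return written
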