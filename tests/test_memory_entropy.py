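"""Memory networks, entropy growth rate and the memory exponent fit."""

import math
from collections import Counter, defaultdict

import numpy as np
import pytest

import tempomem as tm
from tempomem.memory_entropy import (
    EntropyProfile,
    MemoryNetwork,
    build_memory_network,
    entropy_growth_rate,
    entropy_profile,
    fit_memory_exponent,
)
from tempomem.state_space import (
    delay_embed,
    fit_grid_occupancy,
    nonlinear_transform,
    symbolize,
    trajectory_from_series,
)
from tempomem.temporal_graph import aggregate, build_temporal_network


def block_conditional_entropy(seq, tau):
    """Independent oracle: conditional entropy from raw (tau+2)-gram counts."""
    grams = Counter(tuple(seq[i : i + tau + 2]) for i in range(len(seq) - tau - 1))
    prefix = defaultdict(int)
    for g, c in grams.items():
        prefix[g[:-1]] += c
    total = sum(grams.values())
    h = 0.0
    for g, c in grams.items():
        p_joint = c / total
        p_cond = c / prefix[g[:-1]]
        h -= p_joint * math.log(p_cond)
    return h


class TestMemoryNetwork:
    def test_one_step_windows_and_weights(self):
        gt = build_temporal_network(np.array([0, 1, 0, 1, 0]))  # a b a b a
        mn = build_memory_network(gt, tau=1)
        assert mn.nodes == {(0, 1), (1, 0)}
        assert mn.weights == {((0, 1), (1, 0)): 2, ((1, 0), (0, 1)): 1}

    @pytest.mark.parametrize("mode", ["overlapping", "concatenated"])
    def test_tau_zero_reduces_to_aggregate(self, mode):
        rng = np.random.default_rng(3)
        gt = build_temporal_network(rng.integers(0, 5, 200))
        mn = build_memory_network(gt, tau=0, mode=mode)
        agg = aggregate(gt)
        assert mn.to_aggregate().weights == agg.weights
        assert {p[0] for p in mn.nodes} == agg.nodes

    def test_overlapping_edges_respect_shift_structure(self):
        rng = np.random.default_rng(4)
        gt = build_temporal_network(rng.integers(0, 4, 300))
        mn = build_memory_network(gt, tau=2)
        for a, b in mn.weights:
            assert a[1:] == b[:-1]

    def test_sequence_too_short_for_tau(self):
        gt = build_temporal_network(np.array([0, 1, 2]))
        with pytest.raises(ValueError, match="too short"):
            build_memory_network(gt, tau=3)


class TestEntropyGrowthRate:
    def test_deterministic_transitions_have_zero_entropy(self):
        gt = build_temporal_network(np.tile([0, 1, 2], 40))  # period-3 cycle
        prof = entropy_profile(gt, 5)
        assert np.all(prof.h == 0.0)

    def test_balanced_two_way_branching_gives_ln2(self):
        mn = MemoryNetwork(
            tau=0,
            nodes={(0,), (1,)},
            weights={((0,), (0,)): 3, ((0,), (1,)): 3,
                     ((1,), (0,)): 5, ((1,), (1,)): 5},
        )
        assert entropy_growth_rate(mn) == pytest.approx(math.log(2), abs=1e-12)

    def test_iid_uniform_entropy_approaches_ln_k(self):
        rng = np.random.default_rng(5)
        gt = build_temporal_network(rng.integers(0, 10, 100_000))
        mn = build_memory_network(gt, tau=0)
        assert entropy_growth_rate(mn) == pytest.approx(math.log(10), rel=0.02)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            entropy_growth_rate(MemoryNetwork(tau=0, nodes=set(), weights={}))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_block_entropy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = rng.integers(0, rng.integers(2, 6), rng.integers(50, 500))
        gt = build_temporal_network(seq)
        for tau in range(4):
            mn = build_memory_network(gt, tau)
            assert entropy_growth_rate(mn) == pytest.approx(
                block_conditional_entropy(seq.tolist(), tau), abs=1e-10
            )

    @pytest.mark.parametrize("seed", range(8))
    def test_iid_profile_is_non_increasing(self, seed):
        rng = np.random.default_rng(seed)
        gt = build_temporal_network(rng.integers(0, 10, 3000))
        h = entropy_profile(gt, 5).h
        assert np.all(np.diff(h) <= 1e-9)


class TestQualitativeProfiles:
    def test_white_noise_entropy_collapses_within_three_scales(self):
        gt, _ = tm.series_to_network(tm.generate("white", seed=3), n_cells=100)
        h = entropy_profile(gt, 4).h
        assert h[0] > 2.0
        assert h[3] < 0.05

    def test_ar3_decreases_over_six_scales_then_flattens(self):
        gt, _ = tm.series_to_network(tm.generate("ar3", seed=3), n_cells=100)
        h = entropy_profile(gt, 6).h
        assert np.all(np.diff(h) < 0)
        assert h[6] < 0.1 * h[0]

    def test_periodic_henon_profile_is_constant(self):
        gt, _ = tm.series_to_network(tm.generate("henon_periodic", seed=3),
                                     n_cells=2500)
        h = entropy_profile(gt, 6).h
        assert np.ptp(h) == 0.0


class TestMemoryExponentFit:
    def test_exact_exponential_recovered(self):
        prof = EntropyProfile([0, 1, 2], [1.0, math.exp(-1), math.exp(-2)], [1, 1, 1])
        fit = fit_memory_exponent(prof)
        assert fit.rho == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_zero_profile_gives_zero(self):
        prof = EntropyProfile(range(7), np.zeros(7), np.ones(7))
        assert fit_memory_exponent(prof).rho == 0.0

    def test_single_usable_point_gives_zero(self):
        prof = EntropyProfile([0, 1, 2], [0.5, 0.0, 0.0], [1, 1, 1])
        assert fit_memory_exponent(prof).rho == 0.0

    def test_best_window_finds_the_exponential_stretch(self):
        taus = np.arange(12)
        h = np.concatenate([np.full(4, 0.8), 0.8 * np.exp(-0.5 * np.arange(1, 9))])
        fit = fit_memory_exponent(EntropyProfile(taus, h, np.ones(12)), select="best")
        assert fit.rho == pytest.approx(0.5, abs=0.02)
        assert fit.fit_taus[0] >= 3


class TestInvarianceOfRho:
    """The memory exponent reflects the dynamics, not the coordinates."""

    @staticmethod
    def _rho(traj):
        part = fit_grid_occupancy(traj, 2500)
        gt = build_temporal_network(symbolize(traj, part))
        return fit_memory_exponent(entropy_profile(gt, 6), tau_fit_max=6).rho

    def test_rho_stable_under_embedding_delay_and_transforms(self, henon_series):
        native = trajectory_from_series(henon_series)
        base = self._rho(native)
        assert base > 0.1
        x = tm.TimeSeries(henon_series.values[:, 0])
        for l in (1, 2, 3):
            assert self._rho(delay_embed(x, 2, l)) == pytest.approx(base, abs=0.05)
        for kind in ("quadratic", "cubic"):
            assert self._rho(nonlinear_transform(native, kind)) == pytest.approx(
                base, abs=0.05
            )
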