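"""Hydrolysis–ligation simulation and Shannon-diversity accounting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolforge.recombination_sim import (
    SequencePool,
    SimParams,
    delta_D_grid,
    hydrolyze,
    ligate,
    shannon_index,
    simulate_recombination,
)
from poolforge.synthetic_data import PoolSpec, make_pool


class TestShannonIndex:
    def test_monomorphic_pool_is_zero(self):
        assert shannon_index({"AAAA": 100}) == 0.0

    def test_uniform_pool_is_log2_n(self):
        pool = {f"s{i}": 1 for i in range(4)}
        assert shannon_index(pool) == pytest.approx(2.0)

    def test_counts_2_1_1(self):
        assert shannon_index({"a": 2, "b": 1, "c": 1}) == pytest.approx(1.5)

    def test_empty_pool_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            shannon_index({})

    @given(counts=st.lists(st.integers(1, 50), min_size=1, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_bounds_and_invariances(self, counts):
        pool = {f"s{i}": c for i, c in enumerate(counts)}
        D = shannon_index(pool)
        assert -1e-12 <= D <= math.log2(len(counts)) + 1e-12
        relabelled = {f"x{i}": c for i, c in enumerate(counts)}
        assert shannon_index(relabelled) == pytest.approx(D)
        scaled = {k: 3 * v for k, v in pool.items()}
        assert shannon_index(scaled) == pytest.approx(D)


class TestHydrolyze:
    def test_rate_zero_leaves_pool_intact(self, rng):
        pool = SequencePool.from_sequences(["ACGUACGU"] * 10)
        frags, survs = hydrolyze(pool, SimParams(0.0, 0.0), rng)
        assert frags.entries == {}
        assert survs.entries == pool.entries

    def test_length_two_molecule_yields_two_monomers(self, rng):
        pool = SequencePool.from_sequences(["AC"] * 5)
        frags, survs = hydrolyze(pool, SimParams(1.0, 0.0, sigma=0.5), rng)
        assert frags.entries == {"A": 5, "C": 5}
        assert survs.entries == {}
        # neither monomer is ligatable under the >2 nt gate
        after = ligate(frags, survs, SimParams(1.0, 1.0, sigma=0.5), rng)
        assert after.entries == {"A": 5, "C": 5}

    def test_breakpoints_follow_midpoint_normal(self, rng):
        pool = SequencePool.from_sequences(
            ["ACGUACGUACGUACGUACGU"] * 10_000  # L = 20, midpoint bond 10
        )
        frags, _ = hydrolyze(pool, SimParams(1.0, 0.0, sigma=2.0), rng)
        # 5' fragment lengths equal the sampled bond indices
        lengths = []
        seqs = frags.to_sequences()
        template = "ACGUACGUACGUACGUACGU"
        for s in seqs:
            if template.startswith(s):
                lengths.append(len(s))
        lengths = np.array(lengths)
        se = 2.0 / np.sqrt(len(lengths))
        assert abs(lengths.mean() - 10.0) < 4 * se

    def test_mass_conserved(self, rng):
        pool = SequencePool.from_sequences(["ACGUACGUAC"] * 100)
        frags, survs = hydrolyze(pool, SimParams(0.7, 0.0), rng)
        assert frags.nucleotide_mass + survs.nucleotide_mass == pool.nucleotide_mass


class TestLigate:
    def test_rate_zero_passthrough(self, rng):
        frags = SequencePool.from_sequences(["ACGU", "GGGG"])
        survs = SequencePool.from_sequences(["UUUUUUUU"])
        out = ligate(frags, survs, SimParams(0.0, 0.0), rng)
        assert out.entries == {"ACGU": 1, "GGGG": 1, "UUUUUUUU": 1}

    def test_two_fragments_rate_one_concatenate(self, rng):
        frags = SequencePool.from_sequences(["AAAA", "CCCC"])
        survs = SequencePool({}, alphabet="ACGU")
        out = ligate(frags, survs, SimParams(0.0, 1.0), rng)
        assert out.total_molecules == 1
        (seq,) = out.entries
        assert sorted(seq) == sorted("AAAACCCC")
        assert out.nucleotide_mass == 8

    def test_seeded_replay_reproduces_event_count(self):
        pool = make_pool(PoolSpec(length=20, n_unique=200, redundancy=5), seed=3)
        params = SimParams(0.8, 1.0)

        def run(seed):
            rng = np.random.default_rng(seed)
            frags, survs = hydrolyze(pool, params, rng)
            out = ligate(frags, survs, params, rng)
            return out.entries

        assert run(99) == run(99)


class TestSimulateRecombination:
    def test_zero_rates_is_identity(self):
        pool = make_pool(PoolSpec(length=10, n_unique=50, redundancy=4), seed=1)
        out = simulate_recombination(pool, SimParams(0.0, 0.0, seed=2))
        assert out.delta_D == 0.0
        assert out.pool_after.entries == pool.entries
        assert out.length_hist_before == out.length_hist_after

    def test_redundant_pool_gains_diversity(self):
        pool = make_pool(PoolSpec(length=20, n_unique=500, redundancy=100), seed=4)
        out = simulate_recombination(pool, SimParams(0.5, 0.5, seed=5))
        assert out.delta_D > 0
        assert out.pool_before.nucleotide_mass == out.pool_after.nucleotide_mass

    def test_degradative_corner_can_lose_diversity(self):
        # redundancy-1 two-letter pool, heavy cleavage, almost no ligation:
        # fragments collide in sequence space, so D can only fall
        deltas = []
        for seed in range(10):
            pool = make_pool(
                PoolSpec(length=10, alphabet="AU", n_unique=512, redundancy=1),
                seed=seed,
            )
            out = simulate_recombination(pool, SimParams(0.95, 0.01, seed=seed + 100))
            deltas.append(out.delta_D)
        assert min(deltas) <= 0

    def test_mass_conservation_under_random_parameters(self, rng):
        for _ in range(20):
            h, l = rng.random(), rng.random()
            pool = make_pool(
                PoolSpec(length=12, n_unique=100, redundancy=10),
                seed=int(rng.integers(2**31)),
            )
            out = simulate_recombination(
                pool, SimParams(h, l, seed=int(rng.integers(2**31)))
            )
            assert out.pool_after.nucleotide_mass == pool.nucleotide_mass


class TestDeltaDGrid:
    def test_single_cell_zero_rates(self):
        spec = PoolSpec(length=10, n_unique=20, redundancy=2)
        mean, sd = delta_D_grid(spec, [0.0], [0.0], replicates=3, seed=1)
        assert mean.shape == (1, 1)
        assert mean[0, 0] == 0.0

    def test_bitwise_reproducible_under_master_seed(self):
        spec = PoolSpec(length=12, n_unique=50, redundancy=5)
        a = delta_D_grid(spec, [0.3, 0.9], [0.5], replicates=3, seed=77)
        b = delta_D_grid(spec, [0.3, 0.9], [0.5], replicates=3, seed=77)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_mean_delta_D_scales_with_redundancy(self):
        lo = delta_D_grid(
            PoolSpec(length=12, n_unique=100, redundancy=1),
            [0.5], [0.5], replicates=8, seed=5,
        )[0].mean()
        hi = delta_D_grid(
            PoolSpec(length=12, n_unique=100, redundancy=50),
            [0.5], [0.5], replicates=8, seed=5,
        )[0].mean()
        assert hi > lo
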