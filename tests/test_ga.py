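"""Gene encoding, genetic operators (vs binomial oracles) and the search loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fexbci.cnn import HyperparamGenome
from fexbci.ga import (Chromosome, FitnessEvaluator, GAConfig,
                       HammingSurrogate, decode, default_layout, encode,
                       make_gene_spec, multipoint_crossover, mutate,
                       random_chromosome, roulette_select, run_ga)


class TestGeneSpec:
    @pytest.mark.parametrize("umin,umax,prec,l,delta", [
        (1, 512, 1.0, 9, 1.0),          # 511/(2^9-1) = 1 exactly
        (1, 20, 1.0, 5, 19 / 31),
        (0, 1, 1.0, 1, 1.0),
    ])
    def test_bit_length_and_precision(self, umin, umax, prec, l, delta):
        spec = make_gene_spec(umin, umax, prec)
        assert spec.l == l
        assert spec.delta == pytest.approx(delta, abs=0)

    def test_default_layout_is_33_bits(self):
        layout = default_layout()
        assert [g.l for g in layout] == [5, 5, 5, 9, 9]
        assert sum(g.l for g in layout) == 33

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            make_gene_spec(5, 5, 1.0)
        with pytest.raises(ValueError, match="integer"):
            make_gene_spec(0.5, 2, 1.0)


class TestEncodeDecode:
    def test_reported_best_genome_round_trips(self):
        g = HyperparamGenome(15, 13, 6, 286, 68)
        assert decode(encode(g)) == g

    def test_exhaustive_round_trip_all_genes(self):
        layout = default_layout()
        for lo, hi in [(1, 20), (1, 512)]:
            spec = make_gene_spec(lo, hi, 1.0)
            for v in range(lo, hi + 1):
                q = round((v - spec.u_min) / spec.delta)
                back = spec.u_min + round(q * spec.delta)
                assert min(max(back, lo), hi) == v
        # and through the full chromosome for the extreme corners
        for tup in [(1, 1, 1, 1, 1), (20, 20, 20, 512, 512), (7, 19, 2, 300, 511)]:
            g = HyperparamGenome(*tup)
            assert decode(encode(g, layout)) == g

    def test_all_zero_and_all_one_bits(self):
        layout = default_layout()
        zeros = Chromosome(bits=(0,) * 33, layout=layout)
        ones = Chromosome(bits=(1,) * 33, layout=layout)
        assert decode(zeros).as_tuple() == (1, 1, 1, 1, 1)
        assert decode(ones).as_tuple() == (20, 20, 20, 512, 512)

    @given(st.integers(0, 2**33 - 1))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_every_bit_pattern_decodes_in_range(self, raw):
        layout = default_layout()
        bits = tuple(int(b) for b in format(raw, "033b"))
        g = decode(Chromosome(bits=bits, layout=layout))
        assert isinstance(g, HyperparamGenome)  # constructor enforces ranges


class TestOperators:
    def test_roulette_probabilities(self, rng):
        idx = roulette_select([1.0, 3.0], 100_000, rng)
        freq = (idx == 1).mean()
        sigma = np.sqrt(0.75 * 0.25 / 100_000)
        assert abs(freq - 0.75) <= 3 * sigma

    def test_roulette_uniform_on_equal_fitness(self, rng):
        idx = roulette_select([2.0, 2.0, 2.0, 2.0], 40_000, rng)
        counts = np.bincount(idx, minlength=4) / 40_000
        assert np.allclose(counts, 0.25, atol=0.01)

    def test_roulette_all_zero_falls_back_to_uniform(self, rng):
        idx = roulette_select([0.0, 0.0], 1000, rng)
        assert set(np.unique(idx)) == {0, 1}

    def test_crossover_forced_example(self):
        layout = (make_gene_spec(0, 63, 1.0),)  # one 6-bit gene
        a = Chromosome(bits=(0, 0, 0, 0, 0, 0), layout=layout)
        b = Chromosome(bits=(1, 1, 1, 1, 1, 1), layout=layout)
        c1, c2 = multipoint_crossover(a, b, points=[2, 4])
        assert c1.bits == (0, 0, 1, 1, 0, 0)
        assert c2.bits == (1, 1, 0, 0, 1, 1)

    def test_crossover_no_cuts_is_identity(self):
        layout = default_layout()
        rng = np.random.default_rng(0)
        a, b = random_chromosome(layout, rng), random_chromosome(layout, rng)
        c1, c2 = multipoint_crossover(a, b, points=[])
        assert c1.bits == a.bits and c2.bits == b.bits

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_crossover_preserves_positionwise_bit_multiset(self, seed):
        layout = default_layout()
        rng = np.random.default_rng(seed)
        a, b = random_chromosome(layout, rng), random_chromosome(layout, rng)
        c1, c2 = multipoint_crossover(a, b, n_points=2, rng=rng)
        for i in range(len(a)):
            assert sorted((c1.bits[i], c2.bits[i])) == sorted((a.bits[i], b.bits[i]))

    def test_crossover_validation(self):
        layout = default_layout()
        rng = np.random.default_rng(0)
        a, b = random_chromosome(layout, rng), random_chromosome(layout, rng)
        with pytest.raises(ValueError, match="duplicate"):
            multipoint_crossover(a, b, points=[3, 3])
        with pytest.raises(ValueError, match="strictly inside"):
            multipoint_crossover(a, b, points=[0])

    def test_mutation_extremes_and_rate(self, rng):
        layout = default_layout()
        c = random_chromosome(layout, rng)
        assert mutate(c, 0.0, rng).bits == c.bits
        assert mutate(c, 1.0, rng).bits == tuple(1 - b for b in c.bits)
        flips = []
        for _ in range(10_000):
            m = mutate(c, 0.1, rng)
            flips.append(sum(a != b for a, b in zip(m.bits, c.bits)))
        L = len(c)
        expected, sd = L * 0.1, np.sqrt(L * 0.1 * 0.9)
        assert abs(np.mean(flips) - expected) <= 3 * sd / np.sqrt(10_000)


class TestFitnessAndSearch:
    def test_cache_contract(self):
        layout = default_layout()
        calls = []

        def fn(ch):
            calls.append(ch.bits)
            return 0.5

        ev = FitnessEvaluator(fn)
        c = random_chromosome(layout, np.random.default_rng(0))
        assert ev(c) == ev(c) == 0.5
        assert len(calls) == 1 and ev.hits == 1

    def test_failed_evaluation_scores_zero(self):
        def bad(ch):
            raise RuntimeError("diverged")
        ev = FitnessEvaluator(bad)
        c = random_chromosome(default_layout(), np.random.default_rng(0))
        assert ev(c) == 0.0
        assert len(ev.failures) == 1

    def test_hamming_surrogate_arithmetic(self):
        layout = (make_gene_spec(0, 15, 1.0),)  # 4 bits
        target = Chromosome(bits=(1, 0, 1, 0), layout=layout)
        probe = Chromosome(bits=(1, 1, 1, 1), layout=layout)
        assert HammingSurrogate(target)(probe) == pytest.approx(1 - 2 / 4)

    def test_history_length_and_elitist_monotonicity(self):
        rng = np.random.default_rng(42)
        target = random_chromosome(default_layout(), rng)
        best, hist = run_ga(HammingSurrogate(target), GAConfig(seed=42))
        assert len(hist) == 20
        assert all(b2 >= b1 for b1, b2 in zip(hist.best_fitness,
                                              hist.best_fitness[1:]))

    def test_surrogate_recovery_across_seeds(self):
        recovered = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            target = random_chromosome(default_layout(), rng)
            _, hist = run_ga(HammingSurrogate(target), GAConfig(seed=seed))
            recovered += hist.best_fitness[-1] == 1.0
        assert recovered >= 9

    def test_ga_beats_random_search_at_equal_budget(self):
        layout = default_layout()
        margins = []
        for seed in range(20):
            rng = np.random.default_rng(300 + seed)
            target = random_chromosome(layout, rng)
            fit = HammingSurrogate(target)
            _, hist = run_ga(fit, GAConfig(seed=seed))
            budget = 20 * 20
            rs = max(fit(random_chromosome(layout, rng)) for _ in range(budget))
            margins.append(hist.best_fitness[-1] - rs)
        assert np.median(margins) > 0

    def test_config_validation(self):
        with pytest.raises(ValueError, match="elitism"):
            GAConfig(population_size=4, elitism=4)
        with pytest.raises(ValueError, match="p_crossover"):
            GAConfig(p_crossover=1.5)
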