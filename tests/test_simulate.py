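"""Cumulative-advantage simulator: exact accounting and sampling laws."""

import itertools

import numpy as np
import pytest

from stemnet import simulate as sim
from stemnet.simulate import EnsembleConfig, SimulationConfig


class TestDrawNovelCount:
    def test_zero_probability_never_creates_lines(self, rng):
        assert all(sim.draw_novel_count(2, 0.0, rng) == 0 for _ in range(100))

    def test_unit_probability_always_creates_all(self, rng):
        assert all(sim.draw_novel_count(2, 1.0, rng) == 2 for _ in range(100))

    def test_binomial_mean_at_reference_parameters(self, rng):
        draws = np.array([sim.draw_novel_count(2, 0.15, rng) for _ in range(10**5)])
        se = np.sqrt(2 * 0.15 * 0.85 / 10**5)
        assert abs(draws.mean() - 0.30) < 3 * se


class TestSelectPreexisting:
    def test_single_positive_line_is_certain(self, rng):
        assert sim.select_preexisting([0, 5, 0], 1, rng) == [1]

    def test_proportional_selection_frequencies(self, rng):
        n = 10**5
        picks = np.array([sim.select_preexisting([3, 1], 1, rng)[0] for _ in range(n)])
        freq_a = np.mean(picks == 0)
        se = np.sqrt(0.75 * 0.25 / n)
        assert abs(freq_a - 0.75) < 3 * se

    def test_exhaustion_returns_all_lines(self, rng):
        assert sorted(sim.select_preexisting([3, 1], 2, rng)) == [0, 1]

    def test_insufficient_pool_raises(self, rng):
        with pytest.raises(ValueError, match="pool"):
            sim.select_preexisting([3, 0], 2, rng)

    def test_sequential_law_matches_enumeration(self, rng):
        # counts {A:3, B:1, C:2}, m=2: exact P(ordered pair) =
        # w_i/6 * w_j/(6-w_i); compare empirical ordered-pair frequencies
        w = [3, 1, 2]
        exact = {
            (i, j): w[i] / 6 * w[j] / (6 - w[i])
            for i, j in itertools.permutations(range(3), 2)
        }
        n = 4 * 10**4
        freqs = {k: 0 for k in exact}
        for _ in range(n):
            pair = tuple(sim.select_preexisting(w, 2, rng))
            freqs[pair] += 1
        for pair, p in exact.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(freqs[pair] / n - p) < 4 * se


class TestSimulateNetwork:
    def test_no_novelty_keeps_founders_only(self):
        net = sim.simulate_network(
            SimulationConfig(n_studies=100, novelty_prob=0.0, n_founders=5, seed=1)
        )
        assert net.n_lines == 5
        assert net.n_edges == 5 + 200

    def test_all_novelty_gives_degree_one_nonfounders(self):
        net = sim.simulate_network(
            SimulationConfig(n_studies=100, novelty_prob=1.0, n_founders=5, seed=1)
        )
        assert net.n_lines == 5 + 200
        assert (net.line_usage[5:] == 1).all()

    def test_edge_count_conservation_across_configs(self):
        for s, n, p, f in [(50, 2, 0.15, 5), (200, 3, 0.4, 2), (10, 1, 0.9, 1)]:
            net = sim.simulate_network(
                SimulationConfig(n_studies=s, lines_per_study=n,
                                 novelty_prob=p, n_founders=f, seed=7)
            )
            assert net.n_edges == f + n * s
            assert net.line_usage.sum() == net.n_edges
            assert net.n_lines == f + net.n_novel

    def test_each_study_uses_distinct_lines(self):
        net = sim.simulate_network(SimulationConfig(n_studies=300, seed=3))
        for s in range(1, net.n_studies):
            lines = net.edge_line[net.edge_study == s]
            assert len(lines) == len(set(lines)) == 2

    def test_deficit_covered_by_novel_lines(self):
        # founders fewer than lines per study: early studies cannot find
        # enough pre-existing lines and must create extras
        net = sim.simulate_network(
            SimulationConfig(n_studies=50, lines_per_study=4,
                             novelty_prob=0.0, n_founders=1, seed=5)
        )
        assert net.n_edges == 1 + 4 * 50
        first = net.edge_line[net.edge_study == 1]
        assert len(set(first)) == 4  # 1 preexisting + 3 forced novel

    def test_determinism_given_seed(self):
        a = sim.simulate_network(SimulationConfig(n_studies=500, seed=11))
        b = sim.simulate_network(SimulationConfig(n_studies=500, seed=11))
        assert np.array_equal(a.edge_line, b.edge_line)
        assert np.array_equal(a.line_usage, b.line_usage)


class TestEnsemble:
    def test_single_replicate_matches_direct_simulation(self):
        cfg = EnsembleConfig(n_replicates=1, base=SimulationConfig(n_studies=200), seed=9)
        (summary,) = sim.simulate_ensemble(cfg)
        net = sim.simulate_network(cfg.base, rng=sim.replicate_seeds(9, 1)[0])
        assert np.array_equal(summary.degrees, net.line_usage)

    def test_same_seed_stream_reproduces_summaries(self):
        cfg = EnsembleConfig(n_replicates=5, base=SimulationConfig(n_studies=200), seed=4)
        a = sim.simulate_ensemble(cfg)
        b = sim.simulate_ensemble(cfg)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.degrees, rb.degrees)
            assert ra.largest_component_lines == rb.largest_component_lines

    def test_distinct_lines_nondecreasing_in_novelty_prob(self):
        # over the candidate grid, higher novelty probability creates more
        # lines on average
        means = []
        for p in (0.05, 0.10, 0.15, 0.20, 0.25, 0.30):
            cfg = EnsembleConfig(
                n_replicates=10,
                base=SimulationConfig(n_studies=500, novelty_prob=p),
                seed=100,
            )
            means.append(np.mean([r.n_lines for r in sim.simulate_ensemble(cfg)]))
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_founder_usage_exceeds_later_lines(self, small_ensemble):
        assert all(
            r.founder_mean_usage > r.nonfounder_mean_usage for r in small_ensemble
        )

    def test_largest_component_dominates(self, small_ensemble):
        for r in small_ensemble:
            assert r.largest_component_lines > 0.5 * r.n_lines
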