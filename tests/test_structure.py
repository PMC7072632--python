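import numpy as np
import pytest

from ecvnet.local_model import ScoreConfig
from ecvnet.structure import (BasalNetwork, EdgeFrequencyNetwork,
                              LocalScoreCache, concordance, exhaustive_search,
                              greedy_hill_climb, nnsr_estimate,
                              read_edge_freq_tsv, read_network_tsv,
                              threshold_network, write_edge_freq_tsv,
                              write_network_tsv)
from ecvnet.synthetic import random_ground_truth, simulate_expression

from conftest import make_matrix

CFG2 = ScoreConfig(max_parents=2)


def _dependent_pair(seed, n=200):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 3, n)
    return make_matrix({"a": x, "b": 2 * x + rng.normal(0, 0.3, n)})


def _total_score(X, net, cfg):
    cache = LocalScoreCache(X, cfg)
    return sum(cache.score(g, net.parents(g)) for g in net.genes)


class TestBasalNetwork:
    def test_rejects_self_loops_and_duplicates(self):
        with pytest.raises(ValueError):
            BasalNetwork(genes=("a",), edges=(("a", "a"),))
        with pytest.raises(ValueError):
            BasalNetwork(genes=("a", "b"), edges=(("a", "b"), ("a", "b")))

    def test_parent_map(self):
        net = BasalNetwork(genes=("a", "b", "c"), edges=(("a", "c"), ("b", "c")))
        assert set(net.parents("c")) == {"a", "b"}
        assert net.parents("a") == ()


class TestExhaustiveSearch:
    def test_single_gene_is_empty_graph(self):
        X = make_matrix({"a": np.random.default_rng(0).normal(0, 1, 30)})
        assert exhaustive_search(X, CFG2).edges == ()

    def test_size_guard(self):
        cols = {f"g{i}": np.random.default_rng(i).normal(0, 1, 20) for i in range(6)}
        with pytest.raises(ValueError):
            exhaustive_search(make_matrix(cols), CFG2, max_nodes=5)

    def test_strongly_dependent_pair_yields_one_edge(self):
        net = exhaustive_search(_dependent_pair(1), CFG2)
        assert len(net.edges) == 1
        assert set(net.edges[0]) == {"a", "b"}

    def test_independent_pair_usually_empty(self):
        empty = 0
        reps = 50
        for s in range(reps):
            rng = np.random.default_rng(600 + s)
            X = make_matrix({"a": rng.normal(0, 1, 200), "b": rng.normal(0, 1, 200)})
            empty += exhaustive_search(X, CFG2).edges == ()
        assert empty >= 0.9 * reps


class TestGreedyHillClimb:
    def test_deterministic(self):
        X = _dependent_pair(5)
        assert greedy_hill_climb(X, CFG2).edges == greedy_hill_climb(X, CFG2).edges

    def test_result_is_acyclic(self):
        import networkx as nx
        for s in range(5):
            gt = random_ground_truth(p=6, seed=s, gain=2.0, root_sd=1.0,
                                     n_lines=1, n_conditions=1, n_replicates=40)
            X = simulate_expression(gt, seed=s + 50)
            net = greedy_hill_climb(X, ScoreConfig())
            g = nx.DiGraph(list(net.edges))
            assert nx.is_directed_acyclic_graph(g)

    def test_respects_max_parents(self):
        gt = random_ground_truth(p=6, seed=9, gain=2.0, root_sd=1.0,
                                 n_lines=1, n_conditions=1, n_replicates=40)
        X = simulate_expression(gt, seed=59)
        cfg = ScoreConfig(max_parents=1)
        net = greedy_hill_climb(X, cfg)
        assert all(len(net.parents(g)) <= 1 for g in net.genes)


@pytest.fixture(scope="module")
def toy():
    gt = random_ground_truth(p=6, seed=77, gain=2.5, root_sd=1.0,
                             n_lines=1, n_conditions=1, n_replicates=60)
    return simulate_expression(gt, seed=78)


class TestNnsr:
    def test_same_seed_same_frequencies(self, toy):
        f1 = nnsr_estimate(toy, 25, 4, CFG2, seed=3)
        f2 = nnsr_estimate(toy, 25, 4, CFG2, seed=3)
        assert f1.edge_freq == f2.edge_freq
        assert f1.cosample_count == f2.cosample_count

    def test_invalid_iterations(self, toy):
        with pytest.raises(ValueError):
            nnsr_estimate(toy, 0, 4, CFG2, seed=0)

    def test_frequencies_within_unit_interval(self, toy):
        f = nnsr_estimate(toy, 40, 4, CFG2, seed=1)
        assert all(0 <= v <= 1 for v in f.edge_freq.values())
        assert all(f.cosample_count[frozenset(e)] > 0 for e in f.edge_freq)

    def test_pairwise_subset_always_finds_strong_edge(self):
        X = _dependent_pair(31)
        f = nnsr_estimate(X, 20, 2, CFG2, seed=4)
        top = max(f.edge_freq.values(), default=0.0)
        assert top >= 0.5
        assert f.cosample_count[frozenset(("a", "b"))] == 20

    def test_higher_T_reduces_frequency_variance(self):
        """Edge-frequency estimates stabilize as iterations grow (measured on
        a small-sample design where subnetwork calls are genuinely unstable)."""
        gt = random_ground_truth(p=10, seed=55)
        X = simulate_expression(gt, seed=56)
        runs = {T: [nnsr_estimate(X, T, 4, CFG2, seed=100 + r).edge_freq
                    for r in range(4)] for T in (20, 200)}
        edges = set().union(*[set(t) for tables in runs.values() for t in tables])
        def var_at(T):
            return np.mean([np.var([t.get(e, 0.0) for t in runs[T]]) for e in edges])
        assert var_at(200) < var_at(20)


class TestThresholdAndConcordance:
    def _freq_net(self, freq):
        genes = tuple(sorted({g for e in freq for g in e}))
        cos = {frozenset(e): 10 for e in freq}
        return EdgeFrequencyNetwork(genes=genes, edge_freq=freq,
                                    cosample_count=cos, T_iter=10,
                                    subset_size=2, seed=0)

    def test_cutoff_validation(self):
        fn = self._freq_net({("a", "b"): 0.5})
        with pytest.raises(ValueError):
            threshold_network(fn, 0.0)

    def test_strict_threshold(self):
        fn = self._freq_net({("a", "b"): 0.3, ("b", "c"): 0.1})
        net = threshold_network(fn, 0.1)
        assert net.edges == (("a", "b"),)

    def test_bidirectional_pair_keeps_stronger_direction(self):
        fn = self._freq_net({("a", "b"): 0.3, ("b", "a"): 0.2})
        assert threshold_network(fn, 0.1).edges == (("a", "b"),)

    def test_bidirectional_tie_resolves_lexicographically(self):
        fn = self._freq_net({("a", "b"): 0.3, ("b", "a"): 0.3})
        assert threshold_network(fn, 0.1).edges == (("a", "b"),)

    def test_cutoff_above_all_gives_empty(self):
        fn = self._freq_net({("a", "b"): 0.3})
        assert threshold_network(fn, 0.9).edges == ()

    def test_concordance_identity_disjoint_and_partial(self):
        genes = ("a", "b", "c")
        nAB = BasalNetwork(genes=genes, edges=(("a", "b"), ("b", "c")))
        nA = BasalNetwork(genes=genes, edges=(("a", "b"),))
        nC = BasalNetwork(genes=genes, edges=(("c", "a"),))
        assert concordance(nAB, nAB) == 1.0
        assert concordance(nA, nC) == 0.0
        assert concordance(nAB, nA) == 0.5

    def test_concordance_gene_universe_checked(self):
        nA = BasalNetwork(genes=("a", "b"), edges=())
        nB = BasalNetwork(genes=("a", "c"), edges=())
        with pytest.raises(ValueError):
            concordance(nA, nB)


class TestStructureRecovery:
    def test_planted_dag_recovered_from_population_data(self):
        """On a strongly-signalled 10-gene system (n=100) the thresholded
        edge-frequency network recovers most true edges with few spurious
        ones (direction ignored)."""
        gt = random_ground_truth(p=10, seed=42, gain=3.0, root_sd=1.0,
                                 n_lines=1, n_conditions=1, n_replicates=100)
        X = simulate_expression(gt, seed=43)
        f = nnsr_estimate(X, 200, 6, ScoreConfig(), seed=11)
        net = threshold_network(f, 0.1)
        true_und = {frozenset(e) for e in gt.dag}
        est_und = {frozenset(e) for e in net.edges}
        tp = len(est_und & true_und)
        assert tp >= 0.7 * len(true_und)
        assert (len(est_und) - tp) <= 0.3 * len(est_und)


class TestIO:
    def test_edge_freq_round_trip(self, tmp_path):
        X = _dependent_pair(13)
        f = nnsr_estimate(X, 10, 2, CFG2, seed=5)
        path = tmp_path / "freq.tsv"
        write_edge_freq_tsv(f, path)
        back = read_edge_freq_tsv(path, genes=f.genes, T_iter=10, subset_size=2, seed=5)
        assert back.edge_freq == f.edge_freq
        assert back.cosample_count == f.cosample_count

    def test_network_round_trip(self, tmp_path):
        net = BasalNetwork(genes=("a", "b", "c"), edges=(("a", "b"), ("b", "c")),
                           edge_freq={("a", "b"): 0.4, ("b", "c"): 0.2})
        path = tmp_path / "net.tsv"
        write_network_tsv(net, path)
        back = read_network_tsv(path, genes=net.genes)
        assert back.edges == net.edges
        assert back.edge_freq == net.edge_freq
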