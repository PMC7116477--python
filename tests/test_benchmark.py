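"""Edge detection, +/-1 scoring and the graph-recovery benchmark."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from dirspec import BenchmarkConfig, DirectedGraph, detect_edges, run_benchmark, score
from dirspec.benchmark import mean_percent_score


class TestScore:
    def test_perfect_prediction_three_nodes(self):
        truth = DirectedGraph(3, ((0, 1, 2), (0, 2, 3), (2, 1, 1))).adjacency()
        res = score(truth, truth)
        assert res.raw_score == 6
        assert res.percent_score == 100.0

    def test_fully_inverted_prediction(self):
        truth = DirectedGraph(3, ((0, 1, 2),)).adjacency()
        off = ~np.eye(3, dtype=bool)
        inverted = ~truth & off
        res = score(truth, inverted)
        assert res.raw_score == -6
        assert res.percent_score == -100.0

    def test_five_correct_one_wrong(self):
        truth = DirectedGraph(3, ((0, 1, 2),)).adjacency()
        pred = truth.copy()
        pred[1, 2] = True  # one false positive
        res = score(truth, pred)
        assert res.raw_score == 4
        assert res.percent_score == pytest.approx(100 * 4 / 6)

    def test_predicting_nothing_on_one_edge_graph(self):
        # brute-force application of the +/-1 rule: 5 matches, 1 miss
        truth = DirectedGraph(3, ((1, 0, 1),)).adjacency()
        res = score(truth, np.zeros((3, 3), dtype=bool))
        assert res.raw_score == 4
        assert res.percent_score == pytest.approx(100 * 4 / 6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score(np.zeros((3, 3), bool), np.zeros((4, 4), bool))

    @given(arrays(bool, (3, 3)), arrays(bool, (3, 3)))
    @settings(max_examples=50, deadline=None)
    def test_bounds_and_parity(self, truth, pred):
        res = score(truth, pred)
        assert -100.0 <= res.percent_score <= 100.0
        assert res.raw_score % 2 == 0  # six off-diagonal cells, +/-1 each

    @given(arrays(bool, (3, 3)), arrays(bool, (3, 3)), st.permutations(range(3)))
    @settings(max_examples=50, deadline=None)
    def test_invariance_under_node_relabeling(self, truth, pred, perm):
        p = list(perm)
        a = score(truth, pred).raw_score
        b = score(truth[np.ix_(p, p)], pred[np.ix_(p, p)]).raw_score
        assert a == b


class TestDetectEdges:
    freqs = 129

    def _spectra(self, levels):
        return {pair: np.full(self.freqs, lvl) for pair, lvl in levels.items()}

    def test_all_below_threshold_gives_empty_adjacency(self):
        pairs = {(i, j): 0.1 for i in range(3) for j in range(3) if i != j}
        adj = detect_edges(self._spectra(pairs), {p: 0.5 for p in pairs})
        assert not adj.any()

    def test_exact_fraction_boundary_detects(self):
        spec = np.zeros(self.freqs)
        n_bins = self.freqs - 1  # DC excluded
        k = int(np.ceil(0.10 * n_bins))
        spec[1 : 1 + k] = 1.0
        adj = detect_edges({(0, 1): spec}, {(0, 1): 0.5}, fraction=0.10, n_nodes=2)
        assert adj[0, 1]
        spec2 = np.zeros(self.freqs)
        spec2[1 : k] = 1.0  # one bin short of 10%
        adj2 = detect_edges({(0, 1): spec2}, {(0, 1): 0.5}, fraction=0.10, n_nodes=2)
        assert not adj2[0, 1]

    def test_dc_bin_excluded_from_counting(self):
        spec = np.zeros(self.freqs)
        spec[0] = 10.0  # only DC above threshold
        adj = detect_edges({(0, 1): spec}, {(0, 1): 0.5}, n_nodes=2)
        assert not adj[0, 1]

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="same frequency grid"):
            detect_edges(
                {(0, 1): np.zeros(10), (1, 0): np.zeros(12)},
                {(0, 1): 0.5, (1, 0): 0.5},
            )

    def test_threshold_coverage_must_match(self):
        with pytest.raises(ValueError, match="same pairs"):
            detect_edges({(0, 1): np.zeros(10)}, {})


class TestRunBenchmark:
    @pytest.mark.parametrize("method", ["npd", "mvnpg"])
    def test_strong_unidirectional_edge_recovered(self, method):
        graphs = [DirectedGraph(2, ((0, 1, 2),))]
        cfg = BenchmarkConfig(trial_len=256, n_trials=80, n_surrogates=60)
        res = run_benchmark(graphs, cfg, method=method, seed=3)[0]
        expected = np.zeros((2, 2), dtype=bool)
        expected[0, 1] = True
        np.testing.assert_array_equal(res.predicted, expected)
        assert res.percent_score == 100.0

    def test_seeded_rerun_identical(self):
        graphs = [DirectedGraph(3, ((0, 1, 2),))]
        cfg = BenchmarkConfig(trial_len=256, n_trials=40, n_surrogates=40)
        a = run_benchmark(graphs, cfg, method="npd", seed=11)[0]
        b = run_benchmark(graphs, cfg, method="npd", seed=11)[0]
        np.testing.assert_array_equal(a.predicted, b.predicted)
        assert a.percent_score == b.percent_score

    def test_mean_percent_score(self):
        graphs = [DirectedGraph(2, ((0, 1, 2),)), DirectedGraph(2, ((1, 0, 2),))]
        cfg = BenchmarkConfig(trial_len=256, n_trials=40, n_surrogates=40)
        results = run_benchmark(graphs, cfg, method="npd", seed=5)
        assert mean_percent_score(results) == pytest.approx(
            np.mean([r.percent_score for r in results])
        )

    def test_unknown_method_rejected(self):
        cfg = BenchmarkConfig(trial_len=256, n_trials=10, n_surrogates=40)
        with pytest.raises(ValueError, match="unknown method"):
            run_benchmark([DirectedGraph(2, ((0, 1, 2),))], cfg, method="dtf", seed=0)
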