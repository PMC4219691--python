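import numpy as np
import pytest
from scipy import stats
from sklearn.linear_model import Lasso as SklearnLasso

from labnet import (
    CandidateSet,
    PipelineConfig,
    SimulationConfig,
    ValidationError,
    infer_neighbourhood,
    lambda_max,
    lasso_fit,
    permutation_counters,
    select_candidates,
    select_stable,
    simulate_expression,
    standardize,
)
from conftest import chain_network


def _toy_problem(seed=0, n=40, p=10):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    X = (X - X.mean(0)) / X.std(0)
    y = X[:, 0] * 1.5 - X[:, 3] + 0.3 * rng.normal(size=n)
    y -= y.mean()
    return y, X


class TestPermutationCounters:
    def test_zero_permutations_zero_counters(self):
        y, X = _toy_problem()
        candidates = CandidateSet(response_index=-1, candidates=[(0, 1.0), (3, 0.8)])
        counters = permutation_counters(y, X, 0.1, candidates, B=0, seed=1)
        assert counters.tolist() == [0, 0]

    def test_zero_predictor_column_never_selected(self):
        y, X = _toy_problem()
        X = X.copy()
        X[:, 5] = 0.0
        candidates = CandidateSet(
            response_index=-1, candidates=[(5, 0.5), (0, 1.0)]
        )
        counters = permutation_counters(y, X, 0.01, candidates, B=30, seed=2)
        assert counters[0] == 0

    def test_counters_bounded_by_b(self):
        y, X = _toy_problem(seed=3)
        fit = lasso_fit(y, X, 0.05)
        candidates = select_candidates(fit)
        counters = permutation_counters(y, X, 0.05, candidates, B=25, seed=4)
        assert counters.min() >= 0 and counters.max() <= 25

    def test_matches_sequential_sklearn_oracle(self):
        # same seeded permutation stream, independent Lasso implementation
        y, X = _toy_problem(seed=5)
        lam = 0.3 * lambda_max(y, X)
        fit = lasso_fit(y, X, lam)
        candidates = select_candidates(fit)
        B = 25
        counters = permutation_counters(y, X, lam, candidates, B=B, seed=6)
        rng = np.random.default_rng(6)
        expected = np.zeros(len(candidates), dtype=int)
        model = SklearnLasso(
            alpha=lam, fit_intercept=False, tol=1e-12, max_iter=10**6
        )
        for _ in range(B):
            permuted = rng.permutation(y)
            coef = model.fit(X, permuted).coef_
            expected += coef[candidates.indices] != 0
        np.testing.assert_array_equal(counters, expected)

    def test_deterministic_across_runs(self):
        y, X = _toy_problem(seed=7)
        candidates = CandidateSet(
            response_index=-1, candidates=[(0, 1.0), (3, 0.8), (7, 0.1)]
        )
        a = permutation_counters(y, X, 0.05, candidates, B=40, seed=8)
        b = permutation_counters(y, X, 0.05, candidates, B=40, seed=8)
        np.testing.assert_array_equal(a, b)

    def test_checkpoints_are_prefix_counts(self):
        y, X = _toy_problem(seed=9)
        candidates = CandidateSet(response_index=-1, candidates=[(0, 1.0), (3, 0.8)])
        snapshots = permutation_counters(
            y, X, 0.05, candidates, B=30, seed=10, checkpoints=[0, 10, 30]
        )
        assert snapshots.shape == (3, 2)
        independent = permutation_counters(y, X, 0.05, candidates, B=10, seed=10)
        np.testing.assert_array_equal(snapshots[1], independent)
        assert np.all(snapshots[0] == 0)

    def test_negative_b_rejected(self):
        y, X = _toy_problem()
        candidates = CandidateSet(response_index=-1, candidates=[(0, 1.0)])
        with pytest.raises(ValidationError):
            permutation_counters(y, X, 0.1, candidates, B=-1)


class TestSelectStable:
    def _candidates(self, items):
        return CandidateSet(response_index=9, candidates=items)

    def test_smallest_counter_wins(self):
        candidates = self._candidates([(2, 1.0), (4, 0.8), (6, 0.5)])
        result = select_stable(
            np.array([0, 3, 7]), candidates, fanout=1, B=50, gate_enabled=False
        )
        assert result.selected == [2]

    def test_smallest_counter_kept_under_gate_when_separated(self):
        candidates = self._candidates([(2, 1.0), (4, 0.8), (6, 0.5)])
        result = select_stable(
            np.array([0, 30, 45]), candidates, fanout=1, B=50, gate_enabled=True
        )
        assert result.selected == [2]
        assert result.p_value == 0.0

    def test_tie_broken_by_step1_coefficient(self):
        candidates = self._candidates([(1, 0.4), (3, 0.9), (5, 0.2)])
        result = select_stable(
            np.array([2, 2, 5]), candidates, fanout=1, B=10, gate_enabled=False
        )
        assert result.selected == [3]

    def test_uniform_counters_gated_out(self):
        candidates = self._candidates([(1, 0.4), (3, 0.9), (5, 0.2)])
        result = select_stable(
            np.array([7, 7, 7]),
            candidates,
            fanout=1,
            B=50,
            significance_level=0.05,
            gate_enabled=True,
        )
        assert result.p_value == 1.0
        assert result.selected == []

    def test_gate_inactive_below_minimum_b(self):
        candidates = self._candidates([(1, 0.4), (3, 0.9)])
        result = select_stable(
            np.array([5, 5]), candidates, fanout=1, B=10, gate_enabled=True
        )
        # p-value reported but too few permutations to act on it
        assert result.p_value == 1.0
        assert result.selected == [3]

    def test_fanout_limits_selection(self):
        candidates = self._candidates([(1, 0.4), (3, 0.9), (5, 0.2), (7, 0.1)])
        result = select_stable(
            np.array([4, 1, 3, 2]), candidates, fanout=2, B=5, gate_enabled=False
        )
        assert result.selected == [3, 7]

    def test_empty_candidates_short_circuit(self):
        result = select_stable(
            np.array([]), self._candidates([]), fanout=1, B=100
        )
        assert result.selected == []
        assert result.p_value is None


class TestInferNeighbourhood:
    def test_all_zero_fit_gives_empty_result(self, small_benchmark):
        _, matrix, _ = small_benchmark
        config = PipelineConfig(permutations=10, seed=0)
        huge_lambda = 1e6
        result = infer_neighbourhood(0, matrix, huge_lambda, config, seed=0)
        assert result.selected == []
        assert result.counters.size == 0

    def test_noiseless_chain_interior_recovery(self):
        config = SimulationConfig(p=3, n=60, noise_sd=0.0, seed=21)
        matrix = standardize(simulate_expression(chain_network(3), config))
        pipeline = PipelineConfig(permutations=100, fanout=1, gate_enabled=False, seed=21)
        result = infer_neighbourhood(1, matrix, 0.05, pipeline, seed=21)
        assert len(result.selected) == 1
        assert result.selected[0] in (0, 2)

    def test_deterministic_and_order_independent(self, small_benchmark):
        _, matrix, _ = small_benchmark
        config = PipelineConfig(permutations=30, seed=5)
        lam = 0.05
        first = [
            infer_neighbourhood(j, matrix, lam, config, seed=5) for j in (3, 1, 2)
        ]
        second = [
            infer_neighbourhood(j, matrix, lam, config, seed=5) for j in (1, 2, 3)
        ]
        by_index_first = {r.response_index: r for r in first}
        by_index_second = {r.response_index: r for r in second}
        for j in (1, 2, 3):
            np.testing.assert_array_equal(
                by_index_first[j].counters, by_index_second[j].counters
            )
            assert by_index_first[j].selected == by_index_second[j].selected


class TestStabilitySemantics:
    def test_true_neighbours_have_smaller_counters_than_decoys(self):
        """Permuting the response should break genuine associations: over
        replicates, counters of true network neighbours sit stochastically
        below counters of decoy candidates."""
        true_counts, decoy_counts = [], []
        for seed in range(20):
            config = SimulationConfig(p=15, n=80, attachment_edges=1, seed=seed)
            from labnet import generate_gold_network

            gold = generate_gold_network(config)
            matrix = standardize(simulate_expression(gold, config))
            pipeline = PipelineConfig(permutations=40, seed=seed)
            lam = 0.05
            for j in range(0, 15, 3):
                result = infer_neighbourhood(j, matrix, lam, pipeline, seed=seed)
                for idx, counter in zip(result.candidate_indices, result.counters):
                    if gold.adjacency[j, idx]:
                        true_counts.append(counter / 40)
                    else:
                        decoy_counts.append(counter / 40)
        assert len(true_counts) > 20 and len(decoy_counts) > 20
        test = stats.mannwhitneyu(true_counts, decoy_counts, alternative="less")
        assert test.pvalue < 0.05
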