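"""Greedy stepwise and genetic-search selectors and their evaluator."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from metabconsensus import (
    CohortConfig,
    MetaboliteSpec,
    class_distance,
    generate_cohort,
    genetic_search,
    greedy_stepwise,
    roulette_select,
    selection_probabilities,
)
from metabconsensus.wrapper_selection import GaParams, squared_gaps

from conftest import make_dataset


def planted_config(p, seed, fold=1 / 20, n=40):
    """One fold-planted metabolite (column 0) among p − 1 nulls."""
    specs = [
        MetaboliteSpec(name="planted", control_mean=100.0, control_sd=30.0,
                       case_fold=fold)
    ] + [
        MetaboliteSpec(name=f"null{j}", control_mean=10.0, control_sd=3.0)
        for j in range(p - 1)
    ]
    return CohortConfig(n_cases=n, n_controls=n, metabolites=specs, seed=seed)


class TestClassDistance:
    def test_coincident_centroids_zero(self):
        values = np.array([[1.0, 5.0], [3.0, 7.0], [1.0, 5.0], [3.0, 7.0]])
        ds = make_dataset(values, [1, 1, 0, 0])
        assert class_distance(ds, ["m0", "m1"]) == pytest.approx(0.0, abs=1e-12)

    def test_single_feature_unit_gap(self):
        # column whose standardized group means sit at ±0.5 → gap exactly 1
        x, y = 1.0, np.sqrt(0.5)
        col = np.array([0.5 + x, 0.5 - x, -0.5 + y, -0.5 - y]) + 10.0
        ds = make_dataset(col[:, None], [1, 1, 0, 0])
        assert class_distance(ds, ["m0"]) == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_centroid_oracle(self):
        rng = np.random.default_rng(12)
        values = rng.lognormal(0, 0.5, (30, 5))
        labels = np.r_[np.ones(15, int), np.zeros(15, int)]
        ds = make_dataset(values, labels)
        subset = ["m1", "m3", "m4"]
        # brute-force oracle: standardize, compute centroids, take the norm
        idx = [1, 3, 4]
        z = (values - values.mean(0)) / values.std(0)
        gap = z[:15, idx].mean(0) - z[15:, idx].mean(0)
        oracle = np.linalg.norm(gap) / math.sqrt(3)
        assert class_distance(ds, subset) == pytest.approx(oracle, abs=1e-12)

    def test_order_invariant(self, toy_dataset):
        a = class_distance(toy_dataset, ["m0", "m2"])
        b = class_distance(toy_dataset, ["m2", "m0"])
        assert a == pytest.approx(b, abs=1e-15)

    def test_empty_subset_rejected(self, toy_dataset):
        with pytest.raises(ValueError):
            class_distance(toy_dataset, [])


class TestGreedy:
    def test_planted_feature_selected_first(self):
        for seed in range(20):
            ds = generate_cohort(planted_config(20, seed))
            result = greedy_stepwise(ds, "forward")
            assert result.names[0] == "planted", f"seed {seed}"

    def test_constant_evaluator_returns_single_feature(self, toy_dataset):
        result = greedy_stepwise(toy_dataset, "forward", normalization="rms")
        # under the rms evaluator no second addition can strictly increase
        # the score when the first pick is the per-feature maximum
        d2 = squared_gaps(toy_dataset)
        assert result.names[0] == toy_dataset.metabolite_names[int(np.argmax(d2))]
        assert len(result.names) == 1

    @pytest.mark.parametrize("normalization", ["energy", "rms"])
    def test_matches_exhaustive_hill_climb_oracle(self, normalization):
        """p = 4: identical to a brute-force climb over all 15 subsets."""
        values = np.array(
            [
                [5.0, 1.0, 9.0, 2.0],
                [6.0, 2.0, 8.0, 2.5],
                [7.0, 1.5, 8.5, 2.2],
                [1.0, 1.2, 3.0, 2.1],
                [2.0, 2.2, 2.0, 2.4],
                [1.5, 1.8, 2.5, 2.3],
            ]
        )
        ds = make_dataset(values, [1, 1, 1, 0, 0, 0])

        def oracle():
            current: tuple = ()
            score = -np.inf
            while True:
                best_next, best_score = None, score
                for j in range(4):
                    name = f"m{j}"
                    if name in current:
                        continue
                    s = class_distance(ds, list(current) + [name], normalization)
                    if s > best_score or (not current and s >= best_score):
                        best_next, best_score = name, s
                if best_next is None:
                    return current, score
                current += (best_next,)
                score = best_score

        expected_names, expected_score = oracle()
        result = greedy_stepwise(ds, "forward", normalization)
        assert result.names == expected_names
        assert result.score == pytest.approx(expected_score, abs=1e-12)

    def test_forward_path_score_monotone(self, default_cohort):
        result = greedy_stepwise(default_cohort, "forward")
        scores = [
            class_distance(default_cohort, list(result.names[: k + 1]), "energy")
            for k in range(len(result.names))
        ]
        # every accepted addition strictly increased the evaluator
        assert all(b > a for a, b in zip(scores, scores[1:]))
        assert scores[-1] == pytest.approx(result.score, abs=1e-9)

    def test_backward_keeps_strong_features(self):
        ds = generate_cohort(planted_config(10, seed=0))
        result = greedy_stepwise(ds, "backward")
        assert "planted" in result.names

    def test_unknown_direction_rejected(self, toy_dataset):
        with pytest.raises(ValueError):
            greedy_stepwise(toy_dataset, "sideways")


class TestGaMechanics:
    def test_selection_probabilities_forced_values(self):
        np.testing.assert_allclose(
            selection_probabilities([1, 2, 3, 4]), [0.1, 0.2, 0.3, 0.4]
        )

    def test_uniform_fitness_uniform_probabilities(self):
        np.testing.assert_allclose(selection_probabilities([2.0] * 5), [0.2] * 5)

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=30).filter(
        lambda f: sum(f) > 0))
    def test_probabilities_normalized(self, fitness):
        assert selection_probabilities(fitness).sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_fitness_rejected(self):
        with pytest.raises(ValueError):
            selection_probabilities([0.0, 0.0])

    def test_roulette_rule(self):
        probs = np.array([0.1, 0.2, 0.3, 0.4])
        assert roulette_select(probs, 0.25) == 1  # q = [.1, .3, .6, 1.]
        assert roulette_select(probs, 0.0) == 0
        with pytest.raises(ValueError):
            roulette_select(probs, 1.5)

    def test_roulette_empirical_frequencies(self):
        probs = np.array([0.1, 0.2, 0.3, 0.4])
        rng = np.random.default_rng(123)
        draws = rng.random(100_000)
        counts = np.bincount([roulette_select(probs, r) for r in draws], minlength=4)
        np.testing.assert_allclose(counts / draws.size, probs, atol=0.01)


class TestGeneticSearch:
    def test_reproducible_given_seed(self, default_cohort):
        a = genetic_search(default_cohort, GaParams(seed=9))
        b = genetic_search(default_cohort, GaParams(seed=9))
        assert a.names == b.names and a.score == b.score

    def test_best_ever_fitness_monotone(self, default_cohort):
        result = genetic_search(default_cohort, GaParams(seed=2))
        assert result.trace is not None
        assert all(b >= a for a, b in zip(result.trace, result.trace[1:]))

    def test_planted_feature_recovered(self):
        hits = 0
        for seed in range(20):
            ds = generate_cohort(planted_config(20, seed))
            result = genetic_search(ds, GaParams(seed=seed + 1))
            hits += "planted" in result.names
        assert hits >= 18

    def test_population_invariants(self):
        # population size is structural: the returned subset is over the
        # metabolite universe and scored by the evaluator it optimized
        ds = generate_cohort(planted_config(12, seed=4, n=20))
        result = genetic_search(ds, GaParams(seed=5))
        assert set(result.names) <= set(ds.metabolite_names)
        assert result.score == pytest.approx(
            class_distance(ds, list(result.names), "energy"), abs=1e-9
        )
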