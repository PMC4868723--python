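"""Random forest: bootstrap structure, OOB accounting, permutation importance."""

import numpy as np
import pytest

from metabconsensus import (
    CohortConfig,
    MetaboliteSpec,
    RfConfig,
    default_mtry,
    fit_forest,
    generate_cohort,
    oob_error,
    permutation_importance,
    top_importance,
)
from metabconsensus.random_forest import _Tree, ForestModel, _tree_predict

from conftest import make_dataset


class TestDefaultMtry:
    @pytest.mark.parametrize("p, expected", [(206, 14), (4, 2), (1, 1), (2, 1)])
    def test_floor_sqrt(self, p, expected):
        assert default_mtry(p) == expected

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            default_mtry(0)


def small_planted_cohort(seed, p=30, n=25):
    specs = [
        MetaboliteSpec(name="strong", control_mean=100.0, control_sd=30.0,
                       case_fold=1 / 20)
    ] + [
        MetaboliteSpec(name=f"null{j}", control_mean=5.0, control_sd=1.5,
                       missing_rate=0.05)
        for j in range(p - 1)
    ]
    return generate_cohort(
        CohortConfig(n_cases=n, n_controls=n, metabolites=specs, seed=seed)
    )


class TestBootstrapStructure:
    def test_in_bag_size_and_oob_complement(self):
        ds = small_planted_cohort(0)
        model = fit_forest(ds, RfConfig(n_trees=20, seed=1))
        n = ds.n_samples
        for tree in model.trees:
            assert tree.in_bag.size == n
            expected_oob = np.setdiff1d(np.arange(n), tree.in_bag)
            np.testing.assert_array_equal(tree.oob_idx, expected_oob)

    def test_bootstrap_uniqueness_converges_to_632(self):
        """Unique in-bag fraction → 1 − e⁻¹ over many bootstrap draws."""
        rng = np.random.default_rng(0)
        n = 80
        draws = rng.integers(0, n, size=(10_000, n))
        unique_frac = np.array([np.unique(row).size for row in draws]) / n
        assert unique_frac.mean() == pytest.approx(1 - np.exp(-1), abs=0.01)


class TestFitAndOob:
    def test_planted_cohort_low_oob_error(self):
        for seed in range(10):
            ds = small_planted_cohort(seed)
            model = fit_forest(ds, RfConfig(n_trees=300, mtry=5, seed=seed))
            aggregate, _ = oob_error(model)
            assert aggregate <= 0.05, f"seed {seed}"

    def test_permuted_labels_oob_near_half(self):
        ds = generate_cohort(CohortConfig(seed=3))
        rng = np.random.default_rng(0)
        shuffled = ds.copy()
        shuffled.labels = rng.permutation(ds.labels)
        model = fit_forest(shuffled, RfConfig(n_trees=200, mtry=20, seed=4))
        aggregate, _ = oob_error(model)
        assert 0.35 <= aggregate <= 0.65

    def test_seeded_reproducibility(self):
        ds = small_planted_cohort(2)
        a = fit_forest(ds, RfConfig(n_trees=50, seed=7))
        b = fit_forest(ds, RfConfig(n_trees=50, seed=7))
        np.testing.assert_array_equal(a.oob_prediction, b.oob_prediction)

    def test_aggregate_error_matches_recount_oracle(self):
        ds = small_planted_cohort(5)
        model = fit_forest(ds, RfConfig(n_trees=100, seed=9))
        aggregate, per_tree = oob_error(model)
        votes = np.zeros((ds.n_samples, 2))
        errors = []
        for tree in model.trees:
            for idx, pred in zip(tree.oob_idx, tree.oob_pred):
                votes[idx, pred] += 1
            errors.append((tree.oob_pred != ds.labels[tree.oob_idx]).mean())
        covered = votes.sum(axis=1) > 0
        recount = (np.argmax(votes[covered], axis=1) != ds.labels[covered]).mean()
        assert aggregate == pytest.approx(recount, abs=1e-12)
        assert per_tree == pytest.approx(np.mean(errors), abs=1e-12)

    def test_single_class_rejected(self):
        ds = make_dataset(np.random.default_rng(0).lognormal(0, 1, (6, 3)),
                          [1, 1, 1, 1, 1, 1])
        with pytest.raises(ValueError):
            fit_forest(ds, RfConfig(n_trees=5, seed=0))

    def test_stump_forest_predicts_majority(self):
        """Identical majority-class stumps give OOB error = minority fraction."""
        labels = np.array([1, 1, 1, 0, 0])
        n = labels.size
        stump = _Tree(
            feature=np.array([-1]), threshold=np.array([np.nan]),
            left=np.array([-1]), right=np.array([-1]),
            p_left=np.array([1.0]), leaf_class=np.array([1]),
            in_bag=np.arange(n), oob_idx=np.arange(n),
            oob_pred=np.ones(n, dtype=int),
            oob_error=float((labels != 1).mean()),
        )
        votes = np.zeros((n, 2), dtype=int)
        votes[:, 1] = 3
        model = ForestModel(
            trees=[stump] * 3, config=RfConfig(n_trees=3, seed=0), mtry=1,
            n_samples=n, labels=labels, oob_votes=votes,
            oob_prediction=np.ones(n, dtype=int),
        )
        aggregate, per_tree = oob_error(model)
        assert aggregate == pytest.approx(2 / 5)
        assert per_tree == pytest.approx(2 / 5)

    def test_perfect_single_tree_zero_error(self):
        ds = make_dataset([[10.0], [11.0], [1.0], [2.0], [1.5], [10.5]],
                          [1, 1, 0, 0, 0, 1])
        model = fit_forest(ds, RfConfig(n_trees=1, mtry=1, seed=12))
        with pytest.warns(UserWarning):
            # a single tree leaves some samples in-bag only
            aggregate, _ = oob_error(model)
        tree = model.trees[0]
        assert (tree.oob_pred == ds.labels[tree.oob_idx]).all()
        assert aggregate == 0.0


class TestImportance:
    def test_unused_feature_has_zero_mda(self):
        """A feature no tree splits on contributes exactly zero MDA."""
        rng = np.random.default_rng(1)
        values = np.c_[
            np.abs(np.r_[rng.normal(10, 0.5, 10), rng.normal(1, 0.5, 10)]),
            np.full(20, 7.7),  # constant: no valid split exists
        ]
        ds = make_dataset(values, [1] * 10 + [0] * 10)
        model = fit_forest(ds, RfConfig(n_trees=200, mtry=1, seed=2))
        table = permutation_importance(model, ds)
        assert not any(1 in tree.used_features() for tree in model.trees)
        assert table.loc[1, "mda"] == 0.0

    def test_max_vimp_is_exactly_100(self):
        ds = small_planted_cohort(7)
        model = fit_forest(ds, RfConfig(n_trees=100, mtry=5, seed=3))
        table = permutation_importance(model, ds)
        assert table["vimp_relative"].max() == 100.0
        assert table.loc[table["vimp_relative"].idxmax(), "rank"] == 1

    def test_ranks_are_permutation(self):
        ds = small_planted_cohort(8)
        model = fit_forest(ds, RfConfig(n_trees=50, mtry=5, seed=4))
        table = permutation_importance(model, ds)
        assert sorted(table["rank"]) == list(range(1, ds.n_metabolites + 1))

    def test_planted_feature_ranked_first(self):
        ds = small_planted_cohort(9)
        model = fit_forest(ds, RfConfig(n_trees=300, mtry=5, seed=5))
        table = permutation_importance(model, ds)
        best = table.loc[table["rank"] == 1, "metabolite"].iloc[0]
        assert best == "strong"

    def test_top_view_sorted(self):
        ds = small_planted_cohort(10)
        model = fit_forest(ds, RfConfig(n_trees=50, mtry=5, seed=6))
        table = permutation_importance(model, ds)
        top = top_importance(table, 5)
        assert len(top) == 5
        assert list(top["rank"]) == [1, 2, 3, 4, 5]


class TestMissingDataHandling:
    def test_missing_values_routed_not_dropped(self):
        """Samples missing the split feature still reach a leaf."""
        rng = np.random.default_rng(11)
        strong = np.r_[rng.normal(10, 1, 15), rng.normal(2, 1, 15)]
        strong = np.abs(strong)
        strong[rng.choice(30, 6, replace=False)] = np.nan
        noise = np.abs(rng.normal(5, 1, 30))
        ds = make_dataset(np.c_[strong, noise], [1] * 15 + [0] * 15)
        model = fit_forest(ds, RfConfig(n_trees=100, mtry=2, seed=13))
        assert (model.oob_prediction >= 0).all()
        aggregate, _ = oob_error(model)
        assert aggregate <= 0.35
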