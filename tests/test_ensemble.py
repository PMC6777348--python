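import numpy as np
import pytest

from genomehub.ensemble import (
    assemble_feature_matrix,
    auroc,
    cross_validated_auroc,
    fit_logistic_ensemble,
    fraction_unscored,
    incremental_component_eval,
    read_label_table,
    read_score_table,
)
from genomehub.fixtures import EnsembleConfig, FixtureConfig, make_ensemble_arrays
from genomehub.variant_effects import EffectScoreRecord, Variant


def V(pos):
    return Variant("chr1", pos, "A", "C")


def rec(pos, score=None, region_tag=None):
    if score is None:
        return EffectScoreRecord(V(pos), "m", scored=False)
    return EffectScoreRecord(V(pos), "m", "score", scores={"DIFF": score})


class TestAssemble:
    def test_bookkeeping_with_one_unscored_cell(self):
        variants = [V(1), V(2), V(3)]
        t1 = [rec(1, 0.1), rec(2, 0.2), rec(3, 0.3)]
        t2 = [rec(1, -0.4), rec(2), rec(3, 0.6)]
        X, mask = assemble_feature_matrix([t1, t2], variants)
        assert X.shape == (3, 2)
        assert mask.sum() == 1 and mask[1, 1]
        assert X[0, 1] == -0.4

    def test_multi_region_duplicates_collapse_by_max_abs(self):
        variants = [V(1)]
        table = [rec(1, 0.2), rec(1, -0.5)]
        X, mask = assemble_feature_matrix([table], variants)
        assert X[0, 0] == -0.5 and not mask.any()

    def test_extra_feature_adds_column(self):
        variants = [V(1), V(2)]
        t1 = [rec(1, 0.1), rec(2, 0.2)]
        cons = {"conservation": {V(1).key: 1.5, V(2).key: -0.5}}
        X, mask = assemble_feature_matrix([t1], variants, extra_features=cons)
        assert X.shape == (2, 2)
        np.testing.assert_array_equal(X[:, 1], [1.5, -0.5])


class TestAuroc:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ((0.9, 0.8, 0.2, 0.1), (1, 1, 0, 0), 1.0),
            ((0.9, 0.8, 0.2, 0.1), (0, 0, 1, 1), 0.0),
            # pos scores {0.3, 0.5}, neg {0.6, 0.2}: wins 2 of 4 pairs
            ((0.3, 0.6, 0.5, 0.2), (1, 0, 1, 0), 0.5),
        ],
    )
    def test_known_rankings(self, scores, labels, expected):
        assert auroc(np.array(scores), np.array(labels)) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auroc(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=200)
        y = (rng.random(200) < 0.4).astype(int)
        assert auroc(s, y) == pytest.approx(auroc(np.exp(s), y))
        assert auroc(s, y) == pytest.approx(auroc(3 * s + 7, y))

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        s = rng.normal(size=500).round(1)  # ties included
        y = (rng.random(500) < 0.5).astype(int)
        assert auroc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


class TestFit:
    def test_recovers_generative_weights(self):
        cfg = FixtureConfig(seed=5)
        X, mask, _, labels = make_ensemble_arrays(cfg)
        model = fit_logistic_ensemble(X, mask, labels)
        np.testing.assert_allclose(
            model.head.weights, cfg.ensemble.weights, atol=0.25
        )

    def test_imputation_values_are_observed_means(self):
        cfg = FixtureConfig(
            seed=6, ensemble=EnsembleConfig(missing_rates=(0.0, 0.0, 0.0, 0.2), n=1000)
        )
        X, mask, _, labels = make_ensemble_arrays(cfg)
        model = fit_logistic_ensemble(X, mask, labels)
        obs = X[~mask[:, 3], 3]
        assert model.imputation_values[3] == pytest.approx(obs.mean())

    def test_all_masked_feature_named_in_error(self):
        X = np.zeros((10, 2))
        mask = np.zeros((10, 2), dtype=bool)
        mask[:, 1] = True
        y = np.array([0, 1] * 5)
        with pytest.raises(ValueError, match="c2"):
            fit_logistic_ensemble(X, mask, y, component_names=["c1", "c2"])


class TestCrossValidation:
    def test_perfectly_separable_gives_auroc_one(self):
        rng = np.random.default_rng(2)
        y = np.array([0, 1] * 100)
        X = (y[:, None] * 2.0 - 1.0) + 0.01 * rng.normal(size=(200, 1))
        mask = np.zeros_like(X, dtype=bool)
        per_fold, mean = cross_validated_auroc(X, mask, y, k=5, seed=0)
        assert mean == pytest.approx(1.0)

    def test_null_features_give_chance_level(self):
        means = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(2000, 3))
            y = (rng.random(2000) < 0.5).astype(int)
            _, mean = cross_validated_auroc(X, np.zeros_like(X, dtype=bool), y, k=5, seed=seed)
            means.append(mean)
        assert np.mean(means) == pytest.approx(0.5, abs=0.05)

    def test_same_seed_reproduces_results(self):
        cfg = FixtureConfig(seed=7, ensemble=EnsembleConfig(n=600))
        X, mask, _, labels = make_ensemble_arrays(cfg)
        r1 = cross_validated_auroc(X, mask, labels, k=5, seed=3)
        r2 = cross_validated_auroc(X, mask, labels, k=5, seed=3)
        assert r1 == r2

    def test_imputation_means_unaffected_by_test_labels(self):
        """No-leakage: training-fold imputation means depend only on
        training-fold feature values, never on test-fold labels."""
        from sklearn.model_selection import StratifiedKFold

        cfg = FixtureConfig(
            seed=8, ensemble=EnsembleConfig(missing_rates=(0.3, 0.0, 0.0, 0.0), n=500)
        )
        X, mask, _, labels = make_ensemble_arrays(cfg)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        for train_idx, test_idx in skf.split(X, labels):
            shuffled = labels.copy()
            rng = np.random.default_rng(0)
            shuffled[test_idx] = rng.permutation(shuffled[test_idx])
            m1 = fit_logistic_ensemble(X[train_idx], mask[train_idx], labels[train_idx])
            m2 = fit_logistic_ensemble(X[train_idx], mask[train_idx], shuffled[train_idx])
            np.testing.assert_array_equal(m1.imputation_values, m2.imputation_values)


class TestIncremental:
    def test_prefix_one_equals_single_column_cv(self):
        cfg = FixtureConfig(seed=9, ensemble=EnsembleConfig(n=800))
        X, mask, _, labels = make_ensemble_arrays(cfg)
        prefixes = incremental_component_eval(["a", "b", "c", "d"], X, mask, labels, k=5, seed=1)
        _, single = cross_validated_auroc(X[:, :1], mask[:, :1], labels, k=5, seed=1)
        assert prefixes[0] == pytest.approx(single)

    def test_informative_components_non_decreasing(self):
        cfg = FixtureConfig(
            seed=10, ensemble=EnsembleConfig(weights=(1.0, 0.9, 0.8, 0.7), n=2000)
        )
        X, mask, _, labels = make_ensemble_arrays(cfg)
        prefixes = incremental_component_eval(["a", "b", "c", "d"], X, mask, labels, k=10, seed=0)
        for lo, hi in zip(prefixes, prefixes[1:]):
            assert hi >= lo - 0.02

    def test_pure_noise_column_barely_moves_auroc(self):
        deltas = []
        for seed in range(10):
            cfg = FixtureConfig(
                seed=seed + 20,
                ensemble=EnsembleConfig(weights=(1.5, -1.0, 0.5, 0.0), n=1000),
            )
            X, mask, _, labels = make_ensemble_arrays(cfg)
            prefixes = incremental_component_eval(
                ["a", "b", "c", "noise"], X, mask, labels, k=5, seed=seed
            )
            deltas.append(abs(prefixes[3] - prefixes[2]))
        assert np.mean(deltas) < 0.03


class TestFractionUnscored:
    def test_counts(self):
        variants = [V(i) for i in range(1, 5)]
        table = [rec(1, 0.1), rec(2, 0.2), rec(3, 0.3), rec(4)]
        assert fraction_unscored([table], variants) == [0.25]
        full = [rec(i, 0.1) for i in range(1, 5)]
        assert fraction_unscored([full], variants) == [0.0]
        assert fraction_unscored([[]], variants) == [1.0]


def test_score_table_roundtrip(tmp_path):
    from genomehub.ensemble import write_score_table

    records = [rec(1, 0.123456789), rec(2), rec(3, -4.2)]
    p = tmp_path / "scores.tsv"
    write_score_table(records, p)
    back = read_score_table(p, model_name="m")
    assert [r.scored for r in back] == [True, False, True]
    assert back[0].scores["DIFF"] == pytest.approx(0.123456789)
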