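import numpy as np
import pandas as pd
import pytest
from sklearn.tree import DecisionTreeClassifier

from cppsig.ml_pipeline import (
    Bundle,
    FittedModel,
    RoundResult,
    TrainConfig,
    aggregate_approaches,
    confidence_class,
    default_registry,
    evaluate_holdout,
    evaluate_loocv,
    monte_carlo_train,
    predict_score,
    relevance_score,
    tree_feature_importance,
)


class TestRegistry:
    def test_ten_models_four_tree(self):
        reg = default_registry()
        assert len(reg) == 10
        assert sum(s.tree for s in reg.values()) == 4
        roles = [s.role for s in reg.values()]
        assert roles.count("linear") == 2
        assert roles.count("kernel") == 1
        assert roles.count("neural") == 1
        assert roles.count("ensemble") == 2


def small_registry(names=("random_forest", "logistic")):
    reg = default_registry()
    return {k: reg[k] for k in names}


class TestMonteCarloTrain:
    def test_model_count_product(self, small_training):
        X, y = small_training
        bundle = monte_carlo_train(
            X, y, small_registry(), TrainConfig(n_rounds=2,
                                                feature_preselect_grid=(20,))
        )
        assert bundle.n_final_models == 2 * 2

    def test_seed_contract_identical_reruns(self, small_training):
        X, y = small_training
        cfg = TrainConfig(n_rounds=2, feature_preselect_grid=(15,), seed_base=4)
        b1 = monte_carlo_train(X, y, small_registry(), cfg)
        b2 = monte_carlo_train(X, y, small_registry(), cfg)
        for r1, r2 in zip(b1.rounds, b2.rounds):
            assert r1.train_ids == r2.train_ids and r1.test_ids == r2.test_ids
            for name in r1.models:
                assert (
                    r1.models[name].holdout_balanced_accuracy
                    == r2.models[name].holdout_balanced_accuracy
                )

    def test_single_class_split_aborts(self):
        X = pd.DataFrame(np.random.default_rng(0).random((6, 3)),
                         index=[f"s{i}" for i in range(6)])
        y = pd.Series([1, 1, 1, 1, 1, 0], index=X.index)
        with pytest.raises((RuntimeError, ValueError)):
            monte_carlo_train(X, y, small_registry(("logistic",)),
                              TrainConfig(n_rounds=1, feature_preselect_grid=(3,)))


class _Const:
    """Stub estimator emitting a fixed positive-class probability."""

    def __init__(self, p):
        self.p = p

    def predict_proba(self, X):
        X = np.asarray(X)
        return np.column_stack([np.full(len(X), 1 - self.p),
                                np.full(len(X), self.p)])


def stub_bundle(round_models, train_ids_per_round, all_ids, features=("f0",)):
    rounds = []
    for probs, train_ids in zip(round_models, train_ids_per_round):
        models = {
            f"m{j}": FittedModel(
                name=f"m{j}", estimator=_Const(p), feature_subset=list(features),
                params={}, cv_score=None, holdout_balanced_accuracy=1.0,
            )
            for j, p in enumerate(probs)
        }
        test_ids = [i for i in all_ids if i not in train_ids]
        rounds.append(RoundResult(seed=0, train_ids=list(train_ids),
                                  test_ids=test_ids, models=models,
                                  test_proba=pd.DataFrame()))
    labels = pd.Series(1, index=all_ids)
    return Bundle(rounds=rounds, feature_names=list(features),
                  registry={}, cfg=TrainConfig(n_rounds=len(rounds)),
                  labels=labels)


class TestPredictScore:
    def test_mean_of_model_probabilities(self):
        bundle = stub_bundle([(0.2, 0.6)], [[]], ["a"])
        X = pd.DataFrame({"f0": [0.0]}, index=["a"])
        assert predict_score(bundle, X)["a"] == pytest.approx(0.4)

    def test_all_models_unanimous(self):
        bundle = stub_bundle([(1.0, 1.0, 1.0)], [[]], ["a"])
        X = pd.DataFrame({"f0": [0.0]}, index=["a"])
        assert predict_score(bundle, X)["a"] == pytest.approx(1.0)

    def test_out_of_fold_discipline(self):
        # round 0 trained on 'a' (score 0.9), round 1 held 'a' out (score 0.1)
        bundle = stub_bundle([(0.9,), (0.1,)], [["a"], ["b"]], ["a", "b"])
        X = pd.DataFrame({"f0": [0.0, 0.0]}, index=["a", "b"])
        scores, contrib = predict_score(bundle, X, return_contributions=True)
        assert scores["a"] == pytest.approx(0.1)
        assert {ri for ri, _ in contrib["a"]} == {1}
        assert scores["b"] == pytest.approx(0.9)
        for sid, cons in contrib.items():
            for ri, _ in cons:
                assert sid not in bundle.rounds[ri].train_ids

    def test_missing_feature_errors(self):
        bundle = stub_bundle([(0.5,)], [[]], ["a"])
        with pytest.raises(KeyError):
            predict_score(bundle, pd.DataFrame({"other": [1.0]}, index=["a"]))


class TestAggregation:
    def test_mean_and_sd(self):
        scores = {
            "a1": pd.Series({"p": 0.8}),
            "a2": pd.Series({"p": 1.0}),
        }
        out = aggregate_approaches(scores)
        assert out.loc["p", "score"] == pytest.approx(0.9)
        assert out.loc["p", "sd"] == pytest.approx(np.std([0.8, 1.0], ddof=1))

    def test_identical_approaches_zero_sd(self):
        out = aggregate_approaches(
            {f"a{i}": pd.Series({"p": 0.7}) for i in range(6)}
        )
        assert out.loc["p", "sd"] == pytest.approx(0.0)

    def test_six_approach_closed_form(self):
        vals = [0.9, 0.85, 0.95, 0.8, 0.88, 0.92]
        out = aggregate_approaches(
            {f"a{i}": pd.Series({"p": v}) for i, v in enumerate(vals)}
        )
        assert out.loc["p", "score"] == pytest.approx(np.mean(vals))
        assert out.loc["p", "sd"] == pytest.approx(np.std(vals, ddof=1))


class TestConfidenceClass:
    @pytest.mark.parametrize(
        "score,expected",
        [
            (0.85, "HC substrate"),
            (0.80, "HC substrate"),
            (0.50, "LC substrate"),
            (0.79, "LC substrate"),
            (0.21, "LC non-substrate"),
            (0.49, "LC non-substrate"),
            (0.20, "HC non-substrate"),
            (0.0, "HC non-substrate"),
        ],
    )
    def test_thresholds(self, score, expected):
        assert confidence_class(score) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            confidence_class(1.2)


class TestImportanceAndEvaluation:
    def test_stump_importance_is_one(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(
            {"signal": rng.random(40), "noise": rng.random(40)},
            index=[f"s{i}" for i in range(40)],
        )
        y = (X["signal"] > 0.5).astype(int)
        stump = DecisionTreeClassifier(max_depth=1).fit(X.to_numpy(), y)
        fm = FittedModel("decision_tree", stump, list(X.columns), {}, None, 1.0)
        bundle = Bundle(
            rounds=[RoundResult(0, [], [], {"decision_tree": fm}, pd.DataFrame())],
            feature_names=list(X.columns),
            registry=default_registry(),
            cfg=TrainConfig(n_rounds=1),
            labels=pd.Series(y),
        )
        imp = tree_feature_importance(bundle)
        assert imp["signal"] == pytest.approx(1.0)
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)

    def test_importance_sums_to_one(self, small_training):
        X, y = small_training
        bundle = monte_carlo_train(
            X, y, small_registry(("random_forest", "extra_trees")),
            TrainConfig(n_rounds=2, feature_preselect_grid=(15,)),
        )
        assert tree_feature_importance(bundle).sum() == pytest.approx(1.0, abs=1e-9)

    def test_balanced_accuracy_confusion(self):
        y_true = [1] * 10 + [0] * 10
        y_pred = [1] * 9 + [0] + [0] * 8 + [1] * 2
        m = evaluate_holdout(y_true, y_pred)
        assert m["balanced_accuracy"] == pytest.approx(0.85)
        assert (m["tp"], m["fn"], m["tn"], m["fp"]) == (9, 1, 8, 2)

    def test_perfect_and_constant_classifiers(self):
        assert evaluate_holdout([1, 0], [1, 0])["balanced_accuracy"] == 1.0
        assert (
            evaluate_holdout([1, 1, 0, 0], [1, 1, 1, 1])["balanced_accuracy"] == 0.5
        )

    def test_loocv_on_separable_data(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"f": np.concatenate([rng.random(10), rng.random(10) + 5])})
        y = [0] * 10 + [1] * 10
        m = evaluate_loocv(DecisionTreeClassifier(random_state=0), X, y)
        assert m["balanced_accuracy"] == 1.0


class TestRelevanceScore:
    def test_four_of_five(self):
        assert relevance_score([True, True, True, True, False]) == pytest.approx(0.8)

    def test_extremes(self):
        assert relevance_score([True] * 5) == 1.0
        assert relevance_score([False] * 5) == 0.0

    def test_named_factors(self):
        factors = {
            "new_pathway_link": True,
            "new_disease_link": True,
            "mutated_tmd_jmd": True,
            "new_protein_family": True,
            "dissimilar_tmd_jmd": False,
        }
        assert relevance_score(factors) == pytest.approx(0.8)

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError):
            relevance_score([True, False])
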