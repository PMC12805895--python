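"""The glass-box boosted classifier: fit, decompose, tune, persist."""

import numpy as np
import pandas as pd
import pytest

from lncboost.model import (
    HyperParams,
    LabeledDataset,
    ModelBundle,
    SearchSpace,
    classify,
    decision_scores,
    feature_contributions,
    predict_proba,
    retrain_final,
    term_contributions,
    train,
    tune,
    load_trial_ledger,
)
from lncboost.evaluation import roc_auc, stratified_split
from lncboost.simulate import make_labeled_dataset

HP = HyperParams(learning_rate=0.1, max_rounds=120, seed=0)


@pytest.fixture(scope="module")
def separable():
    data, truth = make_labeled_dataset(
        n=900, n_positive=300, n_features=8, n_informative=1, effect=6.0, seed=4
    )
    return data, truth


@pytest.fixture(scope="module")
def fitted(separable):
    data, _ = separable
    part = stratified_split(data.labels, seed=4)
    bundle = train(data.subset(part.train), HP)
    return data, part, bundle


class TestTrain:
    def test_separable_data_held_out_accuracy(self, fitted):
        data, part, bundle = fitted
        held = np.concatenate([part.test, part.validation])
        calls = classify(predict_proba(bundle, data.features.iloc[held]))
        assert np.mean(calls == data.labels[held]) > 0.99

    def test_permuted_labels_give_chance_auc(self):
        data, _ = make_labeled_dataset(
            n=1200, n_positive=600, n_features=6, n_informative=2, effect=3.0,
            seed=8,
        )
        rng = np.random.default_rng(8)
        shuffled = rng.permutation(data.labels)
        null = LabeledDataset(data.features, shuffled)
        part = stratified_split(null.labels, seed=8)
        bundle = train(null.subset(part.train), HP)
        held = np.concatenate([part.test, part.validation])
        auc = roc_auc(predict_proba(bundle, null.features.iloc[held]),
                      null.labels[held])
        assert 0.45 <= auc <= 0.55

    def test_same_seed_identical_predictions(self, separable):
        data, _ = separable
        b1 = train(data, HP)
        b2 = train(data, HP)
        assert np.array_equal(predict_proba(b1, data.features),
                              predict_proba(b2, data.features))

    def test_single_class_rejected(self, separable):
        data, _ = separable
        ones = LabeledDataset(data.features, np.ones(len(data), dtype=int))
        with pytest.raises(ValueError, match="single class"):
            train(ones, HP)

    def test_missing_values_rejected(self, separable):
        data, _ = separable
        x = data.features.copy()
        x.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            train(LabeledDataset(x, data.labels), HP)

    def test_training_never_resamples(self, separable):
        data, _ = separable
        before = np.bincount(data.labels)
        train(data, HP)
        assert np.array_equal(np.bincount(data.labels), before)

    def test_calibration_near_prevalence(self, separable):
        data, _ = separable
        bundle = train(data, HP)
        assert predict_proba(bundle, data.features).mean() == pytest.approx(
            data.labels.mean(), abs=0.05
        )

    def test_interaction_terms_trainable(self, separable):
        data, _ = separable
        hp = HyperParams(learning_rate=0.1, max_rounds=60,
                         interaction_depth=2, seed=0)
        bundle = train(data, hp)
        assert len(bundle.pair_terms) == 2
        p = predict_proba(bundle, data.features)
        assert np.all((p >= 0) & (p <= 1))


class TestPredict:
    def test_probabilities_bounded_and_order_preserved(self, fitted):
        data, _, bundle = fitted
        p = predict_proba(bundle, data.features)
        assert len(p) == len(data)
        assert np.all((p >= 0) & (p <= 1))

    def test_identical_rows_identical_probabilities(self, fitted):
        data, _, bundle = fitted
        row = data.features.iloc[[0]]
        rep = pd.concat([row] * 5, ignore_index=True)
        rep.columns = data.features.columns
        assert len(np.unique(predict_proba(bundle, rep))) == 1

    def test_positive_scores_dominate_negative(self, fitted):
        data, part, bundle = fitted
        held = np.concatenate([part.test, part.validation])
        p = predict_proba(bundle, data.features.iloc[held])
        y = data.labels[held]
        pos, neg = p[y == 1], p[y == 0]
        wins = (pos[:, None] > neg[None, :]).mean()
        assert wins > 0.99

    def test_additive_decomposition_reaches_probability(self, fitted):
        data, _, bundle = fitted
        x = data.features.iloc[:50]
        contribs = term_contributions(bundle, x)
        logit = bundle.intercept + contribs.sum(axis=1).to_numpy()
        assert 1 / (1 + np.exp(-logit)) == pytest.approx(
            predict_proba(bundle, x), abs=1e-9
        )
        assert decision_scores(bundle, x) == pytest.approx(logit, abs=1e-9)

    def test_schema_mismatch_names_offending_columns(self, fitted):
        data, _, bundle = fitted
        wrong = data.features.rename(columns={"f000": "banana"})
        with pytest.raises(ValueError) as err:
            predict_proba(bundle, wrong)
        assert "f000" in str(err.value) and "banana" in str(err.value)


class TestClassify:
    def test_threshold_boundary_is_inclusive(self):
        assert classify(np.array([0.5]), 0.5).tolist() == [1]
        assert classify(np.array([0.49]), 0.5).tolist() == [0]

    def test_vector_example(self):
        assert classify(np.array([0.1, 0.9, 0.5])).tolist() == [0, 1, 1]

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            classify(np.array([0.5]), 1.5)


class TestContributions:
    def test_planted_feature_ranked_first(self, separable, fitted):
        _, truth = separable
        _, _, bundle = fitted
        ranked = feature_contributions(bundle)
        assert ranked[0][0] == truth.planted_features[0]

    def test_constant_feature_scores_zero(self, separable):
        data, _ = separable
        x = data.features.copy()
        x["constant"] = 1.0
        bundle = train(LabeledDataset(x, data.labels), HP)
        scores = dict(feature_contributions(bundle))
        assert scores["constant"] == 0.0

    def test_invariant_under_row_shuffling(self, separable):
        data, _ = separable
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(data))
        shuffled = LabeledDataset(
            data.features.iloc[perm], data.labels[perm]
        )
        c1 = feature_contributions(train(data, HP))
        c2 = feature_contributions(train(shuffled, HP))
        for (n1, s1), (n2, s2) in zip(c1, c2):
            assert n1 == n2
            assert s1 == pytest.approx(s2, abs=1e-9)


class TestPersistence:
    def test_round_trip_reproduces_predictions_bit_exactly(
        self, fitted, tmp_path
    ):
        data, _, bundle = fitted
        p = tmp_path / "model.json"
        bundle.save(p)
        back = ModelBundle.load(p)
        assert np.array_equal(predict_proba(back, data.features),
                              predict_proba(bundle, data.features))
        assert back.schema_fingerprint == bundle.schema_fingerprint
        assert back.hyperparams == bundle.hyperparams


class TestTune:
    def test_collapsed_space_returns_single_config(self, separable):
        data, _ = separable
        part = stratified_split(data.labels, seed=4)
        only = HyperParams(learning_rate=0.2, max_rounds=30, seed=4)
        best, ledger = tune(data.subset(part.train), data.subset(part.test),
                            [only], n_trials=1, seed=4)
        assert best == only
        assert len(ledger) == 1

    def test_deterministic_and_argmax(self, separable, tmp_path):
        data, _ = separable
        part = stratified_split(data.labels, seed=4)
        space = SearchSpace(max_rounds=(20, 60), interaction_depth=(0, 1))
        args = dict(n_trials=6, seed=9)
        b1, l1 = tune(data.subset(part.train), data.subset(part.test), space,
                      ledger_path=tmp_path / "ledger.jsonl", **args)
        b2, l2 = tune(data.subset(part.train), data.subset(part.test), space,
                      **args)
        assert b1 == b2
        assert l1 == l2
        assert load_trial_ledger(tmp_path / "ledger.jsonl") == l1
        best_precision = max(e["precision"] for e in l1)
        assert dict(l1[0]["params"], seed=9)  # ledger is self-describing
        assert best_precision == [e for e in l1 if e["params"] ==
                                  b1.__dict__][0]["precision"]

    def test_overlapping_train_eval_rejected(self, separable):
        data, _ = separable
        with pytest.raises(ValueError, match="overlap"):
            tune(data, data, n_trials=1, seed=0)


class TestRetrainFinal:
    def test_fits_on_union_and_guards_leakage(self, separable):
        data, _ = separable
        part = stratified_split(data.labels, fractions=(0.70, 0.15, 0.15),
                                seed=4)
        tr, te = data.subset(part.train), data.subset(part.test)
        bundle = retrain_final(tr, te, HP)
        combined = tr.concat(te)
        direct = train(combined, HP)
        assert np.array_equal(predict_proba(bundle, data.features),
                              predict_proba(direct, data.features))
        with pytest.raises(ValueError, match="overlap"):
            retrain_final(tr, tr, HP)

    def test_validation_rows_disjoint_from_refit(self, separable):
        data, _ = separable
        part = stratified_split(data.labels, seed=4)
        refit_ids = set(data.features.index[part.train]) | set(
            data.features.index[part.test]
        )
        val_ids = set(data.features.index[part.validation])
        assert refit_ids.isdisjoint(val_ids)
        assert len(refit_ids) + len(val_ids) == len(data)
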