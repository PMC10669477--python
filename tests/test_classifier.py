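"""Classifier: split arithmetic, training behaviour, prediction contracts."""

from __future__ import annotations

import numpy as np
import pytest

from bbbeeg.classifier import (CLASS_LABELS, BandPowerClassifier,
                               ClassifierResults, ClassifierSpec, TrainConfig,
                               split_dataset)
from bbbeeg.pipeline import corpus_feature_table
from bbbeeg.recording import ConfigurationError


class TestSplit:
    def test_715_per_class_gives_500_215(self, rng):
        X = rng.normal(size=(1430, 5))
        y = np.repeat([0, 1], 715)
        Xtr, ytr, Xte, yte, counts = split_dataset(X, y, 0.70, seed=0)
        assert counts == {0: (500, 215), 1: (500, 215)}
        assert len(Xtr) == 1000 and len(Xte) == 430

    def test_10_per_class_gives_7_3(self, rng):
        X = rng.normal(size=(20, 5))
        y = np.repeat([0, 1], 10)
        *_, counts = split_dataset(X, y, 0.70, seed=1)
        assert counts == {0: (7, 3), 1: (7, 3)}

    def test_partition_property(self, rng):
        """Train and test form a disjoint cover of the full set."""
        X = np.arange(40, dtype=float).reshape(-1, 1) @ np.ones((1, 5))
        y = np.repeat([0, 1], 20)
        Xtr, _, Xte, _, _ = split_dataset(X, y, 0.70, seed=2)
        ids = np.concatenate([Xtr[:, 0], Xte[:, 0]])
        assert sorted(ids) == sorted(X[:, 0])

    def test_empty_class_rejected(self):
        with pytest.raises(ConfigurationError):
            split_dataset(np.zeros((3, 5)), np.array([0, 0, 1]), 0.7, 0)


class TestTraining:
    def test_overfits_eight_examples(self, rng):
        """Capacity sanity: a single batch of 8 is memorised within 500
        epochs."""
        X = rng.normal(size=(8, 5))
        y = np.array([0, 1] * 4)
        model = BandPowerClassifier(X, y)
        res = model.fit(TrainConfig(epochs=500, batch_size=8, seed=0))
        assert res.final_train_accuracy == 1.0

    def test_seed_reproducible(self, rng):
        X = rng.normal(size=(40, 5))
        y = np.repeat([0, 1], 20)
        cfg = TrainConfig(epochs=30, seed=3)
        a = BandPowerClassifier(X, y).fit(cfg)
        b = BandPowerClassifier(X, y).fit(cfg)
        assert np.array_equal(a.train_accuracy, b.train_accuracy)
        assert all(np.array_equal(p, q) for p, q in zip(a.params, b.params))

    def test_accuracy_curves_have_epoch_length(self, rng):
        X = rng.normal(size=(20, 5))
        y = np.repeat([0, 1], 10)
        res = BandPowerClassifier(X, y).fit(TrainConfig(epochs=17, seed=0))
        assert len(res.train_accuracy) == 17
        assert np.all((res.train_accuracy >= 0) & (res.train_accuracy <= 1))

    def test_nonfinite_features_rejected(self):
        X = np.full((4, 5), np.nan)
        with pytest.raises(ConfigurationError, match="non-finite"):
            BandPowerClassifier(X, np.array([0, 1, 0, 1]))

    def test_matches_sklearn_on_separable_surrogate(self, trained, std_corpus):
        """Independent cross-check: a generic sklearn MLP on the same
        features also finds the classes separable."""
        from sklearn.neural_network import MLPClassifier
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        from bbbeeg.features import feature_matrix
        results, _ = trained
        table = corpus_feature_table(std_corpus)
        X = feature_matrix(table)
        y = (table.loc[table["valid"], "label"] == "artificial_obbb").to_numpy(int)
        Xtr, ytr, Xte, yte, _ = split_dataset(X, y, 0.70, seed=0)
        clf = make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=(50,), max_iter=600,
                          random_state=0)).fit(Xtr, ytr)
        assert clf.score(Xte, yte) >= 0.85
        assert results.final_test_accuracy >= 0.85


class TestPrediction:
    def test_softmax_outputs_sum_to_one(self, trained, rng):
        results, _ = trained
        proba = results.predict_proba(rng.normal(0.2, 0.05, size=(50, 5)))
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((proba >= 0) & (proba <= 1))

    def test_obbb_centroid_scores_above_half(self, trained, std_corpus):
        table = corpus_feature_table(std_corpus)
        from bbbeeg.features import FEATURE_COLUMNS
        centroid = (table[table["label"] == "artificial_obbb"]
                    .loc[:, list(FEATURE_COLUMNS)].mean().to_numpy())
        results, _ = trained
        assert results.predict_proba(centroid[None, :])[0, 1] > 0.5

    def test_invalid_windows_become_gaps_not_zeros(self, trained, short_recording):
        import pandas as pd

        from bbbeeg.features import extract_features
        results, _ = trained
        table = extract_features(short_recording, normalization=1)
        table.loc[table.index[3], "valid"] = False
        resp = results.predict_response(table)
        assert np.isnan(resp["response"].iloc[3])
        assert np.isfinite(resp["response"].drop(resp.index[3])).all()


class TestPersistence:
    def test_save_load_round_trip(self, trained, tmp_path, rng):
        results, _ = trained
        path = results.save(tmp_path / "model.json")
        loaded = ClassifierResults.load(path)
        X = rng.normal(0.2, 0.05, size=(20, 5))
        assert np.allclose(loaded.predict_proba(X), results.predict_proba(X))
        assert loaded.model.spec == results.model.spec

    def test_summary_mentions_architecture(self, trained):
        results, _ = trained
        text = results.summary()
        assert "5-150-2" in text and "SELU" in text
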