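"""LSTM classifier: softmax contract, learning on separable data, splits, CV."""

import numpy as np
import pytest

from preictal.io import SeizureEvent
from preictal.model import (
    LSTMClassifier,
    ModelConfig,
    kfold_cv,
    loocv_by_seizure,
    predict_samples,
    split_first_k_seizures,
    train,
)
from preictal.staging import Stage


def separable_xy(rng, n_per_class=150, T=20, C=3, offset=5.0):
    X0 = rng.normal(0.0, 1.0, (n_per_class, T, C))
    X1 = rng.normal(offset, 1.0, (n_per_class, T, C))
    X = np.concatenate([X0, X1])
    y = np.array(["interictal"] * n_per_class + ["preictal"] * n_per_class)
    return X, y


class TestArchitectureContract:
    def test_probabilities_sum_to_one(self, rng):
        X, y = separable_xy(rng, n_per_class=30)
        clf = LSTMClassifier(n_units=8, max_epochs=2, random_state=0).fit(X, y)
        p = clf.predict_proba(np.zeros((5, 20, 3)))
        assert p.shape == (5, 2)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_three_classes_give_three_outputs(self, rng):
        X = rng.normal(0, 1, (60, 10, 2))
        y = np.array(["interictal", "preictal", "postictal"] * 20)
        clf = LSTMClassifier(n_units=8, max_epochs=2, random_state=0).fit(X, y)
        assert clf.predict_proba(X[:4]).shape == (4, 3)

    def test_invalid_dropout_rejected(self, rng):
        X, y = separable_xy(rng, n_per_class=10)
        with pytest.raises(ValueError, match="dropout"):
            LSTMClassifier(dropout=1.0).fit(X, y)
        with pytest.raises(ValueError, match="dropout"):
            ModelConfig(dropout=1.0)

    def test_single_class_rejected(self, rng):
        X = rng.normal(0, 1, (20, 10, 2))
        with pytest.raises(ValueError, match="single class"):
            LSTMClassifier().fit(X, np.array(["preictal"] * 20))

    def test_wrong_channel_count_rejected(self, rng):
        X, y = separable_xy(rng, n_per_class=20)
        clf = LSTMClassifier(n_units=4, max_epochs=1, random_state=0).fit(X, y)
        with pytest.raises(ValueError, match="channels"):
            clf.predict(np.zeros((2, 20, 5)))

    def test_empty_prediction(self, rng, sample_factory):
        samples = sample_factory(
            {Stage.PREICTAL: 20, Stage.INTERICTAL: 20}, n_points=16
        )
        cfg = ModelConfig.reduced(
            input_len=16, n_channels=3, time_pool=1, max_epochs=1
        )
        clf = train(samples, cfg)
        proba, labels = predict_samples(clf, [])
        assert len(labels) == 0 and proba.shape[0] == 0


class TestLearning:
    def test_separable_classes_learned(self, rng):
        X, y = separable_xy(rng)
        clf = LSTMClassifier(n_units=16, max_epochs=30, random_state=0).fit(X, y)
        assert np.mean(clf.predict(X) == y) >= 0.95

    def test_normalization_stats_from_training_only(self, rng):
        X, y = separable_xy(rng, n_per_class=40)
        clf = LSTMClassifier(n_units=4, max_epochs=1, random_state=0).fit(X, y)
        mean_before = clf.norm_mean_.copy()
        clf.predict(rng.normal(100.0, 1.0, (10, 20, 3)))
        assert np.array_equal(clf.norm_mean_, mean_before)

    def test_label_shuffled_data_near_chance(self, rng):
        """Null-signal calibration: shuffled labels give ~coin-flip rates."""
        from preictal.evaluation import segment_metrics

        sens, spec = [], []
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = r.normal(0.0, 1.0, (240, 12, 2))
            y = np.array(["interictal", "preictal"] * 120)
            r.shuffle(y)
            clf = LSTMClassifier(
                n_units=8, max_epochs=5, random_state=seed
            ).fit(X[:160], y[:160])
            pred = clf.predict(X[160:])
            m = segment_metrics(
                [Stage(v) for v in y[160:]], [Stage(v) for v in pred]
            )
            sens.append(m.sensitivity)
            spec.append(m.specificity)
        assert 0.35 <= np.mean(sens) <= 0.65
        assert 0.35 <= np.mean(spec) <= 0.65

    def test_rms_pooling_preserves_power_contrast(self, rng):
        # interictal and preictal differ in variance, not mean: raw mean
        # pooling would erase the contrast, RMS pooling keeps it
        n, T, C = 100, 64, 2
        X0 = rng.normal(0, 1.0, (n, T, C))
        X1 = rng.normal(0, 2.0, (n, T, C))
        X = np.concatenate([X0, X1])
        y = np.array(["interictal"] * n + ["preictal"] * n)
        clf = LSTMClassifier(
            n_units=8, max_epochs=15, time_pool=8, random_state=0
        ).fit(X, y)
        assert np.mean(clf.predict(X) == y) >= 0.9


class TestSplits:
    def _samples_events(self, sample_factory):
        # 4 leading seizures at hours 4, 14, 24, 34; preictal hour before each
        events = []
        samples = []
        for i in range(4):
            onset = (4 + 10 * i) * 3600.0
            events.append(SeizureEvent(onset, onset + 60.0, leading=True))
            samples += sample_factory(
                {Stage.PREICTAL: 6}, n_points=16, start_s=onset - 3600.0
            )
            samples += sample_factory(
                {Stage.POSTICTAL: 6}, n_points=16, start_s=onset + 60.0
            )
            samples += sample_factory(
                {Stage.INTERICTAL: 10}, n_points=16, start_s=onset - 10000.0
            )
        return samples, events

    def test_first_two_split_test_from_later_seizures(self, sample_factory):
        samples, events = self._samples_events(sample_factory)
        train_set, test_set = split_first_k_seizures(samples, events, k=2)
        boundary = events[2].onset_s
        test_pre = [s for s in test_set if s.stage is Stage.PREICTAL]
        assert test_pre and all(s.start_s >= boundary - 3600.0 for s in test_pre)
        train_keys = {s.key for s in train_set}
        test_keys = {s.key for s in test_set}
        assert not train_keys & test_keys
        assert len(train_set) + len(test_set) == len(samples)

    def test_variant_recipe_trains_on_postictal(self, sample_factory):
        samples, events = self._samples_events(sample_factory)
        train_set, test_set = split_first_k_seizures(
            samples, events, k=2, train_on="postictal+interictal"
        )
        assert all(
            s.stage in (Stage.POSTICTAL, Stage.INTERICTAL) for s in train_set
        )
        # the test half is unchanged by the recipe
        _, test_default = split_first_k_seizures(samples, events, k=2)
        assert {s.key for s in test_set} == {s.key for s in test_default}
        with pytest.raises(ValueError, match="train_on"):
            split_first_k_seizures(samples, events, k=2, train_on="ictal")

    def test_checkpoint_round_trip(self, rng, tmp_path):
        X, y = separable_xy(rng, n_per_class=40)
        clf = LSTMClassifier(n_units=8, max_epochs=5, random_state=0).fit(X, y)
        clf.save(tmp_path / "model")
        back = LSTMClassifier.load(tmp_path / "model")
        assert np.allclose(back.predict_proba(X), clf.predict_proba(X))

    def test_split_needs_enough_seizures(self, sample_factory):
        samples, events = self._samples_events(sample_factory)
        with pytest.raises(ValueError, match="leading seizures"):
            split_first_k_seizures(samples, events, k=4)

    def test_kfold_bookkeeping(self, sample_factory):
        samples = sample_factory(
            {Stage.PREICTAL: 50, Stage.INTERICTAL: 50}, n_points=16
        )
        cfg = ModelConfig.reduced(
            input_len=16, n_channels=3, time_pool=1, max_epochs=1, seed=0
        )
        folds = kfold_cv(samples, k=10, config=cfg)
        assert len(folds) == 10
        assert all(f.n == 10 for f in folds)
        assert sum(f.n for f in folds) == 100

    def test_kfold_too_few_samples(self, sample_factory):
        samples = sample_factory(
            {Stage.PREICTAL: 4, Stage.INTERICTAL: 4}, n_points=16
        )
        with pytest.raises(ValueError):
            kfold_cv(samples, k=10)

    def test_loocv_round_per_leading_seizure(self, sample_factory):
        samples, events = self._samples_events(sample_factory)
        cfg = ModelConfig.reduced(
            input_len=16, n_channels=3, time_pool=1, max_epochs=2, seed=0
        )
        rounds = loocv_by_seizure(samples, events, cfg)
        assert len(rounds) == 4
        # every preictal sample is predicted exactly once across rounds
        predicted = [
            s.key
            for r in rounds
            for s in r.test_samples
            if s.stage is Stage.PREICTAL
        ]
        expected = [s.key for s in samples if s.stage is Stage.PREICTAL]
        assert sorted(predicted) == sorted(expected)

    def test_loocv_needs_two_seizures(self, sample_factory):
        samples = sample_factory(
            {Stage.PREICTAL: 5, Stage.INTERICTAL: 5}, n_points=16
        )
        with pytest.raises(ValueError, match="at least 2"):
            loocv_by_seizure(
                samples, [SeizureEvent(100.0, 160.0, leading=True)]
            )
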