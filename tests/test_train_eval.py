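"""Training loop contracts and the four evaluation metrics."""

import numpy as np
import pytest

import p300fuse as pf
from p300fuse.errors import DomainError
from p300fuse.model import build_cnn
from p300fuse.train_eval import (ConfusionCounts, metrics_from_counts,
                                 stratified_split_indices)


def _toy_epochs(n=24, n_time=12, n_channels=4, separable=True, seed=0):
    """Tiny normalized epoch set; class 1 carries an additive deflection."""
    rng = np.random.default_rng(seed)
    labels = (np.arange(n) % 2).astype(bool)
    data = rng.standard_normal((n, n_time, n_channels)) * 0.3
    if separable:
        data[labels, 2:6, :] += 2.0
    return pf.EpochSet(data=data, labels=labels, sampling_rate=120.0,
                       subject_id="S1", normalized=True)


class TestMetrics:
    def test_hand_computed_confusion_case(self):
        m = metrics_from_counts(ConfusionCounts(tp=3, tn=5, fp=1, fn=1))
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["recall"] == pytest.approx(0.75)
        assert m["precision"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(0.75)

    def test_f1_harmonic_mean(self):
        # recall 0.75, precision 0.6 -> F1 = 2*0.75*0.6/1.35
        m = metrics_from_counts(ConfusionCounts(tp=3, tn=0, fp=2, fn=1))
        assert m["recall"] == pytest.approx(0.75)
        assert m["precision"] == pytest.approx(0.6)
        assert m["f1"] == pytest.approx(0.666667, abs=1e-6)

    def test_perfect_predictions(self):
        m = metrics_from_counts(ConfusionCounts(tp=4, tn=6, fp=0, fn=0))
        assert all(m[k] == 1.0 for k in
                   ("accuracy", "recall", "precision", "f1"))

    def test_zero_denominator_reports_zero_with_warning(self):
        with pytest.warns(UserWarning, match="undefined"):
            m = metrics_from_counts(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert m["recall"] == 0.0 and m["precision"] == 0.0 and m["f1"] == 0.0

    def test_agrees_with_brute_force_tally(self, rng):
        """Metric formulas vs an independent per-sample tally oracle."""
        for _ in range(100):
            n = int(rng.integers(1, 200))
            y = rng.integers(0, 2, n)
            pred = rng.integers(0, 2, n)
            tp = sum(1 for a, b in zip(pred, y) if a == 1 and b == 1)
            tn = sum(1 for a, b in zip(pred, y) if a == 0 and b == 0)
            fp = sum(1 for a, b in zip(pred, y) if a == 1 and b == 0)
            fn = sum(1 for a, b in zip(pred, y) if a == 0 and b == 1)
            with np.errstate(all="ignore"):
                import warnings
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    m = metrics_from_counts(ConfusionCounts(tp, tn, fp, fn))
            assert m["accuracy"] == pytest.approx((tp + tn) / n)
            if tp + fn:
                assert m["recall"] == pytest.approx(tp / (tp + fn))
            if tp + fp:
                assert m["precision"] == pytest.approx(tp / (tp + fp))
            assert 0 <= m["f1"] <= 1

    def test_negative_counts_rejected(self):
        with pytest.raises(DomainError):
            ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)


class TestTrain:
    def test_loss_history_length_and_descent(self):
        es = _toy_epochs()
        net, _ = build_cnn(12, 4, seed=0)
        cfg = pf.TrainConfig(epochs=8, batch_size=8, seed=1)
        _, history = pf.train(net, es, cfg)
        assert len(history) == 8
        assert history[-1] <= history[0]

    def test_single_class_rejected(self):
        es = _toy_epochs()
        es.labels[:] = False
        net, _ = build_cnn(12, 4)
        with pytest.raises(DomainError, match="single class"):
            pf.train(net, es, pf.TrainConfig(epochs=1))

    def test_oversized_batch_is_one_batch_per_epoch(self):
        es = _toy_epochs(n=10)
        net, _ = build_cnn(12, 4, seed=0)
        _, history = pf.train(net, es, pf.TrainConfig(epochs=2, batch_size=999))
        assert len(history) == 2

    def test_default_config_mirrors_published_hyperparameters(self):
        cfg = pf.TrainConfig()
        assert (cfg.optimizer, cfg.learning_rate, cfg.epochs, cfg.batch_size) \
            == ("adam", 0.001, 75, 32)
        assert cfg.loss == "categorical_crossentropy"

    def test_invalid_config_rejected(self):
        with pytest.raises(DomainError):
            pf.TrainConfig(learning_rate=0.0)
        with pytest.raises(DomainError):
            pf.TrainConfig(epochs=0)


class TestEvaluate:
    def test_counts_sum_to_test_size(self):
        es = _toy_epochs(n=20)
        net, _ = build_cnn(12, 4, seed=0)
        pf.train(net, es, pf.TrainConfig(epochs=5, batch_size=8, seed=0))
        counts, metrics = pf.evaluate(net, es)
        assert counts.total == 20
        assert all(0.0 <= metrics[k] <= 1.0 for k in metrics)

    def test_separable_toy_is_learned(self):
        es = _toy_epochs(n=32)
        net, _ = build_cnn(12, 4, seed=0)
        pf.train(net, es, pf.TrainConfig(epochs=20, batch_size=8, seed=0))
        _, metrics = pf.evaluate(net, es)
        assert metrics["accuracy"] >= 0.9


class TestSplitAndExperiment:
    def test_stratified_split_shares_event_indices(self):
        labels = np.arange(60) % 6 == 0
        tr, te = stratified_split_indices(labels, 0.2, seed=1)
        assert len(tr) + len(te) == 60
        assert not set(tr) & set(te)
        # stratification keeps the 1:5 class ratio in both halves
        assert labels[te].sum() == 2 and labels[tr].sum() == 8

    def test_single_mode_rows(self, small_epoch_sets):
        cfg = pf.TrainConfig(epochs=2, batch_size=16, seed=0)
        table = pf.run_group_experiment(small_epoch_sets, mode="single",
                                        config=cfg)
        assert list(table["group"]) == ["S1", "S2", "Average"]
        assert set(table.columns) >= {"accuracy", "recall", "precision", "f1"}
        body = table.iloc[:-1]
        avg = table.iloc[-1]
        assert avg["accuracy"] == pytest.approx(body["accuracy"].mean())

    def test_parallel_mode_group_rows(self, small_epoch_sets):
        cfg = pf.TrainConfig(epochs=2, batch_size=16, seed=0)
        table = pf.run_group_experiment(small_epoch_sets, group_size=2,
                                        mode="parallel", config=cfg)
        assert list(table["group"]) == ["C1", "Average"]
        assert (table["mode"] == "parallel").all()

    def test_unknown_mode_rejected(self, small_epoch_sets):
        with pytest.raises(DomainError):
            pf.run_group_experiment(small_epoch_sets, mode="voting")
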