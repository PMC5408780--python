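import numpy as np
import pytest

from subcell.network import build_network
from subcell.preprocess import CellCrop
from subcell.training import (DataError, LabeledDataset, TrainConfig,
                              TransferConfig, accuracy, dataset_from_crops,
                              feature_classifier_baselines, lr_schedule,
                              sample_per_class, train, transfer)

from conftest import SMALL_MODEL_CONFIG


class TestLrSchedule:
    CFG = TrainConfig()

    def test_start_value(self):
        assert lr_schedule(0, self.CFG) == 0.1

    def test_first_decay(self):
        assert lr_schedule(25, self.CFG) == pytest.approx(0.096)

    def test_staircase_holds_within_window(self):
        assert lr_schedule(24, self.CFG) == 0.1
        assert lr_schedule(49, self.CFG) == pytest.approx(0.096)

    def test_iteration_50(self):
        assert lr_schedule(50, self.CFG) == pytest.approx(0.1 * 0.96 ** 2)

    def test_nonincreasing_piecewise_constant(self):
        vals = [lr_schedule(i, self.CFG) for i in range(200)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        for start in range(0, 200, 25):
            assert len(set(vals[start:start + 25])) == 1

    def test_negative_iteration(self):
        with pytest.raises(ValueError):
            lr_schedule(-1, self.CFG)


class TestSamplePerClass:
    y = np.array([0] * 3 + [1] * 100)

    def test_with_replacement_when_scarce(self):
        idx = sample_per_class(self.y, 5, seed=0)
        cls0 = idx[:5]
        assert len(cls0) == 5
        assert len(set(cls0.tolist())) <= 3  # repeats forced

    def test_without_replacement_when_plentiful(self):
        idx = sample_per_class(self.y, 5, seed=0)
        cls1 = idx[5:]
        assert len(set(cls1.tolist())) == 5

    def test_deterministic(self):
        np.testing.assert_array_equal(sample_per_class(self.y, 4, seed=3),
                                      sample_per_class(self.y, 4, seed=3))

    def test_zero_sample_class(self):
        with pytest.raises(DataError):
            sample_per_class(np.array([0, 0]), 2, seed=0, n_classes=2)


def _toy_dataset(n_per_class=8, n_classes=3, seed=0, size=64):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in range(n_classes):
        for _ in range(n_per_class):
            img = rng.random((2, size, size), dtype=np.float32) * 0.1
            img[0, 10 + 10 * c:20 + 10 * c, :] += 0.8  # class-specific band
            X.append(np.clip(img, 0, 1))
            y.append(c)
    return LabeledDataset(np.stack(X), np.array(y), tuple("abc"[:n_classes]))


TINY = SMALL_MODEL_CONFIG.__class__(
    input_size=60, in_channels=2, conv_widths=(4,), pool_after=frozenset({1}),
    fc_widths=(8,), n_classes=3)


class TestTrain:
    def test_zero_iters_returns_initialized_network(self):
        net = build_network(TINY, seed=0)
        ds = _toy_dataset()
        best, log = train(net, ds, TrainConfig(max_iters=0, batch_size=4), ds)
        assert log.empty
        for k, v in net.state_dict().items():
            np.testing.assert_array_equal(v, best.state_dict()[k])

    def test_empty_class_rejected(self):
        ds = _toy_dataset()
        ds.class_names = ("a", "b", "c", "ghost")
        net = build_network(TINY, seed=0)
        with pytest.raises(DataError, match="ghost"):
            train(net, ds, TrainConfig(max_iters=1, batch_size=4), ds)

    def test_deterministic_loss_trajectory(self):
        ds = _toy_dataset()
        cfg = TrainConfig(max_iters=8, batch_size=4, checkpoint_every=4, seed=5)
        logs = []
        for _ in range(2):
            net = build_network(TINY, seed=9)
            _, log = train(net, ds, cfg, ds)
            logs.append(log["loss"].to_numpy())
        np.testing.assert_array_equal(logs[0], logs[1])

    def test_log_schema(self):
        net = build_network(TINY, seed=0)
        ds = _toy_dataset()
        _, log = train(net, ds, TrainConfig(max_iters=6, batch_size=4,
                                            checkpoint_every=3), ds)
        assert list(log.columns) == ["iteration", "lr", "loss", "val_accuracy"]
        assert log["val_accuracy"].notna().sum() == 2  # iters 3 and 6

    def test_model_selection_returns_best_checkpoint(self):
        net = build_network(TINY, seed=1)
        ds = _toy_dataset(n_per_class=6)
        cfg = TrainConfig(max_iters=20, batch_size=6, checkpoint_every=5,
                          base_lr=0.01, seed=2)
        best, log = train(net, ds, cfg, ds)
        best_acc = accuracy(best, ds)
        checkpoint_accs = log["val_accuracy"].dropna()
        assert best_acc == pytest.approx(checkpoint_accs.max())


class TestTrainedModel:
    def test_heldout_accuracy_at_least_90pct(self, trained_model):
        assert trained_model["test_accuracy"] >= 0.90

    def test_selected_checkpoint_is_argmax(self, trained_model, small_datasets):
        log = trained_model["log"]
        ck = log["val_accuracy"].dropna()
        assert len(ck) == 3  # every 500 of 1500
        kept = accuracy(trained_model["network"], small_datasets["val"])
        assert kept == pytest.approx(ck.max())


class TestTransfer:
    def test_zero_iters_uses_frozen_features(self, trained_model, transfer_datasets):
        cfg = TransferConfig(iters=0, n_resamplings=1, samples_per_class=2,
                             batch_size=8, seed=0)
        net, accs = transfer(trained_model["network"],
                             transfer_datasets["train"],
                             transfer_datasets["test"], cfg)
        # all non-final layers must equal the pretrained weights exactly
        pre = trained_model["network"].state_dict()
        post = net.state_dict()
        for k in pre:
            if not k.startswith("out."):
                np.testing.assert_array_equal(pre[k], post[k])
        assert len(accs) == 1

    def test_invalid_init(self, trained_model, transfer_datasets):
        with pytest.raises(ValueError, match="init"):
            transfer(trained_model["network"], transfer_datasets["train"],
                     transfer_datasets["test"], TransferConfig(), init="magic")

    def test_full_set_transfer_close_to_plain_training(self, trained_model,
                                                       transfer_datasets):
        # n_per_class = full pool: transfer accuracy should be within noise of
        # scratch training on the same (full) data under the identical budget
        n_full = int(np.bincount(transfer_datasets["train"].y).max())
        cfg = TransferConfig(iters=120, batch_size=32, n_resamplings=1,
                             samples_per_class=n_full, seed=3)
        _, acc_t = transfer(trained_model["network"], transfer_datasets["train"],
                            transfer_datasets["test"], cfg, init="pretrained")
        _, acc_s = transfer(trained_model["network"], transfer_datasets["train"],
                            transfer_datasets["test"], cfg, init="scratch")
        assert acc_t[0] >= acc_s[0] - 0.15


class TestFeatureBaselines:
    def test_linearly_separable_constructed_case(self):
        # two constant-input classes produce two distinct frozen fc2 feature
        # points -> every baseline separates them perfectly
        net = build_network(TINY.__class__(
            input_size=60, in_channels=2, conv_widths=(4,),
            pool_after=frozenset({1}), fc_widths=(8, 8), n_classes=2), seed=4)
        X = np.concatenate([np.zeros((6, 2, 64, 64), dtype=np.float32),
                            np.ones((6, 2, 64, 64), dtype=np.float32) * 0.9])
        y = np.array([0] * 6 + [1] * 6)
        ds = LabeledDataset(X, y, ("lo", "hi"))
        accs = feature_classifier_baselines(net, ds, ds, n_per_class=3, seed=0)
        assert set(accs) == {"knn", "linear_svm", "random_forest"}
        assert all(a >= 0.95 for a in accs.values()), accs

    def test_fine_tuning_at_least_best_baseline_at_25(self, trained_model,
                                                      transfer_datasets):
        accs = feature_classifier_baselines(trained_model["network"],
                                            transfer_datasets["train"],
                                            transfer_datasets["test"],
                                            n_per_class=25, seed=13)
        cfg = TransferConfig(samples_per_class=25, n_resamplings=1, iters=200,
                             batch_size=32, seed=13)
        _, ft = transfer(trained_model["network"], transfer_datasets["train"],
                         transfer_datasets["test"], cfg, init="pretrained")
        assert ft[0] >= max(accs.values()), (ft, accs)

    def test_knn_n1_training_accuracy_one(self, trained_model, transfer_datasets):
        train_ds = transfer_datasets["train"]
        idx = sample_per_class(train_ds.y, 1, seed=1,
                               n_classes=len(train_ds.class_names))
        sub = train_ds.subset(idx)
        accs = feature_classifier_baselines(trained_model["network"], sub, sub,
                                            n_per_class=1, seed=1)
        assert accs["knn"] == 1.0
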