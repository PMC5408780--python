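"""Training loop, learning-rate schedule, model selection, and transfer.

The full-scale recipe: Adam on cross-entropy over augmented 60x60 patches,
batch size 128, 10,000 iterations, staircase learning-rate decay of 0.96
every 25 iterations starting from 0.1, checkpoints every 500 iterations with
the best-validation-accuracy checkpoint returned. Transfer learning
re-initializes only the final layer, loads every other pretrained parameter,
adds dropout before the final layer, and fine-tunes everything with Adam at
learning rate 0.003 for a fixed budget of at least 500 iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from ._layers import softmax
from .network import ModelConfig, Network, build_network, make_optimizer
from .preprocess import CellCrop, augment_batch, eval_crop_offsets

__all__ = ["TrainConfig", "TransferConfig", "LabeledDataset", "DataError",
           "lr_schedule", "train", "sample_per_class", "transfer",
           "feature_classifier_baselines", "dataset_from_crops", "center_patches"]

log = logging.getLogger(__name__)


class DataError(ValueError):
    """Training data violates a precondition (e.g. an empty class)."""


@dataclass(frozen=True)
class TrainConfig:
    base_lr: float = 0.1
    decay: float = 0.96
    decay_every: int = 25
    batch_size: int = 128
    max_iters: int = 10_000
    checkpoint_every: int = 500
    seed: int = 0

    def __post_init__(self):
        if min(self.base_lr, self.decay, self.decay_every,
               self.batch_size, self.checkpoint_every) <= 0 or self.max_iters < 0:
            raise ValueError("all TrainConfig fields must be positive")


@dataclass(frozen=True)
class TransferConfig:
    lr: float = 0.003
    iters: int = 500                  # fixed budget, >= the protocol's minimum
    batch_size: int = 128
    final_layer_dropout: float = 0.5
    samples_per_class: int = 5
    n_resamplings: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.iters < 0 or self.lr <= 0 or self.batch_size <= 0:
            raise ValueError("invalid TransferConfig")


@dataclass
class LabeledDataset:
    """Normalized 64x64 crops with integer labels into ``class_names``."""

    X: np.ndarray                     # (N, C, 64, 64), float32 in [0, 1]
    y: np.ndarray                     # (N,) int
    class_names: tuple[str, ...]

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float32)
        self.y = np.asarray(self.y, dtype=np.int64)
        if len(self.X) != len(self.y):
            raise DataError("X and y length mismatch")

    def __len__(self):
        return len(self.X)

    def subset(self, idx) -> "LabeledDataset":
        return LabeledDataset(self.X[idx], self.y[idx], self.class_names)


def dataset_from_crops(crops: list[CellCrop],
                       class_names: tuple[str, ...]) -> LabeledDataset:
    index = {c: i for i, c in enumerate(class_names)}
    try:
        y = np.array([index[c.label] for c in crops])
    except KeyError as e:
        raise DataError(f"crop label {e} not in class vocabulary") from e
    if any(not c.normalized for c in crops):
        raise DataError("crops must be normalized before training")
    return LabeledDataset(np.stack([c.pixels for c in crops]), y, tuple(class_names))


def lr_schedule(iteration: int, cfg: TrainConfig) -> float:
    """Staircase decay: base_lr * decay ** floor(iteration / decay_every)."""
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    return cfg.base_lr * cfg.decay ** (iteration // cfg.decay_every)


def center_patches(X: np.ndarray, patch_size: int = 60) -> np.ndarray:
    r, c = eval_crop_offsets(X.shape[2], patch_size)[0]
    return X[:, :, r:r + patch_size, c:c + patch_size]


def _predict_center(net: Network, X: np.ndarray, batch: int = 256) -> np.ndarray:
    """Eval-mode class probabilities on the deterministic center patch."""
    Xc = center_patches(X, net.config.input_size)
    return np.concatenate([net.forward(Xc[i:i + batch])
                           for i in range(0, len(Xc), batch)])


def accuracy(net: Network, ds: LabeledDataset) -> float:
    return float((_predict_center(net, ds.X).argmax(axis=1) == ds.y).mean())


def _check_classes(ds: LabeledDataset) -> None:
    counts = np.bincount(ds.y, minlength=len(ds.class_names))
    empty = [ds.class_names[i] for i in np.flatnonzero(counts == 0)]
    if empty:
        raise DataError(f"classes with zero training samples: {empty}")


def _sgd_loop(net: Network, ds: LabeledDataset, n_iters: int, batch_size: int,
              lr_fn, rng: np.random.Generator, *, val_ds: LabeledDataset | None = None,
              checkpoint_every: int | None = None):
    """Core loop: augmented batches, cross-entropy, Adam. Returns (log, checkpoints)."""
    opt = make_optimizer(net)
    n = len(ds)
    rows, checkpoints = [], []
    for it in range(n_iters):
        lr = lr_fn(it)
        idx = rng.integers(0, n, batch_size)
        xb = augment_batch(ds.X[idx], rng, net.config.input_size)
        logits = net.logits(xb, training=True)
        p = softmax(logits)
        yb = ds.y[idx]
        loss = float(-np.log(np.maximum(p[np.arange(batch_size), yb], 1e-12)).mean())
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite loss {loss} at iteration {it} (lr={lr})")
        dlogits = p.copy()
        dlogits[np.arange(batch_size), yb] -= 1.0
        net.backward((dlogits / batch_size).astype(np.float32))
        opt.step(lr)
        row = {"iteration": it, "lr": lr, "loss": loss, "val_accuracy": np.nan}
        if checkpoint_every and ((it + 1) % checkpoint_every == 0 or it + 1 == n_iters):
            va = accuracy(net, val_ds) if val_ds is not None else np.nan
            checkpoints.append((it + 1, va, net.snapshot()))
            row["val_accuracy"] = va
        rows.append(row)
    return pd.DataFrame(rows, columns=["iteration", "lr", "loss", "val_accuracy"]), checkpoints


def train(network: Network, train_ds: LabeledDataset, cfg: TrainConfig,
          val_ds: LabeledDataset) -> tuple[Network, pd.DataFrame]:
    """Train with the full protocol; return the best-validation checkpoint.

    With ``max_iters == 0`` the initialized network is returned untouched.
    The log has one row per iteration (loss, lr) with validation accuracy
    filled in at checkpoint iterations.
    """
    _check_classes(train_ds)
    rng = np.random.default_rng(cfg.seed)
    net = network.clone()
    log_df, checkpoints = _sgd_loop(
        net, train_ds, cfg.max_iters, cfg.batch_size,
        lambda it: lr_schedule(it, cfg), rng,
        val_ds=val_ds, checkpoint_every=cfg.checkpoint_every)
    if checkpoints:
        best_iter, best_acc, best_state = max(checkpoints, key=lambda t: t[1])
        log.info("selected checkpoint at iteration %d (val acc %.4f)", best_iter, best_acc)
        net.load_state_dict(best_state)
    return net, log_df


def sample_per_class(y: np.ndarray, n_per_class: int, seed: int,
                     n_classes: int | None = None) -> np.ndarray:
    """Per-class subsample indices: without replacement when enough unique
    samples exist, with replacement otherwise. Deterministic given seed."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    k = n_classes or int(y.max()) + 1
    out = []
    for cls in range(k):
        pool = np.flatnonzero(y == cls)
        if len(pool) == 0:
            raise DataError(f"class {cls} has zero samples")
        replace = len(pool) < n_per_class
        out.append(rng.choice(pool, size=n_per_class, replace=replace))
    return np.concatenate(out)


def _init_transfer_net(pretrained: Network, n_classes: int, seed: int,
                       dropout: float) -> Network:
    """New network for a new vocabulary: pretrained weights everywhere except
    the freshly initialized final layer; dropout inserted before it."""
    new_cfg = dc_replace(pretrained.config, n_classes=n_classes)
    rng = np.random.default_rng(seed)
    net = build_network(new_cfg, seed=seed)
    state = pretrained.state_dict()
    for name, layer in net.layers:
        if name == "out":
            continue
        for k in layer.params:
            layer.params[k] = state[f"{name}.{k}"].copy()
        if hasattr(layer, "running_mean"):
            layer.running_mean = state[f"{name}.running_mean"].copy()
            layer.running_var = state[f"{name}.running_var"].copy()
    net.set_final_dropout(dropout, rng)
    return net


def transfer(pretrained: Network, train_ds: LabeledDataset, test_ds: LabeledDataset,
             cfg: TransferConfig, init: str = "pretrained"
             ) -> tuple[Network, list[float]]:
    """Fine-tune onto a new vocabulary over ``n_resamplings`` random subsets.

    ``init="pretrained"`` loads all pretrained parameters except the final
    layer; ``init="scratch"`` trains a fresh network under the identical
    budget (the from-scratch comparison arm). All parameters are updated.
    Returns the last fine-tuned network and per-resampling test accuracies.
    """
    if init not in ("pretrained", "scratch"):
        raise ValueError(f"init must be 'pretrained' or 'scratch', got {init!r}")
    k = len(train_ds.class_names)
    accs, net = [], None
    for r in range(cfg.n_resamplings):
        seed_r = cfg.seed + 1000 * r
        idx = sample_per_class(train_ds.y, cfg.samples_per_class, seed_r, n_classes=k)
        subset = train_ds.subset(idx)
        rng = np.random.default_rng(seed_r + 1)
        if init == "pretrained":
            net = _init_transfer_net(pretrained, k, seed_r + 2, cfg.final_layer_dropout)
        else:
            net = build_network(dc_replace(pretrained.config, n_classes=k), seed=seed_r + 2)
            net.set_final_dropout(cfg.final_layer_dropout, np.random.default_rng(seed_r + 3))
        if cfg.iters > 0:
            _sgd_loop(net, subset, cfg.iters, cfg.batch_size,
                      lambda it: cfg.lr, rng)
        accs.append(accuracy(net, test_ds))
    return net, accs


def extract_fc2_features(net: Network, X: np.ndarray, batch: int = 256) -> np.ndarray:
    Xc = center_patches(X, net.config.input_size)
    return np.concatenate([net.extract_activations(Xc[i:i + batch], "fc2")
                           for i in range(0, len(Xc), batch)])


def feature_classifier_baselines(pretrained: Network, train_ds: LabeledDataset,
                                 test_ds: LabeledDataset, n_per_class: int,
                                 seed: int) -> dict[str, float]:
    """Held-out accuracy of shallow classifiers on frozen fc2 features.

    Baselines follow the published comparison: k-nearest neighbors (k=1 up to
    10 samples per class, else 3), one-vs-one linear SVM (C=0.025), and a
    5-tree random forest.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.multiclass import OneVsOneClassifier
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC

    idx = sample_per_class(train_ds.y, n_per_class, seed,
                           n_classes=len(train_ds.class_names))
    Xtr = extract_fc2_features(pretrained, train_ds.X[idx])
    ytr = train_ds.y[idx]
    Xte = extract_fc2_features(pretrained, test_ds.X)
    models = {
        "knn": KNeighborsClassifier(n_neighbors=1 if n_per_class <= 10 else 3),
        "linear_svm": OneVsOneClassifier(SVC(kernel="linear", C=0.025)),
        "random_forest": RandomForestClassifier(n_estimators=5, random_state=seed),
    }
    return {name: float(m.fit(Xtr, ytr).score(Xte, test_ds.y))
            for name, m in models.items()}
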