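"""Shared fixtures.

The expensive artifacts (the scaled-down trained classifier and the synthetic
screen scored through the full pipeline) are session-scoped and shared
between the module tests and the acceptance suite so the whole run fits the
CPU budget: the network is trained once and reused everywhere.
"""

from __future__ import annotations

import numpy as np
import pytest

from subcell.evaluate import predict_cells
from subcell.network import ModelConfig, build_network
from subcell.preprocess import normalize_crop
from subcell.simulate import MorphologyParams, simulate_cell, simulate_screen
from subcell.training import TrainConfig, accuracy, dataset_from_crops, train

# six visually distinct patterns for the scaled-down benchmark
SMALL_CLASSES = ("cytoplasm", "nucleus", "nuclear_periphery", "cell_periphery",
                 "punctate_k8", "bud_neck")
# four patterns unseen during pretraining, for the transfer benchmark
TRANSFER_CLASSES = ("vacuole", "mitochondria", "punctate_k3", "nucleolus")

SMALL_MODEL_CONFIG = ModelConfig(
    input_size=60, in_channels=2, conv_widths=(8, 8, 16, 16),
    pool_after=frozenset({1, 2, 3, 4}), fc_widths=(32, 32),
    n_classes=len(SMALL_CLASSES))


@pytest.fixture(scope="session")
def morph() -> MorphologyParams:
    return MorphologyParams()


def make_crops(classes, n_per_class, seed0, params=None, normalize=True):
    params = params or MorphologyParams()
    crops = []
    for ci, cls in enumerate(classes):
        for j in range(n_per_class):
            crop = simulate_cell(cls, params, seed=seed0 + ci * 100_000 + j)
            crops.append(normalize_crop(crop) if normalize else crop)
    return crops


@pytest.fixture(scope="session")
def small_datasets(morph):
    train_ds = dataset_from_crops(make_crops(SMALL_CLASSES, 200, 0, morph),
                                  SMALL_CLASSES)
    val_ds = dataset_from_crops(make_crops(SMALL_CLASSES, 40, 5_000_000, morph),
                                SMALL_CLASSES)
    test_ds = dataset_from_crops(make_crops(SMALL_CLASSES, 40, 9_000_000, morph),
                                 SMALL_CLASSES)
    return {"train": train_ds, "val": val_ds, "test": test_ds}


@pytest.fixture(scope="session")
def trained_model(small_datasets):
    """Scaled-down classifier trained with the full protocol (1,500 iters)."""
    net = build_network(SMALL_MODEL_CONFIG, seed=7)
    cfg = TrainConfig(batch_size=64, max_iters=1500, checkpoint_every=500, seed=7)
    best, log = train(net, small_datasets["train"], cfg, small_datasets["val"])
    return {
        "network": best,
        "log": log,
        "initial": net,
        "train_config": cfg,
        "test_accuracy": accuracy(best, small_datasets["test"]),
        "classes": SMALL_CLASSES,
    }


@pytest.fixture(scope="session")
def transfer_datasets(morph):
    """Labeled pools for the transfer benchmark (patterns unseen in pretraining)."""
    train_ds = dataset_from_crops(make_crops(TRANSFER_CLASSES, 50, 2_000_000, morph),
                                  TRANSFER_CLASSES)
    test_ds = dataset_from_crops(make_crops(TRANSFER_CLASSES, 30, 7_000_000, morph),
                                 TRANSFER_CLASSES)
    return {"train": train_ds, "test": test_ds}


@pytest.fixture(scope="session")
def screen_run(trained_model, morph):
    """100-protein screen with 5 planted shifts scored through the pipeline."""
    from subcell.screen_stats import calibrate_scores, change_scores

    screen = simulate_screen(n_proteins=100, cells_per_protein=20,
                             shift_fraction=0.05, params=morph, seed=42,
                             class_names=SMALL_CLASSES)
    net = trained_model["network"]
    tables = {}
    for cond in screen.conditions:
        crops = [normalize_crop(c) for pid in screen.proteins()
                 for c in screen.crops[cond][pid]]
        tables[cond] = predict_cells(net, crops, SMALL_CLASSES)
    scores = change_scores(tables["A"], tables["B"], SMALL_CLASSES)
    calibrated, fits = calibrate_scores(scores)
    return {"screen": screen, "predictions": tables, "scores": scores,
            "calibrated": calibrated, "fits": fits}
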