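"""Per-cell prediction, protein-level aggregation, and evaluation metrics.

Per-cell prediction averages the classifier's output over the five
deterministic evaluation patches (center + four corners). Well/protein-level
localization profiles are the unweighted mean of the per-cell probability
vectors. Average precision is the step-wise area under the precision-recall
curve in descending-score order; "average accuracy" is the unweighted mean of
per-class accuracies (the diagonal of the row-normalized confusion matrix).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .network import Network
from .preprocess import CellCrop, eval_crop_offsets

__all__ = ["predict_cells", "predict_pixels", "aggregate_protein",
           "average_precision", "mean_average_precision", "confusion_matrix",
           "prob_columns"]

log = logging.getLogger(__name__)


def prob_columns(class_names) -> list[str]:
    return [f"p_{c}" for c in class_names]


def predict_pixels(network: Network, X: np.ndarray, batch: int = 128) -> np.ndarray:
    """Five-crop averaged probabilities for an (N, C, 64, 64) pixel array."""
    size = network.config.input_size
    offsets = eval_crop_offsets(X.shape[2], size)
    acc = np.zeros((len(X), network.config.n_classes), dtype=np.float64)
    for r, c in offsets:
        patches = X[:, :, r:r + size, c:c + size]
        for i in range(0, len(X), batch):
            acc[i:i + batch] += network.forward(patches[i:i + batch])
    return acc / len(offsets)


def predict_cells(network: Network, crops: list[CellCrop],
                  class_names: tuple[str, ...] | None = None,
                  batch: int = 128) -> pd.DataFrame:
    """Predict each cell with 5-crop averaging; returns the prediction table.

    Columns: cell_id, protein_id, condition, true_label, p_<class>...
    Each probability row sums to 1 (a convex mean of softmax outputs).
    """
    if any(not c.normalized for c in crops):
        raise ValueError("predict_cells expects normalized crops")
    X = np.stack([c.pixels for c in crops])
    probs = predict_pixels(network, X, batch=batch)
    k = network.config.n_classes
    names = tuple(class_names) if class_names is not None \
        else tuple(f"class{i}" for i in range(k))
    if len(names) != k:
        raise ValueError(f"{len(names)} class names for {k} outputs")
    rows = {
        "cell_id": [c.source.image_id if c.source else str(i)
                    for i, c in enumerate(crops)],
        "protein_id": [c.source.protein_id if c.source else None for c in crops],
        "condition": [c.source.condition if c.source else None for c in crops],
        "true_label": [c.label for c in crops],
    }
    df = pd.DataFrame(rows)
    df[prob_columns(names)] = probs
    return df


def aggregate_protein(table: pd.DataFrame, class_names,
                      group_by: str = "protein_id") -> pd.DataFrame:
    """Unweighted mean probability profile per group, with cell counts.

    Groups with no cells are simply absent; rows with a null group key are
    dropped with a warning.
    """
    cols = prob_columns(class_names)
    null = table[group_by].isna()
    if null.any():
        log.warning("dropping %d cells with no %s", int(null.sum()), group_by)
        table = table[~null]
    grouped = table.groupby(group_by, sort=True)
    out = grouped[cols].mean()
    out["n_cells"] = grouped.size()
    return out.reset_index()


def average_precision(scores, labels) -> float:
    """Step-wise area under the precision-recall curve.

    Items are ranked by descending score; ties are broken by original
    position (stable sort) so the result is deterministic. Equals the sum
    over positive items of precision-at-their-rank divided by the number of
    positives.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1-D arrays")
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("average precision undefined with zero positives")
    order = np.argsort(-scores, kind="stable")
    hits = labels[order].astype(np.float64)
    precision_at = np.cumsum(hits) / np.arange(1, len(hits) + 1)
    return float((precision_at * hits).sum() / n_pos)


def mean_average_precision(prob_matrix: np.ndarray, true_idx: np.ndarray,
                           class_names=None) -> tuple[float, dict]:
    """Unweighted mean AP over classes; classes without positives are skipped."""
    prob_matrix = np.asarray(prob_matrix, dtype=float)
    true_idx = np.asarray(true_idx)
    per_class = {}
    for k in range(prob_matrix.shape[1]):
        name = class_names[k] if class_names is not None else k
        pos = true_idx == k
        if not pos.any():
            log.warning("class %s has no positives; skipped in mean AP", name)
            continue
        per_class[name] = average_precision(prob_matrix[:, k], pos)
    if not per_class:
        raise ValueError("no class with positives")
    return float(np.mean(list(per_class.values()))), per_class


def confusion_matrix(pred_idx: np.ndarray, true_idx: np.ndarray,
                     class_names) -> tuple[pd.DataFrame, pd.Series, float]:
    """Row-normalized confusion matrix (rows = true class).

    Returns (matrix, per-class accuracy = diagonal, average accuracy =
    unweighted mean of per-class accuracies over classes with >= 1 cell).
    """
    k = len(class_names)
    true_idx = np.asarray(true_idx)
    pred_idx = np.asarray(pred_idx)
    if true_idx.min() < 0 or true_idx.max() >= k:
        raise ValueError("true label outside the class vocabulary")
    counts = np.zeros((k, k), dtype=np.float64)
    np.add.at(counts, (true_idx, pred_idx), 1.0)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(row_sums > 0, counts / row_sums, np.nan)
    matrix = pd.DataFrame(norm, index=list(class_names), columns=list(class_names))
    per_class = pd.Series(np.diag(norm), index=list(class_names))
    avg = float(per_class.dropna().mean())
    return matrix, per_class, avg
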