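"""Two-condition change detection for localization screens.

For each (protein, localization class) the per-cell class probabilities in
the two conditions are compared with the Welch's t statistic (positive =
increase in condition B). Per class, the population of protein scores is
calibrated with a two-component mixture: a Gaussian for the background and a
uniform with fixed 1% prior weight for the outliers; proteins whose score is
more likely under the weighted outlier component are called significant
localization changes. Protein abundance changes are scored as the log2 fold
change of mean green intensity per cell area, flagged when the magnitude
exceeds 1, and significant changes are assembled into a flux network after
filtering out scores with magnitude below 10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .preprocess import CellCrop

__all__ = ["MixtureFit", "welch_t", "fit_outlier_mixture", "calibrate_scores",
           "change_scores", "abundance_fold_change", "mean_abundance",
           "abundance_table", "build_flux_network", "flux_graph", "score_screen"]

log = logging.getLogger(__name__)

GREEN_CHANNEL = 0  # generator/order convention: (green, red)


def welch_t(a, b, min_cells: int = 5) -> float:
    """Welch's t statistic (unequal-variance), positive = increase in b.

    Sample variances use the n-1 denominator. Returns NaN (undefined) when
    both sample variances are zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < min_cells or len(b) < min_cells:
        raise ValueError(f"need >= {min_cells} cells per condition, "
                         f"got {len(a)} and {len(b)}")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    denom = np.sqrt(va / len(a) + vb / len(b))
    if denom == 0:
        return float("nan")
    return float((b.mean() - a.mean()) / denom)


@dataclass
class MixtureFit:
    """Gaussian background + fixed-weight uniform outlier mixture."""

    mu: float
    sigma2: float
    support: tuple[float, float]
    pi_out: float
    responsibilities: np.ndarray        # P(outlier | score)
    loglik: list[float] = field(default_factory=list)
    converged: bool = True

    @property
    def outlier(self) -> np.ndarray:
        """Outlier call: score more likely under the weighted outlier density."""
        return self.responsibilities > 0.5


def _gauss_pdf(x, mu, sigma2):
    return np.exp(-((x - mu) ** 2) / (2 * sigma2)) / np.sqrt(2 * np.pi * sigma2)


def fit_outlier_mixture(scores, pi_out: float = 0.01, max_em_iters: int = 200,
                        tol: float = 1e-8, support_pad: float = 0.01) -> MixtureFit:
    """EM fit of the background Gaussian with the outlier weight held fixed.

    The uniform support is fixed to the observed score range padded by
    ``support_pad`` of the range on each side; only (mu, sigma2) are
    re-estimated. The log-likelihood is non-decreasing over iterations.
    """
    x = np.asarray(scores, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 10:
        raise ValueError(f"need >= 10 finite scores to fit mixture, got {len(x)}")
    span = x.max() - x.min()
    if span <= 0:
        raise ValueError("degenerate score spread")
    lo, hi = x.min() - support_pad * span, x.max() + support_pad * span
    u_dens = 1.0 / (hi - lo)
    mu, sigma2 = float(np.median(x)), float(x.var()) or 1.0
    loglik: list[float] = []
    converged = False
    for _ in range(max_em_iters):
        p_out = pi_out * u_dens
        p_bg = (1 - pi_out) * _gauss_pdf(x, mu, sigma2)
        total = p_out + p_bg
        ll = float(np.log(total).sum())
        resp = p_out / total
        w = 1.0 - resp                   # background weights
        mu = float((w * x).sum() / w.sum())
        sigma2 = float((w * (x - mu) ** 2).sum() / w.sum())
        sigma2 = max(sigma2, 1e-12)
        if loglik and abs(ll - loglik[-1]) < tol:
            loglik.append(ll)
            converged = True
            break
        loglik.append(ll)
    if not converged:
        log.warning("mixture EM did not converge in %d iterations", max_em_iters)
    # final responsibilities at the fitted parameters
    p_out = pi_out * u_dens
    p_bg = (1 - pi_out) * _gauss_pdf(x, mu, sigma2)
    resp_full = np.full(len(np.asarray(scores)), np.nan)
    resp_full[np.isfinite(np.asarray(scores, dtype=float))] = p_out / (p_out + p_bg)
    return MixtureFit(mu=mu, sigma2=sigma2, support=(lo, hi), pi_out=pi_out,
                      responsibilities=resp_full, loglik=loglik, converged=converged)


def change_scores(pred_a: pd.DataFrame, pred_b: pd.DataFrame,
                  class_names, min_cells: int = 5) -> pd.DataFrame:
    """Welch's t per (protein, class) from two per-cell prediction tables.

    Proteins with fewer than ``min_cells`` cells in either condition are kept
    in the table with NaN scores and ``skipped=True``.
    """
    cols = [f"p_{c}" for c in class_names]
    rows = []
    proteins = sorted(set(pred_a["protein_id"].dropna())
                      & set(pred_b["protein_id"].dropna()))
    ga = dict(list(pred_a.groupby("protein_id")))
    gb = dict(list(pred_b.groupby("protein_id")))
    for pid in proteins:
        sub_a, sub_b = ga[pid], gb[pid]
        for cls, col in zip(class_names, cols):
            row = {"protein_id": pid, "class": cls,
                   "n_a": len(sub_a), "n_b": len(sub_b)}
            try:
                row["t_score"] = welch_t(sub_a[col].to_numpy(),
                                         sub_b[col].to_numpy(), min_cells)
                row["skipped"] = not np.isfinite(row["t_score"])
            except ValueError:
                row["t_score"] = np.nan
                row["skipped"] = True
            rows.append(row)
    return pd.DataFrame(rows, columns=["protein_id", "class", "t_score",
                                       "n_a", "n_b", "skipped"])


def calibrate_scores(score_table: pd.DataFrame, pi_out: float = 0.01,
                     **fit_kwargs) -> tuple[pd.DataFrame, dict[str, MixtureFit]]:
    """Fit the outlier mixture per class and annotate posterior + call."""
    out = score_table.copy()
    out["outlier_posterior"] = np.nan
    out["outlier_call"] = False
    fits: dict[str, MixtureFit] = {}
    for cls, group in out.groupby("class", sort=False):
        scores = group["t_score"].to_numpy()
        try:
            fit = fit_outlier_mixture(scores, pi_out=pi_out, **fit_kwargs)
        except ValueError as e:
            log.warning("class %s not calibrated: %s", cls, e)
            continue
        fits[cls] = fit
        out.loc[group.index, "outlier_posterior"] = fit.responsibilities
        out.loc[group.index, "outlier_call"] = fit.responsibilities > 0.5
    return out, fits


def abundance_fold_change(i_g_b: float, i_g_a: float) -> tuple[float, bool]:
    """log2 fold change of mean abundance, flagged when |value| > 1."""
    if i_g_b <= 0 or i_g_a <= 0:
        raise ValueError("mean abundances must be positive")
    dpl = float(np.log2(i_g_b / i_g_a))
    return dpl, abs(dpl) > 1.0


def mean_abundance(crops: list[CellCrop]) -> float:
    """Population mean of per-cell mean green intensity by area.

    The cell region is the generator's ellipse mask when available
    (``meta["cell_mask"]``), otherwise the whole crop footprint.
    """
    if not crops:
        raise ValueError("empty cell population")
    vals = []
    for c in crops:
        green = c.pixels[GREEN_CHANNEL]
        mask = c.meta.get("cell_mask")
        vals.append(float(green[mask].mean()) if mask is not None
                    else float(green.mean()))
    return float(np.mean(vals))


def abundance_table(crops_a: dict[str, list[CellCrop]],
                    crops_b: dict[str, list[CellCrop]]) -> pd.DataFrame:
    """Per-protein mean abundances, fold change, and flag for two conditions."""
    rows = []
    for pid in sorted(set(crops_a) & set(crops_b)):
        i_a = mean_abundance(crops_a[pid])
        i_b = mean_abundance(crops_b[pid])
        try:
            dpl, flag = abundance_fold_change(i_b, i_a)
        except ValueError:
            log.warning("protein %s skipped: non-positive abundance", pid)
            continue
        rows.append({"protein_id": pid, "i_g_a": i_a, "i_g_b": i_b,
                     "dpl": dpl, "abundance_flag": flag})
    return pd.DataFrame(rows, columns=["protein_id", "i_g_a", "i_g_b",
                                       "dpl", "abundance_flag"])


def build_flux_network(score_table: pd.DataFrame, profiles_a: pd.DataFrame,
                       profiles_b: pd.DataFrame, class_names,
                       threshold: float = 10.0,
                       abundance: pd.DataFrame | None = None) -> pd.DataFrame:
    """Edge list of significant localization flux between compartments.

    A protein is retained iff its max |t| >= threshold. Each retained protein
    contributes an edge from its dominant condition-A compartment (argmax of
    profile A) to every class whose score is >= +threshold, weighted by |t|.
    Edges carry the protein's fold change / flag when ``abundance`` is given,
    plus whether the dominant compartment changed between conditions.
    """
    cols = [f"p_{c}" for c in class_names]
    prof_a = profiles_a.set_index("protein_id")
    prof_b = profiles_b.set_index("protein_id")
    ab = abundance.set_index("protein_id") if abundance is not None else None
    edges = []
    for pid, group in score_table.dropna(subset=["t_score"]).groupby("protein_id"):
        if group["t_score"].abs().max() < threshold:
            continue
        source = class_names[int(np.argmax(prof_a.loc[pid, cols].to_numpy()))]
        dom_b = class_names[int(np.argmax(prof_b.loc[pid, cols].to_numpy()))]
        for _, row in group[group["t_score"] >= threshold].iterrows():
            edge = {"protein_id": pid, "source": source, "target": row["class"],
                    "weight": abs(float(row["t_score"])),
                    "dominant_changed": dom_b != source}
            if ab is not None and pid in ab.index:
                edge["dpl"] = float(ab.loc[pid, "dpl"])
                edge["abundance_flag"] = bool(ab.loc[pid, "abundance_flag"])
            edges.append(edge)
    columns = ["protein_id", "source", "target", "weight", "dominant_changed"]
    if abundance is not None:
        columns += ["dpl", "abundance_flag"]
    return pd.DataFrame(edges, columns=columns)


def flux_graph(edges: pd.DataFrame) -> nx.MultiDiGraph:
    """Compartment-hub graph view of the edge list (for GraphML export)."""
    g = nx.MultiDiGraph()
    for _, row in edges.iterrows():
        g.add_edge(row["source"], row["target"], protein_id=row["protein_id"],
                   weight=float(row["weight"]))
    return g


def score_screen(pred_a: pd.DataFrame, pred_b: pd.DataFrame, class_names,
                 min_cells: int = 5, pi_out: float = 0.01) -> pd.DataFrame:
    """Convenience: change scores + mixture calibration in one call."""
    scores = change_scores(pred_a, pred_b, class_names, min_cells=min_cells)
    calibrated, _ = calibrate_scores(scores, pi_out=pi_out)
    return calibrated
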