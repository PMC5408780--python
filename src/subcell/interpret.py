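"""Feature-space embedding and activation-maximization synthesis.

Embedding: activations of the last convolutional layer are reduced by their
spatial maximum (one value per feature map, removing spatial dependence) and
projected to 2-D with t-SNE.

Synthesis: an input is iteratively updated by gradient ascent on a chosen
feature or class logit. The naive variant applies the raw gradient; the
regularized variant additionally shrinks the image (L2 decay), periodically
blurs the gradient, zeroes pixels whose contribution |pixel * gradient| falls
below a percentile, holds the red marker channel fixed, and masks updates
outside the cell area — producing realistic-looking cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from sklearn.manifold import TSNE

from .network import Network

__all__ = ["SynthesisConfig", "embed_features", "activation_maximization",
           "reduced_features"]

RED_CHANNEL = 1


@dataclass
class SynthesisConfig:
    """Target and regularization settings for activation maximization.

    ``target`` is ("out", class_index) or ("conv<i>", feature_index). With
    the default coefficients all regularizers are off and the procedure is
    the naive gradient ascent.
    """

    target: tuple[str, int] = ("out", 0)
    steps: int = 200
    step_size: float = 1.0
    l2_decay: float = 0.0
    blur_sigma: float = 0.0
    blur_every: int = 4
    clip_percentile: float = 0.0     # zero the lowest-contribution pixels (0..100)
    clamp_red: bool = False
    cell_mask: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.l2_decay < 0 or self.blur_sigma < 0 or self.step_size <= 0:
            raise ValueError("coefficients must be non-negative, step_size positive")
        if not 0 <= self.clip_percentile <= 100:
            raise ValueError("clip_percentile must be in [0, 100]")

    @classmethod
    def regularized(cls, target, cell_mask, **kw) -> "SynthesisConfig":
        """Defaults for the realistic-cell variant."""
        kw.setdefault("l2_decay", 0.01)
        kw.setdefault("blur_sigma", 1.0)
        kw.setdefault("clip_percentile", 10.0)
        return cls(target=target, clamp_red=True, cell_mask=cell_mask, **kw)


def reduced_features(network: Network, X: np.ndarray, layer: str | None = None,
                     batch: int = 256) -> np.ndarray:
    """Spatial-max-reduced conv activations, one row per crop."""
    layer = layer or f"conv{len(network.config.conv_widths)}"
    out = []
    for i in range(0, len(X), batch):
        _, reduced = network.extract_activations(X[i:i + batch], layer)
        out.append(reduced)
    return np.concatenate(out)


def embed_features(network: Network, X: np.ndarray, seed: int = 0,
                   perplexity: float | None = None) -> np.ndarray:
    """2-D t-SNE embedding of spatial-max-reduced last-conv-layer features."""
    if len(X) < 10:
        raise ValueError(f"need >= 10 crops to embed, got {len(X)}")
    feats = reduced_features(network, X)
    if perplexity is None:
        perplexity = min(30.0, (len(X) - 1) / 3.0)
    tsne = TSNE(n_components=2, random_state=seed, perplexity=perplexity,
                init="pca")
    return tsne.fit_transform(feats.astype(np.float64))


def activation_maximization(network: Network, cfg: SynthesisConfig,
                            init: np.ndarray | None = None
                            ) -> tuple[np.ndarray, list[float]]:
    """Synthesize an input that drives the target activation up.

    ``init`` is a (C, S, S) image in [0, 1]; when omitted, uniform noise.
    Returns the synthesized image and the per-step activation trace.
    """
    c, s = network.config.in_channels, network.config.input_size
    rng = np.random.default_rng(cfg.seed)
    if init is None:
        x = rng.uniform(0, 1, size=(c, s, s)).astype(np.float32)
    else:
        x = np.asarray(init, dtype=np.float32).copy()
        if x.shape != (c, s, s):
            raise ValueError(f"init must have shape {(c, s, s)}, got {x.shape}")
    x0 = x.copy()
    mask = None
    if cfg.cell_mask is not None:
        mask = np.asarray(cfg.cell_mask, dtype=bool)
        if mask.shape != (s, s):
            raise ValueError(f"cell_mask must have shape {(s, s)}")
    trace: list[float] = []
    for step in range(cfg.steps):
        grad, score = network.input_gradient(x[None], cfg.target)
        if not np.isfinite(score):
            raise RuntimeError(f"activation diverged at step {step}; trace={trace}")
        trace.append(score)
        g = grad[0]
        if cfg.blur_sigma > 0 and cfg.blur_every > 0 and step % cfg.blur_every == 0:
            g = gaussian_filter(g, sigma=(0, cfg.blur_sigma, cfg.blur_sigma))
        if cfg.clip_percentile > 0:
            contrib = np.abs(x * g)
            thresh = np.percentile(contrib, cfg.clip_percentile)
            g = np.where(contrib >= thresh, g, 0.0)
        if cfg.clamp_red:
            g[RED_CHANNEL] = 0.0
        if mask is not None:
            g = g * mask
        if cfg.l2_decay > 0:
            decay = np.full_like(x, cfg.l2_decay)
            if cfg.clamp_red:
                decay[RED_CHANNEL] = 0.0
            if mask is not None:
                decay *= mask
            x = x * (1.0 - decay)
        x = np.clip(x + cfg.step_size * g, 0.0, 1.0).astype(np.float32)
        if cfg.clamp_red:
            x[RED_CHANNEL] = x0[RED_CHANNEL]
        if mask is not None:
            x = np.where(mask, x, x0).astype(np.float32)
    return x, trace
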