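"""Crop extraction, intensity normalization, and patch augmentation.

Single cells are represented as 64x64 bounding-box crops centered on their
table coordinates. Before classification each crop is normalized per channel
to [0, 1] with the top and bottom 0.1 percentile of pixel values saturated.
Training draws random 60x60 patches with random reflections and 90-degree
rotations; evaluation uses the deterministic center + four-corner patches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .dataio import CellRecord, ImageField

__all__ = ["CellCrop", "extract_crop", "normalize_crop", "augment",
           "augment_batch", "eval_crops", "eval_crop_offsets"]

log = logging.getLogger(__name__)

CROP_SIZE = 64
PATCH_SIZE = 60


@dataclass
class CellCrop:
    """Fixed-size multi-channel patch around one cell.

    ``pixels`` is (C, S, S); ``normalized`` records whether the [0, 1]
    percentile mapping has been applied. ``meta`` carries generator-side
    ground truth (masks, abundance scale) for synthetic crops.
    """

    pixels: np.ndarray
    normalized: bool = False
    label: str | None = None
    source: CellRecord | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[1] != self.pixels.shape[2]:
            raise ValueError(f"crop pixels must be (C, S, S), got {self.pixels.shape}")

    @property
    def size(self) -> int:
        return self.pixels.shape[1]


def extract_crop(field_: ImageField, record: CellRecord, size: int = CROP_SIZE) -> CellCrop:
    """Cut a size x size window centered on the record's (x, y).

    Regions falling outside the image are zero-padded so the crop geometry is
    preserved for boundary cells; all channels are cropped identically.
    """
    if record.image_id != field_.image_id:
        raise ValueError(f"record refers to image {record.image_id!r}, "
                         f"field is {field_.image_id!r}")
    h, w = field_.shape
    if not (0 <= record.x < w and 0 <= record.y < h):
        raise ValueError(f"cell center ({record.x}, {record.y}) outside "
                         f"image bounds {w}x{h}")
    half = size // 2
    r0, c0 = record.y - half, record.x - half
    out = np.zeros((field_.pixels.shape[0], size, size), dtype=field_.pixels.dtype)
    rs, re = max(r0, 0), min(r0 + size, h)
    cs, ce = max(c0, 0), min(c0 + size, w)
    out[:, rs - r0:re - r0, cs - c0:ce - c0] = field_.pixels[:, rs:re, cs:ce]
    return CellCrop(out, normalized=False, label=record.label, source=record)


def normalize_crop(crop: CellCrop, saturation_pct: float = 0.001) -> CellCrop:
    """Map each channel to [0, 1], saturating the extreme ``saturation_pct``.

    Per channel, values are clipped to the [saturation_pct, 1 - saturation_pct]
    empirical quantiles (linear interpolation) and affinely rescaled. A
    constant channel has no dynamic range and maps to all zeros.
    """
    if crop.normalized:
        raise ValueError("crop is already normalized")
    px = crop.pixels.astype(np.float32)
    out = np.empty_like(px)
    for c in range(px.shape[0]):
        lo, hi = np.quantile(px[c], [saturation_pct, 1.0 - saturation_pct])
        if hi <= lo:
            log.warning("constant channel %d in crop; mapping to zeros", c)
            out[c] = 0.0
        else:
            out[c] = (np.clip(px[c], lo, hi) - lo) / (hi - lo)
    return replace(crop, pixels=out, normalized=True)


def _orient(patch: np.ndarray, flip_v: bool, flip_h: bool, k_rot: int) -> np.ndarray:
    if flip_v:
        patch = patch[:, ::-1, :]
    if flip_h:
        patch = patch[:, :, ::-1]
    if k_rot:
        patch = np.rot90(patch, k_rot, axes=(1, 2))
    return np.ascontiguousarray(patch)


def augment(crop: CellCrop, seed: int, patch_size: int = PATCH_SIZE) -> CellCrop:
    """Random patch + random reflections and 90-degree rotation.

    Offset uniform over the valid positions, independent fair coin flips per
    reflection axis, rotation uniform over {0, 90, 180, 270} degrees.
    Deterministic given ``seed``. Pure pixel permutation within the window.
    """
    rng = np.random.default_rng(seed)
    return _augment_with_rng(crop, rng, patch_size)


def _augment_with_rng(crop: CellCrop, rng: np.random.Generator,
                      patch_size: int = PATCH_SIZE) -> CellCrop:
    if not crop.normalized:
        raise ValueError("augment expects a normalized crop")
    margin = crop.size - patch_size
    if margin < 0:
        raise ValueError(f"crop size {crop.size} smaller than patch size {patch_size}")
    r, c = rng.integers(0, margin + 1, size=2)
    flip_v, flip_h = rng.integers(0, 2, size=2).astype(bool)
    k_rot = int(rng.integers(0, 4))
    patch = _orient(crop.pixels[:, r:r + patch_size, c:c + patch_size],
                    flip_v, flip_h, k_rot)
    return replace(crop, pixels=patch)


def augment_batch(pixels: np.ndarray, rng: np.random.Generator,
                  patch_size: int = PATCH_SIZE) -> np.ndarray:
    """Vectorized batch augmentation for training: (N, C, S, S) -> (N, C, p, p)."""
    n, ch, s, _ = pixels.shape
    margin = s - patch_size
    offs = rng.integers(0, margin + 1, size=(n, 2))
    flips = rng.integers(0, 2, size=(n, 2)).astype(bool)
    rots = rng.integers(0, 4, size=n)
    out = np.empty((n, ch, patch_size, patch_size), dtype=pixels.dtype)
    for i in range(n):
        r, c = offs[i]
        out[i] = _orient(pixels[i, :, r:r + patch_size, c:c + patch_size],
                         flips[i, 0], flips[i, 1], int(rots[i]))
    return out


def eval_crop_offsets(size: int, patch_size: int) -> list[tuple[int, int]]:
    """Center-first offset list: center, then corners TL, TR, BL, BR."""
    m = size - patch_size
    c = m // 2
    return [(c, c), (0, 0), (0, m), (m, 0), (m, m)]


def eval_crops(crop: CellCrop, patch_size: int = PATCH_SIZE) -> list[CellCrop]:
    """The five deterministic evaluation patches: center + four corners."""
    if not crop.normalized:
        raise ValueError("eval_crops expects a normalized crop")
    if crop.size < patch_size:
        raise ValueError(f"crop size {crop.size} smaller than patch size {patch_size}")
    return [replace(crop, pixels=np.ascontiguousarray(
        crop.pixels[:, r:r + patch_size, c:c + patch_size]))
        for r, c in eval_crop_offsets(crop.size, patch_size)]
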