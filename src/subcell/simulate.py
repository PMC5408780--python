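"""Synthetic fluorescence-microscopy generator.

Produces labeled 64x64 two-channel single-cell crops (red = cytosolic marker
filling the cell body, green = compartment-specific pattern), whole fields
with coordinate tables, and two-condition screens with planted localization
shifts and abundance fold changes. Cell bodies are anti-aliased ellipses with
random orientation averaging 49 px along the major and 37 px along the minor
axis; intensities live in a 16-bit-like range and are left un-normalized.

All generators are pure functions of (parameters, seed). Each crop's ``meta``
records the generator's own ground truth (cell/pattern masks and the
noise-free green signal) so downstream modules can be tested against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .dataio import CellRecord, ImageField
from .preprocess import CellCrop

__all__ = ["MorphologyParams", "SyntheticScreen", "DEFAULT_CLASSES",
           "simulate_cell", "simulate_field", "simulate_screen",
           "pattern_names", "VocabularyError"]

DEFAULT_CLASSES = (
    "cytoplasm", "nucleus", "nuclear_periphery", "cell_periphery",
    "punctate_k8", "bud_neck", "vacuole", "mitochondria",
)
#: extra patterns available for transfer-learning benchmarks
EXTRA_CLASSES = ("punctate_k3", "nucleolus")

CHANNELS = ("green", "red")


class VocabularyError(ValueError):
    """Unknown localization class name."""


@dataclass
class MorphologyParams:
    """Geometry and intensity parameters for the generator."""

    major_axis_px: float = 49.0
    minor_axis_px: float = 37.0
    axis_cv: float = 0.08
    background_level: float = 60.0
    noise_sd: float = 20.0
    green_amplitude: float = 2000.0
    red_amplitude: float = 3000.0
    crop_size: int = 64
    class_pattern: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.major_axis_px <= 0 or self.minor_axis_px <= 0:
            raise ValueError("cell axes must be positive")
        if not 0 <= self.axis_cv < 1:
            raise ValueError("axis_cv must be in [0, 1)")


class _Geometry:
    """Per-cell coordinate frames shared by all pattern generators."""

    def __init__(self, size: int, rng: np.random.Generator, p: MorphologyParams):
        yy, xx = np.mgrid[0:size, 0:size].astype(np.float32)
        self.cy = size / 2 + rng.uniform(-2, 2)
        self.cx = size / 2 + rng.uniform(-2, 2)
        theta = rng.uniform(0, np.pi)
        scale = float(np.clip(1.0 + rng.normal(0, p.axis_cv), 0.6, 1.4))
        self.a = p.major_axis_px / 2 * scale
        self.b = p.minor_axis_px / 2 * scale
        ct, st = np.cos(theta), np.sin(theta)
        dx, dy = xx - self.cx, yy - self.cy
        self.u = ct * dx + st * dy           # along major axis
        self.v = -st * dx + ct * dy          # along minor axis
        self.e = np.sqrt((self.u / self.a) ** 2 + (self.v / self.b) ** 2 + 1e-12)
        self.body = np.clip((1.0 - self.e) / 0.08, 0.0, 1.0)  # soft ellipse fill
        self.xx, self.yy = xx, yy
        self.rot = np.array([[ct, -st], [st, ct]])
        # nucleus sits near the cell center with a small random offset
        off = self.rot @ np.array([rng.uniform(-0.15, 0.15) * self.a,
                                   rng.uniform(-0.15, 0.15) * self.b])
        self.ncx, self.ncy = self.cx + off[0], self.cy + off[1]
        self.d_nuc = np.hypot(xx - self.ncx, yy - self.ncy)

    def disk_distance(self, offset_u: float, offset_v: float):
        off = self.rot @ np.array([offset_u, offset_v])
        return np.hypot(self.xx - (self.cx + off[0]), self.yy - (self.cy + off[1]))

    def point_in_body(self, rng: np.random.Generator, e_max: float = 0.65):
        while True:
            pu = rng.uniform(-self.a, self.a)
            pv = rng.uniform(-self.b, self.b)
            if (pu / self.a) ** 2 + (pv / self.b) ** 2 < e_max ** 2:
                off = self.rot @ np.array([pu, pv])
                return self.cx + off[0], self.cy + off[1]


# -- pattern library ----------------------------------------------------------
# each generator maps (geometry, rng, options) -> (green in [0, 1], truth mask)

def _pat_cytoplasm(g, rng, opt):
    green = g.body * (1.0 - 0.7 * np.exp(-g.d_nuc ** 2 / (2 * 4.0 ** 2)))
    return green, g.body > 0.5


def _pat_nucleus(g, rng, opt):
    sigma = opt.get("sigma", 3.0)
    green = np.exp(-g.d_nuc ** 2 / (2 * sigma ** 2)).astype(np.float32)
    return green, g.d_nuc <= opt.get("mask_radius", 7.0)


def _pat_nuclear_periphery(g, rng, opt):
    r = opt.get("radius", 6.0)
    green = np.exp(-(g.d_nuc - r) ** 2 / (2 * 1.5 ** 2)) * (g.e < 1.0)
    return green.astype(np.float32), np.abs(g.d_nuc - r) <= 3.0


def _pat_cell_periphery(g, rng, opt):
    s = (g.e - 1.0) * g.b  # approx signed distance to the ellipse edge, px
    green = np.exp(-s ** 2 / (2 * opt.get("thickness", 1.5) ** 2))
    return green.astype(np.float32), np.abs(s) <= 3.0


def _pat_punctate(g, rng, opt):
    k = opt["k"]
    sigma = opt.get("sigma", 1.5)
    min_sep = opt.get("min_separation", 6.0)
    centers: list[tuple[float, float]] = []
    sep = min_sep
    while len(centers) < k:
        placed = False
        for _ in range(300):
            px, py = g.point_in_body(rng, e_max=0.8)
            if all(np.hypot(px - qx, py - qy) >= sep for qx, qy in centers):
                centers.append((px, py))
                placed = True
                break
        if not placed:
            sep *= 0.8  # relax deterministically rather than fail
            # spots merge at half-max below ~2.36 sigma; keep a margin
            if sep < 2.8 * sigma:
                raise ValueError(f"could not place {k} spots (sigma={sigma})")
    green = np.zeros_like(g.body)
    for px, py in centers:
        d2 = (g.xx - px) ** 2 + (g.yy - py) ** 2
        green = np.maximum(green, np.exp(-d2 / (2 * sigma ** 2)))
    return green.astype(np.float32), green > 0.5


def _pat_bud_neck(g, rng, opt):
    pos = opt.get("position", 0.8)
    band = np.exp(-(np.abs(g.u) - pos * g.a) ** 2 / (2 * 2.0 ** 2))
    green = band * np.clip((1.1 - g.e) / 0.1, 0.0, 1.0) * (g.u > 0)
    return green.astype(np.float32), green > 0.5


def _pat_vacuole(g, rng, opt):
    r = opt.get("radius", 8.0)
    d = g.disk_distance(-0.25 * g.a, 0.0)
    green = (np.exp(-(d - r) ** 2 / (2 * 1.5 ** 2)) + 0.25 * (d < r)) * (g.e < 1.0)
    return green.astype(np.float32), d <= r + 2.0


def _pat_mitochondria(g, rng, opt):
    n_seg = opt.get("n_segments", 3)
    sigma = opt.get("sigma", 1.2)
    green = np.zeros_like(g.body)
    for _ in range(n_seg):
        x0, y0 = g.point_in_body(rng, e_max=0.7)
        ang = rng.uniform(0, np.pi)
        length = rng.uniform(10, 16)
        ex = x0 + length * np.cos(ang)
        ey = y0 + length * np.sin(ang)
        # distance from every pixel to the segment (x0,y0)-(ex,ey)
        vx, vy = ex - x0, ey - y0
        t = np.clip(((g.xx - x0) * vx + (g.yy - y0) * vy) / (vx * vx + vy * vy), 0, 1)
        d2 = (g.xx - (x0 + t * vx)) ** 2 + (g.yy - (y0 + t * vy)) ** 2
        green = np.maximum(green, np.exp(-d2 / (2 * sigma ** 2)))
    green = green * g.body
    return green.astype(np.float32), green > 0.3


def _pat_nucleolus(g, rng, opt):
    ang = rng.uniform(0, 2 * np.pi)
    ncx = g.ncx + 4.0 * np.cos(ang)
    ncy = g.ncy + 4.0 * np.sin(ang)
    d = np.hypot(g.xx - ncx, g.yy - ncy)
    green = np.exp(-d ** 2 / (2 * 2.0 ** 2))
    return green.astype(np.float32), d <= 5.0


_PATTERNS: dict[str, Callable] = {
    "cytoplasm": _pat_cytoplasm,
    "nucleus": _pat_nucleus,
    "nuclear_periphery": _pat_nuclear_periphery,
    "cell_periphery": _pat_cell_periphery,
    "bud_neck": _pat_bud_neck,
    "vacuole": _pat_vacuole,
    "mitochondria": _pat_mitochondria,
    "nucleolus": _pat_nucleolus,
}


def pattern_names() -> list[str]:
    return sorted(_PATTERNS) + ["punctate_k<k>"]


def _resolve_pattern(class_name: str, params: MorphologyParams):
    opt = dict(params.class_pattern.get(class_name, {}))
    if class_name in _PATTERNS:
        return _PATTERNS[class_name], opt
    if class_name.startswith("punctate_k"):
        try:
            opt.setdefault("k", int(class_name[len("punctate_k"):]))
        except ValueError:
            raise VocabularyError(f"bad punctate class name {class_name!r}")
        return _pat_punctate, opt
    raise VocabularyError(
        f"unknown class {class_name!r}; available patterns: {pattern_names()}")


def _render_cell(class_name: str, params: MorphologyParams,
                 rng: np.random.Generator, abundance_scale: float = 1.0):
    """Noise-free signal render: (red_signal, green_signal, meta)."""
    fn, opt = _resolve_pattern(class_name, params)
    geom = _Geometry(params.crop_size, rng, params)
    green_rel, mask = fn(geom, rng, opt)
    red_signal = params.red_amplitude * geom.body
    green_signal = params.green_amplitude * abundance_scale * green_rel
    meta = {
        "cell_mask": geom.body > 0.5,
        "pattern_mask": mask,
        "green_signal": green_signal,
        "abundance_scale": abundance_scale,
        "center": (geom.cy, geom.cx),
    }
    return red_signal, green_signal, meta


def _compose(signal: np.ndarray, params: MorphologyParams,
             rng: np.random.Generator) -> np.ndarray:
    out = signal + params.background_level
    if params.noise_sd > 0:
        out = out + rng.normal(0, params.noise_sd, signal.shape)
    return np.clip(out, 0, 65535).astype(np.float32)


def simulate_cell(class_name: str, params: MorphologyParams | None = None,
                  seed: int = 0, abundance_scale: float = 1.0) -> CellCrop:
    """Render one labeled crop; deterministic given (class_name, params, seed).

    Channel order is (green, red): green follows the class pattern, red fills
    the cell body like the cytosolic marker in real screens.
    """
    params = params or MorphologyParams()
    rng = np.random.default_rng(seed)
    red_sig, green_sig, meta = _render_cell(class_name, params, rng, abundance_scale)
    pixels = np.stack([_compose(green_sig, params, rng),
                       _compose(red_sig, params, rng)])
    return CellCrop(pixels, normalized=False, label=class_name, meta=meta)


def simulate_field(n_cells: int, params: MorphologyParams | None = None,
                   seed: int = 0, class_names: tuple[str, ...] = DEFAULT_CLASSES,
                   image_id: str | None = None, return_buffers: bool = False):
    """Render a whole field on a jittered grid plus its coordinate table.

    Returned records carry the true rendered cell centers. With
    ``return_buffers`` also returns per-cell noise-free green render buffers
    (full-field sized) for mass-recovery oracles.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    params = params or MorphologyParams()
    rng = np.random.default_rng(seed)
    image_id = image_id or f"synthetic_field_{seed}"
    spacing, margin = 52, 36
    cols = max(1, int(np.ceil(np.sqrt(n_cells))))
    rows = max(1, -(-n_cells // cols))
    h = rows * spacing + 2 * margin - spacing
    w = cols * spacing + 2 * margin - spacing
    size = params.crop_size
    green = np.zeros((h, w), dtype=np.float32)
    red = np.zeros((h, w), dtype=np.float32)
    records, buffers = [], []
    for i in range(n_cells):
        r_grid = margin + (i // cols) * spacing + rng.integers(-5, 6)
        c_grid = margin + (i % cols) * spacing + rng.integers(-5, 6)
        cls = class_names[int(rng.integers(len(class_names)))]
        red_sig, green_sig, meta = _render_cell(cls, params, rng)
        cy, cx = meta["center"]
        r0, c0 = int(r_grid - size // 2), int(c_grid - size // 2)
        buf = np.zeros_like(green)
        rs, re = max(r0, 0), min(r0 + size, h)
        cs, ce = max(c0, 0), min(c0 + size, w)
        buf[rs:re, cs:ce] = green_sig[rs - r0:re - r0, cs - c0:ce - c0]
        green += buf
        red[rs:re, cs:ce] += red_sig[rs - r0:re - r0, cs - c0:ce - c0]
        records.append(CellRecord(image_id=image_id,
                                  x=int(round(c0 + cx)), y=int(round(r0 + cy)),
                                  label=cls))
        if return_buffers:
            buffers.append(buf)
    field = ImageField(np.stack([_compose(green, params, rng),
                                 _compose(red, params, rng)]),
                       CHANNELS, image_id)
    if return_buffers:
        return field, records, buffers
    return field, records


@dataclass
class SyntheticScreen:
    """Two-condition crop collection with recorded ground truth."""

    crops: dict[str, dict[str, list[CellCrop]]]   # condition -> protein -> crops
    truth: dict[str, dict[str, str]]              # condition -> protein -> class
    planted_shifts: frozenset[str]
    planted_abundance: dict[str, float]           # protein -> green fold change (B/A)
    class_names: tuple[str, ...]
    conditions: tuple[str, str] = ("A", "B")

    def proteins(self) -> list[str]:
        return sorted(self.truth[self.conditions[0]])


def simulate_screen(n_proteins: int, cells_per_protein: int,
                    shift_fraction: float = 0.0,
                    abundance_effects: dict | None = None,
                    params: MorphologyParams | None = None, seed: int = 0,
                    class_names: tuple[str, ...] = DEFAULT_CLASSES) -> SyntheticScreen:
    """Generate a two-condition screen with planted effects.

    ``round(n_proteins * shift_fraction)`` proteins change localization class
    between conditions A and B; ``abundance_effects`` maps protein ids (or
    integer indices) to green-intensity fold changes applied in condition B.
    """
    if not 0.0 <= shift_fraction <= 1.0:
        raise ValueError("shift_fraction must be in [0, 1]")
    params = params or MorphologyParams()
    rng = np.random.default_rng(seed)
    protein_ids = [f"P{i:04d}" for i in range(n_proteins)]
    abundance = {}
    for key, fold in (abundance_effects or {}).items():
        pid = f"P{int(key):04d}" if not isinstance(key, str) else key
        if pid not in protein_ids:
            raise ValueError(f"abundance effect for unknown protein {pid}")
        abundance[pid] = float(fold)

    n_shift = int(round(n_proteins * shift_fraction))
    shifted = frozenset(rng.choice(protein_ids, size=n_shift, replace=False).tolist()) \
        if n_shift else frozenset()

    truth: dict[str, dict[str, str]] = {"A": {}, "B": {}}
    crops: dict[str, dict[str, list[CellCrop]]] = {"A": {}, "B": {}}
    for pid in protein_ids:
        cls_a = class_names[int(rng.integers(len(class_names)))]
        if pid in shifted:
            others = [c for c in class_names if c != cls_a]
            cls_b = others[int(rng.integers(len(others)))]
        else:
            cls_b = cls_a
        truth["A"][pid], truth["B"][pid] = cls_a, cls_b
        for cond, cls in (("A", cls_a), ("B", cls_b)):
            scale = abundance.get(pid, 1.0) if cond == "B" else 1.0
            cell_list = []
            for j in range(cells_per_protein):
                crop = simulate_cell(cls, params, seed=int(rng.integers(2 ** 31)),
                                     abundance_scale=scale)
                crop.source = CellRecord(image_id=f"{cond}_{pid}_{j}", x=32, y=32,
                                         label=cls, protein_id=pid, condition=cond)
                cell_list.append(crop)
            crops[cond][pid] = cell_list
    return SyntheticScreen(crops=crops, truth=truth, planted_shifts=shifted,
                           planted_abundance=abundance, class_names=tuple(class_names))
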