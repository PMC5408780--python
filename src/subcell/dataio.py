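"""Reading and writing images, cell tables, result tables, and run configs.

On-disk conventions for the whole package:

* images: TIFF (multi-page or 3-D plane stack = channels) or PNG, intensities
  preserved in native units — readers never rescale;
* tables: TSV with a mandatory header (delimiter sniffed for CSV input);
  coordinates are 0-based pixel indices with x = column, y = row of the crop
  center;
* config: JSON or YAML.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

__all__ = [
    "CellRecord", "ImageField", "SchemaError",
    "read_image", "write_image", "read_cell_table", "write_cell_table",
    "write_table", "read_table", "read_config", "write_config",
]

MANDATORY_COLUMNS = ("image_id", "x", "y")
OPTIONAL_COLUMNS = ("label", "protein_id", "condition")


class SchemaError(ValueError):
    """A table is missing mandatory columns or holds unparseable values."""


@dataclass
class CellRecord:
    """One cell: image of origin and 0-based (x=column, y=row) center."""

    image_id: str
    x: int
    y: int
    label: str | None = None
    protein_id: str | None = None
    condition: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.x < 0 or self.y < 0:
            raise ValueError(f"cell coordinates must be non-negative, got ({self.x}, {self.y})")


@dataclass
class ImageField:
    """Multi-channel image; ``pixels`` is (C, H, W), ``channels`` names each plane."""

    pixels: np.ndarray
    channels: tuple[str, ...]
    image_id: str

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[None]
        if self.pixels.ndim != 3:
            raise ValueError(f"pixels must be (C, H, W), got shape {self.pixels.shape}")
        self.channels = tuple(self.channels)
        if len(self.channels) != self.pixels.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel names for {self.pixels.shape[0]} planes")
        if not self.channels:
            raise ValueError("at least one channel required")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]


def read_image(path: str | Path, channels: tuple[str, ...] | None = None,
               image_id: str | None = None) -> ImageField:
    """Read a TIFF or PNG into an ImageField without rescaling intensities.

    ``channels`` gives the expected role names in plane order (from the run
    config); a mismatch with the file's plane count is a config error.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif suffix == ".png":
        arr = np.asarray(Image.open(path))
        if arr.ndim == 3:  # PNG is (H, W, C)
            arr = arr.transpose(2, 0, 1)
    else:
        raise IOError(f"unsupported image format: {path.suffix}")
    if arr.ndim == 2:
        arr = arr[None]
    if channels is not None and arr.shape[0] != len(channels):
        raise ValueError(
            f"config expects {len(channels)} channels but {path.name} has {arr.shape[0]}")
    names = channels if channels is not None else tuple(f"ch{i}" for i in range(arr.shape[0]))
    return ImageField(arr, names, image_id or path.stem)


def write_image(field: ImageField | np.ndarray, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = field.pixels if isinstance(field, ImageField) else np.asarray(field)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    elif path.suffix.lower() == ".png":
        a = arr[0] if arr.ndim == 3 and arr.shape[0] == 1 else arr.transpose(1, 2, 0)
        Image.fromarray(a).save(path)
    else:
        raise IOError(f"unsupported image format: {path.suffix}")


def _sniff_delimiter(path: Path) -> str:
    if path.suffix.lower() == ".tsv":
        return "\t"
    with open(path, newline="") as fh:
        sample = fh.read(65536)
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def read_cell_table(path: str | Path) -> list[CellRecord]:
    """Parse a delimited cell table into records.

    Requires a header naming at least image_id, x, y; recognized optional
    columns are promoted to fields, everything else lands in ``metadata``.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cell table not found: {path}")
    df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cell table {path.name} missing mandatory column(s): {missing}")
    extra = [c for c in df.columns if c not in MANDATORY_COLUMNS + OPTIONAL_COLUMNS]
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        try:
            x, y = int(float(d["x"])), int(float(d["y"]))
        except ValueError as e:
            raise SchemaError(f"row {i} of {path.name}: non-numeric coordinate "
                              f"(x={d['x']!r}, y={d['y']!r})") from e
        records.append(CellRecord(
            image_id=d["image_id"], x=x, y=y,
            label=d.get("label") or None,
            protein_id=d.get("protein_id") or None,
            condition=d.get("condition") or None,
            metadata={c: d[c] for c in extra},
        ))
    return records


def write_cell_table(records: list[CellRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {"image_id": r.image_id, "x": r.x, "y": r.y}
        for c in OPTIONAL_COLUMNS:
            v = getattr(r, c)
            if v is not None:
                row[c] = v
        row.update(r.metadata)
        rows.append(row)
    cols = list(MANDATORY_COLUMNS) + [c for c in OPTIONAL_COLUMNS
                                      if any(getattr(r, c) is not None for r in records)]
    extra = sorted({k for r in records for k in r.metadata})
    df = pd.DataFrame(rows, columns=cols + extra) if rows else pd.DataFrame(columns=cols)
    write_table(df, path)


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as TSV with full float precision (repr round-trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows.to_csv(path, sep="\t", index=False)  # default str() is shortest round-trip repr


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise IOError(f"table not found: {path}")
    return pd.read_csv(path, sep=_sniff_delimiter(path))


def read_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def write_config(config: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(config, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(config, sort_keys=True))
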