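"""Image input and feature-table persistence.

The canonical in-memory image is :class:`GrayImage`: a 2-D integer grid of
gray levels in ``[0, L-1]``.  RGB rasters are collapsed to one channel with
ITU-R BT.601 luma weights before quantization, matching the most common
"convert to grayscale" convention in image-processing libraries.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GrayImage",
    "LabeledImage",
    "FeatureTable",
    "LUMA_WEIGHTS",
    "FIGSHARE_LABELS",
    "load_grayscale",
    "save_grayscale",
    "read_figshare_mat",
    "write_feature_table",
    "read_feature_table",
]

#: ITU-R BT.601 luma weights applied to (R, G, B).
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: Numeric labels of the Figshare brain-tumor release mapped to class names.
FIGSHARE_LABELS = {1: "meningioma", 2: "glioma", 3: "pituitary"}


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grid of integer gray levels in ``[0, levels - 1]``.

    Parameters
    ----------
    pixels
        2-D integer array, at least 3x3 (the LBP operator needs an interior).
    levels
        Number of gray levels ``L``; every pixel must lie in ``[0, L - 1]``.
    """

    pixels: np.ndarray
    levels: int = 256

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError(f"pixels must be a non-empty 2-D array, got shape {px.shape}")
        if px.shape[0] < 3 or px.shape[1] < 3:
            raise ValueError(f"image must be at least 3x3, got {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError(f"pixels must be integer-typed, got dtype {px.dtype}")
        if self.levels < 2:
            raise ValueError(f"levels must be >= 2, got {self.levels}")
        if px.min() < 0 or px.max() >= self.levels:
            raise ValueError(
                f"pixel values must lie in [0, {self.levels - 1}], "
                f"got range [{px.min()}, {px.max()}]"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class LabeledImage:
    """A :class:`GrayImage` with a class label and an opaque source id."""

    image: GrayImage
    label: str
    source_id: str = ""


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(np.int64)


def _quantize(gray: np.ndarray, source_max: float, levels: int) -> np.ndarray:
    """Rescale float intensities in [0, source_max] to integers in [0, levels-1]."""
    if source_max <= 0:
        return np.zeros(gray.shape, dtype=np.int64)
    q = _round_half_up(gray * ((levels - 1) / source_max))
    return np.clip(q, 0, levels - 1)


def load_grayscale(path: str | Path, levels: int = 256) -> GrayImage:
    """Read a raster image (PNG/JPEG/TIFF) as a quantized grayscale grid.

    RGB(A) input is collapsed to one channel via the BT.601 luma weights
    (0.299, 0.587, 0.114); already-gray input is only quantized.  Intensities
    are rescaled from the source dtype range to ``[0, levels - 1]`` with
    round-half-up.
    """
    from PIL import Image

    path = Path(path)
    with Image.open(path) as img:
        if img.mode in ("P", "PA"):
            img = img.convert("RGB")
        elif img.mode in ("RGBA", "CMYK", "YCbCr", "LA"):
            img = img.convert("RGB")
        arr = np.asarray(img)
    if arr.size == 0:
        raise ValueError(f"zero-size image: {path}")
    if np.issubdtype(arr.dtype, np.integer):
        source_max = float(np.iinfo(arr.dtype).max)
    else:  # float TIFF: assume intensities already in [0, 1]
        source_max = 1.0
    arr = arr.astype(np.float64)
    if arr.ndim == 3:
        gray = arr[..., :3] @ np.asarray(LUMA_WEIGHTS)
    else:
        gray = arr
    return GrayImage(_quantize(gray, source_max, levels), levels=levels)


def save_grayscale(image: GrayImage, path: str | Path) -> None:
    """Write a :class:`GrayImage` (levels <= 256) as an 8-bit grayscale PNG."""
    from PIL import Image

    if image.levels > 256:
        raise ValueError("save_grayscale supports at most 256 gray levels")
    Image.fromarray(image.pixels.astype(np.uint8), mode="L").save(Path(path))


def read_figshare_mat(path: str | Path) -> LabeledImage:
    """Read one slice of the Figshare brain-tumor release (v7.3 ``.mat``).

    The file is an HDF5 container with a ``cjdata`` group holding ``image``
    (a 2-D intensity grid) and ``label`` (1 = meningioma, 2 = glioma,
    3 = pituitary).  The image is min-max rescaled to 8-bit integers.
    """
    import h5py

    path = Path(path)
    with h5py.File(path, "r") as f:
        if "cjdata" not in f:
            raise ValueError(f"{path}: no 'cjdata' group — not a Figshare tumor file")
        grp = f["cjdata"]
        if "label" not in grp or "image" not in grp:
            raise ValueError(f"{path}: cjdata group lacks 'image' or 'label'")
        label_num = int(np.asarray(grp["label"]).ravel()[0])
        raw = np.asarray(grp["image"], dtype=np.float64)
    if label_num not in FIGSHARE_LABELS:
        raise ValueError(f"{path}: label {label_num} outside {{1, 2, 3}}")
    lo, hi = float(raw.min()), float(raw.max())
    pixels = _quantize(raw - lo, hi - lo, 256)
    return LabeledImage(
        image=GrayImage(pixels, levels=256),
        label=FIGSHARE_LABELS[label_num],
        source_id=path.stem,
    )


@dataclass
class FeatureTable:
    """Per-image feature vectors with labels, backed by a dense matrix.

    ``values`` is an ``(n_samples, n_features)`` float matrix; row ``i``
    belongs to ``source_ids[i]`` with class ``labels[i]``.
    """

    source_ids: list[str]
    labels: list[str]
    values: np.ndarray
    column_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.source_ids)
        if n == 0:
            raise ValueError("feature table must contain at least one row")
        if self.values.ndim != 2 or self.values.shape[0] != n or len(self.labels) != n:
            raise ValueError(
                "inconsistent table: "
                f"{n} ids, {len(self.labels)} labels, values shape {self.values.shape}"
            )
        if self.values.shape[1] != len(self.column_names):
            raise ValueError(
                f"{len(self.column_names)} column names for "
                f"{self.values.shape[1]} feature columns"
            )

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def class_names(self) -> list[str]:
        return sorted(set(self.labels))

    def subset(self, indices: Sequence[int]) -> "FeatureTable":
        idx = list(indices)
        return FeatureTable(
            source_ids=[self.source_ids[i] for i in idx],
            labels=[self.labels[i] for i in idx],
            values=self.values[idx],
            column_names=list(self.column_names),
        )

    def iter_rows(self) -> Iterator[tuple[str, str, np.ndarray]]:
        for i in range(len(self)):
            yield self.source_ids[i], self.labels[i], self.values[i]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "source_id", self.source_ids)
        return df


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as CSV: header ``source_id,label,<features...>``.

    Floats are formatted with 17 significant digits so a write/read round
    trip reproduces every value exactly.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source_id", "label", *table.column_names])
        for sid, label, row in table.iter_rows():
            writer.writerow([sid, label, *(format(v, ".17g") for v in row)])


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a CSV written by :func:`write_feature_table`."""
    df = pd.read_csv(path, dtype={"source_id": str, "label": str}, float_precision="round_trip")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty feature table")
    for col in ("source_id", "label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    feature_cols = [c for c in df.columns if c not in ("source_id", "label")]
    return FeatureTable(
        source_ids=df["source_id"].tolist(),
        labels=df["label"].tolist(),
        values=df[feature_cols].to_numpy(dtype=np.float64),
        column_names=feature_cols,
    )
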