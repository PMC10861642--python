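"""Synthetic texture generation.

Three generator families produce grayscale images whose classes differ in
second-order texture statistics — exactly the axis the GLCM/LBP pipeline
measures — without claiming visual realism:

* ``smooth_field`` — Gaussian white noise low-pass filtered at a correlation
  length of a few pixels (slowly varying intensity, low local contrast);
* ``fine_noise`` — i.i.d. uniform noise (maximal local contrast);
* ``oriented_grating`` — a sinusoidal grating at a fixed period and
  orientation plus mild noise (anisotropic correlation).

Generation is a pure function of (class spec, seed, image index): the
per-image seed is derived from a SHA-256 hash of ``seed|class|index``, so
any single image can be regenerated without building the whole dataset.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io import GrayImage, LabeledImage

__all__ = [
    "TextureClassSpec",
    "SyntheticDataset",
    "default_class_specs",
    "derive_seed",
    "generate_texture_image",
    "generate_dataset",
    "fixture_images",
]

_KINDS = ("smooth_field", "fine_noise", "oriented_grating")


@dataclass(frozen=True)
class TextureClassSpec:
    """Parameters of one synthetic texture class.

    ``correlation_length`` (pixels) applies to smooth fields,
    ``period`` (pixels) and ``angle_deg`` to gratings, and
    ``noise_amplitude`` (fraction of the intensity range) to the additive
    noise on gratings.
    """

    name: str
    kind: str
    correlation_length: float = 8.0
    noise_amplitude: float = 0.1
    period: float = 8.0
    angle_deg: float = 0.0
    intensity_range: tuple[int, int] = (0, 255)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown generator kind {self.kind!r}; choose from {_KINDS}")
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be positive")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if not 0.0 <= self.noise_amplitude <= 1.0:
            raise ValueError("noise_amplitude must lie in [0, 1]")
        lo, hi = self.intensity_range
        if not (0 <= lo < hi <= 255):
            raise ValueError(f"intensity_range must satisfy 0 <= lo < hi <= 255, got {self.intensity_range}")


@dataclass(frozen=True)
class SyntheticDataset:
    """A balanced, fully reproducible labeled image collection."""

    images: tuple[LabeledImage, ...]
    specs: tuple[TextureClassSpec, ...]
    n_per_class: int
    seed: int


def default_class_specs() -> list[TextureClassSpec]:
    """The default three-class study conditions.

    One smoothly varying field, one fine-grained noise class, and one
    oriented grating stand in for the three tumor classes: they are cleanly
    separable by second-order texture statistics.
    """
    return [
        TextureClassSpec(name="smooth", kind="smooth_field", correlation_length=8.0),
        TextureClassSpec(name="speckle", kind="fine_noise"),
        TextureClassSpec(name="grating", kind="oriented_grating", period=8.0, angle_deg=0.0,
                         noise_amplitude=0.1),
    ]


def derive_seed(seed: int, class_name: str, index: int) -> int:
    """Stable per-image seed: SHA-256 of ``seed|class|index``, below 2^31."""
    digest = hashlib.sha256(f"{seed}|{class_name}|{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _rescale_quantize(x: np.ndarray, lo: int, hi: int) -> np.ndarray:
    span = x.max() - x.min()
    if span == 0:
        return np.full(x.shape, (lo + hi) // 2, dtype=np.int64)
    unit = (x - x.min()) / span
    return np.floor(unit * (hi - lo) + lo + 0.5).astype(np.int64)


def generate_texture_image(
    spec: TextureClassSpec,
    seed: int,
    index: int,
    size: tuple[int, int] = (64, 64),
) -> GrayImage:
    """Generate one quantized texture image for (spec, seed, index)."""
    h, w = size
    if h < 32 or w < 32:
        raise ValueError(f"size must be at least 32x32, got {size}")
    rng = np.random.default_rng(derive_seed(seed, spec.name, index))
    lo, hi = spec.intensity_range
    if spec.kind == "smooth_field":
        noise = rng.standard_normal((h, w))
        smooth = ndimage.gaussian_filter(noise, sigma=spec.correlation_length, mode="reflect")
        field = smooth
    elif spec.kind == "fine_noise":
        field = rng.uniform(size=(h, w))
    else:  # oriented_grating
        theta = np.deg2rad(spec.angle_deg)
        rows, cols = np.mgrid[0:h, 0:w]
        # phase advances along the direction theta (0 deg -> varies with column)
        phase = (np.cos(theta) * cols + np.sin(theta) * rows) / spec.period
        grating = np.sin(2 * np.pi * phase + rng.uniform(0, 2 * np.pi))
        field = grating + spec.noise_amplitude * 2.0 * rng.standard_normal((h, w))
    return GrayImage(_rescale_quantize(field, lo, hi), levels=256)


def generate_dataset(
    specs: Sequence[TextureClassSpec] | None = None,
    n_per_class: int = 100,
    seed: int = 42,
    size: tuple[int, int] = (64, 64),
) -> SyntheticDataset:
    """Generate a balanced labeled dataset, bit-identical for fixed inputs."""
    if specs is None:
        specs = default_class_specs()
    if len(specs) < 2:
        raise ValueError("need at least 2 class specs")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate class names in {names}")
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    images = []
    for spec in specs:
        for i in range(n_per_class):
            img = generate_texture_image(spec, seed, i, size=size)
            images.append(
                LabeledImage(image=img, label=spec.name, source_id=f"{spec.name}_{i:04d}")
            )
    return SyntheticDataset(
        images=tuple(images), specs=tuple(specs), n_per_class=n_per_class, seed=seed
    )


def fixture_images() -> dict[str, GrayImage]:
    """Small analytic images with hand-checkable texture statistics.

    * ``constant`` — 64x64 all equal to 7 (zero contrast everywhere);
    * ``checkerboard`` — 64x64 alternating 0/255 (all horizontal
      co-occurrence mass on (0,255) and (255,0); contrast 255^2);
    * ``hramp`` — 64x64 with pixel value = column index;
    * ``tiny_glcm`` — the 3x3 grid [[0,0,1],[0,0,1],[0,2,2]] at 3 levels,
      whose horizontal pair counts can be enumerated by hand.
    """
    rows, cols = np.mgrid[0:64, 0:64]
    return {
        "constant": GrayImage(np.full((64, 64), 7, dtype=np.int64), levels=256),
        "checkerboard": GrayImage(((rows + cols) % 2 * 255).astype(np.int64), levels=256),
        "hramp": GrayImage(cols.astype(np.int64), levels=256),
        "tiny_glcm": GrayImage(
            np.array([[0, 0, 1], [0, 0, 1], [0, 2, 2]], dtype=np.int64), levels=3
        ),
    }
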