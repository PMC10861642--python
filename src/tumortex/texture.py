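"""Second-order (GLCM) and local-pattern (LBP) texture descriptors.

The gray-level co-occurrence matrix (GLCM) counts ordered pixel pairs at a
fixed offset; five Haralick-style statistics (contrast, dissimilarity,
homogeneity, energy, correlation) summarize it.  Statistics are computed at
four offsets (0, 45, 90, 135 degrees) and averaged into a single 5-vector.

The local binary pattern (LBP) operator thresholds the 8 neighbors of each
interior pixel against the center (neighbor >= center counts as 1, ties
included) and packs the bits into an 8-bit code; the image texture is
summarized as the normalized 256-bin code histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .io import GrayImage

__all__ = [
    "GLCMConfig",
    "GLCMatrix",
    "GLCMFeatures",
    "LBPConfig",
    "ANGLE_OFFSETS",
    "GLCM_FEATURE_NAMES",
    "compute_glcm",
    "glcm_properties",
    "glcm_feature_vector",
    "lbp_code_image",
    "lbp_histogram",
]

#: (row, col) displacement per unit distance for each supported angle,
#: with row 0 at the top of the image.
ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

GLCM_FEATURE_NAMES = ("contrast", "dissimilarity", "homogeneity", "energy", "correlation")


@dataclass(frozen=True)
class GLCMConfig:
    """Configuration of the co-occurrence computation.

    ``energy_mode`` selects between the square root of the angular second
    moment (``"sqrt_asm"``, the common library convention) and the raw
    angular second moment (``"asm"``).
    """

    distance: int = 1
    angles: tuple[int, ...] = (0, 45, 90, 135)
    levels: int = 256
    symmetric: bool = True
    normalized: bool = True
    energy_mode: str = "sqrt_asm"

    def __post_init__(self) -> None:
        if self.distance < 1:
            raise ValueError(f"distance must be >= 1, got {self.distance}")
        if not self.angles:
            raise ValueError("angles must be non-empty")
        bad = [a for a in self.angles if a not in ANGLE_OFFSETS]
        if bad:
            raise ValueError(f"unsupported angles {bad}; choose from {sorted(ANGLE_OFFSETS)}")
        if self.energy_mode not in ("sqrt_asm", "asm"):
            raise ValueError(f"energy_mode must be 'sqrt_asm' or 'asm', got {self.energy_mode!r}")


class GLCMFeatures(NamedTuple):
    """The 5-vector of GLCM statistics, in fixed order (C, D, H, E, Corr)."""

    contrast: float
    dissimilarity: float
    homogeneity: float
    energy: float
    correlation: float

    def as_array(self) -> np.ndarray:
        return np.asarray(self, dtype=np.float64)


@dataclass(frozen=True)
class GLCMatrix:
    """An L x L co-occurrence matrix at one angle, plus its configuration."""

    P: np.ndarray
    config: GLCMConfig
    angle: int

    @property
    def marginal_means(self) -> tuple[float, float]:
        """(mu_i, mu_j): means of the row and column marginal distributions."""
        levels = np.arange(self.P.shape[0], dtype=np.float64)
        px = self.P.sum(axis=1)
        py = self.P.sum(axis=0)
        return float(levels @ px), float(levels @ py)

    @property
    def marginal_stds(self) -> tuple[float, float]:
        levels = np.arange(self.P.shape[0], dtype=np.float64)
        px = self.P.sum(axis=1)
        py = self.P.sum(axis=0)
        mu_i, mu_j = self.marginal_means
        var_i = float(((levels - mu_i) ** 2) @ px)
        var_j = float(((levels - mu_j) ** 2) @ py)
        return float(np.sqrt(var_i)), float(np.sqrt(var_j))


def compute_glcm(image: GrayImage, config: GLCMConfig, angle: int) -> GLCMatrix:
    """Count co-occurring gray-level pairs at one (distance, angle) offset.

    Ordered pairs ``(p[r, c], p[r + dr, c + dc])`` are tallied into an
    ``L x L`` matrix; with ``symmetric`` the transpose is added (each pair is
    counted in both directions), and with ``normalized`` the matrix is scaled
    to total weight 1.
    """
    if angle not in config.angles:
        raise ValueError(f"angle {angle} not in configured angles {config.angles}")
    if image.levels > config.levels or int(image.pixels.max()) >= config.levels:
        raise ValueError(
            f"image gray levels exceed config.levels={config.levels}"
        )
    dr, dc = ANGLE_OFFSETS[angle]
    dr *= config.distance
    dc *= config.distance
    h, w = image.pixels.shape
    if h <= abs(dr) or w <= abs(dc):
        raise ValueError(
            f"image {h}x{w} too small for offset ({dr}, {dc}) at angle {angle}"
        )
    r0, r1 = max(0, -dr), h - max(0, dr)
    c0, c1 = max(0, -dc), w - max(0, dc)
    i = image.pixels[r0:r1, c0:c1].ravel()
    j = image.pixels[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    L = config.levels
    P = np.bincount(i.astype(np.int64) * L + j, minlength=L * L).reshape(L, L)
    P = P.astype(np.float64)
    if config.symmetric:
        P = P + P.T
    if config.normalized:
        P /= P.sum()
    return GLCMatrix(P=P, config=config, angle=angle)


def glcm_properties(glcm: GLCMatrix) -> GLCMFeatures:
    """The five statistics of a normalized co-occurrence matrix.

    contrast      = sum P(i,j) (i-j)^2
    dissimilarity = sum P(i,j) |i-j|
    homogeneity   = sum P(i,j) / (1 + |i-j|)
    energy        = sqrt(sum P(i,j)^2)      (or the raw sum under "asm")
    correlation   = sum P(i,j) (i-mu_i)(j-mu_j) / (sigma_i sigma_j)

    A matrix with zero marginal variance (a constant image) is perfectly
    self-correlated; its correlation is defined as 1.
    """
    P = glcm.P
    total = P.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"glcm_properties requires a normalized matrix (sum={total})")
    L = P.shape[0]
    levels = np.arange(L, dtype=np.float64)
    diff = levels[:, None] - levels[None, :]
    contrast = float((P * diff**2).sum())
    dissimilarity = float((P * np.abs(diff)).sum())
    homogeneity = float((P / (1.0 + np.abs(diff))).sum())
    asm = float((P**2).sum())
    energy = float(np.sqrt(asm)) if glcm.config.energy_mode == "sqrt_asm" else asm
    mu_i, mu_j = glcm.marginal_means
    sigma_i, sigma_j = glcm.marginal_stds
    denom = sigma_i * sigma_j
    if denom <= 0.0:
        correlation = 1.0
    else:
        correlation = float(
            (P * (levels[:, None] - mu_i) * (levels[None, :] - mu_j)).sum() / denom
        )
    return GLCMFeatures(contrast, dissimilarity, homogeneity, energy, correlation)


def glcm_feature_vector(image: GrayImage, config: GLCMConfig | None = None) -> GLCMFeatures:
    """Per-angle GLCM statistics averaged element-wise over the configured angles.

    Averaging the four per-angle 5-vectors yields one orientation-pooled
    5-vector, keeping the feature count at five regardless of the number of
    angles.
    """
    if config is None:
        config = GLCMConfig(levels=image.levels)
    per_angle = np.stack(
        [glcm_properties(compute_glcm(image, config, a)).as_array() for a in config.angles]
    )
    return GLCMFeatures(*per_angle.mean(axis=0))


@dataclass(frozen=True)
class LBPConfig:
    """LBP sampling geometry: 8 points on a radius-1 circle.

    With nearest-neighbor sampling this is exactly the classic 3x3 operator;
    other geometries would change the histogram length and are not supported.
    """

    points: int = 8
    radius: float = 1.0

    def __post_init__(self) -> None:
        if self.points != 8 or self.radius != 1.0:
            raise ValueError(
                "only the reference configuration (8 points, radius 1) is supported"
            )

    @property
    def n_bins(self) -> int:
        return 2**self.points


# 3x3 neighbors enumerated clockwise from the top-left; bit p has weight 2^p.
_LBP_OFFSETS = ((-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1))


def lbp_code_image(image: GrayImage, config: LBPConfig | None = None) -> np.ndarray:
    """8-bit LBP code for every interior pixel (border excluded).

    Bit ``p`` is set when the p-th neighbor (clockwise from top-left) is
    greater than **or equal to** the center; ties count as 1.
    """
    if config is None:
        config = LBPConfig()
    px = image.pixels
    h, w = px.shape
    if h < 3 or w < 3:
        raise ValueError(f"LBP needs an interior: image {h}x{w} is smaller than 3x3")
    center = px[1:-1, 1:-1]
    codes = np.zeros(center.shape, dtype=np.int64)
    for p, (dr, dc) in enumerate(_LBP_OFFSETS):
        neighbor = px[1 + dr : h - 1 + dr, 1 + dc : w - 1 + dc]
        codes |= (neighbor >= center).astype(np.int64) << p
    return codes


def lbp_histogram(codes: np.ndarray, n_bins: int = 256) -> np.ndarray:
    """Normalized frequency of each LBP code value (sums to 1)."""
    codes = np.asarray(codes)
    if codes.size == 0:
        raise ValueError("empty code grid")
    counts = np.bincount(codes.ravel(), minlength=n_bins)
    if len(counts) > n_bins:
        raise ValueError(f"code values exceed {n_bins - 1}")
    return counts / counts.sum()
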