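"""Composite feature construction.

From one image, the pipeline derives six ingredient blocks:

* ``glcm`` — the 5 orientation-pooled GLCM statistics g = (C, D, H, E, Corr);
* ``lbp`` — the 256-bin normalized LBP histogram l;
* ``interaction`` — the outer product g (x) l flattened row-major (1280 values),
  each entry the product of one GLCM statistic and one LBP bin frequency;
* ``aggregated`` — sum, mean, median of g;
* ``statistical`` — population variance, skewness, excess kurtosis of g;
* ``nonlinear`` — element-wise log(1 + g), optional.

The reference configuration concatenates the first five blocks into a
5 + 256 + 1280 + 3 + 3 = 1547-dimensional vector.  The nonlinear block can be
appended (1552 values) or substituted for the raw GLCM block (1547 values);
interaction features always use the raw, untransformed GLCM vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .io import GrayImage
from .texture import (
    GLCM_FEATURE_NAMES,
    GLCMConfig,
    LBPConfig,
    glcm_feature_vector,
    lbp_code_image,
    lbp_histogram,
)

__all__ = [
    "InteractionFeatures",
    "AggregatedFeatures",
    "StatisticalFeatures",
    "CompositeConfig",
    "CompositeFeatureVector",
    "interaction_features",
    "aggregated_features",
    "statistical_features",
    "nonlinear_features",
    "composite_vector",
    "feature_names",
    "REFERENCE_LENGTH",
]

#: Length of the reference-configuration composite vector.
REFERENCE_LENGTH = 5 + 256 + 5 * 256 + 3 + 3


@dataclass(frozen=True)
class InteractionFeatures:
    """Outer-product interaction matrix M with M[i, j] = g[i] * l[j]."""

    matrix: np.ndarray
    flat: np.ndarray


class AggregatedFeatures(NamedTuple):
    g_sum: float
    g_mean: float
    g_median: float


class StatisticalFeatures(NamedTuple):
    variance: float
    skewness: float
    kurtosis: float  # excess kurtosis (normal distribution -> 0)


def interaction_features(g: np.ndarray, l: np.ndarray) -> InteractionFeatures:
    """Outer product of the GLCM statistic vector and the LBP histogram.

    ``flat`` is the row-major flattening: entry ``(i - 1) * n + j`` (1-based)
    equals ``g_i * l_j``.
    """
    g = np.asarray(g, dtype=np.float64)
    l = np.asarray(l, dtype=np.float64)
    if g.ndim != 1 or l.ndim != 1 or g.size == 0 or l.size == 0:
        raise ValueError("g and l must be non-empty 1-D vectors")
    if not (np.isfinite(g).all() and np.isfinite(l).all()):
        raise ValueError("interaction features require finite inputs")
    M = np.outer(g, l)
    return InteractionFeatures(matrix=M, flat=M.ravel())


def aggregated_features(g: np.ndarray) -> AggregatedFeatures:
    """Sum, arithmetic mean, and median of the GLCM statistic vector.

    The median follows the sorted-midpoint rule: the central order statistic
    for odd length, the mean of the two central ones for even length.
    """
    g = np.asarray(g, dtype=np.float64)
    if g.ndim != 1 or g.size == 0:
        raise ValueError("aggregated features require a non-empty 1-D vector")
    if not np.isfinite(g).all():
        raise ValueError("aggregated features require finite inputs")
    return AggregatedFeatures(float(g.sum()), float(g.mean()), float(np.median(g)))


def statistical_features(g: np.ndarray) -> StatisticalFeatures:
    """Population variance, skewness, and excess kurtosis of g.

    All moments use the 1/m (population) normalization:

        variance = (1/m) sum (g_i - mean)^2
        skewness = (1/m) sum ((g_i - mean) / std)^3
        kurtosis = (1/m) sum ((g_i - mean) / std)^4 - 3

    A constant vector has zero standard deviation; its skewness and kurtosis
    are defined as 0 so constant-texture images stay finite.
    """
    g = np.asarray(g, dtype=np.float64)
    if g.ndim != 1 or g.size == 0:
        raise ValueError("statistical features require a non-empty 1-D vector")
    if not np.isfinite(g).all():
        raise ValueError("statistical features require finite inputs")
    mean = g.mean()
    centered = g - mean
    variance = float((centered**2).mean())
    std = np.sqrt(variance)
    if std == 0.0:
        return StatisticalFeatures(0.0, 0.0, 0.0)
    z = centered / std
    return StatisticalFeatures(variance, float((z**3).mean()), float((z**4).mean() - 3.0))


def nonlinear_features(g: np.ndarray) -> np.ndarray:
    """Element-wise natural log of (1 + g); requires every g_i > -1.

    The +1 shift keeps the transform defined at 0 (log 1 = 0), so statistics
    that vanish on flat textures map to 0 rather than -inf.
    """
    g = np.asarray(g, dtype=np.float64)
    if not np.isfinite(g).all():
        raise ValueError("nonlinear features require finite inputs")
    if (g <= -1.0).any():
        raise ValueError("log(1 + g) undefined: some g_i <= -1")
    return np.log1p(g)


@dataclass(frozen=True)
class CompositeConfig:
    """Configuration of the composite extraction.

    ``include_nonlinear`` turns the log-transform block on; ``nonlinear_mode``
    chooses between appending it after the statistical block (``"append"``,
    length 1552) and substituting it for the raw GLCM block (``"substitute"``,
    length 1547).
    """

    glcm: GLCMConfig = field(default_factory=GLCMConfig)
    lbp: LBPConfig = field(default_factory=LBPConfig)
    include_nonlinear: bool = False
    nonlinear_mode: str = "append"

    def __post_init__(self) -> None:
        if self.nonlinear_mode not in ("append", "substitute"):
            raise ValueError(
                f"nonlinear_mode must be 'append' or 'substitute', got {self.nonlinear_mode!r}"
            )

    @property
    def n_features(self) -> int:
        if self.include_nonlinear and self.nonlinear_mode == "append":
            return REFERENCE_LENGTH + 5
        return REFERENCE_LENGTH


@dataclass(frozen=True)
class CompositeFeatureVector:
    """The concatenated per-image feature vector with named block slices."""

    values: np.ndarray
    blocks: dict[str, slice]
    column_names: tuple[str, ...]

    def block(self, name: str) -> np.ndarray:
        return self.values[self.blocks[name]]

    def __len__(self) -> int:
        return self.values.shape[0]


def _block_layout(config: CompositeConfig) -> list[tuple[str, int]]:
    if config.include_nonlinear and config.nonlinear_mode == "substitute":
        first = ("nonlinear", 5)
    else:
        first = ("glcm", 5)
    layout = [first, ("lbp", 256), ("interaction", 5 * 256), ("aggregated", 3), ("statistical", 3)]
    if config.include_nonlinear and config.nonlinear_mode == "append":
        layout.append(("nonlinear", 5))
    return layout


def feature_names(config: CompositeConfig | None = None) -> list[str]:
    """Ordered column names matching :func:`composite_vector` output."""
    if config is None:
        config = CompositeConfig()
    names: list[str] = []
    for block, size in _block_layout(config):
        if block == "glcm":
            names += [f"glcm_{n}" for n in GLCM_FEATURE_NAMES]
        elif block == "nonlinear":
            names += [f"nl_{n}" for n in GLCM_FEATURE_NAMES]
        elif block == "lbp":
            names += [f"lbp_{b:03d}" for b in range(256)]
        elif block == "interaction":
            names += [f"ix_{i}_{j}" for i in range(5) for j in range(256)]
        elif block == "aggregated":
            names += ["agg_sum", "agg_mean", "agg_median"]
        elif block == "statistical":
            names += ["stat_variance", "stat_skewness", "stat_kurtosis"]
    return names


def composite_vector(
    image: GrayImage, config: CompositeConfig | None = None
) -> CompositeFeatureVector:
    """Extract the full composite feature vector for one image.

    Blocks are concatenated in the fixed order glcm, lbp, interaction,
    aggregated, statistical (plus the optional nonlinear block); the
    reference configuration yields exactly 1547 values.
    """
    if config is None:
        config = CompositeConfig()
    g = glcm_feature_vector(image, config.glcm).as_array()
    l = lbp_histogram(lbp_code_image(image, config.lbp))
    parts: dict[str, np.ndarray] = {
        "glcm": g,
        "lbp": l,
        "interaction": interaction_features(g, l).flat,
        "aggregated": np.asarray(aggregated_features(g), dtype=np.float64),
        "statistical": np.asarray(statistical_features(g), dtype=np.float64),
    }
    if config.include_nonlinear:
        parts["nonlinear"] = nonlinear_features(g)
    layout = _block_layout(config)
    values = np.concatenate([parts[name] for name, _ in layout])
    blocks: dict[str, slice] = {}
    start = 0
    for name, size in layout:
        blocks[name] = slice(start, start + size)
        start += size
    return CompositeFeatureVector(
        values=values, blocks=blocks, column_names=tuple(feature_names(config))
    )
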