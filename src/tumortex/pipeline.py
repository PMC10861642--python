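"""End-to-end runs: extract features from an image folder, train, evaluate.

A run is driven by a single :class:`PipelineConfig`, serialized as strict
YAML (unknown keys are rejected so a typo cannot silently fall back to a
default).  Outputs are plain text: CSV feature tables, a JSON metrics report
with a provenance block, CSV confusion matrix and per-class ROC points.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .classify import (
    SplitSpec,
    decision_scores,
    evaluate,
    fit_linear_svm,
    roc_ovr,
    stratified_split,
)
from .composite import CompositeConfig, composite_vector, feature_names
from .io import (
    FeatureTable,
    LabeledImage,
    load_grayscale,
    read_feature_table,
    write_feature_table,
)
from .texture import GLCMConfig, LBPConfig

__all__ = [
    "PipelineConfig",
    "extract_table",
    "collect_images",
    "run_extract",
    "run_train_eval",
]

logger = logging.getLogger("tumortex")

IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg", ".tif", ".tiff")


def _dataclass_from_dict(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(data)
    if "angles" in kwargs and kwargs["angles"] is not None:
        kwargs["angles"] = tuple(kwargs["angles"])
    return cls(**kwargs)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a reproducible extract/train/evaluate run depends on."""

    glcm: GLCMConfig = field(default_factory=GLCMConfig)
    lbp: LBPConfig = field(default_factory=LBPConfig)
    include_nonlinear: bool = False
    nonlinear_mode: str = "append"
    svm_c: float = 1.0
    svm_seed: int = 0
    split: SplitSpec = field(default_factory=SplitSpec)
    levels: int = 256

    def composite(self) -> CompositeConfig:
        return CompositeConfig(
            glcm=self.glcm,
            lbp=self.lbp,
            include_nonlinear=self.include_nonlinear,
            nonlinear_mode=self.nonlinear_mode,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "glcm" in data:
            data["glcm"] = _dataclass_from_dict(GLCMConfig, data["glcm"])
        if "lbp" in data:
            data["lbp"] = _dataclass_from_dict(LBPConfig, data["lbp"])
        if "split" in data:
            data["split"] = _dataclass_from_dict(SplitSpec, data["split"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})


def extract_table(
    images: Sequence[LabeledImage], config: CompositeConfig | None = None
) -> FeatureTable:
    """Composite feature vectors for a batch of labeled images."""
    if config is None:
        config = CompositeConfig()
    if len(images) == 0:
        raise ValueError("no images to extract")
    names = feature_names(config)
    rows = np.empty((len(images), len(names)), dtype=np.float64)
    source_ids, labels = [], []
    for i, item in enumerate(images):
        rows[i] = composite_vector(item.image, config).values
        source_ids.append(item.source_id or f"image_{i:05d}")
        labels.append(item.label)
        if (i + 1) % 100 == 0:
            logger.info("extracted %d/%d images", i + 1, len(images))
    return FeatureTable(
        source_ids=source_ids, labels=labels, values=rows, column_names=names
    )


def collect_images(input_dir: str | Path, levels: int = 256) -> list[LabeledImage]:
    """Load labeled images from ``input_dir``.

    Two layouts are supported: class subdirectories (label = directory name)
    or a ``manifest.csv`` with ``source_id`` and ``label`` columns naming
    image files at the top level.  Unreadable files are skipped with a
    warning.
    """
    input_dir = Path(input_dir)
    if not input_dir.is_dir():
        raise FileNotFoundError(f"input directory not found: {input_dir}")
    items: list[LabeledImage] = []
    manifest = input_dir / "manifest.csv"
    if manifest.exists():
        import pandas as pd

        df = pd.read_csv(manifest, dtype=str)
        for _, row in df.iterrows():
            path = input_dir / f"{row['source_id']}.png"
            if not path.exists():
                candidates = [
                    input_dir / f"{row['source_id']}{s}" for s in IMAGE_SUFFIXES
                ]
                path = next((c for c in candidates if c.exists()), path)
            try:
                img = load_grayscale(path, levels=levels)
            except Exception as exc:  # noqa: BLE001 - skip-and-report contract
                warnings.warn(f"skipping unreadable image {path}: {exc}")
                continue
            items.append(LabeledImage(image=img, label=row["label"], source_id=row["source_id"]))
        return items
    for class_dir in sorted(p for p in input_dir.iterdir() if p.is_dir()):
        for path in sorted(class_dir.iterdir()):
            if path.suffix.lower() not in IMAGE_SUFFIXES:
                continue
            try:
                img = load_grayscale(path, levels=levels)
            except Exception as exc:  # noqa: BLE001
                warnings.warn(f"skipping unreadable image {path}: {exc}")
                continue
            items.append(
                LabeledImage(image=img, label=class_dir.name, source_id=path.stem)
            )
    return items


def run_extract(
    input_dir: str | Path, out_csv: str | Path, config: PipelineConfig | None = None
) -> FeatureTable:
    """Extract composite features for every image under ``input_dir`` to CSV."""
    if config is None:
        config = PipelineConfig()
    images = collect_images(input_dir, levels=config.levels)
    if not images:
        raise FileNotFoundError(f"no readable images found under {input_dir}")
    table = extract_table(images, config.composite())
    write_feature_table(table, out_csv)
    return table


def _provenance(config: PipelineConfig) -> dict:
    return {
        "package": "tumortex",
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.split.seed,
    }


def run_train_eval(
    table_path: str | Path, out_dir: str | Path, config: PipelineConfig | None = None
) -> dict:
    """Split, train the linear SVM, evaluate, and write all reports.

    Writes ``metrics.json`` (per-class/macro/micro metrics, Dice, AUC, and a
    provenance block), ``confusion.csv``, and ``roc_<class>.csv`` files into
    ``out_dir``; returns the metrics dictionary.  Deterministic for a fixed
    config, so reruns produce byte-identical output.
    """
    if config is None:
        config = PipelineConfig()
    table = read_feature_table(table_path)
    if len(set(table.labels)) < 2:
        raise ValueError("feature table contains fewer than 2 classes")
    train, test = stratified_split(table, config.split)
    model = fit_linear_svm(train, C=config.svm_c, seed=config.svm_seed)
    cm, report = evaluate(model, test)
    roc = roc_ovr(decision_scores(model, test), test.labels, model.classes)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "provenance": _provenance(config),
        "n_train": len(train),
        "n_test": len(test),
        "metrics": report.to_dict(),
        "confusion": {
            "labels": list(cm.labels),
            "counts": cm.counts.tolist(),
        },
    }
    with open(out_dir / "metrics.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out_dir / "confusion.csv", "w") as fh:
        fh.write("," + ",".join(cm.labels) + "\n")
        for label, row in zip(cm.labels, cm.counts):
            fh.write(label + "," + ",".join(str(int(v)) for v in row) + "\n")
    for label, (fpr, tpr, thr) in roc.curves.items():
        with open(out_dir / f"roc_{label}.csv", "w") as fh:
            fh.write("fpr,tpr,threshold\n")
            for a, b, c in zip(fpr, tpr, thr):
                fh.write(f"{a:.17g},{b:.17g},{c:.17g}\n")
    return payload


def plot_roc(roc, path: str | Path) -> None:
    """Write a one-vs-rest ROC plot (PNG) for a :class:`ROCResult`."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for label, (fpr, tpr, _) in roc.curves.items():
        ax.plot(fpr, tpr, label=f"{label} (AUC={roc.auc_per_class[label]:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(f"One-vs-rest ROC (micro AUC={roc.auc_micro:.3f})")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
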