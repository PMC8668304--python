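"""End-to-end pipeline: phantom generation -> preprocessing -> skull
stripping -> FCNN segmentation -> postprocessing -> classification ->
evaluation, with a manifest capturing the fully resolved configuration.

A single global seed fans out to per-stage seeds (seed + CRC32 of the
stage name, mod 2^31) so any stage can be rerun in isolation and still be
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as clf
from . import evaluate as ev
from . import postprocess as post
from . import preprocess as pre
from . import segnet
from . import skullstrip as strip
from .errors import ConfigError, DependencyError
from .io import write_json
from .phantom import (
    NoiseSpec,
    PhantomDataset,
    PhantomSpec,
    SkullRingSpec,
    TumorSpec,
    generate_dataset,
)

log = logging.getLogger("tumorseg")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(global_seed) + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """Desk-scale defaults: 200 phantoms, 64x64, noise sigma 0.05."""

    seed: int = 0
    out_dir: str = "runs/latest"
    n_images: int = 200
    image_size: int = 64
    tumor_fraction: float = 0.5
    n_subjects: int = 20
    noise_sigma: float = 0.05
    noise_model: str = "gaussian"
    tumor_radius_px: float = 9.0
    preprocess_enabled: bool = True
    skullstrip_enabled: bool = True
    segment_enabled: bool = True
    postprocess_enabled: bool = True
    classify_enabled: bool = True
    segnet_filters: int = 32
    segnet_epochs: int = 20
    focal_gamma: float = 2.0
    postprocess_cfg: post.PostprocessConfig = field(
        default_factory=lambda: post.PostprocessConfig(min_region_px=10)
    )
    classifier_epochs: int = 15

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "postprocess_cfg" in raw and isinstance(raw["postprocess_cfg"], dict):
            raw = dict(raw)
            raw["postprocess_cfg"] = post.PostprocessConfig(**raw["postprocess_cfg"])
        return cls(**raw)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def subset(dataset: PhantomDataset, idx) -> PhantomDataset:
    idx = list(map(int, idx))
    return PhantomDataset(
        images=[dataset.images[i] for i in idx],
        masks=[dataset.masks[i] for i in idx],
        labels=[dataset.labels[i] for i in idx],
        subject_ids=[dataset.subject_ids[i] for i in idx],
        modality_tags=[dataset.modality_tags[i] for i in idx],
        specs=[dataset.specs[i] for i in idx] if dataset.specs else [],
    )


def make_base_spec(config: PipelineConfig) -> PhantomSpec:
    # ring geometry scales with the slice so the skull stays inside the
    # field of view with a background margin, as in a real axial slice
    return PhantomSpec(
        height=config.image_size,
        width=config.image_size,
        skull_ring=SkullRingSpec(
            inner_radius_frac=0.75, thickness_px=max(2.0, 0.05 * config.image_size)
        ),
        tumor=TumorSpec(radius_px=config.tumor_radius_px),
        noise=NoiseSpec(model=config.noise_model, sigma=config.noise_sigma),
    )


def _prepare_stage(dataset: PhantomDataset, config: PipelineConfig) -> PhantomDataset:
    """Preprocess and skull-strip every image, keeping masks aligned."""
    images = []
    for img in dataset.images:
        out = img
        if config.preprocess_enabled:
            out = pre.preprocess_image(out)
        if config.skullstrip_enabled:
            out, _ = strip.strip_skull(out)
        images.append(out)
    return PhantomDataset(
        images=images,
        masks=dataset.masks,
        labels=dataset.labels,
        subject_ids=dataset.subject_ids,
        modality_tags=dataset.modality_tags,
        specs=dataset.specs,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns a dict of in-memory artifacts and
    writes masks/metrics/history/manifest under ``config.out_dir``."""
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    log.info("generate: %d phantoms (%dx%d)", config.n_images, config.image_size, config.image_size)
    data = generate_dataset(
        config.n_images,
        tumor_fraction=config.tumor_fraction,
        n_subjects=config.n_subjects,
        base_spec=make_base_spec(config),
        seed=stage_seed(config.seed, "phantom"),
    )
    artifacts["dataset"] = data

    log.info("preprocess + skullstrip")
    prepared = _prepare_stage(data, config)
    artifacts["prepared"] = prepared

    split = ev.split_dataset(len(prepared), seed=stage_seed(config.seed, "split"))
    artifacts["split"] = split
    fit_idx = np.concatenate([split.train_idx, split.val_idx])
    val_frac = len(split.val_idx) / len(fit_idx)

    seg_metrics = None
    if config.segment_enabled:
        log.info("train-seg: %d epochs", config.segnet_epochs)
        model = segnet.build_fcnn(
            segnet.NetworkSpec(n_filters=config.segnet_filters),
            seed=stage_seed(config.seed, "segnet"),
        )
        train_cfg = segnet.TrainingConfig(
            max_epochs=config.segnet_epochs,
            focal_gamma=config.focal_gamma,
            seed=stage_seed(config.seed, "segnet-train"),
            validation_fraction=val_frac,
        )
        model, history = segnet.train_segmenter(model, subset(prepared, fit_idx), train_cfg)
        history.to_csv(out_dir / "seg_history.csv", index=False)
        artifacts["seg_model"] = model
        artifacts["seg_history"] = history

        dices = []
        cms = []
        for i in split.test_idx:
            prob, raw_mask = segnet.predict_mask(model, prepared.images[i])
            mask = raw_mask
            if config.postprocess_enabled:
                mask = post.postprocess_probability_map(prob[:, :, 1], config.postprocess_cfg)
            cms.append(ev.segmentation_confusion(mask, prepared.masks[i]))
            d = ev.dice_score(mask, prepared.masks[i])
            if not np.isnan(d):
                dices.append(d)
        pooled = ev.ConfusionMatrix(
            TP=sum(c.TP for c in cms), FP=sum(c.FP for c in cms),
            FN=sum(c.FN for c in cms), TN=sum(c.TN for c in cms),
        )
        seg_metrics = ev.metrics(pooled)
        artifacts["seg_metrics"] = seg_metrics
        artifacts["seg_mean_dice"] = float(np.mean(dices)) if dices else float("nan")
    elif config.postprocess_enabled:
        raise DependencyError("postprocess requires the segment stage")

    clf_metrics = None
    if config.classify_enabled:
        log.info("train-clf: %d epochs", config.classifier_epochs)
        cmodel = clf.adapt_backbone(seed=stage_seed(config.seed, "classify"))
        clf_cfg = clf.TransferConfig(
            epochs=config.classifier_epochs,
            seed=stage_seed(config.seed, "classify-train"),
            validation_fraction=val_frac,
        )
        cmodel, chistory = clf.train_classifier(cmodel, subset(prepared, fit_idx), clf_cfg)
        chistory.to_csv(out_dir / "clf_history.csv", index=False)
        artifacts["clf_model"] = cmodel
        artifacts["clf_history"] = chistory

        test = subset(prepared, split.test_idx)
        preds = clf.predict_labels(cmodel, test.images)
        cm = ev.confusion(test.labels, preds, positive="tumor")
        clf_metrics = ev.metrics(cm)
        artifacts["clf_confusion"] = cm
        artifacts["clf_metrics"] = clf_metrics

    rows = []
    if seg_metrics is not None:
        rows.append({"task": "segmentation", **seg_metrics.as_dict(),
                     "mean_dice_per_image": artifacts["seg_mean_dice"] * 100.0})
    if clf_metrics is not None:
        rows.append({"task": "classification", **clf_metrics.as_dict()})
    if rows:
        pd.DataFrame(rows).to_csv(out_dir / "metrics.csv", index=False)

    resolved = config.resolved()
    manifest = {
        "config": resolved,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(resolved, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "n_train": len(split.train_idx),
        "n_val": len(split.val_idx),
        "n_test": len(split.test_idx),
        "runtime_s": round(time.time() - t0, 2),
    }
    write_json(out_dir / "manifest.json", manifest)
    artifacts["manifest"] = manifest
    return artifacts
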