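"""End-to-end orchestration of the brain-tumor analysis pipeline.

Stage order: phantom generation (or user images) -> greyscale conversion ->
skull stripping -> CLAHE -> GA cluster segmentation -> DWT features on the
segmented region -> PSO feature selection -> classification, evaluated on a
held-out set.

Two classification paths are reported side by side and labelled distinctly:

* ``unet`` — the dual-head U-Net image classifier (the pipeline's stated
  endpoint); and
* ``features`` — a nearest-centroid classifier on the PSO-selected DWT
  features, the consumer that makes the feature-extraction and
  feature-selection stages functional.

Every intermediate artifact (stage PNGs, feature CSV, selection mask JSON,
metrics JSON) is persisted when an output directory is given, and the whole
run is reproducible from config + seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestCentroid
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from . import phantom as ph
from .dwt_features import DWTFeatureExtractor
from .ga_segment import GAClusterSegmenter
from .image import ImageSlice
from .io import write_png
from .metrics import classification_report, mask_overlap
from .preprocess import ClaheConfig, SkullStripConfig, clahe, skull_strip
from .pso_select import PSOFeatureSelector
from .unet_classify import UNetClassifier

log = logging.getLogger("gliopipe")


@dataclass
class RunConfig:
    """Desk-scale defaults; every stage stays configurable."""

    n_train_per_class: int = 5
    n_test_per_class: int = 3
    image_side: int = 64
    seed: int = 0

    run_skull_strip: bool = True
    run_clahe: bool = True
    skull_strip: SkullStripConfig = field(default_factory=SkullStripConfig)
    clahe: ClaheConfig = field(default_factory=ClaheConfig)

    ga_clusters: int = 3
    ga_population: int = 20
    ga_generations: int = 40

    wavelet: str = "haar"
    dwt_levels: int = 2
    strict_formulas: bool = True
    feature_region: str = "tumor"  # or "image"

    pso_particles: int = 20
    pso_iterations: int = 30
    pso_sparsity_weight: float = 0.02

    unet_base_channels: int = 8
    unet_encoder_blocks: int = 4
    unet_epochs: int = 12
    unet_lr: float = 1e-3
    unet_batch_size: int = 4

    save_artifacts: bool = True


def _preprocess_one(sample, cfg: RunConfig):
    """Skull-strip + CLAHE one phantom; returns (enhanced image, brain mask)."""
    img = sample.image
    if cfg.run_skull_strip:
        brain, img = skull_strip(img, cfg.skull_strip)
    else:
        brain = np.ones(img.pixels.shape, bool)
    if cfg.run_clahe:
        enhanced = clahe(img, cfg.clahe)
        lo, hi = enhanced.value_range
        # back to the 0-255 intensity scale so later stages share one range
        px = enhanced.pixels / hi * 255.0
        px[~brain] = 0.0
        img = ImageSlice(px, (0.0, 255.0), {"stage": "clahe"})
    return img, brain


def _stage_dataset(samples, cfg: RunConfig, rng, out_dir, tag):
    """Run preprocessing + GA segmentation for a sample list."""
    images, brains, ga_masks, overlaps = [], [], [], []
    for i, s in enumerate(samples):
        img, brain = _preprocess_one(s, cfg)
        seg = GAClusterSegmenter(
            n_clusters=cfg.ga_clusters, population_size=cfg.ga_population,
            max_generations=cfg.ga_generations,
            random_state=int(rng.integers(2**31 - 1)),
        ).segment(img, brain_mask=brain)
        images.append(img)
        brains.append(brain)
        ga_masks.append(seg.tumor_mask)
        if s.tumor_mask.any():
            overlaps.append(mask_overlap(seg.tumor_mask, s.tumor_mask))
        if out_dir is not None and cfg.save_artifacts:
            d = out_dir / tag
            write_png(d / f"{i:03d}_input.png", s.image)
            write_png(d / f"{i:03d}_preprocessed.png", img)
            write_png(d / f"{i:03d}_brain_mask.png", brain)
            write_png(d / f"{i:03d}_ga_mask.png", seg.tumor_mask)
    return images, brains, ga_masks, overlaps


def run_pipeline(cfg: RunConfig | None = None, out_dir=None) -> dict:
    """Execute all stages and return (and optionally persist) the run report."""
    cfg = cfg or RunConfig()
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    report: dict = {"config": _config_dict(cfg), "stages": {}}
    t0 = time.time()

    def mark(stage, status="done", **extra):
        report["stages"][stage] = {
            "status": status, "elapsed_s": round(time.time() - t0, 3), **extra
        }
        log.info("stage %s: %s (%.1fs)", stage, status, time.time() - t0)

    train, train_manifest = ph.generate_dataset(
        cfg.n_train_per_class, seed=cfg.seed, image_side=cfg.image_side)
    test, test_manifest = ph.generate_dataset(
        cfg.n_test_per_class, seed=cfg.seed + 1, image_side=cfg.image_side)
    if out_dir is not None and cfg.save_artifacts:
        train_manifest.to_csv(out_dir / "train_manifest.csv", index=False)
        test_manifest.to_csv(out_dir / "test_manifest.csv", index=False)
    mark("phantom", n_train=len(train), n_test=len(test))

    tr_imgs, tr_brains, tr_ga, tr_overlap = _stage_dataset(
        train, cfg, rng, out_dir, "train")
    te_imgs, te_brains, te_ga, te_overlap = _stage_dataset(
        test, cfg, rng, out_dir, "test")
    mark("skull_strip", status="done" if cfg.run_skull_strip else "skipped")
    mark("clahe", status="done" if cfg.run_clahe else "skipped")
    mark("ga_segmentation",
         mean_tumor_overlap_train=float(np.mean(tr_overlap)),
         mean_tumor_overlap_test=float(np.mean(te_overlap)))

    extractor = DWTFeatureExtractor(
        wavelet=cfg.wavelet, levels=cfg.dwt_levels,
        strict_formulas=cfg.strict_formulas)
    use_masks = cfg.feature_region == "tumor"
    f_train = extractor.fit(tr_imgs).transform(
        tr_imgs, masks=tr_ga if use_masks else None)
    f_test = extractor.transform(te_imgs, masks=te_ga if use_masks else None)
    y_train = np.array([s.label for s in train])
    y_test = np.array([s.label for s in test])
    names = extractor.get_feature_names_out()
    if out_dir is not None and cfg.save_artifacts:
        df = pd.DataFrame(f_train, columns=names)
        df.insert(0, "label", y_train)
        df.to_csv(out_dir / "features_train.csv", index=False)
    mark("dwt_features", n_features=int(f_train.shape[1]))

    selector = PSOFeatureSelector(
        n_particles=cfg.pso_particles, n_iterations=cfg.pso_iterations,
        sparsity_weight=cfg.pso_sparsity_weight,
        random_state=int(rng.integers(2**31 - 1)),
    ).fit(f_train, y_train)
    if out_dir is not None and cfg.save_artifacts:
        sel_json = {
            str(n): bool(b) for n, b in zip(names, selector.support_)
        }
        (out_dir / "selected_features.json").write_text(
            json.dumps(sel_json, indent=2, sort_keys=True))
    mark("pso_selection", n_selected=int(selector.support_.sum()))

    centroid = make_pipeline(StandardScaler(), NearestCentroid())
    centroid.fit(selector.transform(f_train), y_train)
    feat_pred = centroid.predict(selector.transform(f_test))
    feat_report = classification_report(y_test, feat_pred)
    mark("feature_classifier",
         accuracy=feat_report["overall_accuracy"])

    unet = UNetClassifier(
        n_encoder_blocks=cfg.unet_encoder_blocks,
        base_channels=cfg.unet_base_channels, epochs=cfg.unet_epochs,
        lr=cfg.unet_lr, batch_size=cfg.unet_batch_size,
        random_state=int(rng.integers(2**31 - 1)),
    )
    unet.fit(
        np.stack([im.pixels for im in tr_imgs]), y_train,
        masks=np.stack([s.tumor_mask for s in train]),
    )
    unet_pred = unet.predict(np.stack([im.pixels for im in te_imgs]))
    unet_report = classification_report(y_test, unet_pred)
    seg_prob = unet.predict_seg(np.stack([im.pixels for im in te_imgs]))
    unet_seg_overlap = [
        mask_overlap(seg_prob[i] > 0.5, s.tumor_mask)
        for i, s in enumerate(test) if s.tumor_mask.any()
    ]
    mark("unet", accuracy=unet_report["overall_accuracy"])

    report["segmentation"] = {
        "ga_mean_tumor_overlap": float(np.mean(tr_overlap + te_overlap)),
        "unet_mean_tumor_overlap": float(np.nanmean(unet_seg_overlap)),
    }
    report["classification"] = {
        "unet": unet_report,
        "features": feat_report,
    }
    report["elapsed_s"] = round(time.time() - t0, 3)

    if out_dir is not None:
        # metrics.json is canonical (timings stripped) so identical
        # config+seed runs produce byte-identical files
        (out_dir / "metrics.json").write_text(dump_report(report))
        (out_dir / "run_log.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
    return report


def _strip_timings(obj):
    if isinstance(obj, dict):
        return {k: _strip_timings(v) for k, v in obj.items()
                if k != "elapsed_s"}
    if isinstance(obj, list):
        return [_strip_timings(v) for v in obj]
    return obj


def dump_report(report: dict) -> str:
    """Canonical JSON serialisation: sorted keys, wall-clock timings removed."""
    return json.dumps(_strip_timings(report), indent=2, sort_keys=True,
                      allow_nan=True)


def _config_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    d["skull_strip"]["threshold"] = str(d["skull_strip"]["threshold"])
    return d
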