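"""End-to-end orchestration of the segmentation pipeline.

Stage order: FOV border extension -> per-channel reflex-removing
morphology -> homomorphic illumination correction -> adaptive Wiener
denoising -> channel selection -> oriented ridge bank -> coherence
diffusion -> double-threshold reconstruction -> small-area filtering.
Every stage is deterministic; a RunRecord captures the configuration
snapshot, stage timings, thresholds and diffusion iterations so a run can
be reproduced exactly.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .binarize import VesselSegmentation, binarize_vessels, compute_double_thresholds
from .coherence import coherence_diffusion, max_ridge_response
from .config import PipelineConfig
from .enhance import adaptive_wiener, homomorphic_filter, select_best_channel
from .evaluate import SegmentationMetrics, confusion_metrics, metrics_table
from .exceptions import StageError
from .io import ColorFundusImage, extend_border_outside_fov, read_binary_mask, \
    read_fundus_image, write_segmentation
from .morphology import remove_central_reflex

__all__ = ["RunRecord", "run_pipeline", "evaluate_batch"]

logger = logging.getLogger("retseg")


@dataclass
class RunRecord:
    """Provenance of one pipeline run, sufficient to reproduce it."""

    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    channel_chosen: str = ""
    thresholds: dict = field(default_factory=dict)
    diffusion_iterations: int = 0
    metrics: dict | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str) + "\n")


class _Timer:
    def __init__(self, record: RunRecord):
        self.record = record

    def run(self, stage: str, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:  # annotate failures with the stage name
            raise StageError(stage, exc) from exc
        dt = time.perf_counter() - t0
        self.record.stage_seconds[stage] = round(dt, 4)
        logger.info("stage %-16s %7.2fs", stage, dt)
        return out


def run_pipeline(image: ColorFundusImage, fov: np.ndarray,
                 cfg: PipelineConfig = PipelineConfig()):
    """Segment the vessels of one fundus image.

    Returns (VesselSegmentation, RunRecord).  Deterministic for fixed
    input and configuration.
    """
    record = RunRecord(config=cfg.to_dict())
    timer = _Timer(record)

    channels = image.channels()
    channels = {name: timer.run(f"border[{name}]", extend_border_outside_fov,
                                ch, fov, cfg.border_iterations)
                for name, ch in channels.items()}

    if cfg.enable_morphology:
        channels = {name: timer.run(f"morphology[{name}]", remove_central_reflex,
                                    ch, cfg.morphology, fov)
                    for name, ch in channels.items()}

    if cfg.enable_homomorphic:
        channels = {name: timer.run(f"homomorphic[{name}]", homomorphic_filter,
                                    ch, fov, cfg.homomorphic)
                    for name, ch in channels.items()}

    if cfg.enable_wiener:
        channels = {name: timer.run(f"wiener[{name}]", adaptive_wiener,
                                    ch, cfg.wiener, fov)
                    for name, ch in channels.items()}

    processed = ColorFundusImage(
        red=np.clip(channels["red"], 0, 1),
        green=np.clip(channels["green"], 0, 1),
        blue=np.clip(channels["blue"], 0, 1))
    if cfg.channel == "auto":
        selection = timer.run("channel", select_best_channel, processed, fov)
        chosen = selection.chosen
    else:
        chosen = cfg.channel
    record.channel_chosen = chosen
    working = processed.channels()[chosen]

    # The morphology stage maps vessels to HIGH values; the detector hunts
    # dark ridges, so the default "dark-ridge" polarity negates the working
    # channel unconditionally.  Running with morphology disabled therefore
    # feeds the detector inverted ridges — the breakage the enhancement
    # ablation measures — unless polarity is set to "bright-ridge".
    if cfg.polarity == "dark-ridge":
        working = 1.0 - working

    ridge = timer.run("ridge", max_ridge_response, working, fov, cfg.ridge_with_case())
    response = ridge.response

    if cfg.enable_diffusion:
        response, iters, _trace = timer.run("diffusion", coherence_diffusion,
                                            response, cfg.diffusion, fov)
        record.diffusion_iterations = iters
        response = np.clip(response, 0.0, 1.0)

    thresholds = timer.run("thresholds", compute_double_thresholds, response, fov,
                           cfg.binarize.k_std, cfg.binarize.edge_fraction,
                           cfg.binarize.tail)
    record.thresholds = {"t_low": thresholds.t_low, "t_high": thresholds.t_high}
    logger.info("thresholds t_low=%.4f t_high=%.4f", thresholds.t_low, thresholds.t_high)

    seg: VesselSegmentation = timer.run("binarize", binarize_vessels, response, fov,
                                        thresholds, cfg.binarize.min_area)
    return seg, record


def evaluate_batch(image_dir: str | Path, truth_dir: str | Path,
                   mask_dir: str | Path, cfg: PipelineConfig = PipelineConfig(),
                   out_dir: str | Path | None = None):
    """Segment and score every (image, truth, mask) triple matched by stem.

    Returns a dict of per-image SegmentationMetrics plus a "mean" row;
    unmatched stems are reported and skipped.  When out_dir is given,
    writes metrics.csv, metrics.json and the segmentations.
    """
    image_dir, truth_dir, mask_dir = Path(image_dir), Path(truth_dir), Path(mask_dir)
    images = {p.stem: p for p in sorted(image_dir.iterdir()) if p.is_file()}
    truths = {p.stem: p for p in sorted(truth_dir.iterdir()) if p.is_file()}
    masks = {p.stem: p for p in sorted(mask_dir.iterdir()) if p.is_file()}

    stems = sorted(set(images) & set(truths) & set(masks))
    skipped = sorted((set(images) | set(truths) | set(masks)) - set(stems))
    for stem in skipped:
        logger.warning("skipping %s: missing image, truth or mask", stem)

    rows: dict[str, SegmentationMetrics] = {}
    for stem in stems:
        image = read_fundus_image(images[stem])
        truth = read_binary_mask(truths[stem])
        fov = read_binary_mask(masks[stem])
        seg, _rec = run_pipeline(image, fov, cfg)
        rows[stem] = confusion_metrics(seg.binary, truth, fov)
        if out_dir is not None:
            Path(out_dir).mkdir(parents=True, exist_ok=True)
            write_segmentation(seg, Path(out_dir) / f"{stem}_seg.png")

    if rows:
        mean = {k: float(np.mean([getattr(m, k) for m in rows.values()]))
                for k in ("sensitivity", "specificity", "accuracy", "auc")}
        counts = {k: int(np.sum([getattr(m, k) for m in rows.values()]))
                  for k in ("tp", "fp", "tn", "fn")}
        rows["mean"] = SegmentationMetrics(**counts, **mean)
    else:
        logger.warning("no matching (image, truth, mask) triples found")

    if out_dir is not None and rows:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "metrics.json").write_text(json.dumps(
            {k: m.to_dict() for k, m in rows.items()}, indent=2) + "\n")
        with open(out_dir / "metrics.csv", "w") as fh:
            fh.write("image,se,sp,ac,auc\n")
            for name, m in rows.items():
                r = m.rounded()
                fh.write(f"{name},{r['sensitivity']},{r['specificity']},"
                         f"{r['accuracy']},{r['auc']}\n")
        logger.info("\n%s", metrics_table(rows))
    return rows
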