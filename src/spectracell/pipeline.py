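"""End-to-end pipeline orchestration.

The synthetic end-to-end run mirrors the full analysis: build a spectral
library from single-stain renders, unmix every image, segment nuclei,
train the tissue classifier on the first ``n_train`` images (using their
ground-truth region masks for tile labels), classify tissue everywhere,
quantify and score cells with batch thresholds derived from
negative-control cells, apply the 10%-tissue image QC, and aggregate
region statistics with planned two-group comparisons. Every stage's
output lands on disk; a manifest records the config hash and seed, and
reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import dump_kv, parse_kv, read_kv, write_kv
from .cube import write_abundance_map, write_cube, write_label_mask
from .library import SpectralLibrary, build_library
from .phenotyping import PhenotypeScorer, quantify_cells, qc_filter_images
from .segmentation import (
    SegmentationParams,
    classify_tissue,
    compute_tissue_fraction,
    extract_tile_features,
    segment_nuclei,
    tile_labels_from_region_mask,
    train_tissue_classifier,
)
from .stats import DEFAULT_PLAN, run_comparisons, subsample_cells, summarize_images
from .synthetic import (
    SceneConfig,
    default_endmembers,
    generate_scene,
    single_stain_cube,
)
from .unmixing import to_optical_density, unmix_cube

logger = logging.getLogger("spectracell.pipeline")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of one synthetic end-to-end run."""

    n_images: int = 20
    n_train: int = 10
    seed: int = 0

    i0: float = 255.0
    od_max: float = 3.0
    tile_size: int = 32
    covariance: str = "diag"
    background_tissue_cutoff: float = 0.2
    ring_px: float = 3.0
    percentile_tet: float = 95.0
    percentile_lineage: float = 99.0
    min_control_cells: int = 50
    qc_min_tissue_fraction: float = 0.10
    tissue_od_threshold: float = 0.05
    alpha: float = 0.05
    scatter_cells_per_region: int = 2000
    save_images: bool = False

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    scene: SceneConfig = field(default_factory=SceneConfig)
    plan: list = field(default_factory=lambda: [list(p) for p in DEFAULT_PLAN])

    def __post_init__(self) -> None:
        if not 0 < self.n_train <= self.n_images:
            raise ValueError("need 0 < n_train ≤ n_images")
        if not 0 <= self.qc_min_tissue_fraction <= 1:
            raise ValueError("qc_min_tissue_fraction must be in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scene"] = self.scene.to_dict()
        d["plan"] = {f"comparison_{i}": list(p) for i, p in enumerate(self.plan)}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "scene" in d:
            d["scene"] = SceneConfig.from_dict(d["scene"])
        if "segmentation" in d and isinstance(d["segmentation"], dict):
            d["segmentation"] = SegmentationParams(**d["segmentation"])
        if "plan" in d and isinstance(d["plan"], dict):
            d["plan"] = [list(v) for _, v in sorted(d["plan"].items())]
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(read_kv(path))

    def to_file(self, path: str | Path) -> Path:
        return write_kv(self.to_dict(), path)

    def content_hash(self) -> str:
        return hashlib.sha256(dump_kv(self.to_dict()).encode()).hexdigest()[:16]


def _image_seeds(config: PipelineConfig) -> np.ndarray:
    rng = np.random.default_rng([config.seed, 4])
    return rng.integers(0, 2**31 - 1, size=config.n_images)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full synthetic analysis; returns a dict of output paths.

    Outputs: ``library.csv``, ``cells.csv`` (scored records),
    ``summaries.csv``, ``stats.csv``, ``qc.csv``, ``thresholds.json``,
    ``scatter_cells.csv``, ``manifest.json`` and ``pipeline.log``; with
    ``save_images`` also per-image cubes, abundance maps and masks.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, outdir, log_path)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir: Path, log_path: Path) -> dict:
    stage = "build-library"
    try:
        endmembers = default_endmembers(mode=config.scene.mode)
        stains = [
            (name, single_stain_cube(name, endmembers, seed=config.seed + 17 + i))
            for i, name in enumerate(endmembers.names)
        ]
        library = build_library(stains, i0=config.i0, od_max=config.od_max)
        library.to_csv(outdir / "library.csv")
        logger.info("library built from %d single-stain cubes", len(stains))

        stage = "simulate+unmix+segment"
        seeds = _image_seeds(config)
        per_image = []
        for i, seed in enumerate(seeds):
            image_id = f"img{i:03d}"
            scene_cfg = dataclasses.replace(
                config.scene, seed=int(seed), image_id=image_id
            )
            truth, cube = generate_scene(scene_cfg, endmembers)
            od = to_optical_density(cube, i0=config.i0, od_max=config.od_max)
            abundances = unmix_cube(od, library)
            cells = segment_nuclei(
                abundances.channel(config.scene.nuclear_channel), config.segmentation
            )
            fraction = compute_tissue_fraction(abundances, config.tissue_od_threshold)
            features = extract_tile_features(
                abundances, cells, config.tile_size, config.tissue_od_threshold
            )
            per_image.append(
                {
                    "image_id": image_id,
                    "truth": truth,
                    "cube": cube,
                    "abundances": abundances,
                    "cells": cells,
                    "tissue_fraction": fraction,
                    "features": features,
                }
            )
            logger.info(
                "%s: %d cells segmented, tissue fraction %.3f",
                image_id, cells.n_cells, fraction,
            )

        stage = "train-tissue"
        train_tiles = []
        for item in per_image[: config.n_train]:
            tiles = item["features"].copy()
            labels = tile_labels_from_region_mask(
                item["truth"].region_mask, config.tile_size
            )
            tiles["label"] = labels["label"].to_numpy()
            train_tiles.append(tiles)
        model = train_tissue_classifier(
            pd.concat(train_tiles, ignore_index=True), covariance=config.covariance
        )
        (outdir / "tissue_model.json").write_text(json.dumps(model.to_json(), indent=1))

        stage = "segment-tissue+quantify"
        records = []
        for item in per_image:
            region_mask = classify_tissue(
                model,
                item["features"],
                item["truth"].region_mask.shape,
                config.tile_size,
                config.background_tissue_cutoff,
            )
            item["region_mask"] = region_mask
            records.append(
                quantify_cells(
                    item["cells"],
                    item["abundances"],
                    region_mask,
                    ring_px=config.ring_px,
                    image_id=item["image_id"],
                )
            )
        records = pd.concat(records, ignore_index=True)

        stage = "qc"
        fractions = {item["image_id"]: item["tissue_fraction"] for item in per_image}
        kept, dropped, qc = qc_filter_images(fractions, config.qc_min_tissue_fraction)
        for image_id in dropped:
            logger.info("QC: dropped %s (tissue fraction %.3f)", image_id, fractions[image_id])
        pd.DataFrame([q.__dict__ for q in qc]).to_csv(outdir / "qc.csv", index=False)
        records = records[records["image_id"].isin(kept)].reset_index(drop=True)

        stage = "score"
        train_ids = {item["image_id"] for item in per_image[: config.n_train]}
        control_pool = records[records["image_id"].isin(train_ids)]
        scorer = PhenotypeScorer(
            percentile_tet=config.percentile_tet,
            percentile_lineage=config.percentile_lineage,
            min_control_cells=config.min_control_cells,
        ).fit(control_pool)
        (outdir / "thresholds.json").write_text(
            json.dumps(scorer.thresholds_.to_json(), indent=1)
        )
        scored = scorer.transform(records)
        scored.to_csv(outdir / "cells.csv", index=False)

        stage = "stats"
        summaries = summarize_images(scored)
        summaries.to_csv(outdir / "summaries.csv", index=False)
        results = run_comparisons(
            summaries, plan=[tuple(p) for p in config.plan], alpha=config.alpha
        )
        pd.DataFrame([r.to_row() for r in results]).to_csv(outdir / "stats.csv", index=False)
        scatter = subsample_cells(
            scored, per_region=config.scatter_cells_per_region, seed=config.seed
        )
        scatter.to_csv(outdir / "scatter_cells.csv", index=False)

        if config.save_images:
            stage = "save-images"
            for item in per_image:
                base = outdir / item["image_id"]
                write_cube(item["cube"], base.with_suffix(".cube.tif"))
                write_abundance_map(item["abundances"], base.with_suffix(".abundance.tif"))
                write_label_mask(item["cells"].labels, base.with_suffix(".cells.tif"))
                write_label_mask(item["region_mask"], base.with_suffix(".regions.tif"))
                write_label_mask(
                    item["truth"].region_mask, base.with_suffix(".regions_truth.tif")
                )
                item["truth"].cells.to_csv(base.with_suffix(".truth.csv"), index=False)

        manifest = {
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "version": __version__,
            "numpy": np.__version__,
            "n_images": config.n_images,
            "kept_images": kept,
            "dropped_images": dropped,
            "thresholds": scorer.thresholds_.to_json(),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        config.to_file(outdir / "config.txt")
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "outdir": outdir,
        "cells": outdir / "cells.csv",
        "summaries": outdir / "summaries.csv",
        "stats": outdir / "stats.csv",
        "qc": outdir / "qc.csv",
        "manifest": outdir / "manifest.json",
        "library": outdir / "library.csv",
        "log": log_path,
    }
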