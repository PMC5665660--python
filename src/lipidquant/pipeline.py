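"""End-to-end orchestration: config, per-FOV pipeline, batch runs, manifests.

The per-FOV pipeline is: read (project the z-stack if any) -> preprocess ->
seeded cell segmentation -> border-cell removal -> mask dilation -> HSV
droplet segmentation -> background correction -> component labeling and
multiplicity -> per-cell attribution and FOV summary. Every stage is
deterministic, so a run manifest (inputs + config snapshot) reproduces
outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from lipidquant import image_io
from lipidquant.cell_segmentation import (
    CellLabelMask,
    SegmentationParams,
    dilate_labels,
    remove_border_cells,
    segment_cells,
)
from lipidquant.droplet_segmentation import (
    DropletComponent,
    HSVParams,
    assign_multiplicity,
    background_correct,
    estimate_reference_area,
    hsv_segment,
    label_droplets,
)
from lipidquant.image_io import FieldOfView, RunManifest, SeedSet
from lipidquant.preprocess import PreprocessParams, preprocess
from lipidquant.quantification import (
    CellRecord,
    FOVSummary,
    assign_droplets_to_cells,
    classify_positive_cells,
    summarize_fov,
)
from lipidquant.synthetic_data import SynthConfig, generate_dose_series, generate_fov
from lipidquant.validation_stats import (
    PairedSeries,
    RatingsMatrix,
    cv_paired,
    icc,
    linreg_r2,
)

logger = logging.getLogger("lipidquant")

_SECTIONS = {
    "preprocess": PreprocessParams,
    "cells": SegmentationParams,
    "droplets": HSVParams,
}


@dataclass
class PipelineConfig:
    """All user-definable parameters, grouped by stage."""

    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    cells: SegmentationParams = field(default_factory=SegmentationParams)
    droplets: HSVParams = field(default_factory=HSVParams)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        """Build from a nested dict (e.g. parsed JSON); unknown keys reject."""
        kwargs = {}
        for section, payload in d.items():
            if section not in _SECTIONS:
                raise ValueError(f"unknown config section {section!r}")
            klass = _SECTIONS[section]
            known = {f.name for f in dataclasses.fields(klass)}
            unknown = set(payload) - known
            if unknown:
                raise ValueError(f"unknown key(s) in [{section}]: {sorted(unknown)}")
            payload = {
                k: tuple(v) if isinstance(v, list) else v for k, v in payload.items()
            }
            kwargs[section] = klass(**payload)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class FOVResult:
    """Everything one FOV run produced, including intermediate masks."""

    fov_id: str
    cell_mask: CellLabelMask  # after border removal, before dilation
    dilated_mask: CellLabelMask
    ld_mask_raw: np.ndarray  # HSV foreground before background correction
    ld_mask: np.ndarray  # after background correction
    components: list[DropletComponent]
    records: list[CellRecord]
    summary: FOVSummary


def quantify_fov(
    fov: FieldOfView,
    seeds: SeedSet,
    config: PipelineConfig | None = None,
    fov_id: str = "",
) -> FOVResult:
    """Run the full pipeline on one field of view."""
    config = config or PipelineConfig()
    enhanced = preprocess(fov, config.preprocess)
    cells = segment_cells(enhanced, seeds, config.cells)
    cells = remove_border_cells(cells)
    dilated = dilate_labels(cells, config.cells.dilation_radius_px)
    ld_mask_raw = hsv_segment(fov, config.droplets)
    ld_mask = background_correct(ld_mask_raw, dilated)
    components = label_droplets(ld_mask, config.droplets.min_area_px)
    if components:
        ref = estimate_reference_area(components, config.droplets.circ_min)
        for comp in components:
            assign_multiplicity(
                comp, ref, config.droplets.circ_min, config.droplets.k2, config.droplets.k3
            )
    components = assign_droplets_to_cells(components, dilated)
    records = classify_positive_cells(dilated, ld_mask, components)
    summary = summarize_fov(records, fov_id=fov_id)
    return FOVResult(
        fov_id=fov_id,
        cell_mask=cells,
        dilated_mask=dilated,
        ld_mask_raw=ld_mask_raw,
        ld_mask=ld_mask,
        components=components,
        records=records,
        summary=summary,
    )


def run_quantify(
    image_paths: Sequence[str | Path],
    seed_paths: Sequence[str | Path],
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    strict: bool = False,
    channel_map: dict[str, int] | None = None,
) -> tuple[list[FOVResult], int]:
    """Batch pipeline over image/seed file pairs.

    A failing image is logged and skipped unless ``strict``; returns the
    per-FOV results and the number of failures. When ``out_dir`` is given,
    ``cells.csv``, ``fov_summary.csv`` and ``manifest.json`` are written.
    """
    config = config or PipelineConfig()
    if len(image_paths) != len(seed_paths):
        raise ValueError(
            f"{len(image_paths)} images but {len(seed_paths)} seed files"
        )
    results: list[FOVResult] = []
    n_failed = 0
    for img_path, seed_path in zip(image_paths, seed_paths):
        fov_id = Path(img_path).stem
        try:
            try:
                stack = image_io.read_stack(img_path, channel_map)
                fov = image_io.max_intensity_projection(stack)
            except ValueError:
                fov = image_io.read_image(img_path, channel_map)
            seeds = image_io.read_seeds(seed_path, fov.shape)
            results.append(quantify_fov(fov, seeds, config, fov_id=fov_id))
        except Exception:
            if strict:
                raise
            n_failed += 1
            logger.exception("FOV %s failed; continuing (strict=False)", fov_id)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        per_cell = [
            {
                "fov_id": res.fov_id,
                "cell_label": rec.cell_label,
                "n_droplet_components": rec.n_droplet_components,
                "ld_count": rec.ld_count,
                "is_positive": rec.is_positive,
                "flagged": rec.flagged,
            }
            for res in results
            for rec in res.records
        ]
        image_io.write_results([r.summary for r in results], per_cell, out_dir)
        RunManifest(
            inputs=[str(p) for p in image_paths],
            config=config.to_dict(),
            software_version=_version(),
        ).to_json(out_dir / "manifest.json")
    return results, n_failed


def run_simulate(
    cfg: SynthConfig,
    out_dir: str | Path,
    rate_multipliers: Sequence[float] | None = None,
    fovs_per_arm: int = 1,
) -> list[Path]:
    """Write synthetic FOVs (TIFF + seeds CSV + truth JSON) to ``out_dir``.

    With ``rate_multipliers`` a dose series is written, one subdirectory per
    multiplier. Returns the directories written.
    """
    out_dir = Path(out_dir)
    if rate_multipliers is None:
        batches = [[generate_fov(dataclasses.replace(cfg, rng_seed=(cfg.rng_seed + 7919 * i) % (2**31)))
                    for i in range(fovs_per_arm)]]
        dirs = [out_dir]
    else:
        batches = generate_dose_series(cfg, list(rate_multipliers), fovs_per_arm)
        dirs = [out_dir / f"dose_{m:g}x" for m in rate_multipliers]
    for d, batch in zip(dirs, batches):
        d.mkdir(parents=True, exist_ok=True)
        for i, (fov, seeds, truth) in enumerate(batch):
            stem = f"fov_{i:03d}"
            tifffile.imwrite(d / f"{stem}.tif", fov.pixels)
            pd.DataFrame(seeds.points, columns=["row", "col"]).to_csv(
                d / f"{stem}_seeds.csv", index=False
            )
            truth_payload = {
                "cells": [
                    {
                        "center": list(c.center),
                        "semi_axes": list(c.semi_axes),
                        "droplet_count": c.droplet_count,
                        "positive": c.positive,
                    }
                    for c in truth.cells
                ],
                "total_droplets": truth.total_droplets,
                "pct_positive": truth.pct_positive,
            }
            (d / f"{stem}_truth.json").write_text(json.dumps(truth_payload, indent=2))
    RunManifest(
        inputs=[],
        config=dataclasses.asdict(cfg),
        software_version=_version(),
        random_seed=cfg.rng_seed,
    ).to_json(out_dir / "manifest.json")
    return dirs


def run_validate(ratings: pd.DataFrame | str | Path) -> dict:
    """Agreement statistics from a long table (subject_id, rater_id, value).

    Returns ICC (both variants) and, for exactly two raters, the paired CV
    and the rater-vs-rater regression.
    """
    if not isinstance(ratings, pd.DataFrame):
        ratings = pd.read_csv(ratings)
    required = {"subject_id", "rater_id", "value"}
    if not required.issubset(ratings.columns):
        raise ValueError(f"ratings table needs columns {sorted(required)}")
    wide = ratings.pivot_table(
        index="subject_id", columns="rater_id", values="value", aggfunc="mean"
    )
    m = RatingsMatrix(values=wide.to_numpy(dtype=float))
    out: dict = {
        "n_subjects": int(m.values.shape[0]),
        "n_raters": int(m.values.shape[1]),
        "icc_absolute_agreement": icc(m, "absolute_agreement"),
        "icc_consistency": icc(m, "consistency"),
    }
    if m.values.shape[1] == 2:
        pair = PairedSeries(a=m.values[:, 0], b=m.values[:, 1])
        out["cv_paired_pct"] = cv_paired(pair)
        if m.values.shape[0] >= 3 and np.ptp(m.values[:, 0]) > 0:
            slope, intercept, r2 = linreg_r2(m.values[:, 0], m.values[:, 1])
            out["regression"] = {"slope": slope, "intercept": intercept, "r2": r2}
    return out


def save_overlay(fov: FieldOfView, result: FOVResult, path: str | Path) -> None:
    """Write a PNG of the original image with cell outlines and droplet
    markers — the visual check that droplets fall inside the dilated masks.

    Cell mask boundaries are drawn white, dilated-mask boundaries gray;
    droplet component centroids get a 3 px cross color-coded by
    multiplicity (blue 1, red 2, green 3, matching the annotation scheme).
    """
    from skimage.segmentation import find_boundaries

    rgb = fov.as_rgb().astype(np.float64)
    rgb[find_boundaries(result.cell_mask.labels, mode="outer")] = [255, 255, 255]
    rgb[find_boundaries(result.dilated_mask.labels, mode="outer")] = [160, 160, 160]
    colors = {1: [64, 64, 255], 2: [255, 64, 64], 3: [64, 255, 64]}
    h, w = fov.shape
    for comp in result.components:
        r, c = int(round(comp.centroid[0])), int(round(comp.centroid[1]))
        color = colors.get(comp.multiplicity, [255, 255, 0])
        for dr, dc in [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1), (2, 0), (-2, 0), (0, 2), (0, -2)]:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                rgb[rr, cc] = color
    import imageio.v3 as iio

    iio.imwrite(Path(path), rgb.astype(np.uint8))


def _version() -> str:
    from lipidquant import __version__

    return __version__
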