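"""End-to-end pipeline: simulate -> segment -> map -> stats -> coloc -> MI.

Wires the stage modules together under a single JSON-serializable config and
emits a run manifest (parameter echo, seeds, per-stage output checksums) so a
rerun with the same config is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import (AtlasVolume, SpatialTransform, apply_transform_to_points,
                    assign_regions, make_toy_atlas)
from .colocalization import monte_carlo_components, overlap_test
from .expression import score_genes
from .segmentation import SegmentationConfig, ThresholdClassifier, segment_volume
from .synthetic import (CohortSpec, EffectRegionSpec, PhantomSpec,
                        SyntheticExpressionSpec, generate_cohort,
                        generate_expression_atlas)
from .voxelstats import (SmoothingKernel, aggregate_to_voxels, binarize_sav,
                         region_stats, smooth_spherical, voxelwise_ttest)


@dataclass
class PipelineConfig:
    """Full-run configuration.

    Defaults follow the published analysis where it states a value: 25-um
    atlas grid, 15-voxel spherical smoothing kernel, alpha in {0.05, 0.10},
    500 Monte-Carlo simulations.  Cohort and phantom sizes are demo-scale
    repo choices.
    """

    out_dir: str = "q3d_run"
    seed: int = 0
    # simulation
    n_control: int = 3
    n_treated: int = 3
    n_plaques: int = 80
    # covers a 17-voxel atlas window, comfortably larger than the kernel
    phantom_shape: tuple[int, int, int] = (128, 128, 136)
    effect_metric: str = "count"
    effect_size: float = 0.3
    inter_brain_cv: float = 0.05
    # segmentation
    volume_threshold_um3: float = 200.0
    connectivity: int = 26
    classifier_threshold: float | None = None  # None -> background + 5 sigma
    # stats
    kernel_diameter: int = 15
    alpha: float = 0.05
    # colocalization
    n_sims: int = 500
    sav_connectivity: int = 6
    # expression
    n_genes: int = 200
    n_spots: int = 1500
    mi_bins: int = 2

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        if "phantom_shape" in d:
            d["phantom_shape"] = tuple(d["phantom_shape"])
        return cls(**d)


def _checksum(obj) -> str:
    if isinstance(obj, pd.DataFrame):
        data = obj.to_csv(index=False).encode()
    elif isinstance(obj, np.ndarray):
        data = np.ascontiguousarray(obj).tobytes()
    else:
        data = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(data).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full demo pipeline; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": asdict(config), "stages": {}}

    def fail(stage: str, exc: Exception):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ---- simulate --------------------------------------------------------
    stage = "simulate"
    try:
        phantom = PhantomSpec(shape=config.phantom_shape, n_plaques=config.n_plaques,
                              radius_log_mean=float(np.log(6.0)),
                              radius_log_sigma=0.25, seed=config.seed)
        extent_vox = np.array(config.phantom_shape) * np.array(phantom.voxel_size) / 25.0
        effect = EffectRegionSpec(center_vox=tuple(extent_vox / 2),
                                  radius_vox=float(extent_vox.min() / 4),
                                  affected_metric=config.effect_metric,
                                  effect_size=config.effect_size)
        cohort = CohortSpec(n_control=config.n_control, n_treated=config.n_treated,
                            phantom=phantom, effects=[effect],
                            inter_brain_cv=config.inter_brain_cv, seed=config.seed)
        brains = generate_cohort(cohort, render=True)
        manifest["stages"][stage] = {
            "n_brains": len(brains),
            "truth_checksums": {b.brain_id: _checksum(b.truth) for b in brains},
            "image_checksums": {b.brain_id: _checksum(b.image.h) for b in brains},
        }
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # ---- segment ---------------------------------------------------------
    stage = "segment"
    try:
        thr = config.classifier_threshold
        if thr is None:
            thr = phantom.background[1] + 5 * max(phantom.noise_sigma[1], 1.0)
        seg_cfg = SegmentationConfig(volume_threshold=config.volume_threshold_um3,
                                     connectivity=config.connectivity)
        tables = {}
        for b in brains:
            tables[b.brain_id] = segment_volume(b.image, ThresholdClassifier(thr), seg_cfg)
        manifest["stages"][stage] = {
            "threshold": thr,
            "plaque_counts": {k: len(v) for k, v in tables.items()},
            "checksums": {k: _checksum(v) for k, v in tables.items()},
        }
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # ---- map -------------------------------------------------------------
    stage = "map"
    try:
        transform = SpatialTransform.identity()
        grid_shape = tuple(int(np.ceil(v)) for v in extent_vox)
        atlas = make_toy_atlas(shape=grid_shape)
        mapped = {}
        excluded = {}
        for b in brains:
            plq = tables[b.brain_id].copy()
            pts, valid = apply_transform_to_points(
                plq[["x_um", "y_um", "z_um"]].to_numpy(), transform)
            plq[["x_um", "y_um", "z_um"]] = pts
            plq["region"] = assign_regions(pts, atlas)
            mapped[b.brain_id] = plq.loc[valid].reset_index(drop=True)
            excluded[b.brain_id] = int((~valid).sum())
        manifest["stages"][stage] = {"excluded_points": excluded,
                                     "grid_shape": list(grid_shape)}
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # ---- stats -----------------------------------------------------------
    stage = "stats"
    try:
        kernel = SmoothingKernel(config.kernel_diameter)
        groups = {"treated": [], "control": []}
        for b in brains:
            hm = aggregate_to_voxels(mapped[b.brain_id], grid_shape, b.brain_id)
            groups[b.group].append(smooth_spherical(hm["count"], kernel))
        comparison = voxelwise_ttest(groups["treated"], groups["control"],
                                     brain_mask=atlas.brain_mask)
        sav = binarize_sav(comparison, config.alpha, cohort="demo")
        sav10 = binarize_sav(comparison, 0.10, cohort="demo")
        regions = region_stats(
            [(b.brain_id, b.group, mapped[b.brain_id]) for b in brains], atlas)
        regions.to_csv(out / "region_stats.csv", index=False)
        manifest["stages"][stage] = {
            "tested_voxels": int(comparison.tested_mask.sum()),
            "sav_count_alpha": sav.count,
            "sav_count_0.10": sav10.count,
            "region_table_checksum": _checksum(regions),
        }
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # ---- coloc -----------------------------------------------------------
    stage = "coloc"
    try:
        coloc: dict = {}
        if sav.count and sav10.count:
            ov = overlap_test(sav, sav10, atlas.brain_mask)
            coloc["overlap"] = {"K_a": ov.K_a, "K_b": ov.K_b, "k": ov.k_overlap,
                                "expected": ov.expected_overlap,
                                "p_depletion": ov.p_depletion,
                                "p_enrichment": ov.p_enrichment}
        if sav.count:
            mc = monte_carlo_components(sav, atlas.brain_mask, n_sims=config.n_sims,
                                        connectivity=config.sav_connectivity,
                                        seed=config.seed + 1)
            coloc["clustering"] = {"observed": mc.observed_components,
                                   "null_mean": float(mc.null_components.mean()),
                                   "fold": mc.fold}
        manifest["stages"][stage] = coloc or {"skipped": "empty SAV map"}
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # ---- mi --------------------------------------------------------------
    stage = "mi"
    try:
        expr_spec = SyntheticExpressionSpec(n_genes=config.n_genes,
                                            n_spots=min(config.n_spots,
                                                        int(atlas.brain_mask.sum())),
                                            seed=config.seed + 2)
        reference = sav.grid if sav.count else atlas.brain_mask
        expr, planted = generate_expression_atlas(expr_spec, reference, atlas.brain_mask)
        ranking = score_genes(sav.grid, expr, n_bins=config.mi_bins)
        ranking.to_csv(out / "mi_ranking.csv", index=False)
        manifest["stages"][stage] = {
            "planted_genes": planted,
            "top_gene": ranking["gene"].iloc[0],
            "ranking_checksum": _checksum(ranking),
        }
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
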