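"""Configuration, orchestration and run manifests.

``run_pipeline`` executes the whole analysis on a synthetic scene:
simulate -> feature space -> reference QC -> two-stage classification ->
vereda reclassification -> assessment, writing rasters, tables and a JSON
run manifest sufficient to re-create the run bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml

from . import assess
from .classify import two_stage_routine, TwoStageResult, ClassifiedMap
from .features import (assemble_feature_space, define_seasons,
                       feature_space_config, FeatureSpaceConfig)
from .postprocess import ReclassParams, vereda_reclassify
from .raster import RasterGrid, write_raster
from .reference import mask_burned_zones, rasterize_zones
from .scheme import DEFAULT_SCHEME
from .simulate import (MonthlyClimatology, SceneConfig, default_climatology,
                       default_scene_config, generate_burn_history,
                       generate_image_collections, generate_landscape,
                       generate_reference_sites, generate_terrain)

__all__ = ["PipelineConfig", "RunManifest", "PipelineResult", "load_config",
           "run_pipeline"]

_KNOWN_KEYS = {
    "feature_space", "seed", "n_outer", "n_inner", "n_trees",
    "n_sites_per_class", "season_threshold_mm", "max_cloud_fraction",
    "reclass_max_distance_m", "reclass_window_area_m2",
    "scene",
}
_SCENE_KEYS = {"rows", "cols", "pixel_size", "n_months", "cloud_fraction",
               "burn_fraction", "relief_amplitude", "seed", "signature_sd"}


@dataclass
class PipelineConfig:
    """Validated run configuration with the documented defaults injected:
    100 trees, 50 inner x 10 outer repeats, strict >50% majority, 100 m /
    1 ha vereda rule, 100 mm season threshold, 70% scene cloud limit."""

    feature_space: str = "F6"
    seed: int = 0
    n_outer: int = 10
    n_inner: int = 50
    n_trees: int = 100
    n_sites_per_class: int = 10
    season_threshold_mm: float = 100.0
    max_cloud_fraction: float = 0.7
    scene: SceneConfig = None
    climatology: MonthlyClimatology = field(
        default_factory=default_climatology)
    reclass: ReclassParams = field(default_factory=ReclassParams)

    def __post_init__(self) -> None:
        if self.scene is None:
            self.scene = default_scene_config(seed=self.seed)
        self.features = feature_space_config(self.feature_space)


def load_config(path: str | Path) -> PipelineConfig:
    """Read and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    scene_raw = raw.pop("scene", {}) or {}
    bad = set(scene_raw) - _SCENE_KEYS
    if bad:
        raise ValueError(f"unknown scene keys: {sorted(bad)}")
    fid = raw.get("feature_space", "F6")
    feature_space_config(fid)  # raises on an invalid identifier
    seed = int(raw.get("seed", 0))
    sd = scene_raw.pop("signature_sd", 0.010)
    scene = default_scene_config(
        rows=int(scene_raw.pop("rows", 200)),
        cols=int(scene_raw.pop("cols", 200)),
        sd=float(sd), seed=int(scene_raw.pop("seed", seed)), **scene_raw)
    reclass = ReclassParams(
        max_distance_m=float(raw.get("reclass_max_distance_m", 100.0)),
        window_area_m2=float(raw.get("reclass_window_area_m2", 10_000.0)))
    return PipelineConfig(
        feature_space=fid, seed=seed,
        n_outer=int(raw.get("n_outer", 10)),
        n_inner=int(raw.get("n_inner", 50)),
        n_trees=int(raw.get("n_trees", 100)),
        n_sites_per_class=int(raw.get("n_sites_per_class", 10)),
        season_threshold_mm=float(raw.get("season_threshold_mm", 100.0)),
        max_cloud_fraction=float(raw.get("max_cloud_fraction", 0.7)),
        scene=scene, reclass=reclass)


@dataclass
class RunManifest:
    """Everything needed to re-create a run."""

    feature_space: str
    seed: int
    n_outer: int
    n_inner: int
    n_trees: int
    config_digest: str
    stage_timings_s: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    summaries: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1, default=float))
        return path


@dataclass
class PipelineResult:
    final_map: ClassifiedMap
    routine: TwoStageResult
    manifest: RunManifest
    stage1_oas: list[float]
    stage2_oas: list[float]
    burn_reduction: dict[str, float]
    reclass_report: dict
    area_table: "object | None"


def _digest(cfg: PipelineConfig) -> str:
    blob = json.dumps({
        "feature_space": cfg.feature_space, "seed": cfg.seed,
        "n_outer": cfg.n_outer, "n_inner": cfg.n_inner,
        "n_trees": cfg.n_trees, "scene_seed": cfg.scene.seed,
        "rows": cfg.scene.rows, "cols": cfg.scene.cols,
        "cloud": cfg.scene.cloud_fraction, "burn": cfg.scene.burn_fraction,
    }, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig, outdir: str | Path | None = None
                 ) -> PipelineResult:
    """Execute the full analysis on a synthetic scene."""
    timings: dict[str, float] = {}
    scheme = DEFAULT_SCHEME

    t0 = time.perf_counter()
    labels = generate_landscape(cfg.scene, scheme)
    terrain = generate_terrain(cfg.scene)
    burns = generate_burn_history(labels, cfg.scene)
    optical, sar = generate_image_collections(
        labels, cfg.scene, cfg.climatology, burns,
        season_threshold_mm=cfg.season_threshold_mm)
    zones = generate_reference_sites(labels, cfg.n_sites_per_class,
                                     seed=cfg.scene.seed)
    timings["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    samples = rasterize_zones(zones, labels.grid, scheme)
    if cfg.features.burn_masking:
        samples, reduction = mask_burned_zones(samples, burns.masks, scheme)
    else:
        reduction = {c: 0.0 for c in scheme.stage1_classes}
    timings["reference_qc"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    seasons = define_seasons(cfg.climatology, cfg.season_threshold_mm)
    needs_sar = any(sp.source == "S1" for sp in cfg.features.layers)
    cube = assemble_feature_space(
        cfg.features, optical, sar if needs_sar else None, terrain, seasons,
        cfg.max_cloud_fraction)
    timings["features"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    routine = two_stage_routine(
        cube, samples, scheme, n_outer=cfg.n_outer, n_inner=cfg.n_inner,
        n_trees=cfg.n_trees, seed=cfg.seed, sample_grid=labels.grid)
    timings["classify"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    final_map, reclass_report = vereda_reclassify(routine.overall,
                                                  cfg.reclass)
    timings["postprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    stage1_oas = assess.stage1_run_accuracies(routine, scheme)
    stage2_oas = assess.stage2_run_accuracies(routine, scheme)
    area_table = _area_estimate(final_map, samples, labels, scheme)
    timings["assess"] = time.perf_counter() - t0

    manifest = RunManifest(
        feature_space=cfg.feature_space, seed=cfg.seed,
        n_outer=cfg.n_outer, n_inner=cfg.n_inner, n_trees=cfg.n_trees,
        config_digest=_digest(cfg), stage_timings_s=timings,
        summaries={
            "stage1_oa_median": float(np.median(stage1_oas)),
            "stage2_oa_median": float(np.median(stage2_oas)),
            "burn_reduction_pct": reduction,
            "n_reclassified": reclass_report["n_reclassified"],
        })

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        p = write_raster(RasterGrid(
            final_map.class_codes.astype(float), final_map.grid,
            name="class", nodata=-1), outdir / "map_class.tif")
        manifest.outputs["map_class"] = str(p)
        p = write_raster(RasterGrid(
            final_map.probability, final_map.grid, name="probability"),
            outdir / "map_probability.tif")
        manifest.outputs["map_probability"] = str(p)
        p = write_raster(RasterGrid(
            final_map.stage.astype(float), final_map.grid, name="stage",
            nodata=-1), outdir / "map_stage.tif")
        manifest.outputs["map_stage"] = str(p)
        if area_table is not None:
            area_table.table.to_csv(outdir / "area_estimates.csv",
                                    index=False)
            manifest.outputs["area_estimates"] = \
                str(outdir / "area_estimates.csv")
        manifest.write(outdir / "run_manifest.json")

    return PipelineResult(final_map, routine, manifest, stage1_oas,
                          stage2_oas, reduction, reclass_report, area_table)


def _area_estimate(final_map: ClassifiedMap, samples, labels, scheme):
    """Stratified area estimate of the final map at the formation level.

    Uses the reference pixels as the evaluation sample and the stage-1
    component of the final map as the stratification; strata with fewer
    than two evaluation pixels are dropped (their mapped area is excluded
    from the estimate's total).
    """
    from .reference import active_samples
    samp = active_samples(samples)
    if not samp:
        return None
    lab = final_map.class_labels()
    same_grid = final_map.grid == labels.grid
    truth, pred = [], []
    for s in samp:
        if same_grid:
            p = lab[s.row, s.col]
        else:
            x = labels.grid.origin_x + (s.col + 0.5) * labels.grid.pixel_size
            y = labels.grid.origin_y - (s.row + 0.5) * labels.grid.pixel_size
            r, c = final_map.grid.xy_to_rowcol(x, y)
            if not (0 <= r < final_map.grid.rows
                    and 0 <= c < final_map.grid.cols):
                continue
            p = lab[r, c]
        truth.append(s.formation_class)
        pred.append(scheme.formation(p) if p in scheme.terminal_classes
                    else (p if p in scheme.stage1_classes else ""))
    codes = final_map.class_codes
    mapped: dict[str, int] = {}
    for cls in scheme.stage1_classes:
        n = 0
        for t in ([cls] if cls not in scheme.formations
                  else list(scheme.physiognomies_of(cls)) + [cls]):
            n += int((codes == scheme.code_of[t]).sum())
        mapped[cls] = n
    cm = assess.confusion_matrix(truth, pred, scheme.stage1_classes)
    # drop under-sampled strata so the strict estimator applies
    keep = [i for i, c in enumerate(cm.classes)
            if cm.counts[i].sum() >= 2 or mapped.get(c, 0) == 0]
    if len(keep) < len(cm.classes):
        kept_classes = tuple(cm.classes[i] for i in keep)
        cm = assess.ConfusionMatrix(
            kept_classes, cm.counts[np.ix_(keep, keep)],
            cm.rejected[keep])
        mapped = {c: mapped.get(c, 0) for c in kept_classes}
    try:
        return assess.estimate_areas(cm, mapped,
                                     final_map.grid.pixel_size ** 2)
    except ValueError:
        return None
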