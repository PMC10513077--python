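"""End-to-end pipeline orchestration.

A run generates synthetic two-cohort image data, trains the two
segmentation networks, segments all scenes, computes per-glomerulus
morphometry and its 3D stereological extrapolation, quantifies slit
density on synthetic super-resolution stacks, evaluates the assay
calculations, and compares a morphometric readout between cohorts with
the screening/test-selection battery.  Every stage writes versioned CSV
or TIFF outputs into the run directory and a manifest records the
configuration hash, the seed and per-stage row counts.  Reruns with the
same configuration and seed reproduce all non-training CSVs bit for
bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import measure

from . import assays, io, slit_density, stereology
from .morphometry import (ExclusionConfig, LabeledMask, compute_morphometrics,
                          label_and_filter, morphometry_frame)
from .segmentation import (SegmentationModel, TrainConfig, load_model,
                           predict, save_model, train)
from .slit_density import AggregationPlan
from .stats_battery import StatsConfig, run_battery
from .stereology import StereologyParams
from .synthetic import (SceneParams, Segment, Sinusoid, generate_count_matrix,
                        generate_glomerulus_scene, generate_plate,
                        generate_sted_scene)

logger = logging.getLogger("podometry")

STAGES = ["generate", "train", "segment", "morpho", "stereo", "slit",
          "assay", "stats"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    The two cohorts share all scene parameters except those overridden in
    ``cohort_effects`` — by default cohort B has larger podocyte nuclei,
    giving the statistics stage a real effect to detect.
    """

    outdir: str = "run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    scenes_per_cohort: int = 6
    scene: SceneParams = field(default_factory=lambda: SceneParams(
        frame_size_px=(256, 256), n_glomeruli=1, tuft_radius_um=(6.0, 10.0),
        nuclei_per_glomerulus=(4, 9), nucleus_radius_um=(1.8, 2.6),
    ))
    cohort_effects: dict = field(default_factory=lambda: {
        "B": {"nucleus_radius_um": (2.4, 3.2)}})
    train: TrainConfig = field(default_factory=lambda: TrainConfig(
        epochs=4, crops_per_scene=6, crop_size=128))
    exclusion: ExclusionConfig = field(default_factory=lambda: ExclusionConfig(
        min_area_um2=20.0, max_area_um2=600.0))
    stereology: StereologyParams = field(default_factory=StereologyParams)
    aggregation: AggregationPlan = field(default_factory=lambda: AggregationPlan(
        areas_per_glomerulus=2, glomeruli_per_mouse_min=2))
    stats: StatsConfig = field(default_factory=StatsConfig)
    stats_column: str = "mean_nuclear_area_um2"
    n_slit_fields: int = 8

    def config_hash(self) -> str:
        blob = json.dumps(_as_jsonable(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def config_from_dict(data: dict) -> RunConfig:
    """Build a RunConfig from a (YAML-loaded) plain dict."""
    cfg = RunConfig()
    sub = {
        "scene": SceneParams, "train": TrainConfig,
        "exclusion": ExclusionConfig, "stereology": StereologyParams,
        "aggregation": AggregationPlan, "stats": StatsConfig,
    }
    for key, value in (data or {}).items():
        if key in sub and isinstance(value, dict):
            base = dataclasses.asdict(getattr(cfg, key))
            base.update(value)
            for fname, fval in list(base.items()):
                if isinstance(fval, list):
                    base[fname] = tuple(fval)
            if key == "train" and isinstance(base.get("augmentation"), dict):
                from .segmentation import AugmentConfig, WeightMapParams
                base["augmentation"] = AugmentConfig(**base["augmentation"])
                base["weight_map"] = WeightMapParams(**base["weight_map"])
            setattr(cfg, key, sub[key](**base))
        elif hasattr(cfg, key):
            setattr(cfg, key, value)
        else:
            raise ValueError(f"unknown config key {key!r}")
    return cfg


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run(config: RunConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory.

    A failing stage writes a ``FAILED`` marker naming the stage and
    re-raises; outputs of completed stages are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            manifest["stages"][stage] = {"status": "skipped"}
            continue
        fn = globals()[f"_stage_{stage}"]
        logger.info("stage %s: starting", stage)
        t0 = time.time()
        try:
            counts = fn(config, outdir, state)
        except Exception as exc:  # noqa: BLE001 - marker + re-raise
            (outdir / "FAILED").write_text(f"{stage}: {exc}\n")
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            _write_manifest(outdir, manifest)
            raise StageFailure(stage, exc) from exc
        manifest["stages"][stage] = {
            "status": "ok", "seconds": round(time.time() - t0, 2), **counts}
        logger.info("stage %s: done (%.1fs)", stage, time.time() - t0)
    _write_manifest(outdir, manifest)
    return outdir


def _write_manifest(outdir: Path, manifest: dict) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _cohort_params(config: RunConfig) -> dict[str, SceneParams]:
    cohorts = {"A": config.scene}
    for name, overrides in config.cohort_effects.items():
        base = dataclasses.asdict(config.scene)
        for k, v in overrides.items():
            base[k] = tuple(v) if isinstance(v, list) else v
        cohorts[name] = SceneParams(**base)
    return cohorts


def _scene_list(config: RunConfig):
    """Deterministic (cohort, index, params-with-seed) list."""
    out = []
    for c_i, (cohort, params) in enumerate(sorted(_cohort_params(config).items())):
        for i in range(config.scenes_per_cohort):
            seed = config.seed + 10_000 * (c_i + 1) + i
            out.append((cohort, i, dataclasses.replace(params, seed=seed)))
    return out


def _load_scenes(config: RunConfig):
    """Regenerate the scene set (seeded, so identical across stages)."""
    return [(cohort, i, generate_glomerulus_scene(p))
            for cohort, i, p in _scene_list(config)]


def _stage_generate(config: RunConfig, outdir: Path, state: dict) -> dict:
    img_dir = outdir / "scenes"
    img_dir.mkdir(exist_ok=True)
    rows = []
    scenes = _load_scenes(config)
    for cohort, i, scene in scenes:
        stem = f"{cohort}_{i:03d}"
        io.save_image(img_dir / f"{stem}_wt1.tif", scene.image_wt1)
        io.save_image(img_dir / f"{stem}_nephrin.tif", scene.image_nephrin)
        io.save_labels(img_dir / f"{stem}_tuft_mask.tif", scene.tuft_mask)
        io.save_labels(img_dir / f"{stem}_nuclei_mask.tif", scene.nuclei_mask)
        for g in scene.per_glomerulus:
            rows.append({"cohort": cohort, "scene": i, **g.__dict__})
    truth = pd.DataFrame(rows)
    truth.to_csv(outdir / "truth.csv", index=False)
    state["scenes"] = scenes
    return {"rows": len(truth), "n_scenes": len(scenes)}


def _stage_train(config: RunConfig, outdir: Path, state: dict) -> dict:
    scenes = [s for _, _, s in state.get("scenes") or _load_scenes(config)]
    state.setdefault("models", {})
    for task in ("tuft", "nuclei"):
        cfg = dataclasses.replace(config.train, seed=config.seed)
        model = train(scenes, task, cfg)
        save_model(model, outdir / f"model_{task}")
        model.training_log.to_csv(outdir / f"training_log_{task}.csv", index=False)
        state["models"][task] = model
        logger.info("task %s: validation Dice %.3f", task, model.val_dice)
    return {"tuft_val_dice": state["models"]["tuft"].val_dice,
            "nuclei_val_dice": state["models"]["nuclei"].val_dice}


def _get_models(config: RunConfig, outdir: Path, state: dict):
    models = state.get("models")
    if not models:
        models = {t: load_model(outdir / f"model_{t}") for t in ("tuft", "nuclei")}
        state["models"] = models
    return models


def _stage_segment(config: RunConfig, outdir: Path, state: dict) -> dict:
    scenes = state.get("scenes") or _load_scenes(config)
    state["scenes"] = scenes
    models = _get_models(config, outdir, state)
    seg_dir = outdir / "segmentations"
    seg_dir.mkdir(exist_ok=True)
    n = 0
    preds = {}
    for cohort, i, scene in scenes:
        stem = f"{cohort}_{i:03d}"
        masks = {}
        for task in ("tuft", "nuclei"):
            _, binary = predict(models[task], scene.image_wt1)
            io.save_labels(seg_dir / f"{stem}_{task}_pred.tif",
                           binary.astype(np.int32))
            masks[task] = binary
            n += 1
        preds[(cohort, i)] = masks
    state["predictions"] = preds
    return {"n_masks": n}


def _stage_morpho(config: RunConfig, outdir: Path, state: dict) -> dict:
    scenes = state.get("scenes") or _load_scenes(config)
    preds = state.get("predictions")
    if preds is None:
        seg_dir = outdir / "segmentations"
        if not seg_dir.is_dir():
            raise RuntimeError("segment stage outputs not available")
        preds = {
            (cohort, i): {
                task: io.load_labels(
                    seg_dir / f"{cohort}_{i:03d}_{task}_pred.tif") > 0
                for task in ("tuft", "nuclei")
            }
            for cohort, i, _ in scenes
        }
    ppm = config.scene.pixels_per_micron
    rows, excl_rows = [], []
    for cohort, i, scene in scenes:
        masks = preds[(cohort, i)]
        tuft_lab, report = label_and_filter(masks["tuft"], config.exclusion, ppm)
        nuc_lab = LabeledMask(measure.label(masks["nuclei"], connectivity=1), ppm)
        records = compute_morphometrics(tuft_lab, nuc_lab, scene.image_nephrin)
        df = morphometry_frame(records)
        df.insert(0, "scene", i)
        df.insert(0, "cohort", cohort)
        rows.append(df)
        for comp, reason in report.excluded:
            excl_rows.append({"cohort": cohort, "scene": i,
                              "component": comp, "reason": reason})
    morpho = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    morpho.to_csv(outdir / "morphometry.csv", index=False)
    pd.DataFrame(excl_rows, columns=["cohort", "scene", "component", "reason"]) \
        .to_csv(outdir / "exclusions.csv", index=False)
    state["morphometry"] = morpho
    return {"rows": len(morpho), "excluded": len(excl_rows)}


def _stage_stereo(config: RunConfig, outdir: Path, state: dict) -> dict:
    morpho = state.get("morphometry")
    if morpho is None:
        morpho = pd.read_csv(outdir / "morphometry.csv")
    table = stereology.stereology_table(morpho, config.stereology)
    table.to_csv(outdir / "stereology.csv", index=False)
    return {"rows": len(table)}


def _stage_slit(config: RunConfig, outdir: Path, state: dict) -> dict:
    ppm = 10.0
    rng = np.random.default_rng(config.seed + 777)
    records = []
    truth_rows = []
    for f in range(config.n_slit_fields):
        n_curves = int(rng.integers(3, 6))
        curves = []
        for _ in range(n_curves):
            y0 = float(rng.uniform(2, 18))
            curves.append(Sinusoid(origin=(y0, 1.0), span=18.0,
                                   amplitude=float(rng.uniform(0.5, 1.5)),
                                   wavelength=float(rng.uniform(5, 12))))
        scene = generate_sted_scene(curves, (20.0, 20.0), ppm,
                                    seed=int(rng.integers(2**31)))
        glom = f"g{f // config.aggregation.areas_per_glomerulus}"
        rec = slit_density.slit_density(scene.zstack, ppm,
                                        field_id=f"field{f}",
                                        glomerulus_id=glom, mouse_id="m0")
        records.append(rec)
        truth_rows.append({"field_id": f"field{f}",
                           "true_length_um": scene.true_total_length_um})
    per_field = pd.DataFrame([r.__dict__ for r in records])
    per_field.to_csv(outdir / "slit_fields.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(outdir / "slit_truth.csv", index=False)
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        per_glom, per_mouse = slit_density.aggregate(records, config.aggregation)
    per_glom.to_csv(outdir / "slit_per_glomerulus.csv", index=False)
    per_mouse.to_csv(outdir / "slit_per_mouse.csv", index=False)
    return {"rows": len(per_field)}


def _stage_assay(config: RunConfig, outdir: Path, state: dict) -> dict:
    plate = generate_plate(noise_sd=0.002, seed=config.seed + 31)
    curve = assays.standard_curve_fit(
        plate.standard_concentrations,
        plate.standard_absorbances - plate.blank)
    recovered = curve.concentration(plate.sample_absorbances - plate.blank)
    pd.DataFrame({
        "true_concentration": plate.sample_true_concentrations,
        "recovered_concentration": recovered,
    }).to_csv(outdir / "assay_plate.csv", index=False)

    cm = generate_count_matrix(n_cells=300, seed=config.seed + 32)
    keep, n_kept = assays.qc_filter(cm.counts, cm.gene_names)
    summary = {"cells_total": int(cm.counts.shape[0]),
               "cells_pass_qc": n_kept,
               "true_pass_count": cm.true_pass_count,
               "r_squared": curve.r_squared}
    (outdir / "assay_summary.json").write_text(json.dumps(summary, indent=2))
    return {"rows": len(recovered), "cells_pass_qc": n_kept}


def _stage_stats(config: RunConfig, outdir: Path, state: dict) -> dict:
    morpho = state.get("morphometry")
    if morpho is None:
        morpho = pd.read_csv(outdir / "morphometry.csv")
    col = config.stats_column
    groups = {
        cohort: sub[col].dropna().to_numpy()
        for cohort, sub in morpho.groupby("cohort")
    }
    report = run_battery(groups, config.stats)
    (outdir / "stats_report.json").write_text(
        json.dumps(report.to_dict(), indent=2))
    pd.DataFrame([p.__dict__ for p in report.pairwise]) \
        .to_csv(outdir / "stats_pairwise.csv", index=False)
    return {"branch": report.branch, "omnibus_p": report.omnibus_p}
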