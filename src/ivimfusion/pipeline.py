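"""End-to-end orchestration: simulate -> register -> fit -> statistics.

A single :class:`RunConfig` (loadable from YAML) drives every stage; all
randomness flows from its one seed.  Each stage logs its wall time, writes
its artifacts under the output directory, and contributes input/output
hashes to a run manifest so that two runs with the same config and seed
are bit-identical (timestamps aside).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import AcquisitionScheme
from .fitting import FitConfig, fit_map
from .registration import (
    ROIMask,
    downsample_mask,
    estimate_transform,
    mirror_roi,
    transfer_roi,
    warp_image,
)
from .reports import (
    age_correlation_table,
    diagnostic_accuracy_table,
    diagnostics_json,
    group_comparison_table,
    paired_comparison_table,
)
from .synthetic import Ellipse, SyntheticCohortSpec, make_scene, simulate_cohort

logger = logging.getLogger("ivimfusion")

ALL_STAGES = ("simulate", "register", "fit", "stats")

# fixed sampling ROIs for zone-level medians on the default phantom layout,
# placed away from both default lesion sites and the mirrored contralateral
TZ_SAMPLE_ROI = Ellipse(38, 31, 4, 3)
PZ_SAMPLE_ROI = Ellipse(50, 26, 3, 3)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "synthetic"
    seed: int = 0
    outdir: str = "runs/default"
    stages: tuple[str, ...] = ALL_STAGES
    method: str = "segmented"
    b_values: tuple[float, ...] | None = None
    b_threshold: float = 400.0
    snr: float = 50.0
    n_patients: int = 16
    n_controls: int = 22
    scene_family: str = "polynomial-2"
    scene_points: int = 7
    scene_jitter: float = 0.5
    bsp_iterations: int = 5000
    bsp_burn_in: int = 1000
    write_artifacts: bool = True
    # real-data mode inputs
    dwi_path: str = ""
    t2_path: str = ""
    histology_path: str = ""
    control_points_path: str = ""
    roi_path: str = ""

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        if isinstance(cfg.b_values, list):
            cfg.b_values = tuple(cfg.b_values)
        return cfg

    def scheme(self) -> AcquisitionScheme:
        return AcquisitionScheme(self.b_values) if self.b_values else AcquisitionScheme()

    def fit_config(self) -> FitConfig:
        return FitConfig(
            method=self.method,
            b_threshold=self.b_threshold,
            n_iter=self.bsp_iterations,
            burn_in=self.bsp_burn_in,
            seed=self.seed,
        )


def validate_config(config: RunConfig) -> list[str]:
    """All violations found in a config (empty list = runnable)."""
    findings: list[str] = []
    if config.mode not in ("synthetic", "real"):
        findings.append(f"mode must be 'synthetic' or 'real', got {config.mode!r}")
    if config.method not in ("segmented", "bsp"):
        findings.append(f"method must be 'segmented' or 'bsp', got {config.method!r}")
    for s in config.stages:
        if s not in ALL_STAGES:
            findings.append(f"unknown stage {s!r}")
    try:
        scheme = config.scheme()
        if not (scheme.array.min() < config.b_threshold < scheme.array.max()):
            findings.append(
                f"b_threshold={config.b_threshold} not strictly inside the "
                f"b-value range [{scheme.array.min()}, {scheme.array.max()}]"
            )
    except ValueError as e:
        findings.append(f"b_values invalid: {e}")
    min_pts = {"affine": 3, "polynomial-2": 6}.get(config.scene_family)
    if min_pts is None:
        findings.append(f"unknown scene_family {config.scene_family!r}")
    elif config.scene_points < min_pts:
        findings.append(
            f"scene_points={config.scene_points} under-determines a "
            f"{config.scene_family} transform (needs >= {min_pts})"
        )
    if config.scene_jitter < 0:
        findings.append("scene_jitter must be non-negative")
    if config.bsp_iterations <= config.bsp_burn_in:
        findings.append("bsp_iterations must exceed bsp_burn_in")
    if config.mode == "real":
        for name in ("dwi_path", "t2_path", "histology_path", "control_points_path", "roi_path"):
            p = getattr(config, name)
            if not p:
                findings.append(f"real-data mode requires {name}")
            elif not Path(p).exists():
                findings.append(f"{name} does not exist: {p}")
    if config.mode == "synthetic" and config.n_patients < 3:
        findings.append("synthetic mode needs n_patients >= 3 for the paired tests")
    return findings


def _hash(obj) -> str:
    h = hashlib.sha256()
    if isinstance(obj, np.ndarray):
        h.update(np.ascontiguousarray(obj).tobytes())
    elif isinstance(obj, pd.DataFrame):
        h.update(obj.to_csv(index=False).encode())
    else:
        h.update(json.dumps(obj, sort_keys=True, default=str).encode())
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    version: str
    config: dict
    stage_hashes: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def _roi_median_row(stack, mask_data, config: RunConfig, pixel_size: float) -> dict:
    """Fit the masked voxels and return reporting-unit medians."""
    mask = ROIMask(np.asarray(mask_data, bool), pixel_size=pixel_size)
    _, df, _ = fit_map(stack, mask, config.fit_config(), config.scheme())
    return {
        "f": float(np.median(df["f"])) * 100.0,
        "d": float(np.median(df["d"])) * 1e3,
        "dstar": float(np.median(df["dstar"])) * 1e3,
        "adc": float(np.median(df["adc"])) * 1e3,
        "n_voxels": len(df),
    }


def run_pipeline(config: RunConfig):
    """Execute the configured stages; returns (manifest, report dict).

    Synthetic mode: simulate the cohort (ground truth + rendered DWI per
    subject), register each patient's synthetic histology to T2 and carry
    the lesion ROI down to the DWI grid (mirroring the contralateral ROI),
    fit every ROI, and produce the report tables (paired lesion/normal
    comparison, diagnostic accuracy, age correlations, subgroup
    comparisons).  Any stage error aborts the downstream stages.
    """
    findings = validate_config(config)
    if findings:
        raise ValueError("invalid config: " + "; ".join(findings))
    outdir = Path(config.outdir)
    if config.write_artifacts:
        outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__, config=asdict(config))
    manifest.started = time.strftime("%Y-%m-%dT%H:%M:%S")
    report: dict = {}
    ctx: dict = {}
    stage_fns = {
        "simulate": _stage_simulate,
        "register": _stage_register,
        "fit": _stage_fit,
        "stats": _stage_stats,
    }
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        if config.mode == "real" and stage == "simulate":
            continue
        t0 = time.perf_counter()
        logger.info("stage %s: start", stage)
        try:
            stage_fns[stage](config, ctx, report, manifest, outdir)
        except Exception:
            logger.exception("stage %s failed; aborting downstream stages", stage)
            raise
        dt = time.perf_counter() - t0
        manifest.stage_seconds[stage] = round(dt, 3)
        logger.info("stage %s: done in %.2fs", stage, dt)
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    if config.write_artifacts:
        manifest.to_json(outdir / "manifest.json")
    return manifest, report


def _stage_simulate(config, ctx, report, manifest, outdir):
    from . import io as fio

    spec = SyntheticCohortSpec(
        n_patients=config.n_patients, n_controls=config.n_controls,
        snr=config.snr, seed=config.seed,
    )
    truth, studies = simulate_cohort(spec, render=True)
    ctx["cohort_spec"] = spec
    ctx["truth"] = truth
    ctx["studies"] = studies
    # one ground-truth scene per patient links histology to the T2 frame
    rng = np.random.default_rng(config.seed + 1)
    scenes = {}
    for sid in truth[truth.group == "patient"].subject_id:
        scenes[sid] = make_scene(
            family=config.scene_family, n_points=config.scene_points,
            jitter_sigma=config.scene_jitter, seed=int(rng.integers(0, 2**31 - 1)),
            phantom=studies[sid]["phantom_spec"],
        )
    ctx["scenes"] = scenes
    manifest.stage_hashes["simulate"] = _hash(truth)
    if config.write_artifacts:
        truth.to_csv(outdir / "cohort_truth.csv", index=False)
        sid0 = truth[truth.group == "patient"].subject_id.iloc[0]
        fio.write_dwi_nifti(
            outdir / f"{sid0}_dwi.nii", studies[sid0]["stack"],
            config.scheme(), pixel_size=3.05,
        )
        fio.write_image_png(outdir / f"{sid0}_t2.png", scenes[sid0].t2_image)
        fio.write_image_png(outdir / f"{sid0}_histology.png", scenes[sid0].histology_image)
        fio.write_control_points(outdir / f"{sid0}_control_points.csv",
                                 scenes[sid0].control_points)


def _stage_register(config, ctx, report, manifest, outdir):
    from . import io as fio

    scenes = ctx["scenes"]
    studies = ctx["studies"]
    dwi_masks = {}
    tre_px = {}
    for sid, scene in scenes.items():
        tf = estimate_transform(scene.control_points, family=config.scene_family)
        t2_shape = scene.t2_image.shape
        dwi_shape = studies[sid]["truth"].shape
        t2_px = 3.05 * dwi_shape[0] / t2_shape[0]
        lesion_t2 = transfer_roi(scene.lesion_mask_histology, tf, t2_shape,
                                 target_pixel_size=t2_px)
        lesion_dwi = downsample_mask(lesion_t2, dwi_shape, 3.05)
        masks = studies[sid]["masks"]
        zone = masks.get("lesion_zone", "pz")
        spec = studies[sid]["phantom_spec"]
        contra = mirror_roi(
            replace_label(lesion_dwi, zone), spec.midline_x, masks[zone]
        )
        dwi_masks[sid] = {"lesion": lesion_dwi, "contralateral": contra, "zone": zone}
        err = np.linalg.norm(tf(scene.control_points.moving) - scene.control_points.fixed, axis=1)
        tre_px[sid] = float(np.sqrt(np.mean(err**2)))
        if config.write_artifacts and sid == next(iter(scenes)):
            warped = warp_image(scene.histology_image, tf, t2_shape)
            fio.write_fusion_overlay(outdir / f"{sid}_fusion.png", warped, scene.t2_image)
            fio.write_mask(outdir / f"{sid}_lesion_dwi.png", lesion_dwi)
            tf.to_json(outdir / f"{sid}_transform.json")
    ctx["dwi_masks"] = dwi_masks
    report["registration_rmse_px"] = tre_px
    manifest.stage_hashes["register"] = _hash(
        {k: int(v["lesion"].data.sum()) for k, v in dwi_masks.items()}
    )


def replace_label(mask: ROIMask, zone: str) -> ROIMask:
    return ROIMask(mask.data, pixel_size=mask.pixel_size, origin=mask.origin,
                   label="lesion", zone=zone)


def _stage_fit(config, ctx, report, manifest, outdir):
    if "truth" not in ctx:
        raise ValueError("fit stage requires the simulate stage (synthetic mode)")
    truth = ctx["truth"]
    studies = ctx["studies"]
    dwi_masks = ctx.get("dwi_masks", {})
    lesion_rows, zone_rows = [], []
    tz_roi = None
    for _, subj in truth.iterrows():
        sid = subj.subject_id
        study = studies[sid]
        stack = study["stack"]
        shape = study["truth"].shape
        if tz_roi is None or shape != tz_roi[0].shape:
            tz_roi = (TZ_SAMPLE_ROI.mask(shape), PZ_SAMPLE_ROI.mask(shape))
        for zone, m in zip(("tz", "pz"), tz_roi):
            row = _roi_median_row(stack, m, config, 3.05)
            row.update(subject_id=sid, age=subj.age, zone=zone, group=subj.group)
            zone_rows.append(row)
        if subj.group != "patient":
            continue
        if sid in dwi_masks:
            lesion_mask = dwi_masks[sid]["lesion"].data
            contra_mask = dwi_masks[sid]["contralateral"].data
            zone = dwi_masks[sid]["zone"]
        else:  # fit-only rerun without registration: use ground-truth masks
            masks = study["masks"]
            zone = masks.get("lesion_zone", "pz")
            lesion_mask = masks["lesion"]
            contra = mirror_roi(
                ROIMask(lesion_mask, pixel_size=3.05, label="lesion", zone=zone),
                study["phantom_spec"].midline_x, masks[zone],
            )
            contra_mask = contra.data
        for tissue, m in (("lesion", lesion_mask), ("contralateral_normal", contra_mask)):
            row = _roi_median_row(stack, m, config, 3.05)
            row.update(
                subject_id=sid, age=subj.age, tissue_class=tissue, zone=zone,
                gleason_group=subj.gleason_group, enhanced=subj.enhanced,
            )
            lesion_rows.append(row)
    ctx["roi_samples"] = pd.DataFrame(lesion_rows)
    ctx["zone_samples"] = pd.DataFrame(zone_rows)
    manifest.stage_hashes["fit"] = _hash(ctx["roi_samples"])
    if config.write_artifacts:
        ctx["roi_samples"].to_csv(outdir / "roi_samples.csv", index=False)
        ctx["zone_samples"].to_csv(outdir / "zone_samples.csv", index=False)


def _stage_stats(config, ctx, report, manifest, outdir):
    if "roi_samples" not in ctx:  # stats-only rerun on existing fit outputs
        ctx["roi_samples"] = pd.read_csv(outdir / "roi_samples.csv")
        ctx["zone_samples"] = pd.read_csv(outdir / "zone_samples.csv")
    samples = ctx["roi_samples"]
    zones = ctx["zone_samples"]
    paired = paired_comparison_table(samples)
    diag = diagnostic_accuracy_table(samples)
    age_corr = age_correlation_table(zones)
    lesions = samples[samples.tissue_class == "lesion"]
    tables = {"paired_comparison": paired, "diagnostic_accuracy": diag,
              "age_correlation": age_corr}
    try:
        tables["gleason_comparison"] = group_comparison_table(
            lesions[lesions.gleason_group.isin(["<=7", ">7"])], "gleason_group"
        )
    except ValueError:
        pass
    try:
        tables["enhancement_comparison"] = group_comparison_table(
            lesions[lesions.enhanced.isin(["yes", "no"])], "enhanced"
        )
    except ValueError:
        pass
    report["tables"] = tables
    report["diagnostics"] = diagnostics_json(diag)
    manifest.stage_hashes["stats"] = _hash(paired)
    if config.write_artifacts:
        for name, tbl in tables.items():
            tbl.to_csv(outdir / f"table_{name}.csv", index=False)
        (outdir / "diagnostics.json").write_text(
            json.dumps(report["diagnostics"], indent=2, default=float)
        )
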