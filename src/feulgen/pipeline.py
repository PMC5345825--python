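"""End-to-end runs: images -> segmentation -> morphometry -> ploidy -> stats.

A run is described by a :class:`RunConfig` (serialisable to YAML). Images
are processed independently and streamed one at a time; the only
cross-image state is the reference standard, which is calibrated from the
nuclei of images labelled ``normal`` before ploidy is assigned.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import feulgen
from feulgen import densitometry, io, morphometry, optics, segmentation, stats, synthetic

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every knob of a pipeline run; round-trips through YAML."""

    # inputs: either real images or a synthetic preset
    images: list[dict] = field(default_factory=list)  # {path, blank, stage, exclusion?}
    synthetic_preset: dict | None = None  # {stages, images_per_stage, nuclei_per_image, ...}

    n_bins: int = 256
    min_size: int = segmentation.DEFAULT_MIN_SIZE
    max_size: float = segmentation.DEFAULT_MAX_SIZE
    dilate_iterations: int = 0
    use_watershed: bool = True
    min_seed_distance: int = 5
    od_max: float = optics.DEFAULT_OD_MAX
    pixel_size_um: float = optics.DEFAULT_PIXEL_SIZE_UM
    cp_pg: float = densitometry.DEFAULT_CP_PG
    bin_width: float = densitometry.DEFAULT_BIN_WIDTH
    smooth_window: int = densitometry.DEFAULT_SMOOTH_WINDOW
    min_prominence: float = densitometry.DEFAULT_MIN_PROMINENCE
    alpha: float = stats.DEFAULT_ALPHA
    f_enter: float = stats.DEFAULT_F_ENTER
    f_remove: float = stats.DEFAULT_F_REMOVE
    seed: int = 0
    outdir: str = "feulgen_run"
    save_images: bool = False

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _synthetic_scenes(cfg: RunConfig):
    """Yield (image_id, stage, rgb, blank, exclusion) for a synthetic preset."""
    preset = dict(cfg.synthetic_preset or {})
    stages = preset.get("stages", list(synthetic.STAGES))
    per_stage = int(preset.get("images_per_stage", 3))
    n_nuclei = int(preset.get("nuclei_per_image", 50))
    kwargs = {
        k: preset[k]
        for k in ("cv", "noise_sd", "od_per_C", "touching_pair_fraction",
                  "illumination_gradient", "background_level")
        if k in preset
    }
    if "illumination_gradient" in kwargs:
        kwargs["illumination_gradient"] = tuple(kwargs["illumination_gradient"])
    counter = 0
    for stage in stages:
        for i in range(per_stage):
            spec = synthetic.stage_preset(
                stage, n_nuclei, seed=cfg.seed + 1000 * counter, **kwargs
            )
            rgb, blank, _truth = synthetic.render_scene(spec)
            yield f"{stage}_{i:02d}", stage, rgb, blank, None
            counter += 1


def _image_inputs(cfg: RunConfig):
    for entry in cfg.images:
        path = Path(entry["path"])
        rgb = io.read_image(path)
        blank_spec = entry.get("blank")
        if blank_spec is None:
            blank = float(np.percentile(rgb, 99))
        elif isinstance(blank_spec, (int, float)):
            blank = float(blank_spec)
        else:
            blank = io.read_image(blank_spec)
        exclusion = entry.get("exclusion")
        if exclusion is not None:
            exclusion = io.read_image(exclusion).astype(bool)
        yield path.stem, entry.get("stage", "unknown"), rgb, blank, exclusion


def process_image(
    cfg: RunConfig,
    image_id: str,
    stage: str,
    rgb: np.ndarray,
    blank,
    exclusion: np.ndarray | None = None,
) -> tuple[pd.DataFrame, optics.ImagePlane, segmentation.LabelMask]:
    """Single-image chain: OD conversion, segmentation, morphometry."""
    green, od = optics.od_from_raw(rgb, blank, od_max=cfg.od_max, pixel_size_um=cfg.pixel_size_um)
    labels = segmentation.segment_nuclei(
        green,
        n_bins=cfg.n_bins,
        min_px=cfg.min_size,
        max_px=cfg.max_size,
        dilate_iterations=cfg.dilate_iterations,
        use_watershed=cfg.use_watershed,
        min_seed_distance=cfg.min_seed_distance,
        exclusion=exclusion,
    )
    table = morphometry.measure_all(labels, od, image_id=image_id, stage=stage)
    return table, od, labels


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute a full run; returns a dict of the main artefacts.

    Writes per-image feature CSVs (plus OD planes and masks when
    ``save_images``), a pooled feature table, group statistics, per-stage
    ploidy profiles with detected peaks, confusion matrices, and a manifest
    recording every parameter of the run.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    source = _synthetic_scenes(cfg) if cfg.synthetic_preset else _image_inputs(cfg)
    if not cfg.synthetic_preset and not cfg.images:
        raise ValueError("config lists no images and no synthetic preset")

    tables = []
    per_stage_counts: dict[str, int] = {}
    for image_id, stage, rgb, blank, exclusion in source:
        try:
            table, od, labels = process_image(cfg, image_id, stage, rgb, blank, exclusion)
        except Exception as exc:  # noqa: BLE001 - abort names the stage/input
            raise RuntimeError(f"pipeline failed on image {image_id!r}: {exc}") from exc
        table.to_csv(outdir / f"features_{image_id}.csv", index=False)
        if cfg.save_images:
            io.write_od_plane(outdir / f"od_{image_id}.tif", od)
            io.write_label_mask(outdir / f"mask_{image_id}.tif", labels)
        per_stage_counts[stage] = per_stage_counts.get(stage, 0) + len(table)
        tables.append(table)
        log.info("image %s (%s): %d nuclei", image_id, stage, len(table))

    pooled = pd.concat(tables, ignore_index=True) if tables else morphometry.measure_all(
        np.zeros((1, 1), dtype=np.int32)
    )
    results: dict = {"features": pooled, "per_stage_counts": per_stage_counts}

    reference = pooled.loc[pooled["stage"] == "normal"]
    if len(reference) and reference["IOD"].mean() > 0:
        standard = densitometry.calibrate_reference(reference, cp_pg=cfg.cp_pg)
        _, ratios = densitometry.ploidy(pooled["IOD"].to_numpy(float), standard)
        pooled["ploidy"] = ratios
        results["reference"] = standard
        peak_rows = []
        for stage, sub in pooled.groupby("stage"):
            profile = densitometry.profile_from_iods(
                sub["IOD"].to_numpy(float), standard,
                bin_width=cfg.bin_width, window=cfg.smooth_window,
                min_prominence=cfg.min_prominence,
            )
            profile.to_frame().to_csv(outdir / f"ploidy_profile_{stage}.csv", index=False)
            for _, row in profile.peaks.iterrows():
                peak_rows.append({"stage": stage, **row})
        peaks = pd.DataFrame(peak_rows, columns=["stage", "location", "height", "prominence"])
        peaks.to_csv(outdir / "ploidy_peaks.csv", index=False)
        results["peaks"] = peaks
    else:
        log.warning("no normal-stage nuclei: ploidy calibration skipped")

    pooled.to_csv(outdir / "features_pooled.csv", index=False)

    pooled["group"] = np.where(pooled["stage"] == "normal", "normal", "neoplastic")
    feature_cols = [
        c for c in morphometry.DESCRIPTOR_COLUMNS if pooled[c].notna().any()
    ]
    if pooled["group"].nunique() == 2:
        comparison = stats.compare_groups(pooled, "group", feature_cols, alpha=cfg.alpha)
        comparison.to_csv(outdir / "group_comparison.csv", index=False)
        results["comparison"] = comparison
    if pooled["stage"].nunique() >= 2:
        glm = stats.multi_group_comparison(pooled, "stage", feature_cols, alpha=cfg.alpha)
        glm.to_csv(outdir / "stage_glm.csv", index=False)
        results["glm"] = glm
        for label_col, name in (("group", "normal_vs_neoplastic"), ("stage", "by_stage")):
            if pooled[label_col].nunique() < 2:
                continue
            model, cm = stats.stepwise_lda(
                pooled, label_col, feature_cols, f_enter=cfg.f_enter, f_remove=cfg.f_remove
            )
            cm.to_frame().to_csv(outdir / f"confusion_{name}.csv")
            results[f"lda_{name}"] = (model, cm)

    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": feulgen.__version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "per_stage_counts": per_stage_counts,
        "n_nuclei": int(len(pooled)),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results


def demo_dataset(outdir: str | Path, seed: int = 42) -> list[Path]:
    """Write a small fixture set: 4 stages x 3 images, ~50 nuclei each.

    Produces PNG images, 16-bit label masks and one pooled ground-truth CSV.
    Deterministic: the same seed writes identical bytes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not outdir.is_dir():
        raise NotADirectoryError(str(outdir))
    written: list[Path] = []
    truth_rows = []
    counter = 0
    for stage in synthetic.STAGES:
        for i in range(3):
            spec = synthetic.stage_preset(stage, 50, seed=seed + 1000 * counter)
            rgb, blank, truth = synthetic.render_scene(spec)
            img_path = outdir / f"{stage}_{i:02d}.png"
            mask_path = outdir / f"{stage}_{i:02d}_mask.png"
            io.write_image(img_path, rgb)
            io.write_label_mask(mask_path, truth.label_mask)
            t = truth.table.copy()
            t.insert(0, "image_id", f"{stage}_{i:02d}")
            t.insert(1, "stage", stage)
            truth_rows.append(t)
            written += [img_path, mask_path]
            counter += 1
    truth_path = outdir / "ground_truth.csv"
    pd.concat(truth_rows, ignore_index=True).to_csv(truth_path, index=False)
    written.append(truth_path)
    return written
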