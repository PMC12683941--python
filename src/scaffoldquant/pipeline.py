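"""End-to-end orchestration: simulation -> preprocessing -> segmentation ->
classification -> quantification -> statistics, driven by a structured
(YAML) config, with a JSON run manifest for reproducibility.

The manifest records the seed, a hash of the canonical config, per-stage
row/voxel counts and the SHA-256 of every written output, so an identical
config + seed reproduces identical manifest content hashes.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cytotox import cytolysis_table
from .errors import ConfigurationError, PipelineStageError
from .markers import (
    add_normalized_intensities,
    aggregate_mask_intensities,
    classify_cells,
    compute_thresholds,
)
from .preprocess import preprocess_stack
from .segment import segment_nuclei
from .simulate import (
    AssaySimConfig,
    CohortConfig,
    ScaffoldSimConfig,
    generate_assay_tables,
    simulate_cohort,
)
from .spatial import aggregate_per_patient, assign_region, compare_conditions, composition_summary

log = logging.getLogger("scaffoldquant")

STAGE_ORDER = ("simulate", "preprocess", "segment", "classify", "quantify", "report")
_STAGE_NEEDS = {
    "preprocess": "simulate",
    "segment": "simulate",
    "classify": "segment",
    "quantify": "classify",
    "report": "quantify",
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def sim_config_from_dict(d: dict) -> ScaffoldSimConfig:
    """Build a :class:`ScaffoldSimConfig` from plain (YAML-loaded) data."""
    kwargs = dict(d)
    for key in ("volume_shape", "voxel_size"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    if "intensity_params" in kwargs and kwargs["intensity_params"] is not None:
        kwargs["intensity_params"] = {
            cls: {ch: tuple(v) for ch, v in per.items()}
            for cls, per in kwargs["intensity_params"].items()
        }
    return ScaffoldSimConfig(**kwargs)


def sim_config_to_dict(config: ScaffoldSimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["volume_shape"] = list(config.volume_shape)
    d["voxel_size"] = list(config.voxel_size)
    d["intensity_params"] = {
        cls: {ch: list(v) for ch, v in per.items()} for cls, per in config.intensity_params.items()
    }
    return d


def validate_pipeline_config(config: dict) -> list:
    """Check stage blocks and dependencies before execution.

    Returns the ordered list of stages to run. A requested stage whose
    upstream block is absent is a configuration error (checked before any
    stage executes).
    """
    stages = config.get("stages")
    if stages is None:
        stages = [s for s in STAGE_ORDER if s in config]
    unknown = [s for s in stages if s not in STAGE_ORDER]
    if unknown:
        raise ConfigurationError(f"unknown pipeline stages {unknown}; valid: {STAGE_ORDER}")
    stages = [s for s in STAGE_ORDER if s in stages]
    present = set(stages)
    for stage in stages:
        need = _STAGE_NEEDS.get(stage)
        if need and need not in present:
            raise ConfigurationError(
                f"stage {stage!r} requested but its upstream stage {need!r} is not configured"
            )
    if not stages:
        raise ConfigurationError("no pipeline stages configured")
    return stages


def run_pipeline(config: dict | str | Path, outdir=None, seed=None) -> dict:
    """Execute the configured stages in order and write a run manifest.

    Returns the manifest dict (also written to ``manifest.json`` in the
    output directory). On stage failure a ``<stage>.partial`` marker is
    left in the output directory and :class:`PipelineStageError` is raised.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    stages = validate_pipeline_config(config)
    seed = int(config.get("seed", 0) if seed is None else seed)
    outdir = Path(outdir or config.get("outdir", "scaffoldquant_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, str(config.get("log_level", "INFO")).upper(), 20))

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "stages": {},
    }
    ctx = {}

    def record(stage, outputs, **counts):
        manifest["stages"][stage] = {
            "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in outputs},
            **counts,
        }

    for stage in stages:
        marker = outdir / f"{stage}.partial"
        marker.write_text("running")
        t0 = time.perf_counter()
        try:
            outputs, counts = _STAGE_IMPL[stage](config.get(stage) or {}, ctx, outdir, seed)
        except Exception as err:  # noqa: BLE001 - report stage then re-raise
            raise PipelineStageError(stage, err) from err
        marker.unlink()
        record(stage, outputs, **counts)
        log.info("stage %s done in %.2fs (%s)", stage, time.perf_counter() - t0, counts)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# stage implementations


def _stage_simulate(block, ctx, outdir, seed):
    cohort_cfg = CohortConfig(
        base=sim_config_from_dict(block.get("base", {})),
        groups=block.get("groups", {"CLL": {}, "ALL": {}}),
        conditions=block.get("conditions", {"car": {}}),
        patients_per_group=int(block.get("patients_per_group", 4)),
        images_per_patient=int(block.get("images_per_patient", 2)),
        anchor_cv=float(block.get("anchor_cv", 0.05)),
        anchor_replicates=int(block.get("anchor_replicates", 3)),
    )
    cohort = simulate_cohort(cohort_cfg, seed=seed)
    ctx["cohort"] = cohort
    outputs = []
    write_images = bool(block.get("write_images", True))
    for im in cohort.images:
        if write_images:
            stack_path = outdir / f"{im.stack_id}.tif"
            labels_path = outdir / f"{im.stack_id}_labels.tif"
            im.stack.write_tiff(stack_path)
            im.labels.write_tiff(labels_path)
            outputs += [stack_path, labels_path]
        truth_path = outdir / f"{im.stack_id}_truth.csv"
        im.truth.to_csv(truth_path)
        outputs.append(truth_path)
    anchors_path = outdir / "anchors.csv"
    cohort.anchors.to_csv(anchors_path, index=False)
    outputs.append(anchors_path)
    n_cells = sum(im.truth.n_cells for im in cohort.images)
    return outputs, dict(n_images=len(cohort.images), n_cells=n_cells)


def _stage_preprocess(block, ctx, outdir, seed):
    cohort = ctx["cohort"]
    for im in cohort.images:
        im.stack = preprocess_stack(
            im.stack,
            op_name=block.get("op_name", "median"),
            radius=int(block.get("radius", 1)),
            channels=tuple(block.get("channels", ("nuclei",))),
        )
    return [], dict(n_images=len(cohort.images))


def _stage_segment(block, ctx, outdir, seed):
    cohort = ctx["cohort"]
    mode = block.get("mode", "truth")
    if mode == "truth":
        ctx["labels"] = {im.stack_id: im.labels for im in cohort.images}
        return [], dict(mode=mode, n_images=len(cohort.images))
    if mode != "baseline":
        raise ConfigurationError(f"unknown segment mode {mode!r}; use truth or baseline")
    labels = {}
    outputs = []
    for im in cohort.images:
        seg = segment_nuclei(
            im.stack.channel(block.get("channel", "nuclei")),
            diameter=float(block.get("diameter", 10.2)),
            min_volume=int(block.get("min_volume", 30)),
            voxel_size=im.stack.voxel_size,
        )
        labels[im.stack_id] = seg
        if block.get("write_labels", False):
            path = outdir / f"{im.stack_id}_segmented.tif"
            seg.write_tiff(path)
            outputs.append(path)
    ctx["labels"] = labels
    return outputs, dict(mode=mode, n_masks=sum(v.n_cells for v in labels.values()))


def _stage_classify(block, ctx, outdir, seed):
    cohort = ctx["cohort"]
    channels = tuple(block.get("channels", ("CD19", "CD3")))
    frames = []
    for im in cohort.images:
        frames.append(
            aggregate_mask_intensities(
                im.stack,
                ctx["labels"][im.stack_id],
                channels=channels,
                stack_id=im.stack_id,
                patient_id=im.patient_id,
                group=im.group,
                condition=im.condition,
            )
        )
    table = pd.concat(frames, ignore_index=True)
    table = add_normalized_intensities(table, channels=channels)
    thresholds = compute_thresholds(table, cohort.anchors, channels=channels)
    cells = classify_cells(table, thresholds)
    cells = assign_region(
        cells,
        cohort.images[0].stack.shape,
        core_radius_fraction=float(block.get("core_radius_fraction", 0.5)),
    )
    ctx["cells"] = cells
    cells_path = outdir / "cells.csv"
    thr_path = outdir / "thresholds.csv"
    cells.to_csv(cells_path, index=False)
    thresholds.to_csv(thr_path, index=False)
    return [cells_path, thr_path], dict(n_rows=len(cells))


def _stage_quantify(block, ctx, outdir, seed):
    cells = ctx["cells"]
    by_image = composition_summary(cells, by=("group", "patient_id", "condition", "stack_id"))
    patient_level, group_level = aggregate_per_patient(by_image, extra_keys=("condition",))
    ctx["summary_image"] = by_image
    ctx["summary_patient"] = patient_level
    paths = []
    for name, df in (
        ("summary.csv", by_image),
        ("summary_patient.csv", patient_level),
        ("summary_group.csv", group_level),
    ):
        path = outdir / name
        df.to_csv(path, index=False)
        paths.append(path)
    return paths, dict(n_image_rows=len(by_image), n_patients=len(patient_level))


def _stage_report(block, ctx, outdir, seed):
    designs = block if isinstance(block, list) else block.get("designs", [])
    if not designs:
        designs = [dict(test="mannwhitney", value="coloc_of_b", factor="group")]
    frames = [compare_conditions(ctx["summary_patient"], design) for design in designs]
    report = pd.concat(frames, ignore_index=True)
    path = outdir / "report.csv"
    report.to_csv(path, index=False)
    return [path], dict(n_tests=len(report))


_STAGE_IMPL = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "segment": _stage_segment,
    "classify": _stage_classify,
    "quantify": _stage_quantify,
    "report": _stage_report,
}


# ---------------------------------------------------------------------------
# fixtures

FIXTURE_CONFIGS = {
    "tiny": dict(
        volume_shape=(32, 48, 48),
        n_stromal=6,
        n_bcell=12,
        n_tcell=12,
        cell_radius=3.0,
        stromal_radius=2.0,
        stromal_length=8.0,
        coloc_fraction=0.25,
        noise_sd=2.0,
    ),
    "small": dict(
        volume_shape=(64, 96, 96),
        n_stromal=60,
        n_bcell=120,
        n_tcell=120,
        cell_radius=3.0,
        stromal_radius=2.0,
        stromal_length=12.0,
        coloc_fraction=0.3,
        noise_sd=2.0,
    ),
}


def make_fixtures(size: str, outdir, seed: int = 0) -> dict:
    """Write a deterministic fixture bundle (stack, labels, truth, anchors,
    viability, kinetics, config) used by the test suite.

    ``tiny`` is a 32^3 volume with ~30 cells; ``small`` is 64^3 with ~300
    cells at low noise. Regenerating with the same seed is byte-identical.
    """
    if size not in FIXTURE_CONFIGS:
        raise ConfigurationError(f"unknown fixture size {size!r}; use {sorted(FIXTURE_CONFIGS)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_cfg = ScaffoldSimConfig(**FIXTURE_CONFIGS[size], seed=seed)
    from .simulate import generate_anchor_table, generate_scaffold_stack

    stack, labels, truth = generate_scaffold_stack(sim_cfg)
    anchors = generate_anchor_table(truth, cv=0.0, n_replicates=2, seed=seed, group="synthetic")
    assays = generate_assay_tables(AssaySimConfig(), seed=seed)

    stack.write_tiff(outdir / "stack.tif")
    labels.write_tiff(outdir / "labels.tif")
    truth.to_csv(outdir / "truth.csv")
    anchors.to_csv(outdir / "anchors.csv", index=False)
    assays.viability.to_csv(outdir / "viability.csv", index=False)
    for condition, trace in assays.kinetics.items():
        trace.to_csv(outdir / f"kinetics_{condition}.csv", index=False)
    config_doc = dict(
        size=size,
        seed=seed,
        simulate=sim_config_to_dict(sim_cfg),
        segment=dict(diameter=2 * sim_cfg.cell_radius, min_volume=30),
    )
    (outdir / "config.yaml").write_text(yaml.safe_dump(config_doc, sort_keys=True))
    files = sorted(p for p in outdir.iterdir() if p.is_file())
    return {p.name: _sha256(p) for p in files}


def cytolysis_outputs(viability: pd.DataFrame, outdir) -> dict:
    """Convenience wrapper writing cytolysis table + region differences."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, diffs = cytolysis_table(viability)
    table.to_csv(outdir / "cytolysis.csv", index=False)
    diffs.to_csv(outdir / "cytolysis_region_diff.csv", index=False)
    return dict(table=table, region_difference=diffs)
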