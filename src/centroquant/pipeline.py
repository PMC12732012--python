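"""End-to-end orchestration: simulate -> segment -> detect -> measure ->
review -> filter -> stats, as one reproducible run.

A run is driven by a versioned config mapping with sections ``simulation``,
``segmentation``, ``detection``, ``stats`` and ``channels`` plus a top-level
``seed``. Unknown keys anywhere are rejected before any output is written.
Every run writes its per-stage artifacts, the resolved config, and a
manifest (artifact hashes, library versions, seed) into the output
directory; identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detect import DetectionConfig, detect_centrosomes, regions_to_dataframe
from .errors import ParameterError
from .io import write_image, write_label_map, CellLabelMap
from .quantify import measure_regions
from .review import annotations_from_truth, apply_review, \
    select_two_centrosome_cells
from .segment import SegmentationConfig, segment_cells
from .simulate import SimulationParams, generate_field
from .stats import fit_random_intercept, mann_whitney, stage_fold_summary

__all__ = ["CONFIG_VERSION", "default_config", "validate_config",
           "run_pipeline", "demo"]

CONFIG_VERSION = 1

_TOP_KEYS = {"version", "seed", "simulation", "segmentation", "detection",
             "stats", "channels"}
_STATS_KEYS = {"n_boot", "reml", "review_tolerance"}
_CHANNEL_KEYS = {"dna", "gamma", "target"}


def default_config(seed: int = 0) -> dict:
    """Default synthetic-scene run configuration."""
    return {
        "version": CONFIG_VERSION,
        "seed": int(seed),
        "simulation": SimulationParams(seed=int(seed)).to_dict(),
        "segmentation": {
            "flow_threshold": 0.0, "cellprob_threshold": 0.0,
            "tile_norm_blocksize": 0.0, "diameter": 68.0, "min_size": 800,
            "niter": 2000, "augment": True,
        },
        "detection": {
            "blur_sigma": 2.0, "max_peaks_per_cell": 2,
            "min_peak_distance": 6.0, "expansion_fraction": 0.70,
            "merge_distance": 10.0, "min_region_area": 30,
        },
        "stats": {"n_boot": 1000, "reml": True, "review_tolerance": 4.0},
        "channels": {"dna": "dna", "gamma": "gamma", "target": "target"},
    }


def validate_config(config: dict) -> dict:
    """Fail-fast validation: version check and rejection of unknown keys."""
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    if config.get("version") != CONFIG_VERSION:
        raise ParameterError(
            f"config version {config.get('version')!r} != {CONFIG_VERSION}")
    defaults = default_config()
    for section, known in (
            ("simulation", set(SimulationParams().to_dict())),
            ("segmentation", set(defaults["segmentation"])),
            ("detection", set(defaults["detection"])),
            ("stats", _STATS_KEYS),
            ("channels", _CHANNEL_KEYS)):
        extra = set(config.get(section, {})) - known
        if extra:
            raise ParameterError(
                f"unknown keys in config section {section!r}: {sorted(extra)}")
    return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the full stage sequence on a synthetic scene.

    Returns the final report (also written as ``report.json``). Artifacts:
    images, truth tables, label map, regions table, measurement tables
    before/after review and filtering, the filter summary, resolved config
    and a manifest.
    """
    config = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    log: list[str] = []

    # --- simulate -----------------------------------------------------
    sim_cfg = dict(config["simulation"])
    sim_cfg["seed"] = seed
    params = SimulationParams.from_dict(sim_cfg)
    stack, truth_labels, truth = generate_field(params)
    write_image(out / "field.tif", stack)
    write_label_map(out / "labels_truth.tif", truth_labels)
    truth.write(out)
    n_mit = int((truth.cells.stage == "mitosis").sum())
    log.append(f"simulate: {params.n_cells} cells "
               f"({n_mit} mitotic, {params.n_cells - n_mit} interphase)")

    # --- segment ------------------------------------------------------
    seg_config = SegmentationConfig(**config["segmentation"])
    labels = segment_cells(stack, seg_config, backend="ground_truth",
                           labels=truth_labels)
    write_label_map(out / "labels.tif", labels)
    log.append(f"segment: {labels.cell_ids.size} cells "
               f"(backend={labels.source})")

    # --- detect -------------------------------------------------------
    det_config = DetectionConfig(**config["detection"])
    regions = detect_centrosomes(stack, labels, det_config,
                                 gamma_channel=config["channels"]["gamma"])
    regions_to_dataframe(regions).to_csv(out / "regions.csv", index=False)
    log.append(f"detect: {len(regions)} centrosome regions")

    # --- measure ------------------------------------------------------
    stage_lookup = dict(zip(truth.cells.cell_id.astype(int),
                            truth.cells.stage))
    records = measure_regions(stack, regions,
                              channel=config["channels"]["target"],
                              image_id=f"sim-{seed}",
                              stage_lookup=stage_lookup)
    records.to_csv(out / "measurements_raw.csv", index=False)

    # --- review (emulated against ground truth) -----------------------
    tol = float(config["stats"]["review_tolerance"])
    annotations = annotations_from_truth(regions, truth.spots, tol=tol)
    reviewed = apply_review(records, annotations)
    n_fp = len(records) - len(reviewed)
    reviewed.to_csv(out / "measurements_reviewed.csv", index=False)
    log.append(f"review: {n_fp} false positives removed, "
               f"{len(reviewed)} records kept")

    # --- two-centrosome filter ---------------------------------------
    filtered, summary = select_two_centrosome_cells(reviewed)
    filtered.to_csv(out / "measurements_filtered.csv", index=False)
    (out / "filter_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    for stage, s in sorted(summary.items()):
        log.append(
            f"filter[{stage}]: {s['cells_before']} cells/"
            f"{s['peaks_before']} peaks -> {s['cells_after']} cells/"
            f"{s['peaks_after']} peaks")

    # --- statistics ---------------------------------------------------
    fit = fit_random_intercept(filtered, reml=bool(config["stats"]["reml"]))
    fold = stage_fold_summary(filtered,
                              n_boot=int(config["stats"]["n_boot"]),
                              seed=seed)
    mwu = mann_whitney(
        filtered.loc[filtered.stage == "interphase", "mean_fluorescence"],
        filtered.loc[filtered.stage == "mitosis", "mean_fluorescence"])

    report = {
        "seed": seed,
        "counts": summary,
        "mixed_model": fit.to_dict(),
        "stage_fold": {"fold": fold.fold, "ci_low": fold.ci_low,
                       "ci_high": fold.ci_high, "n_boot": fold.n_boot,
                       "n_cells": fold.n_cells},
        "mann_whitney": {"U": mwu.U, "p_two_sided": mwu.p_two_sided,
                         "method": mwu.method, "n1": mwu.n1, "n2": mwu.n2},
        "log": log,
    }
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    (out / "config_resolved.yaml").write_text(
        yaml.safe_dump(config, sort_keys=True))

    artifacts = sorted(p.name for p in out.iterdir()
                       if p.name not in ("manifest.json",))
    manifest = {
        "seed": seed,
        "package_version": __version__,
        "library_versions": _library_versions(),
        "artifacts": {name: _sha256(out / name) for name in artifacts},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return report


def _library_versions() -> dict:
    import scipy
    import skimage
    import statsmodels

    return {"numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__, "scikit-image": skimage.__version__,
            "statsmodels": statsmodels.__version__}


def demo(out_dir, seed: int = 0, echo=print) -> dict:
    """Simulate the default scene, run everything, print the headline
    numbers. The package's 60-second smoke test."""
    report = run_pipeline(default_config(seed), out_dir)
    for line in report["log"]:
        echo(line)
    fold = report["stage_fold"]
    fit = report["mixed_model"]
    mwu = report["mann_whitney"]
    echo(f"stage fold (interphase/mitotic): {fold['fold']:.3f} "
         f"[95% CI {fold['ci_low']:.3f}, {fold['ci_high']:.3f}]")
    echo(f"mixed model: beta1 = {fit['beta1']:.1f} "
         f"(SE {fit['beta1_se']:.1f}), p = {fit['beta1_p']:.3g} "
         f"({fit['method']}, {fit['n_cells']} cells)")
    echo(f"Mann-Whitney (interphase vs mitotic records): U = {mwu['U']:.1f}, "
         f"p = {mwu['p_two_sided']:.3g} ({mwu['method']})")
    return report
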