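"""End-to-end orchestration: synthesize → segment → quantize → GLCM features
→ select → classify, with reproducible seeds and per-stage provenance.

A run is driven by one flat config dict (JSON/YAML on disk). Every artifact
lands in the run directory, which is append-only: no stage rewrites a prior
stage's outputs. Defaults equal the pipeline's canonical settings (32 gray
levels, offsets {1,2,4,8}, 13 directions, α = 0.01, 97% variance).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from importlib.metadata import PackageNotFoundError, version

import numpy as np
import pandas as pd

from .classify import loocv_run
from .errors import ParameterError
from .haralick import GROUP_OFFSETS, FeatureMatrix, assemble_group
from .preprocess import average_filter, equalize_to_levels
from .segmentation import segment_cohort
from .selection import select_features
from .synthdata import generate_cohort, write_cohort

log = logging.getLogger("celltex3d")

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline", "extract_features"]

DEFAULT_CONFIG: dict = {
    "outdir": "run",
    "seed": 0,
    "n_per_class": 9,
    "image_size": 512,
    "n_bands": 16,
    "write_images": False,
    "segment": True,
    "work_size": 64,
    "max_iter": 200,
    "kernel": 3,
    "levels": 32,
    "group": "G5",
    "alpha": 0.01,
    "pca_var": 0.97,
    "classifiers": ["DT", "NB", "NN"],
    "refit_selection": True,
}

_CONFIG_TYPES = {
    "outdir": str,
    "seed": int,
    "n_per_class": int,
    "image_size": int,
    "n_bands": int,
    "write_images": bool,
    "segment": bool,
    "work_size": int,
    "max_iter": int,
    "kernel": int,
    "levels": int,
    "group": str,
    "alpha": float,
    "pca_var": float,
    "classifiers": list,
    "refit_selection": bool,
}


def validate_config(config: dict | None) -> dict:
    """Merge a partial config with defaults and type-check every entry."""
    cfg = dict(DEFAULT_CONFIG)
    for key, value in (config or {}).items():
        if key not in DEFAULT_CONFIG:
            raise ParameterError(f"config: unknown key {key!r}")
        expected = _CONFIG_TYPES[key]
        if expected is float and isinstance(value, int):
            value = float(value)
        if not isinstance(value, expected):
            raise ParameterError(
                f"config: {key} must be {expected.__name__}, got {type(value).__name__}"
            )
        cfg[key] = value
    if cfg["group"] not in GROUP_OFFSETS:
        raise ParameterError(f"config: group must be one of {sorted(GROUP_OFFSETS)}")
    for c in cfg["classifiers"]:
        if c not in ("DT", "NB", "NN"):
            raise ParameterError(f"config: unknown classifier {c!r}")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def extract_features(samples, masks, cfg) -> FeatureMatrix:
    """Smooth, quantize and featurize every (volume, mask) pair."""
    quantized = []
    for sample, mask in zip(samples, masks):
        smoothed = average_filter(sample.volume, cfg["kernel"])
        q = equalize_to_levels(smoothed, mask, n_levels=cfg["levels"])
        quantized.append((q, mask))
    return assemble_group(
        quantized,
        group=cfg["group"],
        labels=[s.label for s in samples],
        sample_ids=[s.sample_id for s in samples],
    )


def run_pipeline(config: dict | None = None) -> dict:
    """Run the full pipeline; returns a summary dict (also written to disk).

    Artifacts in the run directory: ``provenance.json``, ``manifest.csv``
    (plus images when ``write_images``), ``segmentation.json``,
    ``features.csv``, ``selection.json`` and one ``report_<ID>.json`` per
    classifier.
    """
    cfg = validate_config(config)
    outdir = cfg["outdir"]
    os.makedirs(outdir, exist_ok=True)
    t0 = time.time()

    try:
        pkg_version = version("celltex3d")
    except PackageNotFoundError:  # running from a source tree
        pkg_version = "unknown"
    provenance = {"config": cfg, "config_hash": config_hash(cfg), "version": pkg_version}
    _write_json(os.path.join(outdir, "provenance.json"), provenance)

    log.info("synthesizing cohort: 3 x %d samples, seed %d", cfg["n_per_class"], cfg["seed"])
    samples = generate_cohort(
        cfg["n_per_class"],
        base_seed=cfg["seed"],
        image_size=cfg["image_size"],
        n_bands=cfg["n_bands"],
    )
    if cfg["write_images"]:
        write_cohort(samples, os.path.join(outdir, "images"))
    pd.DataFrame(
        {"sample_id": [s.sample_id for s in samples], "label": [s.label for s in samples]}
    ).to_csv(os.path.join(outdir, "manifest.csv"), index=False)

    if cfg["segment"]:
        log.info("segmenting %d samples (work size %d)", len(samples), cfg["work_size"])
        seg = segment_cohort(samples, work_size=cfg["work_size"], max_iter=cfg["max_iter"])
        masks = [r.mask for r in seg.records]
        seg_report = {
            "mean": seg.mean_scores().as_dict(),
            "per_class": seg.per_class_means(),
            "per_sample": {r.sample_id: r.score.as_dict() for r in seg.records},
        }
    else:
        masks = [s.truth_mask for s in samples]
        seg_report = {"note": "ground-truth masks used; segmentation skipped"}
    _write_json(os.path.join(outdir, "segmentation.json"), seg_report)

    log.info("extracting %s features at %d gray levels", cfg["group"], cfg["levels"])
    features = extract_features(samples, masks, cfg)
    features.data.assign(label=features.labels).to_csv(os.path.join(outdir, "features.csv"))

    sel = select_features(
        features, alpha=cfg["alpha"], variance_target=cfg["pca_var"]
    )
    _write_json(
        os.path.join(outdir, "selection.json"),
        {
            "alpha": cfg["alpha"],
            "n_features": features.n_features,
            "n_selected": len(sel.selected_features),
            "selected_features": sel.selected_features,
            "p_values": {k: float(v) for k, v in sel.p_values.items()},
            "n_components": sel.n_components,
            "explained_variance_ratio": [float(v) for v in sel.explained_variance_ratio],
            "cumulative_variance": [float(v) for v in sel.cumulative_variance],
        },
    )
    sel.scores.assign(label=features.labels).to_csv(os.path.join(outdir, "pcs.csv"))

    reports = {}
    for clf in cfg["classifiers"]:
        log.info("LOOCV with %s", clf)
        rep = loocv_run(
            features,
            classifier=clf,
            refit_selection=cfg["refit_selection"],
            alpha=cfg["alpha"],
            variance_target=cfg["pca_var"],
        )
        reports[clf] = rep
        _write_json(os.path.join(outdir, f"report_{clf}.json"), rep.as_dict())

    summary = {
        "outdir": outdir,
        "config_hash": provenance["config_hash"],
        "n_samples": len(samples),
        "n_selected": len(sel.selected_features),
        "n_components": sel.n_components,
        "accuracy": {clf: rep.accuracy for clf, rep in reports.items()},
        "elapsed_s": round(time.time() - t0, 2),
        "reports": {clf: rep.as_dict() for clf, rep in reports.items()},
    }
    _write_json(os.path.join(outdir, "summary.json"), summary)
    log.info("done in %.1fs", summary["elapsed_s"])
    return summary


def _write_json(path: str, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
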