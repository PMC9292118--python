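"""End-to-end pipeline driver: simulate -> fit -> track -> pathway.

The pipeline is configured by a single YAML file (see
:func:`default_config`), validated up front against the parameter
invariants of every stage it will run, and stamped for reproducibility:
every run writes a manifest with the config hash, the global seed and
per-stage timings, and re-running with an identical config reproduces all
outputs (stochastic stages draw from generators seeded by the global
seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .pathway import PathwayRule, filter_by_rois, pa_map, pathway_ratio
from .phantom import PhantomSpec, make_phantom
from .tensor_model import MaskThresholds, compute_mask, fit_dti, tensor_metrics
from .tracking import SeedRegion, TrackingParams, seed_points, track_det, track_fact, track_prob
from .volumes import ImageVolume

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "default_config"]


class ConfigError(ValueError):
    """Raised when a pipeline configuration violates a stage invariant."""


def default_config() -> dict:
    """A small demonstration configuration (phantom -> fit -> track -> pathway)."""
    return {
        "seed": 0,
        "stages": {"simulate": True, "fit": True, "mask": True,
                   "track": True, "pathway": True},
        "phantom": {"shape": [48, 48, 48], "voxel_size": [0.6, 0.6, 0.6],
                    "noise_sigma": 0.0},
        "mask_thresholds": {"fa": [0.05, 1.0], "trace": [0.0, "inf"],
                            "dw": [1.0, "inf"]},
        "tracking": {"algorithm": "det", "fa_threshold": 0.1,
                     "max_angle_deg": 60.0, "step_mm": 0.05,
                     "max_length_mm": 20.0, "min_length_mm": 1.0},
        "seeding": {"kind": "cylinder", "center": [0.0, -8.1, 0.0],
                    "axis": [0, 0, 1], "radius": 1.5, "half_height": 3.0,
                    "n_seeds": 200},
        "pathway": {
            "include": [{"center": [-8.1, 0.0, 0.0], "axis": [0, 0, 1],
                         "radius": 2.0, "half_height": 4.0}],
            "n_requested": 200},
    }


class PipelineConfig:
    """Validated pipeline configuration."""

    def __init__(self, raw: dict):
        self.raw = dict(raw)
        self.seed = int(raw.get("seed", 0))
        self.stages = dict(raw.get("stages", {}))
        try:
            self.phantom_spec = PhantomSpec(
                shape=tuple(raw["phantom"].get("shape", (32, 32, 32))),
                voxel_size=tuple(raw["phantom"].get("voxel_size", (0.6, 0.6, 0.6))),
                noise_sigma=float(raw["phantom"].get("noise_sigma", 0.0)),
                seed=self.seed)
            tr = raw.get("tracking", {})
            self.tracking_params = TrackingParams(
                fa_threshold=float(tr.get("fa_threshold", 0.1)),
                max_angle_deg=float(tr.get("max_angle_deg", 60.0)),
                step_mm=float(tr.get("step_mm", 0.05)),
                max_length_mm=float(tr.get("max_length_mm", 40.0)),
                min_length_mm=float(tr.get("min_length_mm", 1.0)),
                rng_seed=self.seed)
            self.algorithm = str(tr.get("algorithm", "det")).lower()
            if self.algorithm not in ("fact", "det", "prob"):
                raise ValueError(f"unknown tracking algorithm {self.algorithm!r}")
            sd = raw.get("seeding", {})
            self.seed_region = SeedRegion(
                kind=sd.get("kind", "cylinder"), center=sd.get("center"),
                axis=sd.get("axis"), radius=sd.get("radius"),
                half_height=sd.get("half_height"), name="seed")
            self.n_seeds = int(sd.get("n_seeds", 200))
            mt = raw.get("mask_thresholds", {})

            def bounds(key):
                lo, hi = mt.get(key, [0.0, "inf"])
                return (float(lo), np.inf if hi in ("inf", None) else float(hi))
            self.mask_thresholds = MaskThresholds(
                fa=bounds("fa"), trace=bounds("trace"), dw=bounds("dw"))
            pw = raw.get("pathway", {})
            include = [SeedRegion(kind="cylinder", **c) for c in pw.get("include", [])]
            self.pathway_rule = (PathwayRule(
                seed=self.seed_region, include=include,
                n_requested=int(pw.get("n_requested", 200)))
                if include else None)
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"invalid pipeline configuration: {exc}") from exc

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def config_hash(self) -> str:
        return hashlib.sha1(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute the configured stages; returns the artifact directory.

    Any stage error aborts with the stage name; the manifest written so far
    is persisted for post-mortem inspection.
    """
    out = mio.ensure_dir(out_dir)
    manifest = {"config_hash": config.config_hash(), "seed": config.seed,
                "stages": {}}
    stage = "init"
    try:
        field = tensors = dwi = metrics = None
        if config.stages.get("simulate", True):
            stage = "simulate"
            t0 = time.perf_counter()
            field, tensors, dwi = make_phantom(config.phantom_spec)
            mio.write_dwi(dwi, out / "dwi.nii.gz")
            mio.write_gradients(config.phantom_spec.scheme(),
                                out / "dwi.bval", out / "dwi.bvec")
            mio.write_nifti(ImageVolume(field.vectors, field.affine),
                            out / "gt_v1.nii.gz")
            mio.write_nifti(ImageVolume(field.labels.astype(np.uint8),
                                        field.affine), out / "labels.nii.gz")
            mio.write_nifti(ImageVolume(field.mask.astype(np.uint8),
                                        field.affine), out / "mask.nii.gz")
            manifest["stages"]["simulate"] = {
                "seconds": time.perf_counter() - t0,
                "spec": {k: (list(v) if isinstance(v, tuple) else v)
                         for k, v in asdict(config.phantom_spec).items()}}

        if config.stages.get("fit", True):
            stage = "fit"
            t0 = time.perf_counter()
            if dwi is None:
                dwi = mio.read_dwi(out / "dwi.nii.gz")
            scheme = config.phantom_spec.scheme()
            fitted = fit_dti(dwi, scheme)
            metrics = tensor_metrics(fitted)
            mio.write_tensor_volume(fitted, out / "tensors.nii.gz")
            mio.write_nifti(ImageVolume(metrics.fa, metrics.affine),
                            out / "fa.nii.gz")
            mio.write_nifti(ImageVolume(metrics.adc, metrics.affine),
                            out / "adc.nii.gz")
            mio.write_nifti(ImageVolume(metrics.cfa, metrics.affine),
                            out / "cfa.nii.gz")
            tensors = fitted
            manifest["stages"]["fit"] = {"seconds": time.perf_counter() - t0}

        if config.stages.get("mask", True) and metrics is not None:
            stage = "mask"
            t0 = time.perf_counter()
            mask_vol = compute_mask(metrics, dwi, config.mask_thresholds)
            mio.write_nifti(mask_vol, out / "computed_mask.nii.gz")
            manifest["stages"]["mask"] = {"seconds": time.perf_counter() - t0}

        tractogram = None
        if config.stages.get("track", True):
            stage = "track"
            t0 = time.perf_counter()
            rng = np.random.default_rng(config.seed)
            seeds = seed_points(config.seed_region, config.n_seeds, rng)
            if config.algorithm == "fact":
                tractogram = track_fact(metrics, seeds=seeds,
                                        params=config.tracking_params)
            elif config.algorithm == "det":
                tractogram = track_det(tensors, seeds, config.tracking_params)
            else:
                tractogram = track_prob(tensors, seeds, config.tracking_params,
                                        rng=rng)
            mio.write_tck(tractogram, out / "tractogram.tck")
            manifest["stages"]["track"] = {
                "seconds": time.perf_counter() - t0,
                "n_streamlines": len(tractogram),
                "params_hash": config.tracking_params.params_hash()}

        if config.stages.get("pathway", True) and config.pathway_rule is not None:
            stage = "pathway"
            t0 = time.perf_counter()
            filtered = filter_by_rois(tractogram, config.pathway_rule)
            mio.write_tck(filtered, out / "pathway.tck")
            ratio = 100.0 * len(filtered) / max(len(tractogram), 1)
            pamap = pa_map(tractogram, tensors.shape3, tensors.affine)
            mio.write_nifti(ImageVolume(np.nan_to_num(pamap.values),
                                        pamap.affine), out / "pa_map.nii.gz")
            pd.DataFrame([{"pathway": "configured", "algorithm": config.algorithm,
                           "n_tracked": len(tractogram),
                           "n_surviving": len(filtered),
                           "ratio_percent": ratio}]).to_csv(
                out / "pathway_ratios.csv", index=False)
            manifest["stages"]["pathway"] = {
                "seconds": time.perf_counter() - t0, "ratio_percent": ratio}
    except ConfigError:
        raise
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
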