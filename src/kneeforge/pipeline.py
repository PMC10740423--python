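"""End-to-end inference pipeline: preprocess -> segment -> postprocess ->
reconstruct, with per-stage wall-clock timing and an optional metrics
appendix when reference surfaces or labels are available.

Postprocessing is defined as stitching + argmax (inside the segmentation
stage's prediction call) followed by per-class largest-connected-component
filtering of the labelmap — the minimal steps between raw scores and
meshing.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
from scipy import ndimage

from .core import (
    CLASS_NAMES,
    CTVolume,
    DataQualityError,
    FEMUR,
    LabelVolume,
    PipelineStageError,
    SurfaceMesh,
    TIBIA,
    logger,
)
from .preprocessing import NormalizationParams, normalize_intensity, rescale_to_hu

REPORT_SCHEMA_VERSION = 1


@dataclass
class StageTimings:
    """Wall times (s) per pipeline stage."""

    preprocessing: float = 0.0
    segmentation: float = 0.0
    postprocessing: float = 0.0
    reconstruction_tibia: float = 0.0
    reconstruction_femur: float = 0.0
    overall: float = 0.0

    def as_dict(self) -> Dict[str, float]:
        return {
            "preprocessing": self.preprocessing,
            "segmentation": self.segmentation,
            "postprocessing": self.postprocessing,
            "reconstruction_tibia": self.reconstruction_tibia,
            "reconstruction_femur": self.reconstruction_femur,
            "overall": self.overall,
        }


def largest_component_labels(labels: LabelVolume) -> LabelVolume:
    """Keep only the largest 26-connected component of each class."""
    out = np.zeros_like(labels.voxels)
    structure = np.ones((3, 3, 3), dtype=bool)
    for cid in labels.present_classes():
        if cid == 0:
            continue
        mask = labels.voxels == cid
        comp, n = ndimage.label(mask, structure=structure)
        if n <= 1:
            out[mask] = cid
            continue
        sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        out[comp == keep] = cid
    return LabelVolume(out, spacing=labels.spacing, origin=labels.origin)


@dataclass
class PipelineResult:
    labels: LabelVolume
    meshes: Dict[str, SurfaceMesh]
    timings: StageTimings
    metrics: Dict[str, object] = field(default_factory=dict)
    artifacts: Dict[str, str] = field(default_factory=dict)


def run_pipeline(
    ct: Union[CTVolume, str, Path],
    model,
    out_dir: Optional[Union[str, Path]] = None,
    patch_size: Optional[int] = None,
    norm: Optional[NormalizationParams] = None,
    rescale: Optional[Dict[str, float]] = None,
    ref_meshes: Optional[Dict[str, SurfaceMesh]] = None,
    ref_labels: Optional[LabelVolume] = None,
    smooth_iterations: int = 0,
) -> PipelineResult:
    """Run the automated tibia/femur reconstruction pipeline.

    ``ct`` may be a volume in HU (or raw values with ``rescale`` slope/
    intercept) or a path to a NIfTI file. ``model`` is a trained
    segmentation network (or a path to its checkpoint). Writes tibia.stl,
    femur.stl, seg.nii.gz and report.json into ``out_dir`` when given; any
    stage failure raises :class:`PipelineStageError` naming the stage,
    preserving artifacts already written.
    """
    from . import cel_unet, reconstruction, surface_metrics
    from .io import read_nifti, write_nifti, write_stl

    t_start = time.perf_counter()
    timings = StageTimings()
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    artifacts: Dict[str, str] = {}

    # --- preprocessing -----------------------------------------------------
    try:
        t0 = time.perf_counter()
        if isinstance(ct, (str, Path)):
            ct = read_nifti(ct)
        if rescale is not None:
            ct = rescale_to_hu(ct, rescale["slope"], rescale["intercept"])
        v = ct.voxels
        already_normalized = v.min() >= 0.0 and v.max() <= 1.0
        ct_norm = ct if already_normalized else normalize_intensity(ct, norm)
        timings.preprocessing = time.perf_counter() - t0
        logger.info("preprocessing done: shape %s", ct_norm.shape)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineStageError("preprocessing", str(exc)) from exc

    # --- segmentation ------------------------------------------------------
    try:
        t0 = time.perf_counter()
        if isinstance(model, (str, Path)):
            if not Path(model).exists():
                raise DataQualityError(f"weights file not found: {model}")
            model = cel_unet.load_checkpoint(model)
        raw_labels, scores = cel_unet.predict_volume(model, ct_norm, patch_size=patch_size)
        timings.segmentation = time.perf_counter() - t0
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("segmentation", str(exc)) from exc

    # --- postprocessing ----------------------------------------------------
    try:
        t0 = time.perf_counter()
        labels = largest_component_labels(raw_labels)
        timings.postprocessing = time.perf_counter() - t0
        if out_path is not None:
            write_nifti(labels, out_path / "seg.nii.gz")
            artifacts["seg"] = str(out_path / "seg.nii.gz")
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("postprocessing", str(exc)) from exc

    # --- reconstruction ----------------------------------------------------
    meshes: Dict[str, SurfaceMesh] = {}
    for cid, attr in ((TIBIA, "reconstruction_tibia"), (FEMUR, "reconstruction_femur")):
        name = CLASS_NAMES[cid]
        try:
            t0 = time.perf_counter()
            mesh = reconstruction.labelmap_to_mesh(labels, cid)
            mesh = reconstruction.largest_component(mesh)
            if smooth_iterations:
                mesh = reconstruction.smooth_mesh(mesh, smooth_iterations)
            meshes[name] = mesh
            setattr(timings, attr, time.perf_counter() - t0)
            if out_path is not None:
                write_stl(mesh, out_path / f"{name}.stl")
                artifacts[name] = str(out_path / f"{name}.stl")
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError(f"reconstruction_{name}", str(exc)) from exc

    timings.overall = time.perf_counter() - t_start

    # --- optional metrics --------------------------------------------------
    metrics: Dict[str, object] = {}
    if ref_labels is not None:
        for cid in (TIBIA, FEMUR):
            m, _ = surface_metrics.overlap_metrics(labels, ref_labels, cid)
            metrics[f"overlap_{CLASS_NAMES[cid]}"] = m
    if ref_meshes is not None:
        for name, mesh in meshes.items():
            if name in ref_meshes:
                rep = surface_metrics.surface_distance_report(mesh, ref_meshes[name])
                metrics[f"surface_{name}"] = {
                    "rmse_mm": rep.rmse_mm,
                    "hausdorff_mm": rep.hausdorff_mm,
                }

    result = PipelineResult(labels=labels, meshes=meshes, timings=timings,
                            metrics=metrics, artifacts=artifacts)
    if out_path is not None:
        report = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "timings_s": timings.as_dict(),
            "metrics": metrics,
            "artifacts": artifacts,
        }
        (out_path / "report.json").write_text(json.dumps(report, indent=2))
    return result
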