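"""File I/O: DICOM series, NIfTI volumes, STL surfaces, landmark JSON.

Internally volumes are (z, y, x) arrays with per-axis spacing/origin in the
same order; meshes are mm with (x, y, z) vertices (see ``core``). NIfTI is
written with an RAS-diagonal affine built from spacing and origin.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Tuple, Union

import numpy as np

from .core import (
    CTVolume,
    ConfigurationError,
    DataQualityError,
    LabelVolume,
    LandmarkSet,
    SurfaceMesh,
    logger,
)

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

def read_dicom_series(directory: PathLike) -> Tuple[CTVolume, float, float]:
    """Read an axial DICOM series into a raw volume.

    Returns (volume of stored values, rescale slope, rescale intercept).
    Slices are ordered by ImagePositionPatient along the slice normal;
    spacing comes from PixelSpacing and the inter-slice distance. Missing
    rescale tags raise a configuration error naming them.
    """
    import pydicom

    files = sorted(Path(directory).glob("*.dcm")) or sorted(
        p for p in Path(directory).iterdir() if p.is_file()
    )
    if not files:
        raise DataQualityError(f"no DICOM files found in {directory}")
    slices = [pydicom.dcmread(str(f)) for f in files]
    try:
        normal_positions = [float(s.ImagePositionPatient[2]) for s in slices]
    except AttributeError:
        normal_positions = [float(getattr(s, "InstanceNumber", i)) for i, s in enumerate(slices)]
    order = np.argsort(normal_positions)
    slices = [slices[i] for i in order]
    first = slices[0]
    slope = getattr(first, "RescaleSlope", None)
    intercept = getattr(first, "RescaleIntercept", None)
    if slope is None or intercept is None:
        raise ConfigurationError(
            "DICOM series lacks RescaleSlope (0028,1053) / RescaleIntercept (0028,1052)"
        )
    px_y, px_x = (float(v) for v in first.PixelSpacing)
    if len(slices) > 1:
        zs = np.sort(np.asarray(normal_positions, dtype=float))
        dz = float(np.median(np.diff(zs)))
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    vol = np.stack([s.pixel_array for s in slices]).astype(np.float64)
    origin_xyz = [float(v) for v in getattr(first, "ImagePositionPatient", (0.0, 0.0, 0.0))]
    ct = CTVolume(
        vol,
        spacing=(abs(dz), px_y, px_x),
        origin=(origin_xyz[2], origin_xyz[1], origin_xyz[0]),
    )
    logger.info("read DICOM series: %d slices, shape %s, spacing %s",
                len(slices), ct.shape, ct.spacing)
    return ct, float(slope), float(intercept)


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def read_nifti(path: PathLike, as_label: bool = False) -> Union[CTVolume, LabelVolume]:
    """Read a NIfTI volume; array axes are returned as (z, y, x)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)  # (x, y, z)
    if data.ndim != 3:
        raise DataQualityError(f"expected a 3-D NIfTI, got shape {data.shape}")
    vol = np.transpose(data, (2, 1, 0))
    zooms = img.header.get_zooms()[:3]  # (x, y, z)
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    origin_xyz = img.affine[:3, 3]
    origin = (float(origin_xyz[2]), float(origin_xyz[1]), float(origin_xyz[0]))
    if as_label:
        return LabelVolume(np.rint(vol).astype(np.int16), spacing=spacing, origin=origin)
    return CTVolume(vol.astype(np.float64), spacing=spacing, origin=origin)


def write_nifti(vol: CTVolume, path: PathLike) -> None:
    """Write a volume as NIfTI with a diagonal spacing affine."""
    import nibabel as nib

    data = np.transpose(vol.voxels, (2, 1, 0))  # (x, y, z)
    if isinstance(vol, LabelVolume):
        data = data.astype(np.int16)
    else:
        data = data.astype(np.float32)
    affine = np.diag([vol.spacing[2], vol.spacing[1], vol.spacing[0], 1.0])
    affine[:3, 3] = (vol.origin[2], vol.origin[1], vol.origin[0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


# ---------------------------------------------------------------------------
# STL
# ---------------------------------------------------------------------------

def read_stl(path: PathLike, **provenance) -> SurfaceMesh:
    """Read a binary or ASCII STL (mm units)."""
    import trimesh

    tm = trimesh.load(str(path), force="mesh", process=False)
    tm.merge_vertices()  # STL stores a triangle soup; weld shared vertices
    return SurfaceMesh.from_trimesh(tm, source=str(path), **provenance)


def write_stl(mesh: SurfaceMesh, path: PathLike) -> None:
    """Write a binary STL in mm."""
    mesh.to_trimesh().export(str(path))


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

def read_landmarks(path: PathLike) -> LandmarkSet:
    """Landmark JSON: {"points": [{"name", "xyz", "group"?}], "areas": {...},
    "planes": {...}}; groups may also be given per-point."""
    spec = json.loads(Path(path).read_text())
    points = {p["name"]: np.asarray(p["xyz"], dtype=float) for p in spec["points"]}
    areas: Dict[str, list] = {k: list(v) for k, v in spec.get("areas", {}).items()}
    planes: Dict[str, list] = {k: list(v) for k, v in spec.get("planes", {}).items()}
    for p in spec["points"]:
        g = p.get("group")
        if g and g not in areas and g not in planes:
            areas.setdefault(g, []).append(p["name"])
    return LandmarkSet(points=points, areas=areas, plane_points=planes)


def write_landmarks(lm: LandmarkSet, path: PathLike) -> None:
    payload = {
        "points": [{"name": n, "xyz": [float(v) for v in p]} for n, p in lm.points.items()],
        "areas": lm.areas,
        "planes": lm.plane_points,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def load_config(path: PathLike) -> Dict:
    """YAML or JSON pipeline configuration."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        return yaml.safe_load(text) or {}
    return json.loads(text)
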