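"""Shared domain types, grid geometry and error classes.

Coordinate conventions used throughout the package
--------------------------------------------------
* Voxel arrays are indexed ``(z, y, x)``: axis 0 is axial / cranio-caudal
  (CC), axis 1 is coronal row / antero-posterior (AP), axis 2 is sagittal
  column / medio-lateral (ML).
* ``spacing`` and ``origin`` are stored in the same ``(z, y, x)`` order, in
  millimetres.
* The physical position of the *center* of voxel ``(i, j, k)`` is
  ``origin + (i, j, k) * spacing`` — no half-voxel shift.
* Surface meshes live in physical millimetres with vertices ordered
  ``(x, y, z)`` (the usual STL convention); :func:`index_to_mm` and
  :func:`mm_to_index` convert between the two, flipping axis order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

logger = logging.getLogger("kneeforge")

# Class codes for the labelmaps.
BACKGROUND = 0
TIBIA = 1
FEMUR = 2
CLASS_NAMES = {BACKGROUND: "background", TIBIA: "tibia", FEMUR: "femur"}
CLASS_IDS = {v: k for k, v in CLASS_NAMES.items()}


class KneeforgeError(Exception):
    """Base class for package errors."""


class ConfigurationError(KneeforgeError):
    """Missing or inconsistent configuration (e.g. absent DICOM rescale tags)."""


class DataQualityError(KneeforgeError):
    """Input data violates a precondition (NaNs, empty labels, open meshes...)."""


class PipelineStageError(KneeforgeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def setup_logging(level: int = logging.INFO, logfile: Optional[str] = None) -> None:
    """Configure package logging to stderr and optionally a file."""
    logger.setLevel(level)
    if not logger.handlers:
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(h)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(fh)


# ---------------------------------------------------------------------------
# Grid-attached volumes
# ---------------------------------------------------------------------------

@dataclass
class CTVolume:
    """A scalar voxel grid (HU or normalized) with physical metadata.

    ``voxels`` is a rank-3 array indexed (z, y, x); ``spacing`` and
    ``origin`` follow the same axis order, in mm.
    """

    voxels: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: Tuple[str, str, str] = ("axial", "coronal", "sagittal")

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise DataQualityError(f"expected a rank-3 voxel grid, got rank {self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise DataQualityError(f"spacing components must be > 0, got {self.spacing}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return tuple(self.voxels.shape)

    def with_voxels(self, voxels: np.ndarray) -> "CTVolume":
        """Copy of this volume with new voxel data on the same grid."""
        return replace(self, voxels=voxels)

    def same_grid(self, other: "CTVolume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class LabelVolume(CTVolume):
    """Integer class map on a voxel grid: 0 background, 1 tibia, 2 femur."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise DataQualityError("label voxels must have an integer dtype")

    def class_mask(self, class_id: int) -> np.ndarray:
        return self.voxels == class_id

    def present_classes(self) -> List[int]:
        return sorted(int(c) for c in np.unique(self.voxels))


@dataclass
class EdgeVolume:
    """Per-class binary boundary maps, shape (classes, z, y, x)."""

    voxels: np.ndarray  # bool, (C, z, y, x)
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 4:
            raise DataQualityError("edge voxels must have shape (classes, z, y, x)")


# ---------------------------------------------------------------------------
# Meshes and landmarks
# ---------------------------------------------------------------------------

@dataclass
class SurfaceMesh:
    """Triangulated surface in physical mm, vertices ordered (x, y, z)."""

    vertices: np.ndarray  # (V, 3) float, mm
    faces: np.ndarray     # (F, 3) int
    provenance: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise DataQualityError("face indices out of range")

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @classmethod
    def from_trimesh(cls, tm, **provenance) -> "SurfaceMesh":
        return cls(vertices=np.asarray(tm.vertices, float),
                   faces=np.asarray(tm.faces, np.int64),
                   provenance=dict(provenance))


@dataclass
class LandmarkSet:
    """Named physical-space points (mm, xyz) grouped by contact area or plane.

    ``points`` maps landmark name → xyz; ``areas`` maps area name (e.g. "A")
    → list of landmark names; ``plane_points`` maps cutting-plane name →
    list of exactly four landmark names (two frontal, two posterior).
    """

    points: Dict[str, np.ndarray]
    areas: Dict[str, List[str]] = field(default_factory=dict)
    plane_points: Dict[str, List[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = {k: np.asarray(v, dtype=float) for k, v in self.points.items()}
        for area, names in self.areas.items():
            if len(names) not in (3, 4):
                raise DataQualityError(f"contact area {area!r} must have 3 or 4 landmarks")
        for plane, names in self.plane_points.items():
            if len(names) != 4:
                raise DataQualityError(f"cutting plane {plane!r} must have exactly 4 points")

    def area_points(self, area: str) -> np.ndarray:
        return np.array([self.points[n] for n in self.areas[area]])

    def plane_point_array(self, plane: str) -> np.ndarray:
        return np.array([self.points[n] for n in self.plane_points[plane]])


@dataclass
class CutPlane:
    """A fitted resection plane: centroid + unit normal, in mm."""

    point: np.ndarray
    normal: np.ndarray
    source: str = "reference"

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        n = np.linalg.norm(self.normal)
        if not np.isfinite(n) or n < 1e-12:
            raise DataQualityError("cut plane normal must be nonzero")
        self.normal = self.normal / n


@dataclass
class CutPlaneDeviation:
    """Angular deviation of two cut-plane normals projected on the frontal
    (ML–CC) and sagittal (AP–CC) anatomical planes, in degrees."""

    theta_frontal: float
    theta_sagittal: float


# ---------------------------------------------------------------------------
# Index <-> physical coordinate transforms
# ---------------------------------------------------------------------------

def index_to_mm(idx_zyx: np.ndarray, vol: CTVolume) -> np.ndarray:
    """Map (possibly fractional) (z,y,x) voxel indices to physical (x,y,z) mm."""
    idx = np.atleast_2d(np.asarray(idx_zyx, dtype=float))
    sp = np.asarray(vol.spacing)
    og = np.asarray(vol.origin)
    zyx_mm = og + idx * sp
    return zyx_mm[..., ::-1]


def mm_to_index(xyz_mm: np.ndarray, vol: CTVolume) -> np.ndarray:
    """Map physical (x,y,z) mm points to fractional (z,y,x) voxel indices."""
    pts = np.atleast_2d(np.asarray(xyz_mm, dtype=float))
    zyx_mm = pts[..., ::-1]
    sp = np.asarray(vol.spacing)
    og = np.asarray(vol.origin)
    return (zyx_mm - og) / sp
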