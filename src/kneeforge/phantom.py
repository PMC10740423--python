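"""Seeded synthetic knee phantoms: two bone-like bodies with a tunable
joint gap, rasterized to CT-like HU volumes with exact ground truth.

The phantom is a geometric surrogate of a distal femur / proximal tibia
pair, not anatomy: the femur is two condylar spheres joined by a bridge and
shaft; the tibia is a plateau disk with two shallow articular concavities,
a shaft, and a central intercondylar spine rising between the femoral
condyles. The minimal clearance between the spine and the condyles is the
``joint_gap`` parameter, so axial slices through the joint contain femoral
and tibial cross-sections separated in-plane by exactly that gap — the
configuration in which morphology-based label generation oversegments.

All solids are signed-distance functions (SDFs); ground-truth labels come
from the SDF sign at voxel centers (exact), meshes from high-resolution
marching cubes of the SDF, and the CT from HU plateau assignment
(cortical shell / trabecular core / soft tissue) followed by Gaussian blur
and seeded Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.measure import marching_cubes

from .core import (
    CTVolume,
    CutPlane,
    DataQualityError,
    FEMUR,
    LabelVolume,
    LandmarkSet,
    SurfaceMesh,
    TIBIA,
)
from .surface_metrics import MeshDistanceQuery

# ---------------------------------------------------------------------------
# SDF primitives (points are (N, 3) xyz mm)
# ---------------------------------------------------------------------------

def sd_sphere(p: np.ndarray, center, radius: float) -> np.ndarray:
    return np.linalg.norm(p - np.asarray(center, float), axis=-1) - radius


def sd_capsule(p: np.ndarray, a, b, radius: float) -> np.ndarray:
    a = np.asarray(a, float)
    ab = np.asarray(b, float) - a
    t = np.clip(((p - a) @ ab) / (ab @ ab), 0.0, 1.0)
    return np.linalg.norm(p - (a + t[:, None] * ab), axis=-1) - radius


def sd_capped_cylinder(p: np.ndarray, center, radius: float, half_height: float) -> np.ndarray:
    """Vertical (z-axis) capped cylinder, exact SDF."""
    c = np.asarray(center, float)
    q = p - c
    d_r = np.linalg.norm(q[:, :2], axis=1) - radius
    d_z = np.abs(q[:, 2]) - half_height
    outside = np.sqrt(np.maximum(d_r, 0.0) ** 2 + np.maximum(d_z, 0.0) ** 2)
    inside = np.minimum(np.maximum(d_r, d_z), 0.0)
    return outside + inside


def sd_union(*ds: np.ndarray) -> np.ndarray:
    out = ds[0]
    for d in ds[1:]:
        out = np.minimum(out, d)
    return out


def sd_subtract(d: np.ndarray, cut: np.ndarray) -> np.ndarray:
    """Boolean subtraction: sign-exact, distance approximate near the cut."""
    return np.maximum(d, -cut)


# ---------------------------------------------------------------------------
# Specification
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Parameters of the synthetic knee. Lengths in mm, intensities in HU."""

    shape: Tuple[int, int, int] = (96, 96, 96)  # (z, y, x) voxels
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    joint_gap: float = 4.0            # minimal clearance spine <-> condyles
    condyle_radius: float = 14.0
    spine_radius: float = 6.0
    plateau_radius: float = 22.0
    shaft_radius: float = 7.0
    concavity_depth: float = 2.0
    n_osteophytes: int = 2
    hu_cortical: float = 1200.0
    hu_trabecular: float = 300.0
    hu_soft: float = 50.0
    cortical_thickness: float = 2.5   # mm, shell assigned the cortical HU
    blur_sigma: float = 0.7           # mm
    noise_sigma: float = 20.0         # HU
    mesh_refine: int = 2              # marching-cubes oversampling factor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.joint_gap < 0:
            raise DataQualityError("joint_gap must be >= 0")
        if not (self.hu_cortical > self.hu_trabecular > self.hu_soft):
            raise DataQualityError("HU levels must satisfy cortical > trabecular > soft")
        if any(s <= 0 for s in self.spacing):
            raise DataQualityError("spacing must be positive")


@dataclass
class PhantomBundle:
    """Everything a pipeline stage could need, with exact ground truth."""

    spec: PhantomSpec
    ct: CTVolume
    labels: LabelVolume
    meshes: Dict[str, SurfaceMesh]
    landmarks: Dict[str, LandmarkSet]
    cut_planes: Dict[str, CutPlane]
    gap_mask: np.ndarray              # background voxels inside the joint corridor
    sdfs: Dict[str, Callable[[np.ndarray], np.ndarray]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

# Centers sit slightly off the voxel lattice (and off its half/quarter
# subdivisions used by mesh_refine) so no flat face or tangency plane passes
# exactly through voxel centers or marching-cubes grid points.
_CX = 48.31
_CY = 48.27
_CONDYLE_Z = 60.53     # femoral condyle sphere centers
_SPINE_TOP_Z = 58.53   # tibial spine capsule axis top (cap center)
_PLATEAU_TOP_Z = 38.57


def _condyle_offset(spec: PhantomSpec) -> float:
    """Lateral condyle-center offset giving exactly joint_gap clearance
    between each condyle sphere and the spine's top cap."""
    reach = spec.condyle_radius + spec.spine_radius + spec.joint_gap
    dz = _CONDYLE_Z - _SPINE_TOP_Z
    return float(np.sqrt(reach**2 - dz**2))


def _femur_sdf(spec: PhantomSpec) -> Callable[[np.ndarray], np.ndarray]:
    rc = spec.condyle_radius
    off = _condyle_offset(spec)
    cx, cy = _CX, _CY

    def sdf(p: np.ndarray) -> np.ndarray:
        # two condyles joined by a high transverse bridge and a short shaft;
        # the bridge clears the tibial spine top by >= 9 mm for any
        # joint_gap <= 8, so the spine-condyle clearance is the minimum.
        return sd_union(
            sd_sphere(p, (cx - off, cy, _CONDYLE_Z), rc),
            sd_sphere(p, (cx + off, cy, _CONDYLE_Z), rc),
            sd_capsule(p, (cx - off, cy, 80.53), (cx + off, cy, 80.53), spec.shaft_radius),
            sd_capsule(p, (cx, cy, 80.53), (cx, cy, 84.53), spec.shaft_radius),
        )

    return sdf


def _tibia_sdf(spec: PhantomSpec) -> Callable[[np.ndarray], np.ndarray]:
    cx, cy = _CX, _CY
    rng = np.random.default_rng(spec.seed)
    # osteophyte bumps on the posterior plateau rim, placed clear of the joint
    bump_angles = rng.uniform(np.pi * 0.3, np.pi * 0.7, size=spec.n_osteophytes)
    bump_sides = rng.choice([-1.0, 1.0], size=spec.n_osteophytes)
    bump_r = rng.uniform(2.0, 3.0, size=spec.n_osteophytes)

    def sdf(p: np.ndarray) -> np.ndarray:
        body = sd_union(
            # plateau disk, top at z=38.5 (8 mm below the condyle bottoms)
            sd_capped_cylinder(p, (cx, cy, _PLATEAU_TOP_Z - 7.0), spec.plateau_radius, 7.0),
            # intercondylar spine rising between the condyles
            sd_capsule(p, (cx, cy, 30.53), (cx, cy, _SPINE_TOP_Z), spec.spine_radius),
            sd_capsule(p, (cx, cy, 16.53), (cx, cy, 26.53), 11.0),  # shaft
        )
        # osteophytes poke out of the plateau's cylindrical side at rim
        # height, intersecting it transversally (no grazing contact with
        # the flat top), and stay >= 9 mm clear of the femur.
        for ang, side, r in zip(bump_angles, bump_sides, bump_r):
            bx = cx + side * spec.plateau_radius * np.sin(ang)
            by = cy + spec.plateau_radius * np.cos(ang)
            body = sd_union(body, sd_sphere(p, (bx, by, 31.53), r))
        # articular concavities dipping into the plateau top
        for sx in (-1.0, 1.0):
            body = sd_subtract(
                body,
                sd_sphere(
                    p,
                    (cx + sx * 11.0, cy, _PLATEAU_TOP_Z + 9.0 - spec.concavity_depth),
                    9.0,
                ),
            )
        return body

    return sdf


def _grid_points_mm(spec: PhantomSpec) -> np.ndarray:
    """Voxel-center coordinates (N, 3) xyz mm, z-major ravel order."""
    nz, ny, nx = spec.shape
    sz, sy, sx = spec.spacing
    zz, yy, xx = np.meshgrid(
        np.arange(nz) * sz, np.arange(ny) * sy, np.arange(nx) * sx, indexing="ij"
    )
    return np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)


def _mesh_from_sdf(sdf, spec: PhantomSpec, name: str) -> SurfaceMesh:
    """High-resolution marching cubes of the SDF zero level set, in mm."""
    f = spec.mesh_refine
    nz, ny, nx = spec.shape
    sz, sy, sx = spec.spacing
    fine_spacing = (sz / f, sy / f, sx / f)
    zs = np.arange(nz * f) * fine_spacing[0]
    ys = np.arange(ny * f) * fine_spacing[1]
    xs = np.arange(nx * f) * fine_spacing[2]
    zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
    pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    field_vals = sdf(pts).reshape(zz.shape)
    verts, faces, _, _ = marching_cubes(field_vals, level=0.0, spacing=fine_spacing)
    # verts are (z, y, x) mm -> flip to (x, y, z)
    return SurfaceMesh(vertices=verts[:, ::-1], faces=faces, provenance={"class": name})


def _assign_hu(sdf_vals: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    hu = np.full(sdf_vals.shape, spec.hu_soft)
    inside = sdf_vals < 0
    hu[inside] = np.where(
        sdf_vals[inside] > -spec.cortical_thickness, spec.hu_cortical, spec.hu_trabecular
    )
    return hu


def _project_landmarks(seeds: Dict[str, np.ndarray], mesh: SurfaceMesh) -> Dict[str, np.ndarray]:
    q = MeshDistanceQuery(mesh)
    names = list(seeds)
    pts = np.array([seeds[n] for n in names], dtype=float)
    closest, _, _ = q.query(pts)
    return {n: closest[i] for i, n in enumerate(names)}


# ---------------------------------------------------------------------------
# Public generators
# ---------------------------------------------------------------------------

def generate_phantom(spec: Optional[PhantomSpec] = None) -> PhantomBundle:
    """Build the full two-body knee phantom for a specification (seeded)."""
    spec = spec or PhantomSpec()
    g = spec.joint_gap
    cx, cy = _CX, _CY
    off = _condyle_offset(spec)

    femur = _femur_sdf(spec)
    tibia = _tibia_sdf(spec)

    pts = _grid_points_mm(spec)
    d_f = femur(pts).reshape(spec.shape)
    d_t = tibia(pts).reshape(spec.shape)

    labels = np.zeros(spec.shape, dtype=np.int16)
    labels[d_t < 0] = TIBIA
    labels[d_f < 0] = FEMUR
    if np.any((d_t < 0) & (d_f < 0)):
        raise DataQualityError("phantom solids overlap; joint_gap too small for geometry")

    # joint corridor: background voxels lying *between* the two surfaces
    # (for such points d_femur + d_tibia ~ local clearance)
    slack = 1.0 * max(spec.spacing)
    gap_mask = (labels == 0) & (d_f + d_t <= g + slack)

    hu = _assign_hu(np.minimum(d_f, d_t), spec)
    if spec.blur_sigma > 0:
        hu = ndimage.gaussian_filter(hu, sigma=[spec.blur_sigma / s for s in spec.spacing])
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed + 1)
        hu = hu + rng.normal(0.0, spec.noise_sigma, size=hu.shape)

    meshes = {
        "tibia": _mesh_from_sdf(tibia, spec, "tibia"),
        "femur": _mesh_from_sdf(femur, spec, "femur"),
    }

    # --- landmarks: contact areas A-C (tibia) and D-E (femur) analogues ---
    ant = cy - 20.0  # anterior side (low y)
    tibia_seeds = {
        "L1": (cx - 16.0, cy - 6.0, 40.0), "L2": (cx - 10.0, cy - 6.0, 40.0),
        "L3": (cx - 10.0, cy + 6.0, 40.0), "L4": (cx - 16.0, cy + 6.0, 40.0),
        "L5": (cx - 5.0, ant, 33.0), "L6": (cx + 5.0, ant, 33.0), "L7": (cx, ant, 28.0),
        "L8": (cx + 10.0, cy - 6.0, 40.0), "L9": (cx + 16.0, cy - 6.0, 40.0),
        "L10": (cx + 16.0, cy + 6.0, 40.0), "L11": (cx + 10.0, cy + 6.0, 40.0),
    }
    femur_seeds = {
        "L1": (cx - off - 5.0, cy - 12.0, 58.0), "L2": (cx - off + 5.0, cy - 12.0, 58.0),
        "L3": (cx - off + 5.0, cy - 12.0, 64.0), "L4": (cx - off - 5.0, cy - 12.0, 64.0),
        "L5": (cx + off - 5.0, cy - 12.0, 58.0), "L6": (cx + off + 5.0, cy - 12.0, 58.0),
        "L7": (cx + off + 5.0, cy - 12.0, 64.0), "L8": (cx + off - 5.0, cy - 12.0, 64.0),
    }
    landmarks = {
        "tibia": LandmarkSet(
            points=_project_landmarks(tibia_seeds, meshes["tibia"]),
            areas={"A": ["L1", "L2", "L3", "L4"],
                   "B": ["L5", "L6", "L7"],
                   "C": ["L8", "L9", "L10", "L11"]},
        ),
        "femur": LandmarkSet(
            points=_project_landmarks(femur_seeds, meshes["femur"]),
            areas={"D": ["L1", "L2", "L3", "L4"],
                   "E": ["L5", "L6", "L7", "L8"]},
        ),
    }

    # --- reference cutting planes with four exactly coplanar landmarks ---
    tib_plane_pts = {
        "P1": (cx - 10.0, cy - 8.0, 32.0), "P2": (cx + 10.0, cy - 8.0, 32.0),  # frontal
        "P3": (cx - 10.0, cy + 8.0, 32.0), "P4": (cx + 10.0, cy + 8.0, 32.0),  # posterior
    }
    fem_plane_pts = {
        "P1": (cx - off, cy - 8.0, 66.0), "P2": (cx + off, cy - 8.0, 66.0),
        "P3": (cx - off, cy + 8.0, 66.0), "P4": (cx + off, cy + 8.0, 66.0),
    }
    for bone, plane_pts in (("tibia", tib_plane_pts), ("femur", fem_plane_pts)):
        lm = landmarks[bone]
        lm.points.update({k: np.asarray(v, float) for k, v in plane_pts.items()})
        lm.plane_points["resection"] = ["P1", "P2", "P3", "P4"]
    cut_planes = {
        "tibia": CutPlane(point=np.array([cx, cy, 32.0]), normal=np.array([0.0, 0.0, 1.0]),
                          source="reference"),
        "femur": CutPlane(point=np.array([cx, cy, 66.0]), normal=np.array([0.0, 0.0, 1.0]),
                          source="reference"),
    }

    ct = CTVolume(hu, spacing=spec.spacing)
    return PhantomBundle(
        spec=spec,
        ct=ct,
        labels=LabelVolume(labels, spacing=spec.spacing),
        meshes=meshes,
        landmarks=landmarks,
        cut_planes=cut_planes,
        gap_mask=gap_mask,
        sdfs={"tibia": tibia, "femur": femur},
    )


def sphere_fixture(
    radius: float = 10.0,
    spacing: float = 1.0,
    shape: Optional[Tuple[int, int, int]] = None,
    mesh_refine: int = 4,
    seed: int = 0,
) -> PhantomBundle:
    """Single analytic sphere on a grid — the oracle fixture.

    The sphere center sits exactly on a voxel center at the grid middle.
    """
    if radius <= spacing:
        raise DataQualityError("sphere radius must exceed the voxel spacing")
    if shape is None:
        n = int(np.ceil(2 * radius / spacing)) + 9
        shape = (n, n, n)
    spec = PhantomSpec(
        shape=shape, spacing=(spacing,) * 3, joint_gap=0.0,
        blur_sigma=0.0, noise_sigma=0.0, n_osteophytes=0,
        mesh_refine=mesh_refine, seed=seed,
    )
    c = tuple((s // 2) * spacing for s in shape[::-1])  # xyz mm, on a voxel center

    def sdf(p: np.ndarray) -> np.ndarray:
        return sd_sphere(p, c, radius)

    pts = _grid_points_mm(spec)
    d = sdf(pts).reshape(shape)
    labels = (d < 0).astype(np.int16) * TIBIA
    hu = _assign_hu(d, spec)
    mesh = _mesh_from_sdf(sdf, spec, "tibia")
    mesh.provenance.update({"analytic": "sphere", "center": c, "radius": radius})
    return PhantomBundle(
        spec=spec,
        ct=CTVolume(hu, spacing=spec.spacing),
        labels=LabelVolume(labels, spacing=spec.spacing),
        meshes={"tibia": mesh},
        landmarks={},
        cut_planes={},
        gap_mask=np.zeros(shape, dtype=bool),
        sdfs={"tibia": sdf},
    )
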