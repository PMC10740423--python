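"""PSI (patient-specific instrument) planning feasibility analysis.

A PSI cutting jig only fits if the reconstructed bone matches the true
surface at defined contact areas, and if the planned resection planes keep
their orientation. This module quantifies both:

* each planning landmark is transferred onto the predicted surface by the
  minimal-distance criterion (exact nearest point on the triangulated
  surface, not nearest vertex) and the transfer distances are aggregated
  per contact area (median / IQR);
* a resection plane is fitted to its four landmarks by total least squares
  (smallest principal direction of the centered points) and the angular
  deviation between reference and predicted plane normals is projected
  onto the frontal (ML-CC) and sagittal (AP-CC) anatomical planes, the two
  clinically reported alignment angles.

Anatomical axes default to the scanner frame: ML = x, AP = y, CC = z.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np

from .core import (
    CutPlane,
    CutPlaneDeviation,
    DataQualityError,
    LandmarkSet,
    SurfaceMesh,
)
from .surface_metrics import MeshDistanceQuery

#: Default anatomical frame (rows: ML, AP, CC) in volume xyz coordinates.
DEFAULT_AXES = np.eye(3)


def transfer_landmark(
    point: np.ndarray, predicted: SurfaceMesh,
    query: Optional[MeshDistanceQuery] = None,
) -> Tuple[np.ndarray, float]:
    """Closest point on the predicted surface and its distance in mm."""
    q = query or MeshDistanceQuery(predicted)
    closest, dist, _ = q.query(np.atleast_2d(np.asarray(point, float)))
    return closest[0], float(dist[0])


def contact_area_errors(
    landmarks: LandmarkSet, predicted: SurfaceMesh
) -> Dict[str, object]:
    """Per-landmark transfer distances plus per-area median and IQR (mm)."""
    q = MeshDistanceQuery(predicted)
    per_landmark: Dict[str, float] = {}
    area_members = {n for names in landmarks.areas.values() for n in names}
    for name in sorted(area_members):
        if name not in landmarks.points:
            continue
        _, d = transfer_landmark(landmarks.points[name], predicted, query=q)
        per_landmark[name] = d
    per_area: Dict[str, Dict[str, float]] = {}
    for area, names in landmarks.areas.items():
        missing = [n for n in names if n not in per_landmark]
        if missing:
            per_area[area] = {"absent": True}
            continue
        d = np.array([per_landmark[n] for n in names])
        q1, med, q3 = np.percentile(d, [25, 50, 75])
        per_area[area] = {
            "median": float(med), "iqr_lo": float(q1), "iqr_hi": float(q3),
            "n": len(d),
        }
    return {"per_landmark": per_landmark, "per_area": per_area}


def fit_cutting_plane(points: np.ndarray, source: str = "reference") -> CutPlane:
    """Total-least-squares plane through (typically four) landmark points.

    The normal is the smallest principal direction of the centered points;
    its sign is fixed to point toward +CC (ties broken toward +AP, then
    +ML) so reference and predicted planes share an orientation convention.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 3:
        raise DataQualityError("plane fit needs at least 3 points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise DataQualityError("landmarks are collinear or coincident; plane undefined")
    normal = vt[-1]
    for comp in (2, 1, 0):  # CC, then AP, then ML
        if abs(normal[comp]) > 1e-12:
            if normal[comp] < 0:
                normal = -normal
            break
    return CutPlane(point=centroid, normal=normal, source=source)


def projected_angular_deviation(
    ref: CutPlane, pred: CutPlane, axes: np.ndarray = DEFAULT_AXES
) -> CutPlaneDeviation:
    """Angles between the two normals after projection on the frontal and
    sagittal anatomical planes, in degrees (sign-insensitive, 0..90).

    ``axes`` rows are the orthonormal ML, AP, CC directions. The frontal
    plane is spanned by (ML, CC); the sagittal plane by (AP, CC).
    """
    axes = np.asarray(axes, dtype=float)
    if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-8):
        raise DataQualityError("anatomical axes must be orthonormal")
    ml, ap, cc = axes

    def angle_in_plane(u: np.ndarray, v: np.ndarray, e1, e2) -> float:
        pu = np.array([u @ e1, u @ e2])
        pv = np.array([v @ e1, v @ e2])
        nu, nv = np.linalg.norm(pu), np.linalg.norm(pv)
        if nu < 1e-9 or nv < 1e-9:
            raise DataQualityError(
                "plane normal is perpendicular to the projection plane; "
                "projected angle undefined"
            )
        c = abs(pu @ pv) / (nu * nv)  # sign-flip invariant
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    return CutPlaneDeviation(
        theta_frontal=angle_in_plane(ref.normal, pred.normal, ml, cc),
        theta_sagittal=angle_in_plane(ref.normal, pred.normal, ap, cc),
    )


def psi_feasibility_report(
    landmarks_by_bone: Dict[str, LandmarkSet],
    predicted_meshes: Dict[str, SurfaceMesh],
    reference_planes: Dict[str, CutPlane],
    axes: np.ndarray = DEFAULT_AXES,
) -> Dict[str, object]:
    """Full feasibility summary: contact-area errors and cutting-plane
    deviations per bone, mirroring the clinical report structure."""
    report: Dict[str, object] = {}
    for bone, lm in landmarks_by_bone.items():
        if bone not in predicted_meshes:
            report[bone] = {"absent": True}
            continue
        mesh = predicted_meshes[bone]
        entry: Dict[str, object] = contact_area_errors(lm, mesh)
        planes: Dict[str, object] = {}
        q = MeshDistanceQuery(mesh)
        for plane_name in lm.plane_points:
            ref_pts = lm.plane_point_array(plane_name)
            pred_pts = np.stack([q.query(p[None])[0][0] for p in ref_pts])
            ref_plane = reference_planes.get(bone) or fit_cutting_plane(ref_pts)
            pred_plane = fit_cutting_plane(pred_pts, source="predicted")
            dev = projected_angular_deviation(ref_plane, pred_plane, axes)
            planes[plane_name] = {
                "theta_frontal_deg": dev.theta_frontal,
                "theta_sagittal_deg": dev.theta_sagittal,
            }
        entry["cut_planes"] = planes
        report[bone] = entry
    return report
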