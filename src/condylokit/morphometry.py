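"""Linear, angular and volumetric measurements on mandibular surface models.

Condylar volumes are measured above a cutting plane (the C-plane) that
delineates the caudal border of the condyle. The clipped region is never
capped explicitly: because every cap facet is coplanar with a reference
point chosen on the plane, the signed-tetrahedron sum over the clipped open
surface about that point equals the closed region's volume exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from trimesh.intersections import slice_mesh_plane

from .core import CANONICAL_FRAME, AnatomicalFrame, SurfaceMesh
from .kinematics import register_rigid

__all__ = [
    "Plane",
    "CondyleMetrics",
    "FacialMeasures",
    "construct_c_plane",
    "condylar_volume",
    "volume_above_plane",
    "condylar_change",
    "ramal_height",
    "facial_measures",
]


@dataclass(frozen=True)
class Plane:
    """Oriented plane; ``normal`` points toward the kept (condylar) side."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("plane normal must be nonzero")
        object.__setattr__(self, "normal", n / norm)


@dataclass
class CondyleMetrics:
    side: str
    volume_t0: float
    volume_t2: float
    ramal_height_t0: float
    ramal_height_t2: float

    @property
    def delta_volume(self) -> float:
        return self.volume_t2 - self.volume_t0

    @property
    def delta_volume_pct(self) -> float:
        return 100.0 * self.delta_volume / self.volume_t0

    @property
    def delta_ramal_height(self) -> float:
        return self.ramal_height_t2 - self.ramal_height_t0


@dataclass(frozen=True)
class FacialMeasures:
    anterior_lower_facial_height: float
    ramal_height_left: float
    ramal_height_right: float
    ap_ratio: float
    mandibular_plane_angle: float


def construct_c_plane(
    mesh: SurfaceMesh,
    side: str,
    frame: AnatomicalFrame | None = None,
) -> Plane:
    """Axial-normal plane through the side's sigmoid-notch nadir."""
    frame = frame or mesh.frame
    key = f"sigmoid_notch_{side}"
    if key not in mesh.landmarks:
        raise KeyError(f"missing landmark {key!r}")
    return Plane(mesh.landmarks[key], frame.si)


def _signed_volume_about(triangles: np.ndarray, origin: np.ndarray) -> float:
    """Sum of signed tetrahedra of ``triangles`` about ``origin``."""
    t = triangles - origin
    return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)


def _clip_open(mesh: trimesh.Trimesh, plane: Plane) -> trimesh.Trimesh:
    return slice_mesh_plane(mesh, plane_normal=plane.normal, plane_origin=plane.point, cap=False)


def volume_above_plane(mesh: trimesh.Trimesh | SurfaceMesh, plane: Plane) -> float:
    """Total volume of the mesh region on the plane's positive side."""
    tm = mesh.mesh if isinstance(mesh, SurfaceMesh) else mesh
    if not tm.is_watertight:
        raise ValueError("volume requires a watertight mesh")
    clipped = _clip_open(tm, plane)
    if clipped.is_empty or len(clipped.faces) == 0:
        return 0.0
    return _signed_volume_about(clipped.triangles, plane.point)


def condylar_volume(
    mesh: SurfaceMesh,
    plane: Plane,
    side: str,
) -> float:
    """Volume of the side's condyle above the C-plane (mm^3).

    The clip can contain both condyles as separate components; the connected
    component nearest the side's condylion landmark is taken.
    """
    tm = mesh.mesh
    if not tm.is_watertight:
        raise ValueError("condylar volume requires a watertight mesh")
    clipped = _clip_open(tm, plane)
    if clipped.is_empty or len(clipped.faces) == 0:
        raise ValueError("empty clip: plane does not intersect the condylar region")
    parts = clipped.split(only_watertight=False)
    if len(parts) == 0:
        parts = [clipped]
    condylion = mesh.landmarks.get(f"condylion_{side}")
    if condylion is None:
        raise KeyError(f"missing landmark condylion_{side}")
    dists = [np.min(np.linalg.norm(p.vertices - condylion, axis=1)) for p in parts]
    part = parts[int(np.argmin(dists))]
    return _signed_volume_about(part.triangles, plane.point)


def ramal_height(landmarks: dict[str, np.ndarray], side: str) -> float:
    """Condylion-to-gonion Euclidean distance (mm)."""
    try:
        c = np.asarray(landmarks[f"condylion_{side}"], dtype=float)
        g = np.asarray(landmarks[f"gonion_{side}"], dtype=float)
    except KeyError as exc:
        raise KeyError(f"missing landmark for ramal height: {exc}") from exc
    return float(np.linalg.norm(c - g))


def condylar_change(
    t0: SurfaceMesh,
    t2: SurfaceMesh,
    side: str,
) -> CondyleMetrics:
    """Condylar volume and ramal height change between T0 and T2.

    The T2 model is registered onto T0 by the side's modified-ramus VOI
    (correspondence mode; the two models share topology), the T0 C-plane is
    applied to both, and volumes plus ramal heights are returned.
    """
    voi = f"ramus_{side}"
    reg = register_rigid(t2.mask_points(voi), t0.mask_points(voi), mode="correspondence")
    t2_in_t0 = t2.transformed(reg.transform)

    plane = construct_c_plane(t0, side)
    v0 = condylar_volume(t0, plane, side)
    v2 = condylar_volume(t2_in_t0, plane, side)
    return CondyleMetrics(
        side=side,
        volume_t0=v0,
        volume_t2=v2,
        ramal_height_t0=ramal_height(t0.landmarks, side),
        ramal_height_t2=ramal_height(t2_in_t0.landmarks, side),
    )


def facial_measures(
    landmarks: dict[str, np.ndarray],
    frame: AnatomicalFrame = CANONICAL_FRAME,
) -> FacialMeasures:
    """Anterior lower facial height, A/P ratio and mandibular plane angle.

    The anterior lower facial height runs from the anterior-nasal-spine
    surrogate to menton; the A/P ratio divides it by the mean bilateral
    ramal height; the mandibular plane angle is the dihedral angle between
    the bilateral gonion-menton plane and the frame's axial plane.
    """
    required = ["ans", "menton", "gonion_left", "gonion_right", "condylion_left", "condylion_right"]
    missing = [k for k in required if k not in landmarks]
    if missing:
        raise KeyError(f"missing landmarks: {missing}")
    lm = {k: np.asarray(landmarks[k], dtype=float) for k in required}

    anterior = float(np.linalg.norm(lm["ans"] - lm["menton"]))
    rh_l = ramal_height(landmarks, "left")
    rh_r = ramal_height(landmarks, "right")
    ap_ratio = anterior / ((rh_l + rh_r) / 2.0)

    u = lm["gonion_right"] - lm["gonion_left"]
    v = lm["menton"] - lm["gonion_left"]
    n = np.cross(u, v)
    norm = np.linalg.norm(n)
    if norm == 0:
        raise ValueError("degenerate mandibular plane (collinear landmarks)")
    cosang = np.clip(abs(np.dot(n / norm, frame.si)), -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cosang)))

    return FacialMeasures(
        anterior_lower_facial_height=anterior,
        ramal_height_left=rh_l,
        ramal_height_right=rh_r,
        ap_ratio=float(ap_ratio),
        mandibular_plane_angle=angle,
    )
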