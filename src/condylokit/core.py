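"""Core geometric containers: anatomical frames, rigid transforms, annotated meshes.

All coordinates are millimetres in a patient-based frame whose canonical axes
are ML (+x = patient right), AP (+y = anterior) and SI (+z = superior).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import trimesh

__all__ = [
    "AnatomicalFrame",
    "RigidTransform",
    "SurfaceMesh",
    "CANONICAL_FRAME",
]


@dataclass(frozen=True)
class AnatomicalFrame:
    """Right-handed orthonormal anatomical frame.

    ML points to the patient's right, AP anteriorly, SI superiorly.
    """

    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    ml: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    ap: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    si: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        B = self.basis
        if not np.allclose(B.T @ B, np.eye(3), atol=1e-9):
            raise ValueError("frame axes must be orthonormal")
        if np.linalg.det(B) < 0:
            raise ValueError("frame must be right-handed (det +1)")

    @property
    def basis(self) -> np.ndarray:
        """Columns are the ML, AP, SI axes."""
        return np.column_stack([self.ml, self.ap, self.si]).astype(float)


CANONICAL_FRAME = AnatomicalFrame()


def _project_rotation(R: np.ndarray) -> np.ndarray:
    """Nearest proper rotation by polar (SVD) projection."""
    U, _, Vt = np.linalg.svd(R)
    d = np.sign(np.linalg.det(U @ Vt))
    return U @ np.diag([1.0, 1.0, d]) @ Vt


@dataclass
class RigidTransform:
    """Homogeneous rigid motion ``x -> R x + t`` (mm).

    The rotation is projected to the nearest proper rotation on construction,
    so transforms estimated from noisy data stay in SO(3).
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        self.rotation = _project_rotation(R)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        return cls(m[:3, :3], m[:3, 3])

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Returns self∘other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    # -- serialization (4x4 row-major JSON) --------------------------------
    def to_json(self) -> str:
        return json.dumps({"matrix": self.matrix.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "RigidTransform":
        return cls.from_matrix(np.asarray(json.loads(text)["matrix"]))


class SurfaceMesh:
    """Watertight triangle mesh with named landmarks and vertex masks.

    Landmarks are 3D points (mm); most lie on the surface but some (the
    anterior-nasal-spine surrogate) are free points that travel rigidly with
    the mesh. Masks are boolean arrays over vertices naming anatomical
    regions (condyles, modified rami, osteotomy-free body, segments).
    """

    def __init__(
        self,
        mesh: trimesh.Trimesh,
        landmarks: dict[str, np.ndarray] | None = None,
        masks: dict[str, np.ndarray] | None = None,
        frame: AnatomicalFrame = CANONICAL_FRAME,
    ):
        self.mesh = mesh
        self.landmarks = {k: np.asarray(v, dtype=float) for k, v in (landmarks or {}).items()}
        self.masks = {k: np.asarray(v, dtype=bool) for k, v in (masks or {}).items()}
        self.frame = frame
        for name, m in self.masks.items():
            if m.shape != (len(mesh.vertices),):
                raise ValueError(f"mask {name!r} does not cover the vertex set")

    @property
    def vertices(self) -> np.ndarray:
        return self.mesh.vertices

    @property
    def is_watertight(self) -> bool:
        return bool(self.mesh.is_watertight)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            self.mesh.copy(),
            {k: v.copy() for k, v in self.landmarks.items()},
            {k: v.copy() for k, v in self.masks.items()},
            self.frame,
        )

    def transformed(self, transform: RigidTransform) -> "SurfaceMesh":
        """Rigidly moved copy (landmarks travel with the surface)."""
        out = self.copy()
        out.mesh.vertices = transform.apply(out.mesh.vertices)
        out.landmarks = {k: transform.apply(v) for k, v in out.landmarks.items()}
        return out

    def mask_points(self, name: str) -> np.ndarray:
        if name not in self.masks:
            raise KeyError(f"no vertex mask named {name!r}")
        return np.asarray(self.mesh.vertices[self.masks[name]])

    # -- I/O ---------------------------------------------------------------
    def save(self, mesh_path, landmarks_path=None) -> None:
        self.mesh.export(mesh_path)
        if landmarks_path is not None:
            payload = {
                "landmarks": {k: v.tolist() for k, v in self.landmarks.items()},
                "masks": {k: np.flatnonzero(v).tolist() for k, v in self.masks.items()},
            }
            with open(landmarks_path, "w") as fh:
                json.dump(payload, fh)

    @classmethod
    def load(cls, mesh_path, landmarks_path=None) -> "SurfaceMesh":
        mesh = trimesh.load(mesh_path, process=False, force="mesh")
        landmarks, masks = {}, {}
        if landmarks_path is not None:
            with open(landmarks_path) as fh:
                payload = json.load(fh)
            landmarks = {k: np.asarray(v) for k, v in payload["landmarks"].items()}
            n = len(mesh.vertices)
            for k, idx in payload["masks"].items():
                m = np.zeros(n, dtype=bool)
                m[np.asarray(idx, dtype=int)] = True
                masks[k] = m
        return cls(mesh, landmarks, masks)
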