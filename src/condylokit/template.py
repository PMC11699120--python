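"""Parametric mandible template with landmarks and anatomical vertex masks.

The mandible is modelled as a closed swept tube: a cubic-spline centerline
runs from the top of the left condyle, down the left ramus, around the body
through the menton region, and up to the top of the right condyle. A
varying-radius circular cross-section is swept along rotation-minimizing
frames and the two ends are closed with pole vertices, giving a watertight
genus-0 surface with fixed topology across subjects (dense correspondence
by construction).

Two special rings (one per side) are flattened onto the sigmoid-notch level
so that the C-plane cuts the mesh exactly along a vertex ring. Condylar size
factors are applied as an isotropic scaling of everything above that ring
about a centre point ON the ring plane, which makes the clipped condylar
volume scale exactly with the cube of the factor.

This is a CSG-style stand-in for segmented patient models: only the
measured quantities (volumes, heights, angles, motions) are meant to be
realistic, not the anatomy itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.interpolate import splev, splprep

from .core import SurfaceMesh

__all__ = ["MandibleParams", "MandibleModel", "make_template_mandible"]

SIDES = ("left", "right")


@dataclass(frozen=True)
class MandibleParams:
    """Per-subject shape parameters (mm / degrees / unitless factors)."""

    intercondylar_width: float = 94.0
    ramal_height: float = 49.0
    plane_angle: float = 39.4
    anterior_height: float = 60.0
    condyle_scale_left: float = 1.0
    condyle_scale_right: float = 1.0
    global_scale: float = 1.0


class MandibleModel(SurfaceMesh):
    """Template mandible: a :class:`SurfaceMesh` plus sweep-structure info.

    ``ring_of`` maps each vertex to its sweep ring index (-1 and -2 for the
    start/end pole vertices); ``ring_index`` names the anatomically special
    rings (sigmoid notches, osteotomy cuts, body VOI bounds).
    """

    def __init__(self, mesh, landmarks, masks, ring_of, n_u, n_v, ring_index, notch_centers):
        super().__init__(mesh, landmarks, masks)
        self.ring_of = ring_of
        self.n_u = n_u
        self.n_v = n_v
        self.ring_index = ring_index
        self.notch_centers = {k: np.asarray(v, dtype=float) for k, v in notch_centers.items()}

    def copy(self) -> "MandibleModel":
        return MandibleModel(
            self.mesh.copy(),
            {k: v.copy() for k, v in self.landmarks.items()},
            {k: v.copy() for k, v in self.masks.items()},
            self.ring_of.copy(),
            self.n_u,
            self.n_v,
            dict(self.ring_index),
            {k: v.copy() for k, v in self.notch_centers.items()},
        )

    def extract_segment(self, name: str):
        """Capped watertight submesh of a segment plus its original vertex ids.

        ``name`` is one of ``distal``, ``proximal_left``, ``proximal_right``.
        The submesh is cut at osteotomy rings and closed with centroid fans.
        """
        if name == "distal":
            rings = range(self.ring_index["osteotomy_left"] + 1, self.ring_index["osteotomy_right"])
            poles = []
        elif name == "proximal_left":
            rings = range(0, self.ring_index["osteotomy_left"] + 1)
            poles = [-1]
        elif name == "proximal_right":
            rings = range(self.ring_index["osteotomy_right"], self.n_u)
            poles = [-2]
        else:
            raise ValueError(f"unknown segment {name!r}")

        rings = list(rings)
        keep = np.isin(self.ring_of, rings) | np.isin(self.ring_of, poles)
        orig_idx = np.flatnonzero(keep)
        remap = -np.ones(len(self.vertices), dtype=int)
        remap[orig_idx] = np.arange(len(orig_idx))

        fmask = keep[self.mesh.faces].all(axis=1)
        faces = remap[self.mesh.faces[fmask]]
        verts = self.vertices[orig_idx].copy()

        # close open ring boundaries with centroid fans
        n_v = self.n_v
        extra_verts, extra_faces = [], []
        open_rings = []
        if -1 not in poles and rings:
            open_rings.append((rings[0], True))
        if -2 not in poles and rings:
            open_rings.append((rings[-1], False))
        for ring, at_start in open_rings:
            ring_orig = ring * n_v + np.arange(n_v)
            ring_new = remap[ring_orig]
            centroid = self.vertices[ring_orig].mean(axis=0)
            c_idx = len(verts) + len(extra_verts)
            extra_verts.append(centroid)
            for j in range(n_v):
                a, b = ring_new[j], ring_new[(j + 1) % n_v]
                # winding chosen so the cap faces outward at either end
                tri = [c_idx, a, b] if at_start else [c_idx, b, a]
                extra_faces.append(tri)
        if extra_verts:
            verts = np.vstack([verts, np.asarray(extra_verts)])
            faces = np.vstack([faces, np.asarray(extra_faces, dtype=int)])

        sub = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        if sub.volume < 0:
            sub.invert()
        if not sub.is_watertight:
            raise RuntimeError(f"segment {name!r} extraction produced a non-watertight mesh")
        lm = {
            k: v.copy()
            for k, v in self.landmarks.items()
            if LANDMARK_SEGMENT.get(k) == name
        }
        return SurfaceMesh(sub, lm), orig_idx


#: which rigid segment each landmark travels with during surgery/relapse
LANDMARK_SEGMENT = {
    "condylion_left": "proximal_left",
    "condylion_right": "proximal_right",
    "gonion_left": "proximal_left",
    "gonion_right": "proximal_right",
    "sigmoid_notch_left": "proximal_left",
    "sigmoid_notch_right": "proximal_right",
    "menton": "distal",
    "ans": "cranial",
}


def _control_points(p: MandibleParams):
    """Left-branch centerline controls (top of condyle -> menton), mirrored."""
    x0 = -p.intercondylar_width / 2.0
    # condylion-to-gonion target ~= ramal_height; solved approximately
    zc = max(20.0, np.sqrt(max(p.ramal_height**2 - 80.0, 400.0)) - 9.5)
    z_me = -np.tan(np.radians(p.plane_angle)) * 72.0 + 2.0
    left = np.array(
        [
            [x0, -38.0, zc + 2.0],        # condyle top (tube end)
            [x0, -38.0, zc - 5.0],        # condyle centre
            [x0 + 1.5, -36.0, zc - 11.0], # sigmoid-notch level (neck)
            [x0 + 3.0, -33.0, (zc - 11.0) / 2.0],
            [x0 + 4.0, -30.0, 0.0],       # gonial corner
            [x0 + 10.0, -8.0, 0.25 * z_me],
            [x0 + 22.0, 16.0, 0.60 * z_me],
            [x0 + 34.0, 34.0, 0.88 * z_me],
        ]
    )
    menton = np.array([[0.0, 42.0, z_me]])
    right = left[::-1].copy()
    right[:, 0] *= -1.0
    pts = np.vstack([left, menton, right])
    radii_left = [2.5, 7.5, 4.5, 6.5, 7.5, 8.0, 8.0, 8.0]
    radii = np.array(radii_left + [8.5] + radii_left[::-1])
    # names of special controls, by index into pts
    named = {
        "notch_left": 2,
        "corner_left": 4,
        "body_left": 6,
        "body_right": len(pts) - 7,
        "corner_right": len(pts) - 5,
        "notch_right": len(pts) - 3,
    }
    return pts, radii, named


def _rotation_minimizing_frames(tangents: np.ndarray):
    """Propagate a normal along the curve with minimal twist."""
    n = np.cross(tangents[0], [0.0, 0.0, 1.0])
    if np.linalg.norm(n) < 1e-6:
        n = np.cross(tangents[0], [0.0, 1.0, 0.0])
    n /= np.linalg.norm(n)
    normals = [n]
    for t in tangents[1:]:
        n = normals[-1] - np.dot(normals[-1], t) * t
        n /= np.linalg.norm(n)
        normals.append(n)
    normals = np.asarray(normals)
    binormals = np.cross(tangents, normals)
    return normals, binormals


def _grid_counts(resolution: int):
    n_v = max(12, int(round(np.sqrt(resolution / 5.2))))
    n_u = max(40, int(round(resolution / n_v)))
    return n_u, n_v


def make_template_mandible(
    resolution: int = 2000,
    params: MandibleParams = MandibleParams(),
) -> MandibleModel:
    """Build a watertight template mandible with landmarks and masks.

    ``resolution`` is the target vertex count (>= 500). The returned model
    carries landmarks (condylia, gonia, sigmoid-notch nadirs, menton, an
    anterior-nasal-spine surrogate) and vertex masks for both condyles,
    both modified rami, the osteotomy-free body VOI and the three surgical
    segments.
    """
    if resolution < 500:
        raise ValueError("mesh resolution must be at least 500 vertices")

    ctrl, radii_ctrl, named = _control_points(params)
    tck, u_ctrl = splprep(ctrl.T, s=0.0, k=3)
    n_u, n_v = _grid_counts(resolution)
    u = np.linspace(0.0, 1.0, n_u)
    center = np.asarray(splev(u, tck)).T
    deriv = np.asarray(splev(u, tck, der=1)).T
    tangents = deriv / np.linalg.norm(deriv, axis=1, keepdims=True)
    normals, binormals = _rotation_minimizing_frames(tangents)
    radii = np.interp(u, u_ctrl, radii_ctrl)

    theta = np.linspace(0.0, 2.0 * np.pi, n_v, endpoint=False)
    ring_dirs = np.cos(theta)[:, None, None] * normals[None] + np.sin(theta)[:, None, None] * binormals[None]
    # vertices laid out ring-major: index = ring * n_v + j
    verts = (center[None] + radii[None, :, None] * ring_dirs).transpose(1, 0, 2).reshape(-1, 3)

    # special rings: nearest samples to the named control parameters
    ring_index = {}
    for side in SIDES:
        ring_index[f"notch_{side}"] = int(np.argmin(np.abs(u - u_ctrl[named[f"notch_{side}"]])))
        ring_index[f"osteotomy_{side}"] = int(np.argmin(np.abs(u - (u_ctrl[named[f"corner_{side}"]] + (0.03 if side == "left" else -0.03)))))
    ring_index["osteotomy_left"] = max(ring_index["osteotomy_left"], ring_index["notch_left"] + 3)
    ring_index["osteotomy_right"] = min(ring_index["osteotomy_right"], ring_index["notch_right"] - 3)

    # flatten the notch rings onto their C-plane level
    notch_centers = {}
    for side in SIDES:
        ridx = ring_index[f"notch_{side}"]
        z_notch = center[ridx, 2]
        sel = slice(ridx * n_v, (ridx + 1) * n_v)
        verts[sel, 2] = z_notch
        notch_centers[side] = np.array([center[ridx, 0], center[ridx, 1], z_notch])

    # pole vertices closing the condylar ends
    pole_start = center[0] - tangents[0] * radii[0] * 0.9
    pole_end = center[-1] + tangents[-1] * radii[-1] * 0.9
    verts = np.vstack([verts, pole_start, pole_end])
    i_pole_start = n_u * n_v
    i_pole_end = n_u * n_v + 1

    faces = []
    for i in range(n_u - 1):
        for j in range(n_v):
            a = i * n_v + j
            b = i * n_v + (j + 1) % n_v
            c = (i + 1) * n_v + (j + 1) % n_v
            d = (i + 1) * n_v + j
            faces.append([a, b, c])
            faces.append([a, c, d])
    for j in range(n_v):
        a = j
        b = (j + 1) % n_v
        faces.append([i_pole_start, b, a])
        a = (n_u - 1) * n_v + j
        b = (n_u - 1) * n_v + (j + 1) % n_v
        faces.append([i_pole_end, a, b])
    faces = np.asarray(faces, dtype=int)

    ring_of = np.concatenate([np.repeat(np.arange(n_u), n_v), [-1, -2]])

    # condylar size factors: isotropic scaling above the notch ring about a
    # centre on the ring plane (exactly cubic in clipped volume)
    for side, s in (("left", params.condyle_scale_left), ("right", params.condyle_scale_right)):
        if s == 1.0:
            continue
        ridx = ring_index[f"notch_{side}"]
        cond = (ring_of <= ridx) if side == "left" else (ring_of >= ridx)
        cond &= ring_of >= 0
        if side == "left":
            cond[i_pole_start] = True
        else:
            cond[i_pole_end] = True
        c = notch_centers[side]
        verts[cond] = c + s * (verts[cond] - c)

    if params.global_scale != 1.0:
        verts = verts * params.global_scale
        notch_centers = {k: v * params.global_scale for k, v in notch_centers.items()}

    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    if not mesh.is_watertight:
        raise RuntimeError("template construction produced a non-watertight mesh")
    if mesh.euler_number != 2:
        raise RuntimeError("template is not a closed genus-0 surface")

    # ---- landmarks -------------------------------------------------------
    gs = params.global_scale

    def ring_vertices(ridx):
        return mesh.vertices[ridx * n_v: (ridx + 1) * n_v]

    landmarks = {
        "condylion_left": mesh.vertices[i_pole_start].copy(),
        "condylion_right": mesh.vertices[i_pole_end].copy(),
        "sigmoid_notch_left": notch_centers["left"].copy(),
        "sigmoid_notch_right": notch_centers["right"].copy(),
    }
    for side in SIDES:
        ridx = ring_index[f"osteotomy_{side}"] - (2 if side == "left" else -2)
        rv = ring_vertices(max(ridx, 0))
        landmarks[f"gonion_{side}"] = rv[np.argmin(rv[:, 2])].copy()
    mid_ring = n_u // 2
    rv = ring_vertices(mid_ring)
    landmarks["menton"] = rv[np.argmax(rv[:, 1] - rv[:, 2])].copy()
    up_fwd = np.array([0.0, 0.1, 1.0])
    up_fwd /= np.linalg.norm(up_fwd)
    landmarks["ans"] = landmarks["menton"] + params.anterior_height * gs * up_fwd

    # ---- masks -----------------------------------------------------------
    masks = {}
    nl, nr = ring_index["notch_left"], ring_index["notch_right"]
    ol, or_ = ring_index["osteotomy_left"], ring_index["osteotomy_right"]
    cond_l = (ring_of >= 0) & (ring_of <= nl)
    cond_l[i_pole_start] = True
    cond_r = (ring_of >= nr) & (ring_of >= 0)
    cond_r[i_pole_end] = True
    masks["condyle_left"] = cond_l
    masks["condyle_right"] = cond_r
    masks["ramus_left"] = (ring_of > nl) & (ring_of <= ol)
    masks["ramus_right"] = (ring_of >= or_) & (ring_of < nr)
    prox_l = (ring_of >= 0) & (ring_of <= ol)
    prox_l[i_pole_start] = True
    prox_r = (ring_of >= or_) & (ring_of >= 0)
    prox_r[i_pole_end] = True
    masks["proximal_left"] = prox_l
    masks["proximal_right"] = prox_r
    masks["distal"] = ~(prox_l | prox_r)
    margin = max(2, int(0.15 * (or_ - ol)))
    masks["body"] = (ring_of > ol + margin) & (ring_of < or_ - margin)

    return MandibleModel(mesh, landmarks, masks, ring_of, n_u, n_v, ring_index, notch_centers)
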