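"""Rigid registration of mandibular segments and anatomical 6-DOF decomposition.

A segment's motion between timepoints is recovered by rigid registration of a
volume of interest (VOI) and expressed as three translations (mediolateral,
anteroposterior, superoinferior, mm) and three rotations (pitch, roll, yaw,
degrees). Signs follow the clinical view convention: positive translations
are to the patient's right, anterior and upward; positive rotations are
clockwise as seen from the right lateral (pitch), frontal (roll) and bottom
(yaw) views. For the right proximal segment the mediolateral translation,
roll and yaw can be mirrored so both sides are reported from a left-side
perspective.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .core import CANONICAL_FRAME, AnatomicalFrame, RigidTransform

__all__ = [
    "SixDOF",
    "RegistrationResult",
    "register_rigid",
    "relative_motion",
    "decompose_six_dof",
    "compose_six_dof",
]

#: sides whose lateral quantities are mirrored to the left-side perspective
MIRRORED_SIDES = frozenset({"proximal_right"})

#: Euler extraction order: yaw about SI, then roll about AP, then pitch about ML
EULER_ORDER = "XYZ"  # intrinsic; R = Rx(pitch') Ry(roll') Rz(yaw') in frame axes


@dataclass(frozen=True)
class SixDOF:
    """Anatomically signed six degrees of freedom of a rigid segment motion."""

    t_ml: float = 0.0
    t_ap: float = 0.0
    t_si: float = 0.0
    pitch: float = 0.0
    roll: float = 0.0
    yaw: float = 0.0
    side: str = "distal"
    mirrored: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.t_ml, self.t_ap, self.t_si, self.pitch, self.roll, self.yaw])


@dataclass(frozen=True)
class RegistrationResult:
    transform: RigidTransform
    rms: float
    iterations: int = 0
    converged: bool = True


def _kabsch(moving: np.ndarray, fixed: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping ``moving`` onto ``fixed`` (SVD)."""
    cm = moving.mean(axis=0)
    cf = fixed.mean(axis=0)
    P = moving - cm
    Q = fixed - cf
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, cf - R @ cm)


def _check_nondegenerate(points: np.ndarray) -> None:
    if len(points) < 3:
        raise ValueError("need at least 3 points for rigid registration")
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) point set")


def register_rigid(
    moving: np.ndarray,
    fixed: np.ndarray,
    mode: str = "correspondence",
    max_iterations: int = 200,
    tol: float = 1e-6,
) -> RegistrationResult:
    """Estimate the rigid transform mapping ``moving`` onto ``fixed``.

    ``correspondence`` mode assumes row-wise point correspondence and returns
    the closed-form Kabsch optimum. ``icp`` mode alternates nearest-neighbour
    matching and Kabsch until the mean residual changes by less than ``tol``
    mm or ``max_iterations`` is reached.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    _check_nondegenerate(moving)
    _check_nondegenerate(fixed)

    if mode == "correspondence":
        if moving.shape != fixed.shape:
            raise ValueError("correspondence mode needs matching point counts")
        t = _kabsch(moving, fixed)
        rms = float(np.sqrt(np.mean(np.sum((t.apply(moving) - fixed) ** 2, axis=1))))
        return RegistrationResult(t, rms)

    if mode != "icp":
        raise ValueError(f"unknown registration mode {mode!r}")

    tree = cKDTree(fixed)
    current = RigidTransform.identity()
    points = moving
    prev_mean = np.inf
    for iteration in range(1, max_iterations + 1):
        dists, idx = tree.query(points)
        step = _kabsch(points, fixed[idx])
        current = step.compose(current)
        points = step.apply(points)
        mean_resid = float(np.mean(dists))
        if abs(prev_mean - mean_resid) < tol:
            rms = float(np.sqrt(np.mean(dists**2)))
            return RegistrationResult(current, rms, iteration, True)
        prev_mean = mean_resid
    dists, _ = tree.query(points)
    rms = float(np.sqrt(np.mean(dists**2)))
    return RegistrationResult(current, rms, max_iterations, False)


def relative_motion(tA: RigidTransform, tB: RigidTransform) -> RigidTransform:
    """Motion of a segment between two timepoints in the common frame.

    Given cranial-base-aligned poses ``tA`` (earlier) and ``tB`` (later), the
    segment's motion is ``tB ∘ tA⁻¹``.
    """
    return tB.compose(tA.inverse())


def _mirror(d: SixDOF) -> SixDOF:
    return replace(d, t_ml=-d.t_ml, roll=-d.roll, yaw=-d.yaw, mirrored=not d.mirrored)


def decompose_six_dof(
    transform: RigidTransform,
    frame: AnatomicalFrame = CANONICAL_FRAME,
    side: str = "distal",
    mirror: bool = True,
) -> SixDOF:
    """Decompose a rigid transform into anatomically signed six DOF.

    Translations are the displacement of the frame origin projected on the
    ML/AP/SI axes. Rotations are Euler angles extracted in the fixed order
    yaw (SI) -> roll (AP) -> pitch (ML) and sign-flipped so positive means
    clockwise in the right-lateral / frontal / bottom view. Right proximal
    segments are mirrored to the left-side perspective when ``mirror`` is on.
    """
    B = frame.basis
    R_local = B.T @ transform.rotation @ B
    # R_local = Rx(a) Ry(b) Rz(c) (intrinsic XYZ); view convention negates.
    a, b, c = Rotation.from_matrix(R_local).as_euler(EULER_ORDER, degrees=True)
    if min(90.0 - abs(a), 90.0 - abs(b), 90.0 - abs(c)) < 1e-6:
        raise ValueError("rotation outside the non-degenerate Euler range (|angle| < 90 deg)")
    disp = transform.apply(frame.origin) - frame.origin
    t_ml, t_ap, t_si = B.T @ disp
    d = SixDOF(
        t_ml=float(t_ml),
        t_ap=float(t_ap),
        t_si=float(t_si),
        pitch=float(-a),
        roll=float(-b),
        yaw=float(-c),
        side=side,
        mirrored=False,
    )
    if mirror and side in MIRRORED_SIDES:
        d = _mirror(d)
    return d


def compose_six_dof(
    d: SixDOF,
    frame: AnatomicalFrame = CANONICAL_FRAME,
) -> RigidTransform:
    """Exact inverse of :func:`decompose_six_dof` on the non-degenerate range."""
    if d.mirrored:
        d = _mirror(d)
    B = frame.basis
    R_local = Rotation.from_euler(EULER_ORDER, [-d.pitch, -d.roll, -d.yaw], degrees=True).as_matrix()
    R = B @ R_local @ B.T
    disp = B @ np.array([d.t_ml, d.t_ap, d.t_si])
    t = disp + frame.origin - R @ frame.origin
    return RigidTransform(R, t)
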