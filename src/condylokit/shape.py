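"""Statistical shape analysis of preoperative mandibles.

Dense homologous configurations (shared template topology) are aligned by
generalized Procrustes analysis — centring, scaling to unit centroid size
and iterative rotation to the evolving mean — which removes position,
orientation and size so only shape remains. A one-component partial
least-squares regression of the aligned, vectorized shapes onto binary
resorption status gives the test statistic (the covariance between shape
scores and status, equal to the norm of the centred cross-covariance
``X_c' y_c``); its significance comes from label permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh

__all__ = [
    "ShapeTestResult",
    "gpa_align",
    "pls_shape_test",
    "difference_colormap",
    "save_colormap",
    "load_colormap",
    "match_controls",
    "extract_region",
]


@dataclass
class ShapeTestResult:
    p_value: float
    statistic: float
    effect_vector: np.ndarray  # (k, 3) per-point group difference along the PLS axis
    n_permutations: int


def _centroid_size(config: np.ndarray) -> float:
    centered = config - config.mean(axis=0)
    return float(np.sqrt((centered**2).sum()))


def _optimal_rotation(config: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation (no scaling/reflection correction beyond det +1) minimizing
    ||config R - target||."""
    H = config.T @ target
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    return U @ np.diag([1.0, 1.0, d]) @ Vt


def gpa_align(configs: np.ndarray, tol: float = 1e-8, max_iterations: int = 100):
    """Generalized Procrustes alignment of (n, k, 3) configurations.

    Returns the aligned configurations (unit centroid size, centred at the
    origin) and the mean shape. Raises on degenerate (collinear) input.
    """
    X = np.asarray(configs, dtype=float)
    if X.ndim != 3 or X.shape[2] != 3:
        raise ValueError("configs must have shape (n, k, 3)")
    if X.shape[0] < 2 or X.shape[1] < 3:
        raise ValueError("need at least 2 subjects and 3 points")

    aligned = X - X.mean(axis=1, keepdims=True)
    sizes = np.sqrt((aligned**2).sum(axis=(1, 2)))
    if np.any(sizes < 1e-12):
        raise ValueError("degenerate configuration with zero centroid size")
    aligned = aligned / sizes[:, None, None]
    for a in aligned:
        if np.linalg.svd(a, compute_uv=False)[1] < 1e-12:
            raise ValueError("degenerate (collinear) configuration")

    # initialize from the raw average when it is non-degenerate (makes
    # alignment of already-aligned data a fixed point); otherwise from the
    # first configuration
    mean = aligned.mean(axis=0)
    if _centroid_size(mean) < 0.1:
        mean = aligned[0].copy()
    mean = mean - mean.mean(axis=0)
    mean = mean / _centroid_size(mean)
    for _ in range(max_iterations):
        for i in range(len(aligned)):
            aligned[i] = aligned[i] @ _optimal_rotation(aligned[i], mean)
        new_mean = aligned.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        new_mean /= _centroid_size(new_mean)
        converged = np.linalg.norm(new_mean - mean) < tol
        mean = new_mean
        if converged:
            break
    # final sync so every configuration is optimally rotated to the
    # converged mean (idempotence of re-alignment)
    for i in range(len(aligned)):
        aligned[i] = aligned[i] @ _optimal_rotation(aligned[i], mean)
    return aligned, mean


def pls_shape_test(
    aligned: np.ndarray,
    labels,
    n_permutations: int = 1000,
    seed: int = 0,
) -> ShapeTestResult:
    """Permutation test of shape difference between two groups.

    The observed statistic is the norm of the centred cross-covariance
    between vectorized shapes and the binary label (the covariance of the
    one-component PLS shape scores with the label, up to a constant). The
    p-value is ``(1 + #{permuted >= observed}) / (1 + n_permutations)``.
    """
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations")
    X = np.asarray(aligned, dtype=float)
    n, k = X.shape[0], X.shape[1]
    Xf = X.reshape(n, k * 3)
    y = np.asarray(labels).astype(float)
    if len(np.unique(y)) != 2:
        raise ValueError("labels must be binary")
    for cls in np.unique(y):
        if (y == cls).sum() < 2:
            raise ValueError("both groups need at least 2 subjects")

    Xc = Xf - Xf.mean(axis=0)

    def statistic(yv):
        yc = yv - yv.mean()
        return float(np.linalg.norm(Xc.T @ yc) / n)

    observed = statistic(y)
    rng = np.random.default_rng(seed % (2**31))
    exceed = 0
    for _ in range(n_permutations):
        if statistic(rng.permutation(y)) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)

    # group mean difference projected on the PLS axis
    w = Xc.T @ (y - y.mean())
    norm = np.linalg.norm(w)
    hi, lo = np.unique(y)[::-1]
    delta = Xf[y == hi].mean(axis=0) - Xf[y == lo].mean(axis=0)
    if norm > 0:
        w_hat = w / norm
        effect = (delta @ w_hat) * w_hat
    else:
        effect = np.zeros_like(delta)
    return ShapeTestResult(
        p_value=float(p),
        statistic=observed,
        effect_vector=effect.reshape(k, 3),
        n_permutations=n_permutations,
    )


def difference_colormap(
    mean_control: np.ndarray,
    mean_resorption: np.ndarray,
    faces: np.ndarray,
) -> tuple[np.ndarray, trimesh.Trimesh]:
    """Per-vertex signed normal displacement (control -> resorption).

    Positive values mean the resorption mean lies outside the control
    surface along its vertex normal. The scalar field is attached to the
    control-mean mesh as a ``quality`` vertex attribute.
    """
    ctrl = np.asarray(mean_control, dtype=float)
    res = np.asarray(mean_resorption, dtype=float)
    if ctrl.shape != res.shape:
        raise ValueError("mean shapes must share topology")
    mesh = trimesh.Trimesh(vertices=ctrl, faces=np.asarray(faces, dtype=int), process=False)
    normals = mesh.vertex_normals
    field = np.einsum("ij,ij->i", res - ctrl, normals)
    mesh.vertex_attributes["quality"] = field
    return field, mesh


def save_colormap(mesh: trimesh.Trimesh, path) -> None:
    """Write the colormap mesh as binary PLY with a per-vertex quality scalar."""
    data = trimesh.exchange.ply.export_ply(mesh, encoding="binary")
    with open(path, "wb") as fh:
        fh.write(data)


def load_colormap(path) -> tuple[trimesh.Trimesh, np.ndarray]:
    """Read a colormap PLY; returns the mesh and the quality scalar field."""
    mesh = trimesh.load(path, process=False, force="mesh")
    raw = mesh.metadata.get("_ply_raw", {}).get("vertex", {}).get("data", {})
    names = raw.dtype.names if isinstance(raw, np.ndarray) else raw.keys()
    if names is None or "quality" not in names:
        raise ValueError("PLY file has no per-vertex quality scalar")
    return mesh, np.asarray(raw["quality"], dtype=float).ravel()


def match_controls(records: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Greedy nearest-age same-sex matching of controls to resorption cases.

    One control per case; ties broken by the seeded shuffle order. Expects
    columns ``patient_id``, ``age``, ``sex`` and ``resorbed_any``.
    """
    rng = np.random.default_rng(seed % (2**31))
    cases = records[records["resorbed_any"].astype(bool)]
    controls = records[~records["resorbed_any"].astype(bool)].copy()
    rows = []
    order = cases.iloc[rng.permutation(len(cases))]
    for _, case in order.iterrows():
        pool = controls[controls["sex"] == case["sex"]]
        if pool.empty:
            pool = controls
        if pool.empty:
            break
        best = (pool["age"] - case["age"]).abs().idxmin()
        rows.append({"case_id": int(case["patient_id"]), "control_id": int(controls.loc[best, "patient_id"])})
        controls = controls.drop(index=best)
    return pd.DataFrame(rows)


def extract_region(model, region: str) -> np.ndarray:
    """Vertex configuration of a named region of a template-topology model.

    ``region`` is ``full_mandible`` or one of the mask names
    (``condyle_left``, ``ramus_right``, ...).
    """
    if region == "full_mandible":
        return np.asarray(model.vertices)
    if region not in model.masks:
        raise KeyError(f"unknown region {region!r}")
    return model.mask_points(region)
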