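"""Synthetic orthognathic-surgery cohort generator.

Emulates the statistical structure the downstream analysis assumes: a
cohort of patients with demographic and surgical covariates, homologous
mandible meshes at three timepoints (T0 pre-op, T1 one week post-op, T2 one
year post-op), ground-truth rigid segment motions, and condylar
remodeling/resorption between T1 and T2 at a configurable prevalence driven
by a logistic model on the covariates.

Covariate distributions default to the demographics of a 200-patient
orthognathic cohort (age median ~19 with strong right skew, 42% male, 80%
class II, mean advancement 4 mm, mean preoperative condylar volume
~1710 mm^3, ...). Resorbed condyles receive injected volume loss, ramal
height loss and posterior displacement drawn from the resorption-group
distributions (means -230 mm^3, -3.9 mm, +3.1 mm); unaffected condyles
receive zero-mean physiological remodeling noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from math import log

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .core import RigidTransform, SurfaceMesh
from .kinematics import SixDOF, compose_six_dof
from .morphometry import condylar_volume, construct_c_plane
from .template import (
    LANDMARK_SEGMENT,
    MandibleModel,
    MandibleParams,
    make_template_mandible,
)

__all__ = [
    "CohortConfig",
    "SurgicalPlan",
    "CondyleTruth",
    "Cohort",
    "make_subject_mandible",
    "apply_surgery",
    "apply_remodeling",
    "generate_cohort",
]

SIDES = ("left", "right")

#: generative per-unit log odds ratios on the patient-level predictors
DEFAULT_EFFECTS = {
    "trans_ap": log(1.41),  # per mm of mandibular advancement
    "age": log(0.92),       # per year
    "trans_si": log(1.24),  # per mm upward movement
    "pitch": log(0.82),     # per degree (CCW pitch negative -> protective sign)
}

#: Table-1-style covariate distribution parameters (means/sds/category probs)
DEFAULT_COVARIATES = {
    "age": {"offset": 14.0, "mean": 10.5, "sd": 11.4},  # shifted gamma, right-skewed
    "sex_male_p": 0.42,
    "class_II_p": 0.80,
    "bmi": {"mean": 22.1, "sd": 3.8, "lo": 15.0, "hi": 40.0},
    "mouth_opening": {"mean": 47.0, "sd": 6.5, "lo": 25.0, "hi": 70.0},
    "tmj_pain_p": {"none": 0.83, "bilateral": 0.05, "left": 0.075, "right": 0.045},
    "tmj_sounds_p": {"none": 0.61, "bilateral": 0.125, "left": 0.155, "right": 0.11},
    "procedure_p": {"BSSO": 0.46, "BIMAX": 0.27, "BIMAX_genioplasty": 0.135, "BSSO_genioplasty": 0.135},
    "trans_ml": {"mean": -0.3, "sd": 1.9},
    "trans_ap": {"mean": 4.0, "sd": 5.0},
    "trans_si": {"mean": 0.5, "sd": 2.9},
    "pitch": {"mean": -2.2, "sd": 4.2},
    "roll": {"mean": -0.1, "sd": 1.5},
    "yaw": {"mean": -0.4, "sd": 2.1},
    "condylar_volume": {"mean": 1710.0, "sd": 540.0, "lo": 800.0, "hi": 3400.0},
    "plane_angle": {"mean": 39.4, "sd": 7.9, "lo": 20.0, "hi": 60.0},
    "ramal_height": {"mean": 49.0, "sd": 4.0, "lo": 38.0, "hi": 62.0},
    "anterior_height": {"mean": 60.0, "sd": 6.0, "lo": 45.0, "hi": 78.0},
    # proximal (ramus) surgical movements, left-perspective signs
    "ramus_lateral": {"mean": 1.6, "sd": 1.4},
    "ramus_ap": {"mean": 0.6, "sd": 2.3},
    "ramus_si": {"mean": 1.0, "sd": 1.8},
    "ramus_pitch": {"mean": -2.9, "sd": 3.5},
    "ramus_roll": {"mean": -4.7, "sd": 3.0},
    "ramus_yaw": {"mean": -4.2, "sd": 3.7},
}

#: injected change distributions for resorbed condyles (resorption-group)
RESORPTION_INJECTION = {
    "delta_volume": {"mean": -230.2, "sd": 168.0, "lo": -700.0, "hi": -80.0},
    "delta_height": {"mean": -3.9, "sd": 1.7, "lo": -8.0, "hi": -2.3},
    "posterior": {"mean": 3.1, "sd": 0.9, "lo": 2.3, "hi": 6.5},
}

PHYSIOLOGIC_TRANSLATION_BOUND = 15.0  # mm
PHYSIOLOGIC_ROTATION_BOUND = 15.0  # degrees


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 200
    resorption_prevalence: float = 0.095
    effect_log_odds: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    covariate_params: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATES))
    mesh_resolution: int = 2000
    seed: int = 0
    with_meshes: bool = True
    bilateral_given_resorbed: float = 4.0 / 19.0
    remodel_noise_volume_sd: float = 50.0  # mm^3, below the 30 mm^3 margin's reach jointly
    remodel_noise_height_sd: float = 1.0  # mm
    relapse_noise_mean: float = 0.6  # mm posterior drift in unaffected patients
    relapse_noise_sd: float = 1.0
    relapse_pitch_per_mm: float = 0.6  # deg clockwise pitch per mm posterior displacement

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.resorption_prevalence <= 1.0:
            raise ValueError("resorption_prevalence must be in [0, 1]")


@dataclass(frozen=True)
class SurgicalPlan:
    """Planned rigid motions of the three mandibular segments (T0 -> T1)."""

    distal: SixDOF
    proximal_left: SixDOF
    proximal_right: SixDOF

    def __post_init__(self):
        for d in (self.distal, self.proximal_left, self.proximal_right):
            t = max(abs(d.t_ml), abs(d.t_ap), abs(d.t_si))
            r = max(abs(d.pitch), abs(d.roll), abs(d.yaw))
            if t > PHYSIOLOGIC_TRANSLATION_BOUND or r > PHYSIOLOGIC_ROTATION_BOUND:
                raise ValueError(
                    f"plan outside physiologic bounds (|t| <= {PHYSIOLOGIC_TRANSLATION_BOUND} mm,"
                    f" |rot| <= {PHYSIOLOGIC_ROTATION_BOUND} deg): {d}"
                )

    def transform(self, segment: str) -> RigidTransform:
        return compose_six_dof(getattr(self, segment))


@dataclass
class CondyleTruth:
    """Injected T1->T2 change for one condyle."""

    resorbed: bool
    delta_volume: float  # mm^3 (negative = loss)
    delta_height: float  # mm (negative = ramal height loss)


@dataclass
class Cohort:
    config: CohortConfig
    records: pd.DataFrame  # one row per patient: covariates + plan + truth summary
    truth: pd.DataFrame  # per-condyle ground truth
    meshes: dict  # patient_id -> {"t0": MandibleModel, "t1": {segment: SurfaceMesh}, "t2": SurfaceMesh}

    def save_provenance(self, path) -> None:
        payload = {"config": asdict(self.config)}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)

    def save(self, outdir) -> None:
        """Write the cohort to disk: per-patient STL meshes and landmark
        JSON, plus cohort-level covariates, ground truth and provenance."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "covariates.csv", index=False)
        self.truth.to_csv(out / "ground_truth.csv", index=False)
        self.save_provenance(out / "config.json")
        for pid, bundle in self.meshes.items():
            pdir = out / f"patient_{pid:04d}"
            pdir.mkdir(exist_ok=True)
            # PLY keeps indexed vertices (STL is a triangle soup), so the
            # landmark/mask vertex indices in landmarks.json stay valid
            bundle["t0"].save(pdir / "t0.ply", pdir / "landmarks.json")
            for seg in ("distal", "proximal_left", "proximal_right"):
                bundle["t1"][seg].save(pdir / f"t1_{seg}.ply")
            bundle["t2"].save(pdir / "t2.ply")


def _truncnorm(rng, mean, sd, lo=-np.inf, hi=np.inf, size=None):
    draws = rng.normal(mean, sd, size=size)
    return np.clip(draws, lo, hi)


def make_subject_mandible(
    resolution: int,
    condylar_volume_target: dict,
    ramal_height: float,
    plane_angle: float,
    anterior_height: float,
) -> MandibleModel:
    """Subject mandible whose measured condylar volumes hit the targets.

    A unit-scale template is measured once and each side's condylar size
    factor is the cube root of the target/template volume ratio (exact by
    the isotropic-above-plane construction).
    """
    base = make_template_mandible(
        resolution,
        MandibleParams(ramal_height=ramal_height, plane_angle=plane_angle, anterior_height=anterior_height),
    )
    scales = {}
    for side in SIDES:
        v0 = condylar_volume(base, construct_c_plane(base, side), side)
        scales[side] = float((condylar_volume_target[side] / v0) ** (1.0 / 3.0))
    return make_template_mandible(
        resolution,
        MandibleParams(
            ramal_height=ramal_height,
            plane_angle=plane_angle,
            anterior_height=anterior_height,
            condyle_scale_left=scales["left"],
            condyle_scale_right=scales["right"],
        ),
    )


def apply_surgery(t0: MandibleModel, plan: SurgicalPlan) -> dict:
    """Move the three osteotomy segments rigidly; returns capped T1 meshes."""
    out = {}
    for segment in ("distal", "proximal_left", "proximal_right"):
        sub, orig_idx = t0.extract_segment(segment)
        moved = sub.transformed(plan.transform(segment))
        out[segment] = moved
        out[f"{segment}_vertex_ids"] = orig_idx
    return out


def _apply_segment_transforms(t0: MandibleModel, transforms: dict) -> SurfaceMesh:
    """Full-topology mesh with each segment's rigid transform baked in."""
    verts = t0.vertices.copy()
    for segment in ("distal", "proximal_left", "proximal_right"):
        mask = t0.masks[segment]
        verts[mask] = transforms[segment].apply(verts[mask])
    landmarks = {}
    for name, p in t0.landmarks.items():
        seg = LANDMARK_SEGMENT.get(name, "cranial")
        landmarks[name] = transforms[seg].apply(p) if seg in transforms else p.copy()
    mesh = t0.mesh.copy()
    mesh.vertices = verts
    return SurfaceMesh(mesh, landmarks, {k: v.copy() for k, v in t0.masks.items()})


def _erode_condyle_local(t0: MandibleModel, side: str, truth: CondyleTruth) -> np.ndarray:
    """T0-frame condylar vertices after injected height loss and volume change.

    Height loss translates the condylar region along the condylion->gonion
    line (exactly reducing ramal height by the injected amount); the volume
    change is a cylindrical in-plane erosion/accretion about the condylar
    axis whose factor is solved so the C-plane-clipped volume matches the
    injected change. Raises if the deformed mesh loses watertightness.
    """
    mask = t0.masks[f"condyle_{side}"]
    c = t0.notch_centers[side]
    plane = construct_c_plane(t0, side)
    target = condylar_volume(t0, plane, side) + truth.delta_volume

    verts0 = t0.vertices.copy()
    if truth.delta_height != 0.0:
        condylion = t0.landmarks[f"condylion_{side}"]
        gonion = t0.landmarks[f"gonion_{side}"]
        u = gonion - condylion
        u /= np.linalg.norm(u)
        verts0[mask] = verts0[mask] + (-truth.delta_height) * u

    work = t0.copy()

    def clipped_volume(s: float) -> float:
        v = verts0.copy()
        xy = v[mask][:, :2]
        v[mask, 0] = c[0] + s * (xy[:, 0] - c[0])
        v[mask, 1] = c[1] + s * (xy[:, 1] - c[1])
        work.mesh.vertices = v
        return condylar_volume(work, plane, side)

    if abs(truth.delta_volume) < 1e-9:
        s_star = 1.0
    else:
        lo, hi = 0.2, 2.5
        f = lambda s: clipped_volume(s) - target
        try:
            s_star = brentq(f, lo, hi, xtol=1e-5)
        except ValueError as exc:
            raise RuntimeError(
                f"condylar erosion could not reach injected volume change {truth.delta_volume} mm^3"
            ) from exc
    v = verts0.copy()
    xy = v[mask][:, :2]
    v[mask, 0] = c[0] + s_star * (xy[:, 0] - c[0])
    v[mask, 1] = c[1] + s_star * (xy[:, 1] - c[1])
    work.mesh.vertices = v
    if not work.mesh.is_watertight:
        raise RuntimeError("condylar erosion broke mesh watertightness")
    return v[mask]


def apply_remodeling(
    t0: MandibleModel,
    plan: SurgicalPlan,
    truth_left: CondyleTruth,
    truth_right: CondyleTruth,
    posterior_displacement: float,
    relapse_pitch: float = 0.0,
) -> tuple[SurfaceMesh, SixDOF]:
    """Build the T2 mandible: relapse of the distal segment plus condylar change.

    The distal segment receives a clockwise pitch and posterior translation
    (T1 -> T2 relapse); each condyle receives its injected volume and ramal
    height change. Returns the full-topology T2 model and the ground-truth
    relapse six-DOF.
    """
    relapse = SixDOF(t_ap=-posterior_displacement, pitch=relapse_pitch, side="distal")
    t_relapse = compose_six_dof(relapse)
    transforms = {
        "distal": t_relapse.compose(plan.transform("distal")),
        "proximal_left": plan.transform("proximal_left"),
        "proximal_right": plan.transform("proximal_right"),
    }

    # condylar remodeling is applied in the T0 frame, then carried by the
    # proximal segment's rigid transform
    t0_mod = t0.copy()
    for side, truth in (("left", truth_left), ("right", truth_right)):
        new_local = _erode_condyle_local(t0_mod, side, truth)
        t0_mod.mesh.vertices[t0_mod.masks[f"condyle_{side}"]] = new_local
        # the condylion landmark rides the pole vertex of its condyle
        pole_idx = int(np.flatnonzero(t0_mod.ring_of == (-1 if side == "left" else -2))[0])
        t0_mod.landmarks[f"condylion_{side}"] = t0_mod.mesh.vertices[pole_idx].copy()

    t2 = _apply_segment_transforms(t0_mod, transforms)
    return t2, relapse


def _sample_covariates(rng: np.random.Generator, n: int, cp: dict) -> pd.DataFrame:
    age_p = cp["age"]
    k = (age_p["mean"] / age_p["sd"]) ** 2
    theta = age_p["sd"] ** 2 / age_p["mean"]
    df = pd.DataFrame({"patient_id": np.arange(n)})
    df["age"] = age_p["offset"] + rng.gamma(k, theta, size=n)
    df["sex"] = np.where(rng.random(n) < cp["sex_male_p"], "male", "female")
    df["angle_class"] = np.where(rng.random(n) < cp["class_II_p"], "II", "III")
    df["bmi"] = _truncnorm(rng, cp["bmi"]["mean"], cp["bmi"]["sd"], cp["bmi"]["lo"], cp["bmi"]["hi"], n)
    mo = cp["mouth_opening"]
    df["mouth_opening"] = _truncnorm(rng, mo["mean"], mo["sd"], mo["lo"], mo["hi"], n)
    for var in ("tmj_pain", "tmj_sounds", "procedure"):
        probs = cp[f"{var}_p"]
        levels = list(probs)
        df[var] = rng.choice(levels, size=n, p=np.array([probs[l] for l in levels]) / sum(probs.values()))
    for var in ("trans_ml", "trans_ap", "trans_si", "pitch", "roll", "yaw"):
        p = cp[var]
        df[var] = np.clip(rng.normal(p["mean"], p["sd"], size=n), -14.0, 14.0)
    cv = cp["condylar_volume"]
    for side in SIDES:
        df[f"condylar_volume_{side}"] = _truncnorm(rng, cv["mean"], cv["sd"], cv["lo"], cv["hi"], n)
    pa = cp["plane_angle"]
    df["mandibular_plane_angle"] = _truncnorm(rng, pa["mean"], pa["sd"], pa["lo"], pa["hi"], n)
    rh = cp["ramal_height"]
    df["ramal_height_target"] = _truncnorm(rng, rh["mean"], rh["sd"], rh["lo"], rh["hi"], n)
    ah = cp["anterior_height"]
    df["anterior_height_target"] = _truncnorm(rng, ah["mean"], ah["sd"], ah["lo"], ah["hi"], n)
    df["ap_ratio"] = df["anterior_height_target"] / df["ramal_height_target"]
    for side in SIDES:
        for var in ("ramus_lateral", "ramus_ap", "ramus_si", "ramus_pitch", "ramus_roll", "ramus_yaw"):
            p = cp[var]
            df[f"{var}_{side}"] = np.clip(rng.normal(p["mean"], p["sd"], size=n), -14.0, 14.0)
    return df


def _assign_resorption(rng, df: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Bernoulli resorption labels from a calibrated logistic model."""
    eta = np.zeros(len(df))
    for var, beta in config.effect_log_odds.items():
        eta += beta * df[var].to_numpy(dtype=float)

    if config.resorption_prevalence in (0.0, 1.0):
        p = np.full(len(df), config.resorption_prevalence)
    else:
        def mean_gap(alpha):
            return expit(alpha + eta).mean() - config.resorption_prevalence

        try:
            alpha = brentq(mean_gap, -40.0, 40.0)
        except ValueError as exc:
            raise ValueError("infeasible effect sizes: prevalence not attainable") from exc
        p = expit(alpha + eta)

    resorbed = rng.random(len(df)) < p
    bilateral = resorbed & (rng.random(len(df)) < config.bilateral_given_resorbed)
    left_side = rng.random(len(df)) < 0.5
    out = df.copy()
    out["resorbed_any"] = resorbed
    out["resorbed_left"] = resorbed & (bilateral | left_side)
    out["resorbed_right"] = resorbed & (bilateral | ~left_side)
    out["p_resorption"] = p
    return out


def _draw_injections(config: CohortConfig, df: pd.DataFrame) -> pd.DataFrame:
    """Per-condyle injected T1->T2 changes from per-patient substreams."""
    rows = []
    inj = RESORPTION_INJECTION
    for _, row in df.iterrows():
        sub = np.random.default_rng([config.seed % (2**31), 7919, int(row["patient_id"])])
        rec = {"patient_id": int(row["patient_id"])}
        posterior_opts = []
        for side in SIDES:
            if row[f"resorbed_{side}"]:
                dv = float(_truncnorm(sub, inj["delta_volume"]["mean"], inj["delta_volume"]["sd"],
                                      inj["delta_volume"]["lo"], inj["delta_volume"]["hi"]))
                dv = max(dv, -0.55 * float(row[f"condylar_volume_{side}"]))
                dh = float(_truncnorm(sub, inj["delta_height"]["mean"], inj["delta_height"]["sd"],
                                      inj["delta_height"]["lo"], inj["delta_height"]["hi"]))
                post = float(_truncnorm(sub, inj["posterior"]["mean"], inj["posterior"]["sd"],
                                        inj["posterior"]["lo"], inj["posterior"]["hi"]))
                posterior_opts.append(post)
            else:
                dv = float(sub.normal(0.0, config.remodel_noise_volume_sd))
                dh = float(sub.normal(0.0, config.remodel_noise_height_sd))
            rec[f"delta_volume_{side}"] = dv
            rec[f"delta_height_{side}"] = dh
        if posterior_opts:
            rec["posterior_displacement"] = max(posterior_opts)
        else:
            rec["posterior_displacement"] = float(
                sub.normal(config.relapse_noise_mean, config.relapse_noise_sd)
            )
        rec["relapse_pitch"] = config.relapse_pitch_per_mm * max(rec["posterior_displacement"], 0.0)
        rows.append(rec)
    return pd.DataFrame(rows)


def _make_plan(row: pd.Series) -> SurgicalPlan:
    distal = SixDOF(
        t_ml=row["trans_ml"], t_ap=row["trans_ap"], t_si=row["trans_si"],
        pitch=row["pitch"], roll=row["roll"], yaw=row["yaw"], side="distal",
    )
    prox = {}
    for side in SIDES:
        # lateral (outward) in left perspective corresponds to -ML for the
        # left side; the right side is stored mirrored
        prox[side] = SixDOF(
            t_ml=-row[f"ramus_lateral_{side}"],
            t_ap=row[f"ramus_ap_{side}"],
            t_si=row[f"ramus_si_{side}"],
            pitch=row[f"ramus_pitch_{side}"],
            roll=row[f"ramus_roll_{side}"],
            yaw=row[f"ramus_yaw_{side}"],
            side=f"proximal_{side}",
            mirrored=(side == "right"),
        )
    return SurgicalPlan(distal=distal, proximal_left=prox["left"], proximal_right=prox["right"])


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full synthetic cohort (records, ground truth, meshes).

    Deterministic under the config seed (per-patient substreams). With
    ``with_meshes=False`` only the tabular records and ground truth are
    produced, which is the path used for large parameter-recovery runs.
    """
    rng = np.random.default_rng([config.seed % (2**31), 104729])
    df = _sample_covariates(rng, config.n_patients, config.covariate_params)
    df = _assign_resorption(rng, df, config)
    injections = _draw_injections(config, df)
    records = df.merge(injections, on="patient_id")

    truth_rows = []
    for _, row in records.iterrows():
        for side in SIDES:
            truth_rows.append(
                {
                    "patient_id": int(row["patient_id"]),
                    "side": side,
                    "resorbed": bool(row[f"resorbed_{side}"]),
                    "delta_volume": row[f"delta_volume_{side}"],
                    "delta_height": row[f"delta_height_{side}"],
                    "posterior_displacement": row["posterior_displacement"],
                }
            )
    truth = pd.DataFrame(truth_rows)

    meshes = {}
    if config.with_meshes:
        for _, row in records.iterrows():
            pid = int(row["patient_id"])
            t0 = make_subject_mandible(
                config.mesh_resolution,
                {s: float(row[f"condylar_volume_{s}"]) for s in SIDES},
                float(row["ramal_height_target"]),
                float(row["mandibular_plane_angle"]),
                float(row["anterior_height_target"]),
            )
            plan = _make_plan(row)
            t1 = apply_surgery(t0, plan)
            t2, relapse = apply_remodeling(
                t0,
                plan,
                CondyleTruth(bool(row["resorbed_left"]), row["delta_volume_left"], row["delta_height_left"]),
                CondyleTruth(bool(row["resorbed_right"]), row["delta_volume_right"], row["delta_height_right"]),
                float(row["posterior_displacement"]),
                float(row["relapse_pitch"]),
            )
            meshes[pid] = {"t0": t0, "t1": t1, "t2": t2, "plan": plan}

    return Cohort(config=config, records=records, truth=truth, meshes=meshes)
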