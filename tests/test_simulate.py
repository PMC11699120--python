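"""Synthetic cohort generator: template, surgery, remodeling, cohort."""

import numpy as np
import pandas as pd
import pytest

from condylokit.kinematics import SixDOF, decompose_six_dof, register_rigid
from condylokit.morphometry import condylar_volume, construct_c_plane
from condylokit.resorption import classify_condyle
from condylokit.simulate import (
    CohortConfig,
    CondyleTruth,
    SurgicalPlan,
    apply_remodeling,
    apply_surgery,
    generate_cohort,
)
from condylokit.template import MandibleParams, make_template_mandible


def identity_plan():
    return SurgicalPlan(
        SixDOF(side="distal"),
        SixDOF(side="proximal_left"),
        SixDOF(side="proximal_right", mirrored=True),
    )


class TestTemplate:
    def test_resolution_and_topology(self, template):
        assert abs(len(template.vertices) - 2000) <= 200
        assert template.is_watertight
        assert template.mesh.euler_number == 2  # closed genus-0 surface

    def test_determinism(self, template):
        again = make_template_mandible(2000)
        assert np.array_equal(template.vertices, again.vertices)

    def test_condylar_cube_law(self, template):
        """A condylar size factor of 0.8 scales the clipped condylar volume
        by 0.8^3 = 0.512."""
        scaled = make_template_mandible(2000, MandibleParams(condyle_scale_left=0.8))
        v1 = condylar_volume(template, construct_c_plane(template, "left"), "left")
        v2 = condylar_volume(scaled, construct_c_plane(scaled, "left"), "left")
        assert v2 / v1 == pytest.approx(0.512, rel=0.01)

    def test_minimum_resolution_enforced(self):
        with pytest.raises(ValueError):
            make_template_mandible(400)

    def test_masks_partition_segments(self, template):
        prox_l = template.masks["proximal_left"]
        prox_r = template.masks["proximal_right"]
        distal = template.masks["distal"]
        total = prox_l.astype(int) + prox_r.astype(int) + distal.astype(int)
        assert np.all(total == 1)

    def test_save_load_round_trip(self, template, tmp_path):
        template.save(tmp_path / "m.ply", tmp_path / "lm.json")
        from condylokit.core import SurfaceMesh

        loaded = SurfaceMesh.load(tmp_path / "m.ply", tmp_path / "lm.json")
        assert np.allclose(loaded.vertices, template.vertices, atol=1e-4)
        assert np.allclose(loaded.landmarks["menton"], template.landmarks["menton"])
        assert np.array_equal(loaded.masks["condyle_left"], template.masks["condyle_left"])


class TestSurgery:
    def test_identity_plan_leaves_segments_in_place(self, template):
        t1 = apply_surgery(template, identity_plan())
        for seg in ("distal", "proximal_left", "proximal_right"):
            ids = t1[f"{seg}_vertex_ids"]
            n = len(ids)
            assert np.allclose(t1[seg].vertices[:n], template.vertices[ids], atol=1e-12)

    def test_advancement_moves_distal_centroid(self, template):
        """A 4.9 mm advancement (the cohort median) shifts the distal body
        centroid by +4.9 mm along AP."""
        plan = identity_plan()
        plan = SurgicalPlan(SixDOF(t_ap=4.9, side="distal"), plan.proximal_left, plan.proximal_right)
        t1 = apply_surgery(template, plan)
        ids = t1["distal_vertex_ids"]
        n = len(ids)
        shift = t1["distal"].vertices[:n].mean(axis=0) - template.vertices[ids].mean(axis=0)
        assert np.allclose(shift, [0, 4.9, 0], atol=1e-9)

    def test_plan_recovered_by_registration(self, template, rng):
        """Registration of the moved body VOI recovers the planned distal
        six DOF within 0.05 mm / 0.05 deg."""
        d = SixDOF(*rng.uniform(-5, 5, 3), *rng.uniform(-8, 8, 3), side="distal")
        plan = SurgicalPlan(d, SixDOF(side="proximal_left"), SixDOF(side="proximal_right"))
        t1 = apply_surgery(template, plan)
        ids = t1["distal_vertex_ids"]
        pos = {orig: i for i, orig in enumerate(ids)}
        body_ids = np.flatnonzero(template.masks["body"])
        moved = t1["distal"].vertices[[pos[i] for i in body_ids]]
        est = register_rigid(template.vertices[body_ids], moved).transform
        out = decompose_six_dof(est, side="distal")
        assert np.abs(out.as_array() - d.as_array()).max() < 0.05

    def test_out_of_bounds_plan_rejected(self):
        with pytest.raises(ValueError, match="physiologic"):
            SurgicalPlan(SixDOF(t_ap=16.0), SixDOF(), SixDOF())

    def test_segments_watertight(self, template):
        t1 = apply_surgery(template, identity_plan())
        for seg in ("distal", "proximal_left", "proximal_right"):
            assert t1[seg].is_watertight


class TestRemodeling:
    def test_zero_injection_zero_noise_is_identity(self, template):
        t2, _ = apply_remodeling(
            template, identity_plan(),
            CondyleTruth(False, 0.0, 0.0), CondyleTruth(False, 0.0, 0.0),
            posterior_displacement=0.0,
        )
        assert np.allclose(t2.vertices, template.vertices, atol=1e-12)

    def test_injected_volume_loss_measured(self, template):
        """An injected 230 mm^3 loss is measured as -230 +/- 15 by the
        C-plane volumetry."""
        from condylokit.morphometry import condylar_change

        t2, _ = apply_remodeling(
            template, identity_plan(),
            CondyleTruth(True, -230.0, -3.9), CondyleTruth(False, 0.0, 0.0),
            posterior_displacement=3.1,
        )
        m = condylar_change(template, t2, "left")
        assert m.delta_volume == pytest.approx(-230.0, abs=15.0)
        assert m.delta_ramal_height == pytest.approx(-3.9, abs=0.2)

    def test_resorption_group_injection_classifies_positive(self, template):
        """The (-230 mm^3, -3.9 mm, +3.1 mm) injection triple is called
        resorption by the classification rule."""
        from condylokit.morphometry import condylar_change

        t2, relapse = apply_remodeling(
            template, identity_plan(),
            CondyleTruth(True, -230.0, -3.9), CondyleTruth(False, 0.0, 0.0),
            posterior_displacement=3.1,
        )
        m = condylar_change(template, t2, "left")
        assert classify_condyle(m, relapse)

    def test_unaffected_side_unchanged(self, template):
        t2, _ = apply_remodeling(
            template, identity_plan(),
            CondyleTruth(True, -150.0, -3.0), CondyleTruth(False, 0.0, 0.0),
            posterior_displacement=2.5,
        )
        right = template.masks["condyle_right"]
        assert np.allclose(t2.vertices[right], template.vertices[right], atol=1e-12)


class TestGenerateCohort:
    def test_determinism_same_seed(self):
        cfg = CohortConfig(n_patients=4, seed=11, with_meshes=True)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        pd.testing.assert_frame_equal(a.records, b.records)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        for pid in a.meshes:
            assert np.array_equal(a.meshes[pid]["t0"].vertices, b.meshes[pid]["t0"].vertices)
            assert np.array_equal(a.meshes[pid]["t2"].vertices, b.meshes[pid]["t2"].vertices)

    def test_prevalence_within_binomial_error(self):
        cfg = CohortConfig(n_patients=600, seed=5, with_meshes=False)
        c = generate_cohort(cfg)
        rate = c.records["resorbed_any"].mean()
        se = np.sqrt(0.095 * 0.905 / 600)
        assert abs(rate - 0.095) < 3 * se

    def test_zero_effects_pure_binomial(self):
        cfg = CohortConfig(n_patients=300, seed=2, effect_log_odds={}, with_meshes=False)
        c = generate_cohort(cfg)
        assert np.allclose(c.records["p_resorption"], 0.095)

    def test_advancement_odds_ratio_recovered(self):
        """Refitting logistic regression on the generative labels recovers
        the advancement odds ratio 1.41 within 0.25 at n=2000."""
        import statsmodels.api as sm

        cfg = CohortConfig(n_patients=2000, seed=9, with_meshes=False)
        c = generate_cohort(cfg)
        X = sm.add_constant(c.records[["trans_ap", "age", "trans_si", "pitch"]].to_numpy())
        fit = sm.GLM(c.records["resorbed_any"].astype(int).to_numpy(), X,
                     family=sm.families.Binomial()).fit()
        assert np.exp(fit.params[1]) == pytest.approx(1.41, abs=0.25)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_patients=0)
        with pytest.raises(ValueError):
            CohortConfig(resorption_prevalence=1.5)

    def test_cohort_save_writes_expected_files(self, small_cohort, tmp_path):
        small_cohort.save(tmp_path)
        assert (tmp_path / "covariates.csv").exists()
        assert (tmp_path / "ground_truth.csv").exists()
        assert (tmp_path / "config.json").exists()
        assert (tmp_path / "patient_0000" / "t0.ply").exists()
        assert (tmp_path / "patient_0000" / "t1_distal.ply").exists()
        assert (tmp_path / "patient_0000" / "landmarks.json").exists()
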