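"""Recover surgical six-DOF movements by rigid registration.

A known surgical plan moves the distal segment; registering the moved body
VOI back onto the preoperative model and decomposing the transform returns
the plan. Translations are mm (ML/AP/SI, + = right/anterior/up); rotations
are degrees (+ = clockwise in the right-lateral/frontal/bottom view).
"""

import numpy as np

from condylokit.kinematics import SixDOF, decompose_six_dof, register_rigid
from condylokit.simulate import SurgicalPlan, apply_surgery
from condylokit.template import make_template_mandible

t0 = make_template_mandible(2000)
plan = SurgicalPlan(
    SixDOF(t_ml=-0.3, t_ap=4.9, t_si=0.5, pitch=-2.0, roll=-0.1, yaw=-0.4, side="distal"),
    SixDOF(side="proximal_left"),
    SixDOF(side="proximal_right", mirrored=True),
)
t1 = apply_surgery(t0, plan)

body_ids = np.flatnonzero(t0.masks["body"])
pos = {orig: i for i, orig in enumerate(t1["distal_vertex_ids"])}
moved = t1["distal"].vertices[[pos[i] for i in body_ids]]
est = register_rigid(t0.vertices[body_ids], moved, mode="correspondence")
d = decompose_six_dof(est.transform, side="distal")

print("planned :", np.round(plan.distal.as_array(), 3))
print("measured:", np.round(d.as_array(), 3))
print("residual RMS (mm):", est.rms)
print()
print("Order: t_ml, t_ap, t_si (mm), pitch, roll, yaw (deg). The 4.9 mm")
print("advancement is the cohort median; the measured row recovers the")
print("plan to numerical precision because correspondence is exact.")
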