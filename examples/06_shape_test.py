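"""Procrustes + PLS permutation test of condylar shape.

Aligns small synthetic point configurations by generalized Procrustes
analysis and tests whether the two groups differ in shape. The first test
uses identical populations (expected non-significant); the second injects a
mean shift three times the residual noise (expected significant). The group
difference field is exported as a PLY colormap.
"""

import numpy as np

from condylokit.shape import difference_colormap, gpa_align, pls_shape_test, save_colormap
from condylokit.template import make_template_mandible

rng = np.random.default_rng(0)
base = rng.normal(size=(30, 3))

def cohort(shift):
    configs, labels = [], []
    for i in range(40):
        x = base + 0.1 * rng.normal(size=base.shape)
        if i < 20:
            x = x + shift
        configs.append(x)
        labels.append(1 if i < 20 else 0)
    return np.asarray(configs), np.asarray(labels)

# the injected difference must be a *shape* change (a pure translation of
# all points would be removed by Procrustes centring): displace one
# landmark by 3x the residual noise sd
shape_shift = np.zeros((30, 3))
shape_shift[0, 0] = 0.3
for name, shift in [("null (no group difference)", np.zeros((30, 3))),
                    ("3-sigma single-landmark shift", shape_shift)]:
    configs, labels = cohort(shift)
    aligned, mean = gpa_align(configs)
    res = pls_shape_test(aligned, labels, n_permutations=999, seed=1)
    print(f"{name}: p = {res.p_value:.3f}  (statistic {res.statistic:.4f})")

# colormap on the mandible template: +0.5 mm uniform inflation
t = make_template_mandible(2000)
field, cm = difference_colormap(
    t.vertices, t.vertices + 0.5 * t.mesh.vertex_normals, t.mesh.faces
)
save_colormap(cm, "diffmap.ply")
print()
print(f"wrote diffmap.ply; field mean {field.mean():.3f} mm (uniform +0.5 mm offset)")
print("Positive values: the second group's surface lies outside the first's")
print("along its vertex normals.")
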