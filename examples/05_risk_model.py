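"""Multivariable risk modelling on a simulated cohort.

Generates a tabular cohort of 2000 patients where mandibular advancement is
the dominant generative risk factor, then runs the full recipe: stratified
70/30 split, SMOTE on the training set, Boruta selection, random-forest
evaluation. Advancement should top the importance ranking.
"""

from condylokit.ml import MLConfig, rank_features, run_risk_model
from condylokit.simulate import CohortConfig, generate_cohort

FEATURES = [
    "age", "bmi", "mouth_opening", "trans_ml", "trans_ap", "trans_si",
    "pitch", "roll", "yaw", "condylar_volume_left", "condylar_volume_right",
    "ap_ratio", "mandibular_plane_angle",
]

cohort = generate_cohort(CohortConfig(n_patients=2000, seed=7, with_meshes=False))
X = cohort.records[FEATURES]
y = cohort.records["resorbed_any"].astype(int)

print("feature ranking (random-forest importance on SMOTE-balanced data):")
for i, name in enumerate(rank_features(X, y, MLConfig(seed=7)), 1):
    print(f"  {i:2d}. {name}")

report = run_risk_model(X, y, "random_forest", MLConfig(seed=7))
print()
print(f"test AUC {report.auc:.2f}, F1 {report.f_score:.2f}, "
      f"accuracy {report.accuracy:.2f}, misclassification {report.misclassification:.2f}")
print("selected features:", report.selected_features)
print()
print("trans_ap (mandibular advancement) ranks first: it carries the")
print("largest generative per-sd log odds ratio in the simulator.")
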