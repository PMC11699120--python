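# Methods

## Problem and model

Condylar resorption after mandibular orthognathic surgery is defined here
radiologically, on 3D surface models at three timepoints (T0 pre-op, T1
one week post-op, T2 one year post-op). A condyle is resorbed when three
conditions hold simultaneously between T1 and T2:

1. condylar volume loss strictly greater than 30 mm³ — the margin equals
   the mean segmentation error of condylar volumetry, so "real" loss must
   exceed measurement noise;
2. posterior displacement of the distal (tooth-bearing) segment of at
   least 2 mm, read from the anteroposterior component of the T1→T2
   six-DOF relapse with the sign flipped (posterior positive), evaluated
   once per patient and shared by both sides;
3. ramal height (condylion–gonion distance) loss of at least 2 mm.

"At least 2 mm" is inclusive (≥); "greater than 30 mm³" is strict (>).
Posterior displacement rather than "relapse" is used deliberately: in a
class-III patient resorption produces a class-II drift, not a return to
the preoperative position.

## Kinematics

Segment motions are recovered by rigid registration of a volume of
interest that the surgery does not alter: the osteotomy-free mandibular
body for the distal segment and the "modified ramus" (the ramus between
osteotomy and sigmoid notch, excluding the remodeling condyle) for the
proximal segments. Registration is correspondence-based Kabsch (exact
closed form via SVD) when the two models share topology — which the
simulator guarantees — and iterative closest point (nearest-neighbour
matching + Kabsch, convergence when the mean residual changes by
< 1e-6 mm, cap 200 iterations) otherwise. Estimated rotations are
projected onto SO(3) by polar decomposition.

A motion is reported as six anatomical degrees of freedom in a frame with
ML = +x (patient right), AP = +y (anterior), SI = +z (superior):
translations are the displacement of the frame origin projected on the
axes; rotations are Euler angles extracted in the fixed order
yaw (SI) → roll (AP) → pitch (ML). Clinical sign convention: positive
rotation is clockwise in the right-lateral (pitch), frontal (roll) and
bottom (yaw) view, which maps to the negative right-hand angle about the
corresponding axis; a counterclockwise (chin-up) pitch is therefore
negative, matching the convention in which the typical advancement case
has a small negative pitch. The view-to-axis sign mapping is a package
decision (the convention is stated in terms of views, not axes, in the
clinical literature) and could differ from other software by a global
sign; it is fixed, documented, and covered by round-trip and
mirror-consistency tests. For the right proximal segment, t_ML, roll and
yaw are sign-flipped so both sides read from a left-side perspective
(`mirrored=True`); reflecting all geometry across the mid-sagittal plane
and swapping side labels leaves reported values unchanged.

`compose_six_dof` is the exact inverse of `decompose_six_dof` on the
non-degenerate range (all |angles| < 90°); the round trip is tested to
1e-9 over ±45°/±20 mm. Decomposition order matters at large angles; the
order above is fixed.

## Morphometry

The C-plane is an axial-normal plane through the sigmoid-notch nadir of
each side (the source protocols defer its exact construction to external
references; this landmark-driven construction is reproducible and
delineates the caudal condylar border). Volumes above the plane are
computed by clipping the watertight mesh with the plane and summing
signed tetrahedra **about a reference point on the plane itself** — every
facet of the planar cap is then coplanar with the reference point and
contributes zero, so no cap triangulation is needed and the result is
exact for the polyhedral region. The clip may contain both condyles; the
connected component nearest the side's condylion is taken. Closed-form
checks: full sphere, hemispheres and spherical caps agree within 1% at
the default mesh resolution and converge under refinement; volume above
plus volume below reproduces the total volume to 1e-9 relative.

For T0→T2 change, T2 is registered onto T0 per side by the modified-ramus
VOI and the T0 C-plane is applied to both models. Ramal height is the
condylion–gonion distance; the anterior lower facial height runs from an
anterior-nasal-spine surrogate to menton (endpoints are not fully
specified in the source protocols; this choice is documented); the A/P
ratio divides it by the mean bilateral ramal height; the mandibular plane
angle is the dihedral angle between the bilateral gonion–menton plane and
the frame's axial plane (the reference plane is likewise a documented
package choice).

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes,
not anatomy. The mandible is a parametric swept tube (condyle → ramus →
body → ramus → condyle) closed by pole vertices: watertight, genus 0,
fixed topology across subjects, so dense correspondence holds by
construction (standing in for non-rigid template mapping). One ring per
side is flattened onto the sigmoid-notch level; condylar size factors
scale everything above that ring isotropically about a centre **on** the
ring plane, which makes the clipped condylar volume exactly cubic in the
factor — subject condyles hit their target volumes by a cube-root
calibration against one template measurement.

Covariates are drawn per a 200-patient orthognathic cohort profile: age
14 + Gamma (mean 24.5, sd 11.4, median ≈ 19), 42% male, 80% class II,
BMI N(22.1, 3.8), mouth opening N(47, 6.5), TMJ pain/sounds and procedure
categories at the cohort frequencies, distal six-DOF movements N(4.0, 5.0)
AP advancement etc., preoperative condylar volumes N(1710, 540) truncated,
A/P ratio and plane angle at their cohort moments. Covariates are sampled
independently (the observational study gives no generative model; all
effect sizes are calibration inputs, not claims).

Resorption labels follow a logistic model on patient covariates with
default per-unit log odds ratios log 1.41 (AP advancement, per mm),
log 0.92 (age, per year), log 1.24 (upward movement, per mm) and log 0.82
(pitch, per degree); the intercept is calibrated by root-finding so the
mean probability equals the target prevalence (default 0.095). Resorbed
patients are bilateral with probability 4/19; the side is uniform.
Resorbed condyles receive injected changes drawn from the
resorption-group distributions — volume N(−230.2, 168) mm³ truncated to
[−700, −80] (and at most 55% of the condyle), height N(−3.9, 1.7) mm
truncated to ≤ −2.3, posterior displacement N(+3.1, 0.9) mm truncated to
≥ +2.3 — so injections stay clear of the classification thresholds and
the generative label is recoverable. Unaffected condyles receive
zero-mean remodeling noise (sd 50 mm³ and 1 mm, below the thresholds'
joint reach); unaffected patients get posterior drift N(0.6, 1.0) mm.
The distal relapse couples a clockwise pitch of 0.6°/mm to the posterior
translation. Injection mechanics: ramal height loss translates the
condylar region along the condylion→gonion line (exactly reducing the
measured height); the volume change is a cylindrical in-plane erosion
about the condylar axis whose factor is solved by Brent's method so the
C-plane-clipped volume matches the injected change to < 1 mm³;
watertightness is verified after deformation. One global seed feeds
per-patient substreams, so cohorts are byte-identical under a fixed
config and patients are reproducible in isolation.

What the simulator does **not** emulate: real condylar anatomy (no
coronoid process, idealized cross-sections), segmentation error and
voxel-level noise, correlated covariates (e.g. procedure vs advancement),
osteosynthesis artefacts, and non-rigid inter-subject variation beyond
global/condylar scale. Passing tests therefore demonstrate correctness
of the measurement and inference machinery under controlled truth, not
clinical performance on real CBCT data.

The n = 2000 parameter-recovery and feature-ranking runs use the tabular
path (no meshes); measured-vs-injected fidelity is established on the
mesh path at n ≤ 200. These problem sizes keep the full suite and the
acceptance script at a few minutes on one CPU.

## Statistics

Univariable logistic regression is fitted by IRLS (tolerance 1e-10) with
Wald 95% intervals exp(β ± 1.96·SE) — chosen over profile likelihood
because they reproduce printed contingency-table CIs exactly (for a
saturated categorical model the MLE odds ratios are the cross-product
ratios and SE² is the sum of reciprocal cell counts). Completely
separated levels are reported as OR 0 (or ∞) with CI (0, ∞) rather than
failing; their rows are excluded from the fit of the remaining levels so
those stay the cross-products of their own cells. Quartiles use linear
interpolation (the convention IQRs depend on). Condyle-level outcomes
(two per patient) use GEE with the independence working correlation:
point estimates coincide with the ordinary fit; variances are
cluster-robust sandwich estimates (with singleton clusters this equals
the HC0 robust GLM covariance). Group comparisons gate one-way ANOVA on
per-group Shapiro–Wilk normality at α = 0.05, falling back to
Kruskal–Wallis.

## Risk models

Stratified 70/30 split (stratification is a package decision: with ~19
events an unstratified split can empty a class), SMOTE to class parity on
the training set only (k = 5 neighbours; synthetic points are uniform
interpolations toward a k-NN minority neighbour), then feature selection:
Boruta for the random forest (20 iterations, per-iteration hit when a
feature's importance exceeds the maximum among freshly permuted shadow
copies, two-sided binomial classification at α = 0.05 without
multiple-testing adjustment) or a total-gain threshold of 1 for gradient
boosting ("importance 1" is scale-dependent; total gain is the
interpretation used). Ensembles use library defaults (100 trees);
calibration simulations use 50 trees for runtime, which does not change
the tested properties. Metrics are computed on the untouched test set at
threshold 0.5; AUC is the rank statistic; the F-score is the F1 of the
resorption class. Known limitation: with labels fixed across Boruta
iterations, a noise feature that is by chance correlated with the outcome
(max |r| ≈ 0.09 among 10 features at n = 500) beats the re-permuted
shadows consistently, so the per-dataset family-wise false-confirmation
rate is roughly 10% rather than negligible; this is intrinsic to
all-relevant selection on a fixed dataset and persists under depth limits
and Bonferroni adjustment.

## Shape analysis

Generalized Procrustes analysis centres each configuration, scales to
unit centroid size (shape excludes size), and iteratively rotates to the
evolving mean until the mean changes by < 1e-8 (cap 100 iterations), with
a final synchronizing rotation so re-alignment is a no-op. The group test
is a one-component PLS of the vectorized aligned shapes onto the binary
label; the statistic is ‖X_cᵀ y_c‖/n (the covariance between PLS shape
scores and status up to a constant — the simplest statistic consistent
with "PLS regression of shape onto status"; the cited protocol's exact
internals are not public). Significance comes from seeded label
permutation, p = (1 + #{permuted ≥ observed}) / (1 + N), default
N = 1000 (at least 99 required). Age- and sex-matched controls are chosen
by greedy nearest-age same-sex matching under a seeded order. Group mean
differences are exported as per-vertex signed normal displacements on the
control mean mesh (binary PLY with a `quality` scalar, which round-trips
exactly).

## Numerical choices and degenerate inputs

Rotations estimated from data are polar-projected onto SO(3); collinear
point sets, constant features, single-member minority classes, empty
cohorts, gimbal-range rotations (|angle| ≥ 90°), non-watertight meshes
and empty clips all raise explicit errors. The erosion solver brackets
the cylindrical factor in [0.2, 2.5] and raises if the injected change is
unreachable. Ties in greedy matching are broken by the seeded shuffle.
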