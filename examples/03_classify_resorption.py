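"""Apply the three-criterion resorption classification.

A condyle is resorbed when volume loss exceeds 30 mm^3 (strict), posterior
displacement is at least 2 mm, and ramal height loss is at least 2 mm. The
first case below is the resorption-group average condyle; the second is a
typical remodeling-only condyle.
"""

from condylokit.kinematics import SixDOF
from condylokit.morphometry import CondyleMetrics
from condylokit.resorption import ResorptionCall, classify_condyle, cohort_incidence


def condyle(dv, dh):
    return CondyleMetrics("left", 1400.0, 1400.0 + dv, 50.0, 50.0 + dh)


resorption_like = classify_condyle(condyle(-230.2, -3.9), SixDOF(t_ap=-3.1))
remodeling_like = classify_condyle(condyle(-48.8, -0.03), SixDOF(t_ap=-0.6))
print("resorption-group average (-230.2 mm^3, -3.9 mm, +3.1 mm):", resorption_like)
print("remodeling average       ( -48.8 mm^3, -0.03 mm, +0.6 mm):", remodeling_like)

calls = (
    [ResorptionCall(True, False)] * 15
    + [ResorptionCall(True, True)] * 4
    + [ResorptionCall(False, False)] * 181
)
inc = cohort_incidence(calls)
print()
print(f"cohort of {inc['n_patients']}: any {inc['any_pct']}%, "
      f"unilateral {inc['unilateral_pct']}%, bilateral {inc['bilateral_pct']}%")
print("(15 unilateral + 4 bilateral cases of 200 patients -> 9.5% / 7.5% / 2.0%)")
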