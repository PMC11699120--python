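"""Univariable odds ratios from contingency counts.

Reproduces classic worked examples at patient level (ordinary logistic
regression) and condyle level (GEE with independence working correlation):
for a saturated categorical model the ML odds ratio is the contingency
cross-product ratio, and the Wald CI comes from the log-scale cell-count
standard error.
"""

from condylokit.stats import gee_logistic_from_counts, univariable_logistic_from_counts

# patient level: events / non-events per procedure
fit = univariable_logistic_from_counts(
    ["BSSO", "BIMAX", "BIMAX_genioplasty", "BSSO_genioplasty"],
    [6, 2, 7, 4],
    [86, 52, 20, 23],
    reference="BSSO",
)
print("patient-level procedure odds ratios (vs BSSO):")
print(fit.table.round(2))
print()

# condyle level, clustered two-per-patient: GEE point estimates
gee = gee_logistic_from_counts(
    ["BSSO", "BIMAX", "BIMAX_genioplasty", "BSSO_genioplasty"],
    [7, 2, 10, 4],
    [177, 106, 44, 50],
    reference="BSSO",
)
print("condyle-level procedure odds ratios (GEE, vs BSSO):")
print(gee.table["odds_ratio"].round(2))
print()
print("BIMAX+genioplasty carries a ~5x odds of resorption at patient level")
print("(OR 5.02, 95% CI 1.52-16.56) and ~5.75x at condyle level.")
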