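"""Simulate and report a small two-group cohort.

Generates diabetic and control eyes with a deficit confined to the deep
vascular complex, quantifies every eye, applies the SSI < 7 exclusion, and
prints the two clinical-style report tables: group means +/- SD with
Student's-t p-values, and Pearson correlations of the OCTA metrics with
HbA1c and diabetes duration in the diabetic group.

Note: n = 10 per group here to keep the example quick; the study design
is n = 35 per group (CohortConfig defaults).
"""

import octa3d as o
from octa3d.stats import build_table1, build_table2, run_cohort

base = o.SimEyeConfig(
    geometry=o.reduced_geometry(n_lateral=64, n_axial=160), ilm_depth_um=120.0
)
config = o.CohortConfig(n_per_group=10, base=base)

cohort = run_cohort(o.iter_cohort(config, seed=1))
print(f"included eyes after SSI filter: {len(cohort.records)}\n")

table1 = build_table1(cohort, formatted=True)
print("Group comparison (mean ± SD, Student's t):")
print(table1.to_string())
print()
table2 = build_table2(cohort)
print("Correlations with clinical covariates (diabetic group):")
print(table2.round(3).to_string())
# With only 10 eyes per group the DVC deficit may or may not reach
# p < 0.05; at the design size of 35 per group it does in most runs.
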