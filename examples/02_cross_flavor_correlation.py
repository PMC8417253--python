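"""Cross-flavor feature harmonization on a small synthetic cohort.

Generates a longitudinal phantom cohort, extracts the reference and
IBEX-emulation feature tables, builds the shared-feature registry and
fits one linear correlation per shared pair across all (patient,
timepoint) observations.  Features above the reproducibility threshold
(Pearson r strictly greater than 0.901) are selected as interchangeable.
"""

import numpy as np

import radstab as rs

config = rs.CohortConfig(n_patients=8, n_timepoints=4,
                         grid_shape=(10, 32, 32), seed=42)
cases = rs.generate_cohort(config)
table_ref = rs.extract_cohort_table(cases, "reference")
table_ibx = rs.extract_cohort_table(cases, "ibex-emulation")

registry = rs.build_registry(rs.get_flavor("reference"),
                             rs.get_flavor("ibex-emulation"))
records = rs.fit_feature_correlations(table_ref, table_ibx, registry)
kept = rs.select_reproducible(records, threshold=0.901)

defined = [r for r in records if r.defined]
print(f"shared pairs          : {len(registry)}")
print(f"fitted (defined r)    : {len(defined)}")
print(f"reproducible at 0.901 : {len(kept)}")

print("\nexample records (pair, r, slope, intercept, n_used/n_excluded):")
for rec in records[:3] + [r for r in records if r.pair.klass == "SHAPE"][:3]:
    print(f"  {rec.pair.feature_a:45s} ~ {rec.pair.feature_b:45s}"
          f"  r={rec.r:+.4f} slope={rec.slope:+.3f} "
          f"b={rec.intercept:+.2f} ({rec.n_used}/{rec.n_excluded})")

print("\nMesh- vs voxel-based shape primitives correlate near (not at) 1;"
      "\nidentically computed pairs sit at r = 1 exactly.")
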