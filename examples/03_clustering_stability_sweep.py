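"""Patient-clustering stability under a reproducibility-threshold sweep.

Runs the full end-to-end experiment: a 36-patient, 8-timepoint phantom
cohort with two planted response groups, reference and IBEX-emulation
feature tables, plus a block of distractor features that are mutually
correlated within each flavor but poorly correlated across flavors
(emulating non-reproducible texture features).  At a permissive
threshold the distractors dominate both signatures and the two flavors
cluster different patient groups; at the 0.901 reproducibility
threshold only well-correlated features survive and the clusterings
coincide.

Takes about a minute (two full 288-map feature extractions).
"""

import numpy as np

import radstab as rs

exp = rs.distractor_sweep_experiment(seed=7)

print(f"shared + distractor records : {len(exp.records)}")
print(f"distractor cross-flavor |r| : "
      f"max {np.nanmax(np.abs(exp.distractor_r)):.3f}")
print()
print("threshold  n_features  similarity(%)")
for thr in (0.0, 0.5, 0.85, 0.901, 0.965):
    sim = exp.similarity_at(thr)
    print(f"   {thr:5.3f}   {exp.n_features_at(thr):9d}   {sim:10.2f}")

counts = [r.n_features for r in exp.sweep.results]
print(f"\nsweep grid points: {len(counts)}; "
      f"surviving-feature count monotone non-increasing: "
      f"{all(a >= b for a, b in zip(counts, counts[1:]))}")
print("Similarity is degraded at threshold 0 by the distractor block and"
      "\nrestored to 100% once the threshold excludes it.")
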