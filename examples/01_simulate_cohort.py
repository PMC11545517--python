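"""Generate a synthetic cohort with planted biological layers.

Builds the default 142-sample, 2000-gene cohort (seven disjoint layer
blocks, CIN/MSI/GS/EBV subtype labels, exponential survival, 2% missing
values) and prints its headline structure.
"""

from gclayers import attach_survival, generate_cohort, inject_missing

matrix, truth = generate_cohort(seed=1)
matrix = inject_missing(matrix, rate=0.02, seed=2)
clinical = attach_survival(truth, driving_layer=0, log_hazard_ratios=(0.0, 1.1), seed=3)

print(f"matrix: {matrix.n_genes} genes x {matrix.n_samples} samples, "
      f"{matrix.n_missing} missing entries")
print("layer block sizes:", [len(g) for g in truth.layer_genes])
print("subtype counts:", {s: list(truth.subtype.values()).count(s)
                          for s in ("CIN", "MSI", "GS", "EBV")})
print(f"survival: {int(clinical['event'].sum())} events / {len(clinical)} samples")
# The block sizes and subtype mix are the defaults the package emulates;
# events/sample count reflects the exponential survival + censoring model.
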