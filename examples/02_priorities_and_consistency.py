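"""Derive priorities from one judgment matrix and read its consistency
diagnostics; also show the direct-weight entry mode."""

from ahp import (
    PairwiseComparisonMatrix,
    consistency_report,
    derive_priorities,
    matrix_from_direct_weights,
)

# A mildly intransitive 3x3 matrix: a is 2x b, 8x c; b is 2x c
# (perfect transitivity would need a = 4x c).
M = PairwiseComparisonMatrix.from_upper_triangle(
    ("a", "b", "c"), {(0, 1): 2.0, (0, 2): 8.0, (1, 2): 2.0}
)
pv, lambda_max = derive_priorities(M)
rep = consistency_report(M)
print("eigenvector priorities:", {k: round(v, 4) for k, v in pv.as_dict().items()})
print(f"lambda_max = {lambda_max:.4f} (n = 3; equality with n would mean perfect consistency)")
print(f"CI = {rep.ci:.4f}, CR = {rep.cr:.4f} -> {'inconsistent' if rep.inconsistent else 'acceptably consistent'} (cutoff CR > 0.15)")
print()

# Pilot-style entry: type weights, get the consistent ratio matrix back.
D = matrix_from_direct_weights([0.6, 0.2, 0.2])
pv2, _ = derive_priorities(D)
rep2 = consistency_report(D)
print("direct weights (0.6, 0.2, 0.2) -> a_12 =", D.values[0, 1])
print("recovered priorities:", pv2.weights.round(6), "| CI =", round(rep2.ci, 12))
# The eigenvector reproduces the typed weights exactly and CI is 0:
# a ratio matrix built from one weight vector is consistent by construction.
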