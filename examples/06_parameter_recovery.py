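"""How well does the pipeline recover latent priorities from noisy
judgments?  Recovery error (MAE) as a function of judgment noise."""

import numpy as np

from ahp import (
    SyntheticCohortConfig,
    derive_all,
    generate_cohort,
    local_vectors,
    recovery_error,
)
from ahp.hierarchy import DecisionHierarchy, ObjectiveNode

h = DecisionHierarchy(
    goal="pick a treatment",
    objectives=(ObjectiveNode("efficacy"), ObjectiveNode("safety"), ObjectiveNode("tolerability")),
    alternatives=("A", "B", "C", "D"),
)

print("single-expert recovery of latent local priorities (50 replicates each):")
for sigma in (0.0, 0.05, 0.2, 0.5):
    maes = []
    for rep in range(50):
        panel, truth = generate_cohort(
            SyntheticCohortConfig(hierarchy=h, n_experts=1, noise_sigma=sigma, seed=rep)
        )
        locs = local_vectors(derive_all(panel[0], h))
        keys = [k for k, v in truth.locals.items() if len(v) > 1]
        maes.append(np.mean([recovery_error(locs[k], truth.locals[k]).mae for k in keys]))
    print(f"  sigma = {sigma:4.2f}  ->  mean MAE = {np.mean(maes):.4f}")
# MAE falls monotonically as the judgment noise shrinks and is exactly 0 in
# the noise-free limit: the eigenvector inverts a consistent matrix exactly.
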