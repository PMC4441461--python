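"""Simulate a nine-expert panel on the diabetes model, derive everyone's
priorities, aggregate by geometric mean, and report disagreement."""

from ahp import (
    SyntheticCohortConfig,
    derive_all,
    diabetes,
    generate_cohort,
    group_synthesize,
    local_vectors,
)

h = diabetes.build_hierarchy()
cfg = SyntheticCohortConfig(hierarchy=h, n_experts=9, noise_sigma=0.3, seed=2024)
panel, truth = generate_cohort(cfg)

expert_locals = [local_vectors(derive_all(js, h)) for js in panel]
result, info = group_synthesize(h, expert_locals, mode="ideal")

print(f"panel: {info.n_experts} synthetic experts, judgment noise sigma = {cfg.noise_sigma}")
print("\ngroup ranking (ideal mode):")
for rank, label, score in result.ranking():
    true_score = truth.scores["ideal"][label]
    print(f"  {rank}. {label:<14} score {100 * score:5.2f}%   (latent truth {100 * true_score:5.2f}%)")

goal_key = "choose an add-on therapy to metformin for type 2 diabetes"
spread = info.dispersion[goal_key]
print("\nexpert disagreement on the benefit/harm split (SD, percentage points):")
for item, sd in spread.items():
    print(f"  {item}: {sd:.1f}")
# Geometric-mean aggregation pulls the group vector toward the latent truth;
# the SDs show how far individual experts scatter around it.
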