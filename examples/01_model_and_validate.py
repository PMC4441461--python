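"""Build a decision hierarchy from YAML, validate it, and list the pairwise
comparison groups it implies."""

from ahp import parse_model

MODEL = """
goal: choose a commuting mode
context: toy example
objectives:
  - name: cost
  - name: comfort
    children: [seat availability, noise]
alternatives: [bicycle, bus, car]
"""

h = parse_model(MODEL)
print(f"goal: {h.goal}")
print(f"alternatives: {', '.join(h.alternatives)}")
print(f"leaf objectives: {[leaf.name for leaf in h.leaves()]}")
print()
print("comparison groups (alternative comparisons first):")
for g in h.comparison_groups():
    note = "" if g.requires_judgments else "  <- single item, weight 1, no questions"
    print(f"  [{g.kind}] under {g.parent!r}: {len(g.items)} items, "
          f"{g.n_questions} pairwise questions{note}")
# Each multi-item group needs n(n-1)/2 ratio judgments from every expert;
# the single-child group ("comfort" has two children, "cost" is a leaf) is
# weighted automatically.
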