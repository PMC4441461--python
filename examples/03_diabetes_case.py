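"""The built-in diabetes add-on-therapy case: re-synthesize the published
objective priorities and print the relative-difference table."""

from ahp import diabetes, global_objective_priorities, relative_differences, report

fixture = diabetes.load_fixture()
locals_map = diabetes.reference_locals()
globals_ = global_objective_priorities(fixture.hierarchy, locals_map)

print("Re-synthesized global priorities (% of goal):")
print(report.render_globals(globals_, fixture.hierarchy)["markdown"])
print()

table = relative_differences(diabetes.leaf_globals())
print("Relative differences among the lowest-level objectives")
print("(each cell: larger/smaller global priority; bold = ratio >= 1.1, a meaningful difference):")
print(report.render_ratio_table(table)["markdown"])
print()

b, h = globals_[diabetes.BENEFITS], globals_[diabetes.HARMS]
print(f"Maximizing benefits vs minimizing harms: {b:.2f} vs {h:.2f} "
      f"-> benefits judged {100 * (b / h - 1):.0f}% more important.")
print(f"Severe hypoglycemia vs fracture: "
      f"{table.pair_ratio(diabetes.HYPOGLYCEMIA, diabetes.FRACTURE):.2f}x "
      f"(the largest gap at the lowest level).")
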