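# ahp-decide

An Analytic Hierarchy Process (AHP) toolkit for multi-criteria benefit–risk
decisions, built for analysts who need a scriptable, testable alternative to
GUI decision software. It ships the complete pipeline used in structured
expert elicitation studies — in particular the benefit–risk comparison of
add-on therapies to metformin for type 2 diabetes, which is included as a
fully worked case — plus a synthetic expert-panel generator for validating
the machinery when raw judgments are unavailable.

## The method

A decision is modelled as a hierarchy: a goal, a tree of objectives
(criteria), and a common set of alternatives under every leaf objective.
For each group of siblings, experts state pairwise ratio judgments
*a<sub>ij</sub>* (how many times item *i* matters more than item *j*),
forming a positive reciprocal matrix **A** with *a<sub>ji</sub> =
1/a<sub>ij</sub>*. Local priorities **w** are the principal right
eigenvector, **A w** = *λ*<sub>max</sub> **w**, computed by power iteration.
Consistency is diagnosed through

- CI = (*λ*<sub>max</sub> − *n*)/(*n* − 1), which is 0 exactly when
  judgments are transitive, and
- CR = CI/RI(*n*), flagged inconsistent above 0.15.

Global weights propagate multiplicatively (child global = parent global ×
child local); overall alternative scores are leaf-weight sums in either
**distributive** mode (sum-normalized leaf vectors; proportional shares,
vulnerable to rank reversal) or **ideal** mode (max-normalized leaf vectors;
rank-safe under addition or removal of a nowhere-best alternative). Panels
are aggregated by the element-wise **geometric mean** of individual
priorities (AIP), with per-item standard deviations as the disagreement
summary, and score ratios of at least **1.1** are treated as meaningful
differences. Sensitivity scenarios force chosen objectives to fixed weight
shares (siblings rescale proportionally) and re-synthesize.

## Worked example

```python
from ahp import diabetes, global_objective_priorities, relative_differences

fixture = diabetes.load_fixture()
globals_ = global_objective_priorities(fixture.hierarchy, diabetes.reference_locals())
print(round(globals_[diabetes.SERIOUS], 2))       # 30.38
print(round(globals_[diabetes.NON_SERIOUS], 2))   # 14.79

table = relative_differences(diabetes.leaf_globals())
print(round(table.pair_ratio(diabetes.HYPOGLYCEMIA, diabetes.FRACTURE), 2))  # 5.45
print(table.is_significant(diabetes.HYPOGLYCEMIA, diabetes.FRACTURE))        # True
```

The first two numbers are the global priorities (percent of the goal) of
minimizing serious and non-serious harms, re-synthesized from the local
weights the published table implies — children always sum exactly to their
parent. The 5.45 is the largest relative difference at the lowest level of
the hierarchy: avoiding severe hypoglycemia was judged 5.45× as important as
avoiding fractures, well over the 1.1 significance bar. Or from the shell:

```bash
ahp demo                       # the full case: tables plus headline ratios
ahp validate model.yaml        # check a hierarchy file
ahp simulate model.yaml --experts 9 --sigma 0.3 --seed 42 --out j.csv
ahp prioritize model.yaml j.csv --out priorities.csv
ahp group model.yaml priorities.csv --mode ideal
```

`examples/` contains one short script per capability (modelling,
priorities/consistency, the diabetes case, group aggregation, sensitivity,
parameter recovery).

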