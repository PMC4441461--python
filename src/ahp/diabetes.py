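"""Built-in worked example: ranking add-on therapies to metformin for
type 2 diabetes.

A nine-expert panel weighed one benefit (HbA1c lowering) against seven
potential harms — three non-serious (fracture, weight gain, gastrointestinal
symptoms) and four serious (severe hypoglycemia, congestive heart failure,
acute pancreatitis, bladder cancer) — across five alternatives: metformin
(dose escalation), exenatide, sitagliptin, sulfonylureas, and pioglitazone.

The fixture embeds the decision hierarchy and the published group-level
global priorities of the objectives (percent of the goal).  The raw
pairwise judgments and the alternative-level scores were never published,
so alternative-level checks against this case are structural only; the
objective-level numbers support exact regression tests of the synthesis
and ratio machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hierarchy import DecisionHierarchy, ObjectiveNode, norm_label
from .priorities import NORMALIZED, PriorityVector
from .synthesis import RelativeDifferenceTable, SynthesisResult
from . import report

GOAL = "Choose an add-on therapy to metformin for type 2 diabetes"

BENEFITS = "Maximizing benefits"
HBA1C = "Reduce HbA1c"
HARMS = "Minimizing harms"
NON_SERIOUS = "Minimizing non-serious harms"
FRACTURE = "Risk of fracture"
WEIGHT_GAIN = "Weight gain"
GI = "GI symptoms"
SERIOUS = "Minimizing serious harms"
HYPOGLYCEMIA = "Severe hypoglycemia"
CHF = "CHF risk"
PANCREATITIS = "Acute pancreatitis"
BLADDER = "Risk of bladder cancer"

ALTERNATIVES = ("metformin", "exenatide", "sitagliptin", "sulfonylureas", "pioglitazone")

#: Published group-level global priorities of the objectives (percent).
REFERENCE_GLOBALS = {
    BENEFITS: 54.83,
    HBA1C: 54.83,
    HARMS: 45.17,
    NON_SERIOUS: 14.79,
    FRACTURE: 2.57,
    WEIGHT_GAIN: 7.65,
    GI: 4.57,
    SERIOUS: 30.38,
    HYPOGLYCEMIA: 14.01,
    CHF: 7.96,
    PANCREATITIS: 4.46,
    BLADDER: 3.95,
}

#: The seven lowest-level objectives, in published table order.
LEAF_HARMS = (FRACTURE, WEIGHT_GAIN, GI, HYPOGLYCEMIA, CHF, PANCREATITIS, BLADDER)


def build_hierarchy() -> DecisionHierarchy:
    """The final decision model: goal, two top objectives, two harm
    subgroups, eight leaf objectives, five alternatives."""
    return DecisionHierarchy(
        goal=GOAL,
        objectives=(
            ObjectiveNode(BENEFITS, (ObjectiveNode(HBA1C),)),
            ObjectiveNode(
                HARMS,
                (
                    ObjectiveNode(
                        NON_SERIOUS,
                        (ObjectiveNode(FRACTURE), ObjectiveNode(WEIGHT_GAIN), ObjectiveNode(GI)),
                    ),
                    ObjectiveNode(
                        SERIOUS,
                        (
                            ObjectiveNode(HYPOGLYCEMIA),
                            ObjectiveNode(CHF),
                            ObjectiveNode(PANCREATITIS),
                            ObjectiveNode(BLADDER),
                        ),
                    ),
                ),
            ),
        ),
        alternatives=ALTERNATIVES,
        context=(
            "Benefit-risk assessment of add-on therapies to metformin for "
            "adults with type 2 diabetes, judged by a nine-expert panel."
        ),
    ).require_valid()


@dataclass(frozen=True)
class CaseFixture:
    """The embedded case: hierarchy plus published objective globals."""

    hierarchy: DecisionHierarchy
    reference_globals: dict[str, float]
    notes: str


def load_fixture() -> CaseFixture:
    """The diabetes decision model with its published global priorities."""
    return CaseFixture(
        hierarchy=build_hierarchy(),
        reference_globals=dict(REFERENCE_GLOBALS),
        notes=(
            "Objective-level global priorities are the published group "
            "(geometric-mean) results, in percent of the goal; children sum "
            "exactly to their parents. Alternative-level scores were "
            "published only graphically and are not embedded."
        ),
    )


def reference_locals() -> dict[str, PriorityVector]:
    """Local priority vectors implied by the published globals.

    Each child's local weight is its global divided by its parent's global
    (the synthesis identity run backwards); re-synthesizing these locals
    reproduces the published table to display precision.
    """
    g = REFERENCE_GLOBALS

    def vector(parent_global: float, labels: tuple[str, ...]) -> PriorityVector:
        w = np.array([g[lab] / parent_global for lab in labels])
        return PriorityVector(labels, w / w.sum(), NORMALIZED)

    return {
        norm_label(GOAL): vector(100.0, (BENEFITS, HARMS)),
        norm_label(BENEFITS): PriorityVector((HBA1C,), np.array([1.0])),
        norm_label(HARMS): vector(g[HARMS], (NON_SERIOUS, SERIOUS)),
        norm_label(NON_SERIOUS): vector(g[NON_SERIOUS], (FRACTURE, WEIGHT_GAIN, GI)),
        norm_label(SERIOUS): vector(g[SERIOUS], (HYPOGLYCEMIA, CHF, PANCREATITIS, BLADDER)),
    }


def leaf_globals() -> dict[str, float]:
    """Published globals of the seven lowest-level harm objectives."""
    return {lab: REFERENCE_GLOBALS[lab] for lab in LEAF_HARMS}


def render_report(result: SynthesisResult | RelativeDifferenceTable) -> dict[str, str]:
    """Case-style tables: a global-priority listing for a synthesis result,
    or a triangular ratio table with significance marks."""
    if isinstance(result, RelativeDifferenceTable):
        return report.render_ratio_table(result)
    if isinstance(result, SynthesisResult):
        out = report.render_globals(result.objective_globals, build_hierarchy())
        scores = report.render_scores(result)
        return {
            "markdown": out["markdown"] + "\n\n" + scores["markdown"],
            "csv": out["csv"] + "\n" + scores["csv"],
        }
    raise TypeError(f"cannot render {type(result).__name__}")
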