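"""Decision-hierarchy model: goal, objective tree, alternatives.

An AHP decision is structured as a hierarchy whose root is the goal, whose
internal levels are objectives (criteria, possibly nested), and whose leaves
are each compared against a common set of alternatives.  Every node with two
or more children induces one pairwise *comparison group*; every leaf
objective induces one comparison group over the alternatives.  A node with a
single child needs no judgments: normalization forces the child's local
weight to 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import yaml

from .errors import Finding, ModelParseError, ModelValidationError, errors_only

#: Recommended ceiling on siblings in one comparison group; beyond this the
#: number of pairwise questions (n(n-1)/2) strains judgment reliability.
MAX_RECOMMENDED_CHILDREN = 7

OBJECTIVE_GROUP = "objective-group"
ALTERNATIVE_GROUP = "alternative-group"


def norm_label(label: str) -> str:
    """Canonical matching key: trimmed, case-insensitive."""
    return label.strip().casefold()


@dataclass(frozen=True)
class ObjectiveNode:
    """One objective in the tree; a leaf when it has no children."""

    name: str
    children: tuple["ObjectiveNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass(frozen=True)
class ComparisonGroup:
    """One elicitation unit: sibling objectives under ``parent``, or the
    alternatives under a leaf objective."""

    parent: str
    items: tuple[str, ...]
    kind: str  # OBJECTIVE_GROUP or ALTERNATIVE_GROUP

    def __post_init__(self) -> None:
        if len(self.items) < 1:
            raise ModelValidationError(f"comparison group {self.parent!r} has no items")
        if self.kind not in (OBJECTIVE_GROUP, ALTERNATIVE_GROUP):
            raise ModelValidationError(f"unknown group kind {self.kind!r}")

    @property
    def requires_judgments(self) -> bool:
        """Single-item groups need no elicitation; the item gets weight 1."""
        return len(self.items) > 1

    @property
    def n_questions(self) -> int:
        """Number of pairwise questions for this group: n(n-1)/2."""
        n = len(self.items)
        return n * (n - 1) // 2

    @property
    def key(self) -> str:
        return norm_label(self.parent)


@dataclass(frozen=True)
class DecisionHierarchy:
    """The full decision model.

    ``objectives`` are the goal's direct children; nesting is unrestricted.
    All node and alternative labels must be unique case-insensitively, and
    every leaf objective is compared against the same ``alternatives``.
    """

    goal: str
    objectives: tuple[ObjectiveNode, ...]
    alternatives: tuple[str, ...]
    context: str = ""

    # ------------------------------------------------------------------ tree
    def walk(self) -> Iterator[tuple[str, ObjectiveNode]]:
        """Yield (parent label, node) in pre-order, goal's children first."""

        def _walk(parent: str, nodes: Sequence[ObjectiveNode]):
            for node in nodes:
                yield parent, node
                yield from _walk(node.name, node.children)

        yield from _walk(self.goal, self.objectives)

    def nodes(self) -> list[ObjectiveNode]:
        return [node for _, node in self.walk()]

    def leaves(self) -> list[ObjectiveNode]:
        return [node for node in self.nodes() if node.is_leaf]

    def parent_of(self) -> dict[str, str]:
        """Map from normalized node label to its parent's label."""
        return {norm_label(node.name): parent for parent, node in self.walk()}

    def find_node(self, label: str) -> ObjectiveNode | None:
        key = norm_label(label)
        for node in self.nodes():
            if norm_label(node.name) == key:
                return node
        return None

    # ---------------------------------------------------------- validation
    def validate(self) -> list[Finding]:
        """Check structural invariants; returns findings, never raises."""
        findings: list[Finding] = []
        seen: dict[str, str] = {}

        def check_unique(label: str, path: str) -> None:
            key = norm_label(label)
            if not key:
                findings.append(Finding("error", path, "empty label"))
                return
            if key in seen:
                findings.append(
                    Finding(
                        "error",
                        path,
                        f"duplicate label {label!r} (also used at {seen[key]})",
                    )
                )
            else:
                seen[key] = path

        check_unique(self.goal, "goal")
        for parent, node in self.walk():
            check_unique(node.name, f"objective {parent!r} -> {node.name!r}")
        for i, alt in enumerate(self.alternatives):
            check_unique(alt, f"alternatives[{i}]")

        if len(self.alternatives) < 2:
            findings.append(
                Finding(
                    "error",
                    "alternatives",
                    f"need at least 2 alternatives, got {len(self.alternatives)}",
                )
            )
        if not self.objectives:
            findings.append(Finding("error", "objectives", "hierarchy has no objectives"))

        for label, children in [(self.goal, self.objectives)] + [
            (node.name, node.children) for node in self.nodes() if node.children
        ]:
            if len(children) > MAX_RECOMMENDED_CHILDREN:
                findings.append(
                    Finding(
                        "warning",
                        f"node {label!r}",
                        f"{len(children)} children exceed the recommended "
                        f"{MAX_RECOMMENDED_CHILDREN} per level "
                        f"({len(children) * (len(children) - 1) // 2} pairwise questions)",
                    )
                )
        return findings

    def require_valid(self) -> "DecisionHierarchy":
        errs = errors_only(self.validate())
        if errs:
            raise ModelValidationError(
                "invalid hierarchy: " + "; ".join(str(e) for e in errs)
            )
        return self

    # ----------------------------------------------------------- groups
    def comparison_groups(self) -> list[ComparisonGroup]:
        """All comparison groups, alternative-groups first.

        Alternative comparisons come before objective weighting, mirroring
        elicitation practice (judge how treatments perform on each outcome
        before weighting the outcomes themselves).  Single-item objective
        groups are included so downstream code can assign weight 1.
        """
        alt_groups = [
            ComparisonGroup(leaf.name, self.alternatives, ALTERNATIVE_GROUP)
            for leaf in self.leaves()
        ]
        obj_groups = [
            ComparisonGroup(self.goal, tuple(n.name for n in self.objectives), OBJECTIVE_GROUP)
        ] + [
            ComparisonGroup(node.name, tuple(c.name for c in node.children), OBJECTIVE_GROUP)
            for node in self.nodes()
            if node.children
        ]
        return alt_groups + obj_groups

    def group(self, parent: str) -> ComparisonGroup:
        key = norm_label(parent)
        for g in self.comparison_groups():
            if g.key == key:
                return g
        raise KeyError(f"no comparison group with parent {parent!r}")

    # ------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        def node_dict(node: ObjectiveNode):
            if node.is_leaf:
                return {"name": node.name}
            return {"name": node.name, "children": [node_dict(c) for c in node.children]}

        return {
            "goal": self.goal,
            "objectives": [node_dict(n) for n in self.objectives],
            "alternatives": list(self.alternatives),
            "context": self.context,
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False, allow_unicode=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml(), encoding="utf-8")


# --------------------------------------------------------------- parsing

def _parse_node(obj, path: str) -> ObjectiveNode:
    if isinstance(obj, str):  # shorthand for a leaf
        return ObjectiveNode(obj.strip())
    if not isinstance(obj, Mapping):
        raise ModelParseError(f"{path}: expected a mapping or string, got {type(obj).__name__}")
    if "name" not in obj:
        raise ModelParseError(f"{path}: missing required key 'name'")
    name = obj["name"]
    if not isinstance(name, str):
        raise ModelParseError(f"{path}.name: expected a string")
    unknown = set(obj) - {"name", "children"}
    if unknown:
        raise ModelParseError(f"{path}: unknown keys {sorted(unknown)}")
    children_raw = obj.get("children") or []
    if not isinstance(children_raw, list):
        raise ModelParseError(f"{path}.children: expected a list")
    children = tuple(
        _parse_node(c, f"{path}.children[{i}]") for i, c in enumerate(children_raw)
    )
    return ObjectiveNode(name.strip(), children)


def parse_model(source: str | Path | Mapping) -> DecisionHierarchy:
    """Parse and validate a hierarchy from YAML/JSON text, a file path, or a
    mapping.

    Raises :class:`ModelParseError` on schema violations (naming the path)
    and :class:`ModelValidationError` when structural invariants fail
    (duplicate labels, fewer than 2 alternatives).  Warnings — such as a
    group larger than 7 — do not raise; inspect ``validate()`` for those.
    """
    if isinstance(source, Mapping):
        doc = source
    else:
        if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and Path(source).exists()
        ):
            text = Path(source).read_text(encoding="utf-8")
        else:
            text = str(source)
        try:
            doc = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ModelParseError(f"document is not valid YAML/JSON: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise ModelParseError("top level: expected a mapping")
    for key in ("goal", "alternatives", "objectives"):
        if key not in doc:
            raise ModelParseError(f"top level: missing required key {key!r}")
    if not isinstance(doc["goal"], str):
        raise ModelParseError("goal: expected a string")
    if not isinstance(doc["alternatives"], list) or not all(
        isinstance(a, str) for a in doc["alternatives"]
    ):
        raise ModelParseError("alternatives: expected a list of strings")
    if not isinstance(doc["objectives"], list):
        raise ModelParseError("objectives: expected a list")
    context = doc.get("context", "")
    if not isinstance(context, str):
        raise ModelParseError("context: expected a string")
    unknown = set(doc) - {"goal", "objectives", "alternatives", "context"}
    if unknown:
        raise ModelParseError(f"top level: unknown keys {sorted(unknown)}")

    h = DecisionHierarchy(
        goal=doc["goal"].strip(),
        objectives=tuple(
            _parse_node(o, f"objectives[{i}]") for i, o in enumerate(doc["objectives"])
        ),
        alternatives=tuple(a.strip() for a in doc["alternatives"]),
        context=context,
    )
    return h.require_valid()


def validate_model(h: DecisionHierarchy) -> list[Finding]:
    """Return all findings for ``h`` (empty list iff fully valid)."""
    return h.validate()


def comparison_groups(h: DecisionHierarchy) -> list[ComparisonGroup]:
    """Module-level alias for :meth:`DecisionHierarchy.comparison_groups`."""
    return h.comparison_groups()


def schema_document() -> dict:
    """The published JSON-schema document for model files."""
    path = Path(__file__).parent / "schema" / "hierarchy.schema.json"
    return json.loads(path.read_text(encoding="utf-8"))
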