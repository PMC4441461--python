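"""Hierarchical synthesis: global objective priorities, overall alternative
scores (ideal or distributive mode), and relative-difference tables.

Global objective weights propagate multiplicatively down the tree:
global(child) = global(parent) x local(child), with the goal at 100%.  An
alternative's overall score sums, over the leaf objectives, the leaf's
global weight times the alternative's local priority on that leaf.  The two
synthesis modes differ in how the leaf-level alternative vectors enter the
sum:

* distributive — vectors normalized to sum 1; scores are proportional
  shares, but adding or removing an alternative can reverse existing ranks;
* ideal — each leaf vector is divided by its maximum first, so the best
  alternative on each leaf scores 1 there.  Designed to identify the single
  best alternative; ranks among existing alternatives are preserved when an
  alternative that is nowhere the leaf maximum is added or removed.

Score ratios ("relative differences") of at least 1.1 are treated as
meaningful, the conventional AHP significance rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AHPError
from .hierarchy import DecisionHierarchy, norm_label
from .priorities import IDEALIZED, NORMALIZED, PriorityVector

IDEAL = "ideal"
DISTRIBUTIVE = "distributive"

#: Conventional significance threshold on score ratios.
SIGNIFICANCE_RATIO = 1.1


def _lookup(locals_map: dict[str, PriorityVector], parent: str) -> PriorityVector:
    key = norm_label(parent)
    for k, v in locals_map.items():
        if norm_label(k) == key:
            return v
    raise AHPError(f"no local priority vector for comparison group {parent!r}")


def global_objective_priorities(
    h: DecisionHierarchy,
    locals_map: dict[str, PriorityVector],
) -> dict[str, float]:
    """Global weight (percent) of every objective node.

    The goal carries 100%; each child's global is its parent's global times
    its local weight within the sibling group, so every sibling partition
    sums exactly to its parent's global.  Single-child groups may be omitted
    from ``locals_map`` (the child inherits the full parent weight).
    """
    h.require_valid()
    globals_: dict[str, float] = {}

    def descend(parent_label: str, children, parent_global: float) -> None:
        if not children:
            return
        if len(children) == 1:
            local = {norm_label(children[0].name): 1.0}
        else:
            pv = _lookup(locals_map, parent_label).normalized()
            local = {norm_label(i): float(w) for i, w in zip(pv.items, pv.weights)}
        for child in children:
            key = norm_label(child.name)
            if key not in local:
                raise AHPError(
                    f"group {parent_label!r}: vector lacks item {child.name!r}"
                )
            g = parent_global * local[key]
            globals_[child.name] = g
            descend(child.name, child.children, g)

    descend(h.goal, h.objectives, 100.0)
    return globals_


@dataclass(frozen=True)
class SynthesisResult:
    """Outcome of one full synthesis run."""

    mode: str
    objective_globals: dict[str, float]  # percent of the goal
    alternative_scores: PriorityVector   # normalized to sum 1 for reporting
    leaf_locals: dict[str, PriorityVector]  # normalized per-leaf alternative priorities
    raw_scores: np.ndarray = field(repr=False, default=None)  # pre-normalization

    def ranking(self) -> list[tuple[int, str, float]]:
        """(rank, alternative, score) in display order: descending score,
        label order breaking ties.  Tied scores share the better rank."""
        pv = self.alternative_scores
        order = sorted(range(len(pv)), key=lambda k: (-pv.weights[k], pv.items[k]))
        ranks: list[tuple[int, str, float]] = []
        rank = 0
        prev_score = None
        for pos, k in enumerate(order, start=1):
            score = float(pv.weights[k])
            if prev_score is None or not np.isclose(score, prev_score, rtol=0, atol=1e-12):
                rank = pos
            ranks.append((rank, pv.items[k], score))
            prev_score = score
        return ranks

    def rank_of(self) -> dict[str, int]:
        return {label: rank for rank, label, _ in self.ranking()}


def score_alternatives(
    h: DecisionHierarchy,
    locals_map: dict[str, PriorityVector],
    mode: str = IDEAL,
) -> SynthesisResult:
    """Synthesize overall alternative scores under ``mode``.

    ``locals_map`` must hold a priority vector for every multi-item
    comparison group (objective groups and one alternative group per leaf
    objective).  Final scores are renormalized to sum 1 in both modes so
    reports and ratios share a scale; ratios are normalization-invariant.
    """
    if mode not in (IDEAL, DISTRIBUTIVE):
        raise AHPError(f"unknown synthesis mode {mode!r}")
    objective_globals = global_objective_priorities(h, locals_map)
    alts = h.alternatives
    raw = np.zeros(len(alts))
    leaf_locals: dict[str, PriorityVector] = {}
    for leaf in h.leaves():
        pv = _lookup(locals_map, leaf.name).normalized()
        if tuple(norm_label(i) for i in pv.items) != tuple(norm_label(a) for a in alts):
            raise AHPError(
                f"leaf {leaf.name!r}: alternative vector items {pv.items} do not "
                f"match the hierarchy's alternatives {alts}"
            )
        leaf_locals[leaf.name] = pv
        weight = objective_globals[leaf.name] / 100.0
        if mode == IDEAL:
            raw += weight * pv.idealized().weights
        else:
            raw += weight * pv.weights
    total = raw.sum()
    if total <= 0:
        raise AHPError("synthesis produced an all-zero score vector")
    scores = PriorityVector(alts, raw / total, NORMALIZED)
    return SynthesisResult(
        mode=mode,
        objective_globals=objective_globals,
        alternative_scores=scores,
        leaf_locals=leaf_locals,
        raw_scores=raw,
    )


@dataclass(frozen=True)
class RelativeDifferenceTable:
    """Pairwise score ratios with the conventional >= 1.1 significance rule.

    ``ratios[i, j]`` holds score_i / score_j when score_i >= score_j (the
    ratio is displayed in the larger-scoring item's row) and NaN in the
    mirror cell; the diagonal is 1.  ``significant`` is True where the
    (unrounded) stored ratio meets the threshold.  ``pair_ratio`` exposes
    the larger/smaller ratio for any pair regardless of layout.
    """

    items: tuple[str, ...]
    ratios: np.ndarray
    significant: np.ndarray
    threshold: float = SIGNIFICANCE_RATIO

    def pair_ratio(self, a: str, b: str) -> float:
        i = self._index(a)
        j = self._index(b)
        r = self.ratios[i, j]
        if np.isnan(r):
            r = self.ratios[j, i]
        return float(r)

    def is_significant(self, a: str, b: str) -> bool:
        return bool(self.pair_ratio(a, b) >= self.threshold)

    def _index(self, label: str) -> int:
        key = norm_label(label)
        for k, item in enumerate(self.items):
            if norm_label(item) == key:
                return k
        raise KeyError(label)


def relative_differences(
    scores: dict[str, float] | PriorityVector,
    threshold: float = SIGNIFICANCE_RATIO,
) -> RelativeDifferenceTable:
    """Build the triangular ratio table for a set of positive scores.

    Each stored cell is larger/smaller (hence >= 1) and is placed in the row
    of the larger-scoring item; ties are placed in the earlier item's row.
    Display rounding (2 decimals) is left to the renderer — stored ratios
    are exact.
    """
    if isinstance(scores, PriorityVector):
        items = scores.items
        values = np.asarray(scores.weights, dtype=float)
    else:
        items = tuple(scores)
        values = np.array([float(scores[k]) for k in items])
    if np.any(values <= 0):
        bad = items[int(np.argmin(values))]
        raise AHPError(f"relative differences need positive scores; {bad!r} is not")
    n = len(items)
    ratios = np.full((n, n), np.nan)
    np.fill_diagonal(ratios, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            if values[i] >= values[j]:
                ratios[i, j] = values[i] / values[j]
            else:
                ratios[j, i] = values[j] / values[i]
    significant = np.zeros((n, n), dtype=bool)
    mask = ~np.isnan(ratios)
    significant[mask] = ratios[mask] >= threshold
    return RelativeDifferenceTable(items, ratios, significant, threshold)
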