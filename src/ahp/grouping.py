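"""Group aggregation: geometric-mean priorities and expert disagreement.

A panel's group priorities are the element-wise geometric mean of the
individual experts' priority vectors, renormalized to sum 1 (the AIP route:
aggregate individual priorities, not raw judgments).  The geometric mean is
the aggregation rule consistent with the ratio-scale nature of AHP weights —
it commutes with per-expert rescaling.  Disagreement is summarized as the
per-item sample standard deviation of individual weights, in percentage
points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import AHPError
from .hierarchy import DecisionHierarchy, norm_label
from .priorities import NORMALIZED, PriorityVector
from .synthesis import IDEAL, SynthesisResult, score_alternatives

AGGREGATE_LOCALS = "locals"
AGGREGATE_SCORES = "scores"


def _check_same_items(vectors: Sequence[PriorityVector]) -> tuple[str, ...]:
    items = vectors[0].items
    keys = tuple(norm_label(i) for i in items)
    for v in vectors[1:]:
        if tuple(norm_label(i) for i in v.items) != keys:
            raise AHPError(f"item mismatch: {v.items} vs {items}")
    return items


def aggregate_priorities(vectors: Sequence[PriorityVector]) -> PriorityVector:
    """Element-wise geometric mean of the experts' vectors, renormalized.

    All vectors must cover the same ordered items with strictly positive
    weights (eigenvector priorities of positive reciprocal matrices are
    always positive, so a zero signals an upstream bug).
    """
    if len(vectors) < 1:
        raise AHPError("need at least one priority vector to aggregate")
    items = _check_same_items(vectors)
    W = np.stack([v.normalized().weights for v in vectors])
    if np.any(W <= 0):
        raise AHPError("geometric mean undefined: zero weight encountered")
    gm = np.exp(np.mean(np.log(W), axis=0))
    return PriorityVector(items, gm / gm.sum(), NORMALIZED)


def dispersion(vectors: Sequence[PriorityVector]) -> dict[str, float]:
    """Per-item sample standard deviation (n-1 denominator) of the experts'
    weights, expressed in percentage points."""
    if len(vectors) < 2:
        raise AHPError("dispersion needs at least two experts")
    items = _check_same_items(vectors)
    W = np.stack([v.normalized().weights for v in vectors]) * 100.0
    sd = np.std(W, axis=0, ddof=1)
    return {item: float(s) for item, s in zip(items, sd)}


@dataclass(frozen=True)
class GroupResult:
    """Group-level priorities and disagreement for every comparison group."""

    group_priorities: dict[str, PriorityVector]
    dispersion: dict[str, dict[str, float]]  # group key -> item -> SD (% points)
    n_experts: int


def group_synthesize(
    h: DecisionHierarchy,
    expert_locals: Sequence[dict[str, PriorityVector]],
    mode: str = IDEAL,
    aggregate: str = AGGREGATE_LOCALS,
) -> tuple[SynthesisResult, GroupResult]:
    """Aggregate a panel and synthesize once at the group level.

    ``expert_locals`` holds one complete locals map (group key -> priority
    vector) per expert.  The default aggregates local priorities per group
    (AIP on locals) and then synthesizes the group vectors; with
    ``aggregate="scores"`` each expert is synthesized individually and the
    final score vectors are geometric-mean aggregated instead (objective
    globals still come from aggregated locals).
    """
    if not expert_locals:
        raise AHPError("need at least one expert")
    if aggregate not in (AGGREGATE_LOCALS, AGGREGATE_SCORES):
        raise AHPError(f"unknown aggregation level {aggregate!r}")
    n_experts = len(expert_locals)

    keys: list[str] = []
    for g in h.comparison_groups():
        if g.requires_judgments:
            keys.append(g.key)
    group_vectors: dict[str, PriorityVector] = {}
    spreads: dict[str, dict[str, float]] = {}
    for key in keys:
        per_expert = []
        for locs in expert_locals:
            match = {norm_label(k): v for k, v in locs.items()}
            if key not in match:
                raise AHPError(f"an expert's locals are missing group {key!r}")
            per_expert.append(match[key])
        group_vectors[key] = aggregate_priorities(per_expert)
        if n_experts >= 2:
            spreads[key] = dispersion(per_expert)
        else:
            spreads[key] = {item: 0.0 for item in per_expert[0].items}

    if aggregate == AGGREGATE_LOCALS:
        result = score_alternatives(h, group_vectors, mode=mode)
    else:
        individual = [score_alternatives(h, locs, mode=mode) for locs in expert_locals]
        agg_scores = aggregate_priorities([r.alternative_scores for r in individual])
        base = score_alternatives(h, group_vectors, mode=mode)
        result = SynthesisResult(
            mode=mode,
            objective_globals=base.objective_globals,
            alternative_scores=agg_scores,
            leaf_locals=base.leaf_locals,
            raw_scores=agg_scores.weights.copy(),
        )
    return result, GroupResult(group_vectors, spreads, n_experts)
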