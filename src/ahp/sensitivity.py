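"""Weight-scenario sensitivity analysis and synthesis-mode comparison.

A scenario forces chosen objectives' local weights to fixed shares within
their sibling groups (e.g. "maximizing benefits = 100%"); the remaining
siblings split what is left in proportion to their baseline weights, and the
whole hierarchy is re-synthesized.  Overriding a node leaves its descendant
subtree's internal weights untouched — only the sibling split changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ScenarioError
from .hierarchy import DecisionHierarchy, norm_label
from .priorities import NORMALIZED, PriorityVector
from .synthesis import (
    DISTRIBUTIVE,
    IDEAL,
    SynthesisResult,
    score_alternatives,
)

_SHARE_TOL = 1e-9


@dataclass(frozen=True)
class ScenarioSpec:
    """Forced local weight shares (by objective label) plus synthesis mode."""

    overrides: dict[str, float] = field(default_factory=dict)
    mode: str = IDEAL

    def __post_init__(self) -> None:
        for label, share in self.overrides.items():
            if not (-_SHARE_TOL <= share <= 1.0 + _SHARE_TOL):
                raise ScenarioError(
                    f"override {label!r} = {share} is outside [0, 1]"
                )
        if self.mode not in (IDEAL, DISTRIBUTIVE):
            raise ScenarioError(f"unknown synthesis mode {self.mode!r}")


def _reweight_group(
    pv: PriorityVector, forced: dict[str, float], group_label: str
) -> PriorityVector:
    """Apply forced shares to one sibling group, scaling the rest
    proportionally to fill the remainder."""
    keys = [norm_label(i) for i in pv.items]
    for lab in forced:
        if lab not in keys:
            raise ScenarioError(f"override {lab!r} is not in group {group_label!r}")
    forced_total = sum(forced.values())
    if forced_total > 1.0 + _SHARE_TOL:
        raise ScenarioError(
            f"group {group_label!r}: forced shares sum to {forced_total:.6g} > 1"
        )
    w = pv.normalized().weights.copy()
    free_idx = [k for k, key in enumerate(keys) if key not in forced]
    if not free_idx and abs(forced_total - 1.0) > 1e-6:
        raise ScenarioError(
            f"group {group_label!r}: all siblings overridden but shares sum to "
            f"{forced_total:.6g}, not 1"
        )
    remainder = max(1.0 - forced_total, 0.0)
    free_sum = float(w[free_idx].sum()) if free_idx else 0.0
    new = np.empty_like(w)
    for k, key in enumerate(keys):
        if key in forced:
            new[k] = forced[key]
        elif free_sum > 0:
            new[k] = w[k] * remainder / free_sum
        else:  # baseline zeros: split the remainder evenly
            new[k] = remainder / len(free_idx)
    total = new.sum()
    if not np.isclose(total, 1.0, rtol=0, atol=1e-6):
        raise ScenarioError(f"group {group_label!r}: scenario weights sum to {total:.6g}")
    # renormalize only when needed so a no-op scenario (overrides equal to
    # the baseline weights) reproduces the baseline bit-identically
    if abs(total - 1.0) > 1e-12:
        new = new / total
    return PriorityVector(pv.items, new, NORMALIZED)


def apply_scenario(
    h: DecisionHierarchy,
    locals_map: dict[str, PriorityVector],
    spec: ScenarioSpec,
) -> SynthesisResult:
    """Re-synthesize under forced local weights.

    Each override names an objective node; its share replaces the node's
    local weight inside its sibling group.  Overriding the only child of a
    single-child group is rejected (its weight is pinned to 1 by
    normalization).  An empty override map reproduces the baseline exactly.
    """
    h.require_valid()
    parent_of = h.parent_of()
    groups = {g.key: g for g in h.comparison_groups()}

    by_group: dict[str, dict[str, float]] = {}
    for label, share in spec.overrides.items():
        key = norm_label(label)
        if key not in parent_of:
            raise ScenarioError(f"override target {label!r} is not an objective of the hierarchy")
        gkey = norm_label(parent_of[key])
        group = groups[gkey]
        if not group.requires_judgments:
            raise ScenarioError(
                f"cannot override {label!r}: its group {group.parent!r} has a "
                f"single item whose weight is fixed at 1"
            )
        by_group.setdefault(gkey, {})[key] = float(share)

    adjusted = {norm_label(k): v for k, v in locals_map.items()}
    for gkey, forced in by_group.items():
        if gkey not in adjusted:
            raise ScenarioError(f"no local vector supplied for group {groups[gkey].parent!r}")
        adjusted[gkey] = _reweight_group(adjusted[gkey], forced, groups[gkey].parent)
    return score_alternatives(h, adjusted, mode=spec.mode)


@dataclass(frozen=True)
class ModeComparison:
    """Side-by-side ideal vs distributive synthesis from identical locals."""

    ideal: SynthesisResult
    distributive: SynthesisResult
    ranks_ideal: dict[str, int]
    ranks_distributive: dict[str, int]
    agreement: bool


def compare_modes(
    h: DecisionHierarchy, locals_map: dict[str, PriorityVector]
) -> ModeComparison:
    """Synthesize both modes from the same locals and report whether the
    alternative rankings are identical."""
    res_i = score_alternatives(h, locals_map, mode=IDEAL)
    res_d = score_alternatives(h, locals_map, mode=DISTRIBUTIVE)
    ranks_i = res_i.rank_of()
    ranks_d = res_d.rank_of()
    return ModeComparison(
        ideal=res_i,
        distributive=res_d,
        ranks_ideal=ranks_i,
        ranks_distributive=ranks_d,
        agreement=ranks_i == ranks_d,
    )
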