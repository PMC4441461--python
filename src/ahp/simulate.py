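"""Synthetic expert panels for end-to-end pipeline testing.

The study design this emulates — a small panel of domain experts judging
one decision hierarchy — publishes priorities, not raw judgments.  The
generator therefore samples, for every comparison group, a latent "true"
priority vector w from a symmetric Dirichlet (one concentration knob
controls weight skew: small values give lopsided panels, large values
near-uniform ones), and gives each expert a noisy reciprocal matrix

    a_ij = (w_i / w_j) * exp(sigma * z_ij),   z_ji = -z_ij,  z ~ N(0, 1)

Antisymmetric log-normal noise preserves reciprocity exactly, and sigma
maps monotonically to the expected consistency ratio: sigma = 0 reproduces
perfectly consistent matrices whose eigenvector recovers w.  Entries can
optionally be snapped to the nearest point of the 17-value Saaty scale (in
log space, so reciprocal pairs stay reciprocal).

Randomness is reproducible and order-independent: every (expert, group)
pair gets its own stream derived from the root seed and stable label
hashes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .errors import AHPError
from .hierarchy import DecisionHierarchy, norm_label
from .judgments import (
    FREE_MODE,
    SAATY_MODE,
    JudgmentSet,
    PairwiseComparisonMatrix,
    snap_to_saaty,
)
from .priorities import NORMALIZED, PriorityVector
from .synthesis import DISTRIBUTIVE, IDEAL, SynthesisResult, score_alternatives

_TRUTH_TAG = 1
_JUDGE_TAG = 2


def _label_hash(label: str) -> int:
    return zlib.crc32(norm_label(label).encode("utf-8"))


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Configuration of one synthetic expert panel.

    Defaults mirror the emulated study design: a panel of 9 experts with
    varying perspectives (symmetric Dirichlet, concentration 1 = uniform on
    the simplex) at a mid-range judgment-noise level sigma = 0.3.
    """

    hierarchy: DecisionHierarchy
    n_experts: int = 9
    concentration: float = 1.0
    noise_sigma: float = 0.3
    snap_to_saaty: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experts < 1:
            raise AHPError(f"n_experts must be >= 1, got {self.n_experts}")
        if self.noise_sigma < 0:
            raise AHPError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.concentration <= 0:
            raise AHPError(f"concentration must be > 0, got {self.concentration}")


@dataclass(frozen=True)
class GroundTruth:
    """Latent truth behind a synthetic cohort: local priorities per group
    and the synthesis they imply."""

    locals: dict[str, PriorityVector]
    globals: dict[str, float]
    scores: dict[str, PriorityVector]  # mode -> true overall alternative scores

    def synthesis(self, mode: str) -> PriorityVector:
        return self.scores[mode]


def _noisy_matrix(
    w: np.ndarray,
    items: tuple[str, ...],
    sigma: float,
    snap: bool,
    rng: np.random.Generator,
) -> PairwiseComparisonMatrix:
    n = len(w)
    A = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a = (w[i] / w[j]) * float(np.exp(sigma * rng.standard_normal()))
            if snap:
                a = snap_to_saaty(a)
            A[i, j] = a
            A[j, i] = 1.0 / a
    return PairwiseComparisonMatrix(items, A, SAATY_MODE if snap else FREE_MODE)


def expert_ids(n_experts: int) -> list[str]:
    width = max(2, len(str(n_experts)))
    return [f"expert_{k + 1:0{width}d}" for k in range(n_experts)]


def generate_cohort(cfg: SyntheticCohortConfig) -> tuple[list[JudgmentSet], GroundTruth]:
    """Sample a panel of noisy judgment sets plus the ground truth behind it.

    Identical configs (including seed) produce identical output, regardless
    of the order groups or experts are processed in, because every stream is
    keyed by (seed, role, label hashes).
    """
    h = cfg.hierarchy.require_valid()
    groups = [g for g in h.comparison_groups()]

    truth_locals: dict[str, PriorityVector] = {}
    for g in groups:
        if not g.requires_judgments:
            truth_locals[g.key] = PriorityVector(g.items, np.array([1.0]))
            continue
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, _TRUTH_TAG, _label_hash(g.parent)])
        )
        w = rng.dirichlet(np.full(len(g.items), cfg.concentration))
        # Dirichlet mass can land arbitrarily close to 0; floor far below any
        # realistic judgment ratio to keep a_ij finite and positive.
        w = np.maximum(w, 1e-9)
        w = w / w.sum()
        truth_locals[g.key] = PriorityVector(g.items, w, NORMALIZED)

    sets: list[JudgmentSet] = []
    for expert in expert_ids(cfg.n_experts):
        judgments: dict[str, PairwiseComparisonMatrix] = {}
        for g in groups:
            if not g.requires_judgments:
                continue
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    [cfg.seed, _JUDGE_TAG, _label_hash(expert), _label_hash(g.parent)]
                )
            )
            judgments[g.key] = _noisy_matrix(
                truth_locals[g.key].weights,
                g.items,
                cfg.noise_sigma,
                cfg.snap_to_saaty,
                rng,
            )
        sets.append(JudgmentSet(expert, judgments))

    truth = GroundTruth(
        locals=truth_locals,
        globals=score_alternatives(h, truth_locals, mode=DISTRIBUTIVE).objective_globals,
        scores={
            mode: score_alternatives(h, truth_locals, mode=mode).alternative_scores
            for mode in (IDEAL, DISTRIBUTIVE)
        },
    )
    return sets, truth


@dataclass(frozen=True)
class RecoveryError:
    """How far an estimated priority vector sits from the truth."""

    mae: float
    max_abs: float
    rank_agreement: float


def recovery_error(estimated: PriorityVector, truth: PriorityVector) -> RecoveryError:
    """MAE and max-abs error between normalized weight vectors, plus the
    fraction of concordant pairwise orderings (1.0 when every pair of items
    is ordered the same way in both vectors; pairs tied in both count as
    concordant)."""
    if tuple(norm_label(i) for i in estimated.items) != tuple(
        norm_label(i) for i in truth.items
    ):
        raise AHPError(f"item mismatch: {estimated.items} vs {truth.items}")
    e = estimated.normalized().weights
    t = truth.normalized().weights
    diff = np.abs(e - t)
    n = len(e)
    if n < 2:
        agree = 1.0
    else:
        concordant = 0
        total = 0
        for i in range(n):
            for j in range(i + 1, n):
                total += 1
                if np.sign(e[i] - e[j]) == np.sign(t[i] - t[j]):
                    concordant += 1
        agree = concordant / total
    return RecoveryError(
        mae=float(diff.mean()), max_abs=float(diff.max()), rank_agreement=agree
    )
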