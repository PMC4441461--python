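"""Priority derivation and consistency diagnostics.

Local priorities are the normalized principal right eigenvector of the
judgment matrix, computed by power iteration ("matrix multiplication
method": repeatedly multiply the matrix into the current vector and
renormalize).  For a positive matrix the Perron-Frobenius theorem
guarantees a unique positive dominant eigenvector, so the iteration
converges from the uniform start.

Consistency is judged from the dominant eigenvalue: lambda_max >= n always,
with equality exactly when the judgments are transitive (a_ik = a_ij*a_jk).
The consistency index CI = (lambda_max - n)/(n - 1) is scaled by the random
index RI(n) — the expected CI of random reciprocal matrices — to give the
consistency ratio CR = CI/RI, thresholded here at 0.15.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConvergenceError, JudgmentError
from .hierarchy import DecisionHierarchy, norm_label
from .judgments import JudgmentSet, PairwiseComparisonMatrix

#: Saaty's random consistency index by matrix size.
RANDOM_INDEX = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12,
    6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49,
}

#: Judgments with CR above this are flagged inconsistent.
CR_THRESHOLD = 0.15

NORMALIZED = "normalized"
IDEALIZED = "idealized"

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class PriorityVector:
    """Nonnegative weights over ordered ``items``.

    ``convention`` is ``"normalized"`` (weights sum to 1) or ``"idealized"``
    (weights divided by their maximum, so the best item has weight 1).
    """

    items: tuple[str, ...]
    weights: np.ndarray
    convention: str = NORMALIZED

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float).copy()
        if w.shape != (len(self.items),):
            raise ValueError(f"weights shape {w.shape} does not match {len(self.items)} items")
        if np.any(w < 0):
            raise ValueError("priority weights must be nonnegative")
        if self.convention == NORMALIZED:
            if abs(w.sum() - 1.0) > _SUM_TOL:
                raise ValueError(f"normalized vector must sum to 1, got {w.sum()!r}")
        elif self.convention == IDEALIZED:
            if abs(w.max() - 1.0) > _SUM_TOL:
                raise ValueError(f"idealized vector must have max 1, got {w.max()!r}")
        else:
            raise ValueError(f"unknown convention {self.convention!r}")
        w.flags.writeable = False
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, label: str) -> float:
        key = norm_label(label)
        for item, w in zip(self.items, self.weights):
            if norm_label(item) == key:
                return float(w)
        raise KeyError(label)

    def as_dict(self) -> dict[str, float]:
        return {item: float(w) for item, w in zip(self.items, self.weights)}

    def normalized(self) -> "PriorityVector":
        if self.convention == NORMALIZED:
            return self
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("cannot normalize an all-zero vector")
        return PriorityVector(self.items, self.weights / total, NORMALIZED)

    def idealized(self) -> "PriorityVector":
        if self.convention == IDEALIZED:
            return self
        peak = self.weights.max()
        if peak <= 0:
            raise ValueError("cannot idealize an all-zero vector")
        return PriorityVector(self.items, self.weights / peak, IDEALIZED)


@dataclass(frozen=True)
class ConsistencyReport:
    """Consistency diagnostics for one judgment matrix."""

    n: int
    lambda_max: float
    ci: float
    ri: float
    cr: float
    inconsistent: bool

    @property
    def consistent(self) -> bool:
        return not self.inconsistent


def derive_priorities(
    M: PairwiseComparisonMatrix,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> tuple[PriorityVector, float]:
    """Principal right eigenvector of ``M`` by power iteration.

    Returns the normalized priority vector and lambda_max (estimated as the
    mean Rayleigh-type ratio (Mw)_i / w_i, which is exact at the fixed point
    and numerically stabler than any single component).

    Raises :class:`ConvergenceError` if the successive-iterate max-abs change
    stays above ``tol`` after ``max_iter`` multiplications.
    """
    M.require_valid()
    A = M.values
    n = M.n
    if n == 1:
        return PriorityVector(M.items, np.array([1.0])), 1.0
    w = np.full(n, 1.0 / n)
    residual = np.inf
    for _ in range(max_iter):
        nxt = A @ w
        nxt /= nxt.sum()
        residual = float(np.max(np.abs(nxt - w)))
        w = nxt
        if residual <= tol:
            break
    else:
        raise ConvergenceError(
            f"power iteration did not converge within {max_iter} iterations "
            f"(last residual {residual:.3e})",
            residual=residual,
            iterations=max_iter,
        )
    lambda_max = float(np.mean((A @ w) / w))
    return PriorityVector(M.items, w), lambda_max


def consistency_report(M: PairwiseComparisonMatrix) -> ConsistencyReport:
    """Compute lambda_max, CI, RI, CR, and the inconsistency verdict.

    CI = (lambda_max - n)/(n - 1) for n >= 2 and 0 otherwise (1x1 and 2x2
    reciprocal matrices are consistent by construction); CR = CI/RI for
    n >= 3 and 0 otherwise.  The verdict flags CR > 0.15.
    """
    _, lambda_max = derive_priorities(M)
    n = M.n
    if n <= 2:
        ci = 0.0
    else:
        ci = (lambda_max - n) / (n - 1)
    try:
        ri = RANDOM_INDEX[n]
    except KeyError:
        raise JudgmentError(f"no random index tabulated for n = {n} (max 10)") from None
    cr = ci / ri if n >= 3 else 0.0
    return ConsistencyReport(
        n=n, lambda_max=lambda_max, ci=ci, ri=ri, cr=cr,
        inconsistent=bool(cr > CR_THRESHOLD),
    )


def derive_all(
    js: JudgmentSet,
    h: DecisionHierarchy,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> dict[str, tuple[PriorityVector, ConsistencyReport]]:
    """Local priorities and consistency for every comparison group of ``h``.

    Single-item groups receive weight 1 with CI = CR = 0 and no elicited
    matrix.  Keys are normalized group parent labels.
    """
    out: dict[str, tuple[PriorityVector, ConsistencyReport]] = {}
    for g in h.comparison_groups():
        if not g.requires_judgments:
            pv = PriorityVector(g.items, np.array([1.0]))
            out[g.key] = (pv, ConsistencyReport(1, 1.0, 0.0, RANDOM_INDEX[1], 0.0, False))
            continue
        M = js.matrix_for(g.parent)
        pv, lambda_max = derive_priorities(M, tol=tol, max_iter=max_iter)
        out[g.key] = (pv, consistency_report(M))
    return out


def local_vectors(
    derived: dict[str, tuple[PriorityVector, ConsistencyReport]]
) -> dict[str, PriorityVector]:
    """Drop the consistency reports, keeping only the priority vectors."""
    return {key: pv for key, (pv, _) in derived.items()}
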