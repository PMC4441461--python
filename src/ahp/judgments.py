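"""Pairwise-comparison matrices and per-expert judgment I/O.

A judgment matrix A is square and positive with a_ii = 1 and the reciprocal
property a_ji = 1/a_ij: entry a_ij says how many times item i is preferred
to item j.  Judgment files store only the strict upper triangle (one row per
elicited question) so reciprocals can never conflict; the lower triangle is
filled automatically.  Verbal elicitation uses the Saaty 1-9 scale, but
matrices derived from direct numeric weights ("free" mode) may hold any
positive ratio.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import Finding, JudgmentError
from .hierarchy import DecisionHierarchy, norm_label

RECIPROCITY_TOL = 1e-9

SAATY_MODE = "saaty"
FREE_MODE = "free"

#: The 17-point Saaty scale: 1/9 … 1/2, 1, 2 … 9.
SAATY_VALUES = tuple(1.0 / k for k in range(9, 1, -1)) + tuple(float(k) for k in range(1, 10))

JUDGMENT_COLUMNS = ("expert_id", "parent", "row", "col", "value")


@dataclass(frozen=True)
class PairwiseComparisonMatrix:
    """A positive reciprocal judgment matrix over ordered ``items``."""

    items: tuple[str, ...]
    values: np.ndarray
    scale_mode: str = SAATY_MODE

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        n = len(self.items)
        if vals.shape != (n, n):
            raise JudgmentError(
                f"matrix shape {vals.shape} does not match {n} items"
            )
        if self.scale_mode not in (SAATY_MODE, FREE_MODE):
            raise JudgmentError(f"unknown scale_mode {self.scale_mode!r}")
        vals = vals.copy()
        vals.flags.writeable = False
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return len(self.items)

    # ------------------------------------------------------------ builders
    @classmethod
    def from_upper_triangle(
        cls,
        items: Sequence[str],
        cells: Mapping[tuple[int, int], float],
        scale_mode: str = SAATY_MODE,
    ) -> "PairwiseComparisonMatrix":
        """Build a complete matrix from strict upper-triangle cells keyed by
        (row index, col index); reciprocals and the unit diagonal are filled."""
        n = len(items)
        A = np.eye(n)
        expected = {(i, j) for i in range(n) for j in range(i + 1, n)}
        given = set(cells)
        if given - expected:
            raise JudgmentError(f"cells outside the strict upper triangle: {sorted(given - expected)}")
        missing = expected - given
        if missing:
            raise JudgmentError(f"incomplete matrix, missing cells {sorted(missing)}")
        for (i, j), v in cells.items():
            v = float(v)
            if not v > 0:
                raise JudgmentError(f"non-positive value {v} at cell ({i}, {j})")
            A[i, j] = v
            A[j, i] = 1.0 / v
        return cls(tuple(items), A, scale_mode)

    # ---------------------------------------------------------- validation
    def validate(self) -> list[Finding]:
        """Findings for positivity, unit diagonal, reciprocity, scale range."""
        findings: list[Finding] = []
        A = self.values
        n = self.n
        if np.any(A <= 0):
            i, j = map(int, np.argwhere(A <= 0)[0])
            findings.append(
                Finding("error", f"a[{i},{j}]", f"non-positive entry {A[i, j]}")
            )
            return findings
        bad_diag = np.flatnonzero(np.abs(np.diag(A) - 1.0) > RECIPROCITY_TOL)
        for i in bad_diag:
            findings.append(Finding("error", f"a[{i},{i}]", f"diagonal entry {A[i, i]} != 1"))
        recip = np.abs(A * A.T - 1.0)
        for i in range(n):
            for j in range(i + 1, n):
                if recip[i, j] > RECIPROCITY_TOL:
                    findings.append(
                        Finding(
                            "error",
                            f"a[{i},{j}]",
                            f"reciprocity violated: a_ij*a_ji = {A[i, j] * A[j, i]:.6g}",
                        )
                    )
        if self.scale_mode == SAATY_MODE:
            lo, hi = 1.0 / 9.0 - RECIPROCITY_TOL, 9.0 + RECIPROCITY_TOL
            for i in range(n):
                for j in range(n):
                    if i != j and not (lo <= A[i, j] <= hi):
                        findings.append(
                            Finding(
                                "warning",
                                f"a[{i},{j}]",
                                f"entry {A[i, j]:.6g} outside the 1/9..9 scale",
                            )
                        )
        return findings

    def require_valid(self) -> "PairwiseComparisonMatrix":
        errs = [f for f in self.validate() if f.severity == "error"]
        if errs:
            raise JudgmentError("invalid matrix: " + "; ".join(str(e) for e in errs))
        return self

    def permuted(self, order: Sequence[int]) -> "PairwiseComparisonMatrix":
        idx = np.asarray(order)
        return PairwiseComparisonMatrix(
            tuple(self.items[i] for i in idx), self.values[np.ix_(idx, idx)], self.scale_mode
        )


def validate_matrix(M: PairwiseComparisonMatrix) -> list[Finding]:
    """Module-level alias for :meth:`PairwiseComparisonMatrix.validate`."""
    return M.validate()


def matrix_from_direct_weights(
    weights: Sequence[float],
    items: Sequence[str] | None = None,
    clamp_to_saaty: bool = False,
) -> PairwiseComparisonMatrix:
    """Transform direct numeric weights into a (perfectly consistent) ratio
    matrix with a_ij = w_i / w_j.

    This is the pilot-style entry mode where participants type weights
    between 0 and 1 instead of answering pairwise questions.  The principal
    eigenvector of the result recovers the normalized input weights exactly
    and its consistency index is 0.  With ``clamp_to_saaty`` the ratios are
    clipped into [1/9, 9] (which generally breaks perfect consistency).
    """
    w = np.asarray(list(weights), dtype=float)
    if w.ndim != 1 or len(w) == 0:
        raise JudgmentError("weights must be a non-empty 1-D sequence")
    if np.any(w <= 0):
        raise JudgmentError("direct weights must be strictly positive (a_ij = w_i/w_j is undefined at 0)")
    if items is None:
        items = tuple(f"item_{k + 1}" for k in range(len(w)))
    elif len(items) != len(w):
        raise JudgmentError("items and weights length mismatch")
    A = np.outer(w, 1.0 / w)
    np.fill_diagonal(A, 1.0)
    if clamp_to_saaty:
        upper = np.triu_indices(len(w), k=1)
        clipped = np.clip(A[upper], 1.0 / 9.0, 9.0)
        A[upper] = clipped
        A[(upper[1], upper[0])] = 1.0 / clipped
        return PairwiseComparisonMatrix(tuple(items), A, SAATY_MODE)
    return PairwiseComparisonMatrix(tuple(items), A, FREE_MODE)


def snap_to_saaty(value: float) -> float:
    """Nearest value of the 17-point Saaty scale, in log space (so a ratio
    and its reciprocal snap to reciprocal scale points)."""
    if value <= 0:
        raise JudgmentError(f"cannot snap non-positive value {value}")
    grid = np.log(SAATY_VALUES)
    return float(SAATY_VALUES[int(np.argmin(np.abs(grid - np.log(value))))])


# ------------------------------------------------------------ judgment sets

@dataclass(frozen=True)
class JudgmentSet:
    """All of one expert's judgment matrices, keyed by normalized group
    parent label.  Every multi-item group of the hierarchy must be present,
    with item order matching the group."""

    expert_id: str
    judgments: dict[str, PairwiseComparisonMatrix] = field(default_factory=dict)

    def matrix_for(self, parent: str) -> PairwiseComparisonMatrix:
        key = norm_label(parent)
        if key not in self.judgments:
            raise JudgmentError(
                f"expert {self.expert_id!r} has no judgments for group {parent!r}"
            )
        return self.judgments[key]

    def check_complete(self, h: DecisionHierarchy) -> None:
        for g in h.comparison_groups():
            if not g.requires_judgments:
                continue
            M = self.matrix_for(g.parent)
            if tuple(norm_label(i) for i in M.items) != tuple(norm_label(i) for i in g.items):
                raise JudgmentError(
                    f"expert {self.expert_id!r}, group {g.parent!r}: item order "
                    f"{M.items} does not match the group's {g.items}"
                )


def _parse_value(raw) -> float:
    """Parse a judgment cell: decimal or exact fraction like ``1/7``."""
    if isinstance(raw, (int, float)) and not isinstance(raw, bool):
        return float(raw)
    text = str(raw).strip()
    try:
        if "/" in text:
            return float(Fraction(text))
        return float(text)
    except (ValueError, ZeroDivisionError) as exc:
        raise JudgmentError(f"cannot parse judgment value {raw!r}") from exc


def load_judgments(
    source: str | Path | io.TextIOBase | pd.DataFrame,
    h: DecisionHierarchy,
) -> list[JudgmentSet]:
    """Read a long-format judgment table into one :class:`JudgmentSet` per
    expert.

    Expected columns: ``expert_id,parent,row,col,value``.  Only strict
    upper-triangle cells (row before col in the group's item order) are
    accepted; the reciprocal half is derived.  A cell stated in the reverse
    orientation is a reciprocity conflict, a repeated cell is a duplicate,
    and every multi-item group must be complete for every expert.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing_cols = set(JUDGMENT_COLUMNS) - set(df.columns)
    if missing_cols:
        raise JudgmentError(f"judgment table missing columns {sorted(missing_cols)}")

    groups = {g.key: g for g in h.comparison_groups()}
    sets: list[JudgmentSet] = []
    for expert_id, expert_rows in df.groupby("expert_id", sort=False):
        judgments: dict[str, PairwiseComparisonMatrix] = {}
        for parent_raw, grp_rows in expert_rows.groupby("parent", sort=False):
            key = norm_label(str(parent_raw))
            if key not in groups:
                raise JudgmentError(
                    f"expert {expert_id!r}: unknown comparison group {parent_raw!r}"
                )
            group = groups[key]
            index = {norm_label(item): k for k, item in enumerate(group.items)}
            cells: dict[tuple[int, int], float] = {}
            for _, row in grp_rows.iterrows():
                r_lab, c_lab = str(row["row"]), str(row["col"])
                if norm_label(r_lab) not in index:
                    raise JudgmentError(
                        f"expert {expert_id!r}, group {group.parent!r}: unknown item {r_lab!r}"
                    )
                if norm_label(c_lab) not in index:
                    raise JudgmentError(
                        f"expert {expert_id!r}, group {group.parent!r}: unknown item {c_lab!r}"
                    )
                i, j = index[norm_label(r_lab)], index[norm_label(c_lab)]
                value = _parse_value(row["value"])
                if value <= 0:
                    raise JudgmentError(
                        f"expert {expert_id!r}, group {group.parent!r}: "
                        f"non-positive value {value} for {r_lab!r} vs {c_lab!r}"
                    )
                if i == j:
                    raise JudgmentError(
                        f"expert {expert_id!r}, group {group.parent!r}: "
                        f"diagonal cell {r_lab!r} vs itself is implicit and must not be stated"
                    )
                if i > j:
                    # reverse orientation: the cell belongs to the upper
                    # triangle as (j, i) with the reciprocal value
                    if (j, i) in cells:
                        raise JudgmentError(
                            f"expert {expert_id!r}, group {group.parent!r}: reciprocity "
                            f"conflict — both {c_lab!r} vs {r_lab!r} and its reverse were stated"
                        )
                    raise JudgmentError(
                        f"expert {expert_id!r}, group {group.parent!r}: cell "
                        f"{r_lab!r} vs {c_lab!r} is in the lower triangle; state the "
                        f"{c_lab!r} vs {r_lab!r} orientation instead"
                    )
                if (i, j) in cells:
                    raise JudgmentError(
                        f"expert {expert_id!r}, group {group.parent!r}: duplicate cell "
                        f"{r_lab!r} vs {c_lab!r}"
                    )
                cells[(i, j)] = value
            try:
                judgments[key] = PairwiseComparisonMatrix.from_upper_triangle(
                    group.items, cells, scale_mode=FREE_MODE
                )
            except JudgmentError as exc:
                raise JudgmentError(
                    f"expert {expert_id!r}, group {group.parent!r}: {exc}"
                ) from exc
        js = JudgmentSet(str(expert_id), judgments)
        js.check_complete(h)
        sets.append(js)
    return sets


def judgments_to_frame(sets: Iterable[JudgmentSet]) -> pd.DataFrame:
    """Long-format table (strict upper triangle only) for saving."""
    records = []
    for js in sets:
        for key, M in js.judgments.items():
            for i in range(M.n):
                for j in range(i + 1, M.n):
                    records.append(
                        {
                            "expert_id": js.expert_id,
                            "parent": key,
                            "row": M.items[i],
                            "col": M.items[j],
                            "value": repr(float(M.values[i, j])),
                        }
                    )
    return pd.DataFrame.from_records(records, columns=list(JUDGMENT_COLUMNS))


def save_judgments(sets: Iterable[JudgmentSet], path: str | Path) -> None:
    """Write judgments as CSV.  Values are written with ``repr`` so a
    load/save round trip is bit-identical on the numeric cells."""
    judgments_to_frame(sets).to_csv(path, index=False)
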