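"""Plain-text rendering of synthesis outputs: global-priority listings and
triangular relative-difference tables, as Markdown and CSV.

Display values are rounded to 2 decimals (percent for globals/scores, plain
ratios for relative differences); significant ratios (>= 1.1) are bolded in
Markdown and flagged in CSV.  Blank cells mirror the triangular layout —
each ratio appears only in the larger-scoring item's row — while the full
symmetric matrix stays available from the table object itself.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .hierarchy import DecisionHierarchy
from .synthesis import RelativeDifferenceTable, SynthesisResult


def _md_table(header: list[str], rows: list[list[str]]) -> str:
    widths = [
        max(len(str(header[c])), *(len(str(r[c])) for r in rows)) if rows else len(str(header[c]))
        for c in range(len(header))
    ]
    def fmt(cells):
        return "| " + " | ".join(str(c).ljust(w) for c, w in zip(cells, widths)) + " |"
    lines = [fmt(header), "| " + " | ".join("-" * w for w in widths) + " |"]
    lines += [fmt(r) for r in rows]
    return "\n".join(lines)


def _csv(frame: pd.DataFrame) -> str:
    buf = io.StringIO()
    frame.to_csv(buf, index=False)
    return buf.getvalue()


def render_globals(
    globals_: dict[str, float], h: DecisionHierarchy | None = None
) -> dict[str, str]:
    """Global-priority listing (percent, 2 decimals) in hierarchy order when
    ``h`` is given, else in mapping order.  Returns Markdown and CSV text."""
    if h is not None:
        order = [node.name for node in h.nodes() if node.name in globals_]
    else:
        order = list(globals_)
    rows = [[name, f"{globals_[name]:.2f}"] for name in order]
    frame = pd.DataFrame(rows, columns=["objective", "global_priority_pct"])
    return {
        "markdown": _md_table(["Objective", "Global priority, %"], rows),
        "csv": _csv(frame),
    }


def render_scores(result: SynthesisResult) -> dict[str, str]:
    """Ranked alternative scores (percent of the normalized total)."""
    rows = [
        [str(rank), label, f"{100 * score:.2f}"]
        for rank, label, score in result.ranking()
    ]
    frame = pd.DataFrame(rows, columns=["rank", "alternative", "score_pct"])
    return {
        "markdown": _md_table(["Rank", "Alternative", "Score, %"], rows),
        "csv": _csv(frame),
    }


def render_ratio_table(table: RelativeDifferenceTable) -> dict[str, str]:
    """Triangular relative-difference table.

    Markdown: the ratio sits in the larger item's row; significant cells
    (ratio >= threshold) are bolded; the mirror cells are blank.  CSV: long
    format with a ``significant`` flag.
    """
    items = table.items
    md_rows = []
    for i, row_item in enumerate(items):
        cells = [f"**{row_item}**"]
        for j in range(len(items)):
            r = table.ratios[i, j]
            if np.isnan(r):
                cells.append("")
            elif i == j:
                cells.append("1.0")
            else:
                text = f"{r:.2f}"
                cells.append(f"**{text}**" if table.significant[i, j] else text)
        md_rows.append(cells)
    records = []
    for i, row_item in enumerate(items):
        for j, col_item in enumerate(items):
            r = table.ratios[i, j]
            if i != j and not np.isnan(r):
                records.append(
                    {
                        "larger": row_item,
                        "smaller": col_item,
                        "ratio": f"{r:.2f}",
                        "significant": bool(table.significant[i, j]),
                    }
                )
    frame = pd.DataFrame.from_records(
        records, columns=["larger", "smaller", "ratio", "significant"]
    )
    return {
        "markdown": _md_table([""] + list(items), md_rows),
        "csv": _csv(frame),
    }
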