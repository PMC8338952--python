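"""Secretome classification cascade and category summaries.

Secreted proteins are assigned to exactly one secretion route by a strict
precedence cascade over predictor scores: classical secretion (UniProt
"Signal"/"Secreted" keyword or signal-peptide probability >= 0.9), then
nonclassical secretion (neural-network score >= 0.5), then membrane
shedding (>= 1 predicted transmembrane helix), then exosomal release
(exosome catalogue membership), else unclassified. The precedence order is
configurable; categories are always mutually exclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import pandas as pd

__all__ = [
    "CATEGORIES",
    "Thresholds",
    "classify_protein",
    "classify_table",
    "summarize_categories",
]

CATEGORIES: Tuple[str, ...] = (
    "classical",
    "nonclassical",
    "membrane",
    "exosome",
    "unclassified",
)

SCORE_COLUMNS = (
    "keyword_secreted",
    "signalp_score",
    "nnscore",
    "tm_helix_count",
    "exocarta_member",
)


@dataclass(frozen=True)
class Thresholds:
    """Score cut-offs for the cascade (inclusive, >= semantics)."""

    signalp_min: float = 0.9
    nnscore_min: float = 0.5


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def classify_protein(
    keyword_secreted: bool,
    signalp_score: float | None,
    nnscore: float | None,
    tm_helix_count: int,
    exocarta_member: bool,
    thresholds: Thresholds = Thresholds(),
    precedence: Sequence[str] = CATEGORIES[:4],
) -> str:
    """Assign one secretion category by the precedence cascade.

    Missing predictor scores are treated as below threshold; scores exactly
    at a threshold pass (>= semantics).
    """
    signalp = 0.0 if _is_missing(signalp_score) else float(signalp_score)
    nn = 0.0 if _is_missing(nnscore) else float(nnscore)
    tests = {
        "classical": bool(keyword_secreted) or signalp >= thresholds.signalp_min,
        "nonclassical": nn >= thresholds.nnscore_min,
        "membrane": int(tm_helix_count) >= 1,
        "exosome": bool(exocarta_member),
    }
    for category in precedence:
        if tests[category]:
            return category
    return "unclassified"


def classify_table(
    annotations: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
    precedence: Sequence[str] = CATEGORIES[:4],
) -> pd.DataFrame:
    """Classify every row of a predictor-score table.

    Requires the columns ``keyword_secreted``, ``signalp_score``,
    ``nnscore``, ``tm_helix_count`` and ``exocarta_member``; returns a copy
    with a ``category`` column appended.
    """
    missing = [c for c in SCORE_COLUMNS if c not in annotations.columns]
    if missing:
        raise ValueError(f"annotation table lacks columns: {missing}")
    out = annotations.copy()
    out["category"] = [
        classify_protein(
            row.keyword_secreted,
            row.signalp_score,
            row.nnscore,
            row.tm_helix_count,
            row.exocarta_member,
            thresholds=thresholds,
            precedence=precedence,
        )
        for row in annotations.itertuples(index=False)
    ]
    return out


def summarize_categories(classified: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per category plus the combined secreted fraction.

    Returns one row per category (in cascade order) with ``count`` and
    ``percentage`` over all quantified proteins, and a final ``secreted``
    row whose fraction is 1 minus the unclassified fraction.
    """
    if "category" not in classified.columns:
        raise ValueError("table has no 'category' column; classify first")
    total = len(classified)
    counts = classified["category"].value_counts()
    rows = []
    for category in CATEGORIES:
        c = int(counts.get(category, 0))
        rows.append(
            {
                "category": category,
                "count": c,
                "percentage": 100.0 * c / total if total else 0.0,
            }
        )
    secreted = total - int(counts.get("unclassified", 0))
    rows.append(
        {
            "category": "secreted",
            "count": secreted,
            "percentage": 100.0 * secreted / total if total else 0.0,
        }
    )
    return pd.DataFrame(rows)
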