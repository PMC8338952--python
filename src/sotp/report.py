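"""Coverage summaries: panel coverage, sharing distributions, organ classes.

Gene-centric throughout: protein groups are collapsed to gene identifiers
before set operations. Reported percentages are rounded to integers for
display, with full precision retained alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import pandas as pd

from .panel import EvidencePanel

__all__ = [
    "CategoryGeneSet",
    "SharingDistribution",
    "sotp_coverage",
    "sharing_distribution",
    "organ_class_coverage",
]


@dataclass
class CategoryGeneSet:
    """A named functional or organ-class gene set (members may overlap)."""

    name: str
    members: Set[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("category name must be non-empty")
        self.members = {str(g) for g in self.members}


@dataclass
class SharingDistribution:
    """How many cell lines each quantified category gene was seen in."""

    category: str
    counts_by_n_lines: Dict[int, int]
    quantified_total: int

    def __post_init__(self) -> None:
        if sum(self.counts_by_n_lines.values()) != self.quantified_total:
            raise ValueError("sharing counts must sum to the quantified total")

    @property
    def fraction_in_all(self) -> float:
        if self.quantified_total == 0:
            return 0.0
        n_max = max(self.counts_by_n_lines)
        return self.counts_by_n_lines[n_max] / self.quantified_total


def sotp_coverage(
    quantified: Iterable[str], panel: EvidencePanel
) -> Tuple[int, float, int]:
    """Panel coverage by the quantified gene set.

    Returns ``(count, percentage, rounded_percentage)`` where count is the
    overlap with the panel, percentage is 100 * count / |panel| at full
    precision and the rounded value matches display convention.
    """
    if len(panel) == 0:
        raise ValueError("panel is empty; coverage undefined")
    q = {str(g) for g in quantified}
    count = len(q & set(panel.members))
    pct = 100.0 * count / len(panel)
    return count, pct, round(pct)


def sharing_distribution(
    per_line_quantified: Mapping[str, Iterable[str]],
    category: CategoryGeneSet,
) -> SharingDistribution:
    """Tally, per category gene quantified anywhere, its number of lines."""
    if not per_line_quantified:
        raise ValueError("need at least one cell line")
    line_sets = {line: {str(g) for g in genes} for line, genes in per_line_quantified.items()}
    n_lines = len(line_sets)
    counts = {k: 0 for k in range(1, n_lines + 1)}
    total = 0
    for gene in category.members:
        n = sum(1 for s in line_sets.values() if gene in s)
        if n > 0:
            counts[n] += 1
            total += 1
    return SharingDistribution(
        category=category.name, counts_by_n_lines=counts, quantified_total=total
    )


def organ_class_coverage(
    quantified: Iterable[str],
    organ_sets: Sequence[CategoryGeneSet],
) -> Tuple[pd.DataFrame, float]:
    """Coverage of each organ-class gene set and the unweighted mean.

    Empty organ sets are skipped with a warning. Returns a per-organ table
    (count, set size, percentage) and the mean percentage across organ
    classes.
    """
    q = {str(g) for g in quantified}
    rows: List[Dict] = []
    for organ in organ_sets:
        if not organ.members:
            warnings.warn(f"organ set {organ.name!r} is empty; skipped", stacklevel=2)
            continue
        count = len(q & organ.members)
        rows.append(
            {
                "organ_class": organ.name,
                "covered": count,
                "set_size": len(organ.members),
                "percentage": 100.0 * count / len(organ.members),
            }
        )
    if not rows:
        raise ValueError("no non-empty organ sets provided")
    table = pd.DataFrame(rows)
    return table, float(table["percentage"].mean())
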