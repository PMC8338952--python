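"""Cell-line panel selection by greedy maximum coverage of expressed genes.

Expression is first quantile-normalized so every cell line's 70th percentile
equals a fixed target (FPKQ units, target 10), genes with FPKQ >= 1 are
called expressed, and cell lines are then ranked by iteratively adding the
line that covers the most not-yet-covered target genes. Greedy maximum
coverage carries the classic (1 - 1/e) approximation guarantee; a brute-force
optimizer over all k-subsets is provided as a test oracle for small
instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "CoverageTrajectory",
    "quantile_normalize",
    "binarize_expressed",
    "greedy_select",
    "brute_force_select",
    "select_panel",
]


@dataclass
class CoverageTrajectory:
    """Ordered cell-line ranking with cumulative target-gene coverage."""

    ordered_lines: List[str]
    cumulative_covered: List[int]
    target_size: int
    missing_genes: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ordered_lines) != len(self.cumulative_covered):
            raise ValueError("trajectory lists must have equal length")
        if any(
            b < a for a, b in zip(self.cumulative_covered, self.cumulative_covered[1:])
        ):
            raise ValueError("cumulative coverage must be non-decreasing")

    @property
    def cumulative_fraction(self) -> List[float]:
        if self.target_size == 0:
            return [0.0 for _ in self.cumulative_covered]
        return [c / self.target_size for c in self.cumulative_covered]

    def to_frame(self) -> pd.DataFrame:
        newly = [self.cumulative_covered[0]] + [
            b - a
            for a, b in zip(self.cumulative_covered, self.cumulative_covered[1:])
        ]
        return pd.DataFrame(
            {
                "rank": range(1, len(self.ordered_lines) + 1),
                "cell_line": self.ordered_lines,
                "new_genes": newly,
                "cumulative": self.cumulative_covered,
                "fraction": self.cumulative_fraction,
            }
        )


def quantile_normalize(
    matrix: pd.DataFrame, percentile: float = 70.0, target: float = 10.0
) -> pd.DataFrame:
    """Scale each cell-line column so its given percentile equals ``target``.

    The percentile uses linear interpolation between order statistics
    (numpy's default, the "type 7" rule). Columns whose percentile is zero
    have an undefined scale and raise an error naming the column.

    Parameters
    ----------
    matrix
        Genes as rows, cell lines as columns, non-negative values.
    """
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("expression values must be non-negative")
    q = np.percentile(values, percentile, axis=0)
    zero_cols = [str(c) for c, qc in zip(matrix.columns, q) if qc == 0.0]
    if zero_cols:
        raise ValueError(
            f"cannot normalize: {percentile}th percentile is 0 for column(s) "
            f"{zero_cols}"
        )
    scaled = values * (target / q)
    return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns)


def binarize_expressed(matrix: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Expressed-gene indicator: value >= threshold (inclusive)."""
    return matrix.ge(threshold)


def _prepare_target(
    binary: pd.DataFrame, target_genes: Iterable[str]
) -> Tuple[Set[str], List[str]]:
    target = {str(g) for g in target_genes}
    if not target:
        raise ValueError("target gene set is empty")
    present = set(map(str, binary.index))
    missing = sorted(target - present)
    return target & present, missing


def greedy_select(
    binary: pd.DataFrame,
    target_genes: Iterable[str],
    k: int,
    include_missing_in_denominator: bool = False,
) -> CoverageTrajectory:
    """Greedy maximum-coverage ranking of cell lines for a target gene set.

    At each step the cell line adding the most not-yet-covered target genes
    is selected; ties are broken lexicographically by cell-line identifier,
    so the result is deterministic and invariant to column order. Target
    genes absent from the matrix can never be covered; they are reported on
    the trajectory and excluded from the denominator unless
    ``include_missing_in_denominator`` is set.
    """
    if k > binary.shape[1]:
        raise ValueError(f"k={k} exceeds number of cell lines {binary.shape[1]}")
    target, missing = _prepare_target(binary, target_genes)
    target_size = len(target) + (len(missing) if include_missing_in_denominator else 0)

    gene_in_target = np.array([str(g) in target for g in binary.index])
    mat = binary.to_numpy(dtype=bool)[gene_in_target]
    lines = [str(c) for c in binary.columns]
    order = np.argsort(lines, kind="stable")  # lexicographic tie-break

    covered = np.zeros(mat.shape[0], dtype=bool)
    chosen: List[str] = []
    chosen_idx: Set[int] = set()
    cumulative: List[int] = []
    for _ in range(k):
        best_gain, best_col = -1, -1
        for col in order:
            if col in chosen_idx:
                continue
            gain = int(np.count_nonzero(mat[:, col] & ~covered))
            if gain > best_gain:
                best_gain, best_col = gain, int(col)
        chosen_idx.add(best_col)
        chosen.append(lines[best_col])
        covered |= mat[:, best_col]
        cumulative.append(int(covered.sum()))
    return CoverageTrajectory(
        ordered_lines=chosen,
        cumulative_covered=cumulative,
        target_size=target_size,
        missing_genes=missing,
    )


def brute_force_select(
    binary: pd.DataFrame,
    target_genes: Iterable[str],
    k: int,
    budget: int = 10**6,
) -> int:
    """Exact maximum target coverage over all k-subsets of cell lines.

    Test oracle for the greedy heuristic; exhaustive search is only feasible
    on small instances, so the combinatorial budget is enforced.
    """
    n = binary.shape[1]
    if k > n:
        raise ValueError(f"k={k} exceeds number of cell lines {n}")
    if comb(n, k) > budget:
        raise ValueError(f"C({n},{k}) exceeds the combinatorial budget {budget}")
    if k == 0:
        return 0
    target, _ = _prepare_target(binary, target_genes)
    gene_in_target = np.array([str(g) in target for g in binary.index])
    mat = binary.to_numpy(dtype=bool)[gene_in_target]
    best = 0
    for cols in combinations(range(n), k):
        cov = int(mat[:, cols].any(axis=1).sum())
        if cov > best:
            best = cov
    return best


@dataclass
class PanelSelection:
    """Union of the top-k lines for the off-target panel and whole proteome."""

    panel: List[str]
    sotp_trajectory: CoverageTrajectory
    whole_trajectory: CoverageTrajectory


def select_panel(
    binary: pd.DataFrame,
    sotp_genes: Iterable[str],
    all_genes: Iterable[str],
    k_each: int = 3,
) -> PanelSelection:
    """Select the experimental cell-line panel.

    Runs the greedy ranking once against the off-target panel genes and once
    against the whole protein-coding set, and returns the union of the two
    top-``k_each`` lists (sorted, deduplicated) with both trajectories
    attached. With the default ``k_each=3`` two rankings sharing two lines
    yield a four-line panel.
    """
    if k_each == 0:
        empty = CoverageTrajectory([], [], 0)
        return PanelSelection(panel=[], sotp_trajectory=empty, whole_trajectory=empty)
    sotp_traj = greedy_select(binary, sotp_genes, k_each)
    whole_traj = greedy_select(binary, all_genes, k_each)
    panel = sorted(set(sotp_traj.ordered_lines) | set(whole_traj.ordered_lines))
    return PanelSelection(
        panel=panel, sotp_trajectory=sotp_traj, whole_trajectory=whole_traj
    )
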