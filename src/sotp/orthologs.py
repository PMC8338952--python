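"""Cross-species ortholog similarity from global protein alignments.

Each human protein is aligned globally (Needleman-Wunsch with affine gap
penalties, Gotoh's three-state recursion) against its ortholog in a
nonclinical species, and similarity is the fraction of alignment columns
with identical residues. The score lies in [0, 1]: 1 for an identical
alignment, and 0 is reserved for "ortholog not found". Gap columns count
toward the alignment length, so indels penalize similarity.

The default scoring scheme is BLOSUM62 with affine gaps (open -10,
extend -0.5), a common default for global protein alignment; a simple
linear scheme is available for oracle testing. The scheme must be pinned
because the similarity value depends on which optimal alignment is
produced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

__all__ = [
    "AMINO_ACIDS",
    "AlignmentResult",
    "ScoringScheme",
    "SimilarityRecord",
    "needleman_wunsch",
    "similarity_score",
    "similarity_records",
    "species_summary",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

_NEG_INF = float("-inf")


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring: substitution values plus affine gap penalties.

    ``gap_open`` is the cost of the first residue of a gap and
    ``gap_extend`` the cost of each further residue, so a gap of length L
    costs ``gap_open + (L - 1) * gap_extend``. A linear scheme is obtained
    with ``gap_open == gap_extend``.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -1.0
    gap_extend: float = -1.0
    matrix_name: Optional[str] = None  # e.g. "BLOSUM62"; overrides match/mismatch

    def substitution(self) -> Dict[Tuple[str, str], float]:
        table: Dict[Tuple[str, str], float] = {}
        if self.matrix_name is not None:
            mat = substitution_matrices.load(self.matrix_name)
            for x in AMINO_ACIDS:
                for y in AMINO_ACIDS:
                    table[(x, y)] = float(mat[x, y])
        else:
            for x in AMINO_ACIDS:
                for y in AMINO_ACIDS:
                    table[(x, y)] = self.match if x == y else self.mismatch
        return table

    @classmethod
    def default(cls) -> "ScoringScheme":
        return cls(gap_open=-10.0, gap_extend=-0.5, matrix_name="BLOSUM62")

    @classmethod
    def linear(cls, match: float = 1.0, mismatch: float = -1.0, gap: float = -1.0) -> "ScoringScheme":
        return cls(match=match, mismatch=mismatch, gap_open=gap, gap_extend=gap)


@dataclass
class AlignmentResult:
    """A global alignment: gapped sequences plus identity bookkeeping."""

    aligned_a: str
    aligned_b: str
    n_identical: int
    alignment_length: int
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned sequences must have equal length")
        if len(self.aligned_a) != self.alignment_length:
            raise ValueError("alignment_length inconsistent with aligned sequences")
        if not 0 <= self.n_identical <= self.alignment_length:
            raise ValueError("n_identical out of range")


@dataclass
class SimilarityRecord:
    """Per-(human protein, species) similarity outcome."""

    human_id: str
    species: str
    similarity: float
    ortholog_found: bool

    def __post_init__(self) -> None:
        if not self.ortholog_found and self.similarity != 0.0:
            raise ValueError("similarity must be 0 when the ortholog is not found")
        if not 0.0 <= self.similarity <= 1.0:
            raise ValueError("similarity must lie in [0, 1]")


def _check_sequence(seq: str, name: str) -> None:
    for ch in seq:
        if ch not in _AA_SET:
            raise ValueError(f"illegal residue {ch!r} in sequence {name}")


# Traceback states. Preference order on ties: diagonal, then up (gap in b),
# then left (gap in a).
_DIAG, _UP, _LEFT = 0, 1, 2


def needleman_wunsch(
    a: str,
    b: str,
    scoring: ScoringScheme | Tuple[float, float, float, float] | None = None,
) -> AlignmentResult:
    """Optimal global alignment of two protein sequences.

    Uses Gotoh's affine-gap dynamic program. Traceback tie-breaking is
    deterministic: diagonal moves are preferred over up moves (gap in
    ``b``) over left moves (gap in ``a``), both for the final state and at
    every step.

    Parameters
    ----------
    a, b
        Sequences over the 20 standard amino acids.
    scoring
        A :class:`ScoringScheme`, or a ``(match, mismatch, gap_open,
        gap_extend)`` tuple; defaults to BLOSUM62 with affine gaps
        (open -10, extend -0.5).
    """
    if scoring is None:
        scoring = ScoringScheme.default()
    elif isinstance(scoring, tuple):
        scoring = ScoringScheme(*scoring)
    if not a and not b:
        raise ValueError("both sequences are empty; alignment undefined")
    _check_sequence(a, "a")
    _check_sequence(b, "b")

    sub = scoring.substitution()
    go, ge = scoring.gap_open, scoring.gap_extend
    m, n = len(a), len(b)

    # State matrices: M ends in a diagonal move, X in an up move (gap in b),
    # Y in a left move (gap in a).
    M = np.full((m + 1, n + 1), _NEG_INF)
    X = np.full((m + 1, n + 1), _NEG_INF)
    Y = np.full((m + 1, n + 1), _NEG_INF)
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        X[i, 0] = go + (i - 1) * ge
    for j in range(1, n + 1):
        Y[0, j] = go + (j - 1) * ge

    for i in range(1, m + 1):
        ai = a[i - 1]
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        for j in range(1, n + 1):
            s = sub[(ai, b[j - 1])]
            Mi[j] = s + max(Mi1[j - 1], Xi1[j - 1], Yi1[j - 1])
            Xi[j] = max(Mi1[j] + go, Xi1[j] + ge, Yi1[j] + go)
            Yi[j] = max(Mi[j - 1] + go, Xi[j - 1] + go, Yi[j - 1] + ge)

    finals = (M[m, n], X[m, n], Y[m, n])
    score = max(finals)
    state = min(s for s in (_DIAG, _UP, _LEFT) if finals[s] == score)

    out_a: List[str] = []
    out_b: List[str] = []
    i, j = m, n
    tol = 1e-9
    while i > 0 or j > 0:
        if state == _DIAG:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            s = sub[(a[i - 1], b[j - 1])]
            target = M[i, j] - s
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            cands = (M[i, j], X[i, j], Y[i, j])
        elif state == _UP:
            out_a.append(a[i - 1])
            out_b.append("-")
            target = X[i, j]
            i -= 1
            if i == 0 and j == 0:
                break
            cands = (M[i, j] + go, X[i, j] + ge, Y[i, j] + go)
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            target = Y[i, j]
            j -= 1
            if i == 0 and j == 0:
                break
            cands = (M[i, j] + go, X[i, j] + go, Y[i, j] + ge)
        state = min(s for s in (_DIAG, _UP, _LEFT) if abs(cands[s] - target) <= tol)

    out_a.reverse()
    out_b.reverse()
    aligned_a = "".join(out_a)
    aligned_b = "".join(out_b)
    n_identical = sum(1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-")
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        n_identical=n_identical,
        alignment_length=len(aligned_a),
        score=float(score),
    )


def similarity_score(alignment: AlignmentResult) -> float:
    """Identical residues divided by total alignment length (gaps included)."""
    if alignment.alignment_length == 0:
        raise ValueError("zero-length alignment has no similarity score")
    return alignment.n_identical / alignment.alignment_length


def similarity_records(
    pairs: Iterable[Tuple[str, str, Optional[str], str]],
    scoring: ScoringScheme | None = None,
    aggregate: str = "max",
) -> List[SimilarityRecord]:
    """Score a collection of (human_id, human_seq, ortholog_seq, species).

    ``ortholog_seq`` of ``None`` marks an ortholog not found (similarity 0).
    When several orthologs exist for the same (human, species) pair the
    ``aggregate`` rule keeps the maximum similarity (default) or the first
    encountered.
    """
    if aggregate not in ("max", "first"):
        raise ValueError("aggregate must be 'max' or 'first'")
    best: Dict[Tuple[str, str], SimilarityRecord] = {}
    for human_id, human_seq, ortho_seq, species in pairs:
        if ortho_seq is None:
            rec = SimilarityRecord(human_id, species, 0.0, False)
        else:
            aln = needleman_wunsch(human_seq, ortho_seq, scoring)
            rec = SimilarityRecord(human_id, species, similarity_score(aln), True)
        key = (human_id, species)
        if key not in best:
            best[key] = rec
        elif aggregate == "max" and rec.similarity > best[key].similarity:
            best[key] = rec
    return list(best.values())


def species_summary(
    records: Sequence[SimilarityRecord],
    include_missing: bool = False,
) -> pd.DataFrame:
    """Per-species distribution summary (n, median, quartiles).

    Missing-ortholog records (similarity 0 by convention) are excluded
    unless ``include_missing`` is set.
    """
    if not records:
        raise ValueError("no similarity records to summarize")
    rows = [
        {"species": r.species, "similarity": r.similarity}
        for r in records
        if include_missing or r.ortholog_found
    ]
    df = pd.DataFrame(rows)
    out = (
        df.groupby("species")["similarity"]
        .agg(
            n="count",
            q1=lambda s: float(np.percentile(s, 25)),
            median="median",
            q3=lambda s: float(np.percentile(s, 75)),
        )
        .reset_index()
    )
    return out
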