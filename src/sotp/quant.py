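"""Post-search label-free quantification: filtering, MaxLFQ-lite and iBAQ.

Starts from searched peptide/protein tables (MaxQuant dialect). The
MaxLFQ-lite reconstruction follows the published scheme: for every sample
pair, the protein's log ratio is the median of peptide log ratios over
peptides observed in both samples; the per-sample relative abundance
profile is then the least-squares solution of that pairwise ratio system,
anchored so the summed profile intensity equals the summed raw peptide
intensity. iBAQ divides summed intensity by the number of theoretical
tryptic peptides, making values proportional to molar amounts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "SampleDesign",
    "filter_protein_groups",
    "log2_transform",
    "maxlfq_lite",
    "count_theoretical_peptides",
    "digest_tryptic",
    "ibaq",
    "dynamic_range",
]

logger = logging.getLogger(__name__)


@dataclass
class SampleDesign:
    """Maps MS samples to cell lines and replicate indices."""

    sample_ids: List[str]
    cell_line_of: Dict[str, str]
    replicate_of: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [s for s in self.sample_ids if s not in self.cell_line_of]
        if missing:
            raise ValueError(f"samples without a cell line assignment: {missing}")
        if not self.replicate_of:
            seen: Dict[str, int] = {}
            for s in self.sample_ids:
                line = self.cell_line_of[s]
                seen[line] = seen.get(line, 0) + 1
                self.replicate_of[s] = seen[line]

    @property
    def cell_lines(self) -> List[str]:
        out: List[str] = []
        for s in self.sample_ids:
            line = self.cell_line_of[s]
            if line not in out:
                out.append(line)
        return out

    def samples_of(self, cell_line: str) -> List[str]:
        return [s for s in self.sample_ids if self.cell_line_of[s] == cell_line]


FLAG_COLUMNS = ("is_contaminant", "is_reverse", "only_by_site")


def filter_protein_groups(
    records: pd.DataFrame,
    design: SampleDesign,
    min_unique: int = 1,
    min_valid: int = 2,
    lfq_prefix: str = "LFQ intensity ",
) -> pd.DataFrame:
    """Apply the standard protein-group quality filters.

    Drops contaminants, decoy (reverse) hits and groups identified only by
    a site modification; keeps groups with at least ``min_unique`` unique
    peptides and at least ``min_valid`` non-missing LFQ values within at
    least one cell line.
    """
    lfq_cols = {s: f"{lfq_prefix}{s}" for s in design.sample_ids}
    missing_cols = [c for c in lfq_cols.values() if c not in records.columns]
    if missing_cols:
        raise ValueError(f"records lack LFQ columns for design samples: {missing_cols}")
    short = [
        line for line in design.cell_lines if len(design.samples_of(line)) < min_valid
    ]
    if short:
        raise ValueError(
            f"cell line(s) {short} have fewer than min_valid={min_valid} replicates"
        )
    keep = pd.Series(True, index=records.index)
    for flag in FLAG_COLUMNS:
        if flag in records.columns:
            keep &= ~records[flag].fillna(False).astype(bool)
    if "unique_peptide_count" in records.columns:
        keep &= records["unique_peptide_count"] >= min_unique
    valid_somewhere = pd.Series(False, index=records.index)
    for line in design.cell_lines:
        cols = [lfq_cols[s] for s in design.samples_of(line)]
        valid_somewhere |= records[cols].notna().sum(axis=1) >= min_valid
    keep &= valid_somewhere
    return records.loc[keep].copy()


def log2_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2 of positive intensities; missing stays missing."""
    values = matrix.to_numpy(dtype=float)
    observed = ~np.isnan(values)
    if (values[observed] <= 0).any():
        raise ValueError("intensities must be positive for log2 transform")
    out = np.full_like(values, np.nan)
    out[observed] = np.log2(values[observed])
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _solve_profile(log2_peps: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Reconstruct a relative log2 profile from one protein's peptide matrix.

    ``log2_peps`` is peptides x samples with NaN for missing. Returns the
    least-squares log2 profile (mean-anchored per connected component, NaN
    for samples connected to no other sample) and the component label of
    each sample.
    """
    n_samples = log2_peps.shape[1]
    observed = ~np.isnan(log2_peps)
    pairs: List[Tuple[int, int, float]] = []
    for i in range(n_samples):
        for j in range(i + 1, n_samples):
            shared = observed[:, i] & observed[:, j]
            if shared.any():
                ratio = float(np.median(log2_peps[shared, i] - log2_peps[shared, j]))
                pairs.append((i, j, ratio))
    profile = np.full(n_samples, np.nan)
    if not pairs:
        return profile, np.arange(n_samples)
    rows = [p[0] for p in pairs] + [p[1] for p in pairs]
    cols = [p[1] for p in pairs] + [p[0] for p in pairs]
    graph = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_samples, n_samples)
    )
    n_comp, labels = connected_components(graph, directed=False)
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        if len(members) < 2:
            continue
        local = {s: k for k, s in enumerate(members)}
        A_rows, b = [], []
        for i, j, ratio in pairs:
            if labels[i] == comp:
                row = np.zeros(len(members))
                row[local[i]] = 1.0
                row[local[j]] = -1.0
                A_rows.append(row)
                b.append(ratio)
        A = np.array(A_rows)
        x, *_ = np.linalg.lstsq(A, np.array(b), rcond=None)
        profile[members] = x - x.mean()  # relative profile; anchored later
    return profile, labels


def maxlfq_lite(
    peptides: pd.DataFrame,
    sample_ids: Sequence[str],
    protein_column: str = "Proteins",
    intensity_prefix: str = "Intensity ",
) -> pd.DataFrame:
    """MaxLFQ-style protein profiles from a peptide intensity table.

    For each protein, pairwise sample log-ratios are taken as medians of
    shared-peptide log-ratios (minimum one shared peptide per pair), the
    profile is reconstructed by least squares over that ratio system, and
    the result is anchored so the summed profile intensity equals the
    protein's summed raw peptide intensity within each connected component
    of samples. Samples sharing no peptide pair with any other sample get
    missing values. Proteins with zero quantified peptides are skipped with
    a log entry.

    Returns proteins x samples intensities on the linear scale.
    """
    cols = [f"{intensity_prefix}{s}" for s in sample_ids]
    missing_cols = [c for c in cols if c not in peptides.columns]
    if missing_cols:
        raise ValueError(f"peptide table lacks intensity columns: {missing_cols}")
    profiles = {}
    for protein, chunk in peptides.groupby(protein_column, sort=True):
        raw = chunk[cols].to_numpy(dtype=float)
        observed = ~np.isnan(raw)
        if not observed.any():
            logger.info("protein %s has no quantified peptides; skipped", protein)
            continue
        with np.errstate(divide="ignore"):
            log2_peps = np.where(observed, np.log2(np.where(observed, raw, 1.0)), np.nan)
        rel, labels = _solve_profile(log2_peps)
        out = np.full(len(sample_ids), np.nan)
        for comp in np.unique(labels):
            members = np.flatnonzero((labels == comp) & ~np.isnan(rel))
            if members.size == 0:
                continue
            lin = 2.0 ** rel[members]
            total_raw = np.nansum(raw[:, members])
            out[members] = lin * (total_raw / lin.sum())
        profiles[protein] = out
    return pd.DataFrame.from_dict(
        profiles, orient="index", columns=list(sample_ids)
    ).rename_axis("protein")


def digest_tryptic(sequence: str) -> List[str]:
    """Fully tryptic fragments: cleave after K or R except before P.

    Zero missed cleavages; returns the fragments in order.
    """
    if not sequence:
        raise ValueError("empty protein sequence")
    fragments: List[str] = []
    start = 0
    for i, residue in enumerate(sequence):
        at_end = i == len(sequence) - 1
        if residue in "KR" and not at_end and sequence[i + 1] != "P":
            fragments.append(sequence[start : i + 1])
            start = i + 1
    fragments.append(sequence[start:])
    return fragments


def count_theoretical_peptides(
    sequence: str, min_len: int = 6, max_len: int = 30
) -> int:
    """Number of theoretical tryptic peptides with length in [min_len, max_len]."""
    return sum(1 for f in digest_tryptic(sequence) if min_len <= len(f) <= max_len)


def ibaq(
    records: pd.DataFrame,
    sample_ids: Sequence[str],
    intensity_prefix: str = "Intensity ",
    sequence_column: str = "sequence",
    min_len: int = 6,
    max_len: int = 30,
) -> pd.DataFrame:
    """iBAQ values: summed intensity divided by theoretical peptide count.

    Returns one column per sample plus an ``iBAQ total`` column over the
    summed intensities. Proteins with zero theoretical peptides get missing
    iBAQ with a warning.
    """
    cols = [f"{intensity_prefix}{s}" for s in sample_ids]
    missing_cols = [c for c in cols if c not in records.columns]
    if missing_cols:
        raise ValueError(f"records lack intensity columns: {missing_cols}")
    if sequence_column not in records.columns:
        raise ValueError(f"records lack the sequence column {sequence_column!r}")
    n_theoretical = records[sequence_column].map(
        lambda s: count_theoretical_peptides(s, min_len, max_len)
    )
    zero = n_theoretical == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} protein(s) have no theoretical peptides in "
            f"[{min_len}, {max_len}]; iBAQ set to missing",
            stacklevel=2,
        )
    denom = n_theoretical.replace(0, np.nan).astype(float)
    out = records[cols].div(denom, axis=0)
    out.columns = [f"iBAQ {s}" for s in sample_ids]
    out["iBAQ total"] = records[cols].sum(axis=1, min_count=1) / denom
    out.index = records.index
    return out


def dynamic_range(values: Iterable[float]) -> float:
    """Orders of magnitude spanned: log10(max) - log10(min) over positives."""
    arr = np.asarray([v for v in values if not np.isnan(v)], dtype=float)
    if arr.size < 2:
        raise ValueError("dynamic range needs at least two quantified values")
    if (arr <= 0).any():
        raise ValueError("dynamic range requires positive values")
    return float(np.log10(arr.max()) - np.log10(arr.min()))
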