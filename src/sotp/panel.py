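"""Selected off-target proteome (SOTP) construction from evidence tables.

The panel is the union of genes carrying genetic or pharmacological evidence
restricted to safety-relevant MedDRA System Organ Classes (SOCs), decomposed
by evidence source into genetic-only, pharmacological-only and dual-evidence
members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Set, Tuple

import pandas as pd

__all__ = [
    "DEFAULT_IN_SCOPE_SOCS",
    "EvidencePanel",
    "filter_by_soc",
    "select_sotp",
    "venn_decompose",
]

#: MedDRA System Organ Classes considered safety-relevant by default:
#: heart, vascular, nervous, respiratory and mental systems.
DEFAULT_IN_SCOPE_SOCS: FrozenSet[str] = frozenset(
    {
        "Cardiac disorders",
        "Vascular disorders",
        "Nervous system disorders",
        "Respiratory, thoracic and mediastinal disorders",
        "Psychiatric disorders",
    }
)

#: SOC labels outside the safety scope, used by the simulator and available
#: for fixtures. Open vocabulary: unknown labels only trigger a warning.
KNOWN_OUT_OF_SCOPE_SOCS: Tuple[str, ...] = (
    "Gastrointestinal disorders",
    "Hepatobiliary disorders",
    "Renal and urinary disorders",
    "Skin and subcutaneous tissue disorders",
    "Eye disorders",
    "Musculoskeletal and connective tissue disorders",
    "Immune system disorders",
    "Endocrine disorders",
)

_ALL_KNOWN_SOCS = frozenset(DEFAULT_IN_SCOPE_SOCS) | frozenset(KNOWN_OUT_OF_SCOPE_SOCS)

REQUIRED_COLUMNS = ("gene_id", "source", "soc_term")
SOURCES = ("genetic", "pharmacological")


@dataclass
class EvidencePanel:
    """The selected off-target proteome with its evidence decomposition.

    Attributes
    ----------
    members
        All panel gene identifiers.
    evidence_class
        Maps each member to ``"genetic_only"``, ``"pharmacological_only"``
        or ``"both"``.
    annotations
        Optional per-gene annotation payload (subcellular location, target
        class, organ systems); pass-through only.
    """

    members: FrozenSet[str]
    evidence_class: Dict[str, str]
    annotations: Dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.evidence_class) != set(self.members):
            raise ValueError("evidence_class keys must equal panel members")

    def __len__(self) -> int:
        return len(self.members)

    def to_frame(self) -> pd.DataFrame:
        """Panel as a two-column table sorted by gene identifier."""
        genes = sorted(self.members)
        return pd.DataFrame(
            {"gene_id": genes, "evidence_class": [self.evidence_class[g] for g in genes]}
        )


def _validate_evidence(records: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"evidence table missing required columns: {missing}")


def filter_by_soc(
    records: pd.DataFrame,
    in_scope_socs: Iterable[str] = DEFAULT_IN_SCOPE_SOCS,
) -> pd.DataFrame:
    """Keep only evidence rows whose SOC term is in scope.

    Row order is preserved and the input is not modified. Unknown SOC labels
    in ``in_scope_socs`` raise a warning (the vocabulary is open), never an
    error.
    """
    _validate_evidence(records)
    socs = set(in_scope_socs)
    if not socs:
        raise ValueError("in_scope_socs must be non-empty")
    unknown = socs - _ALL_KNOWN_SOCS
    if unknown:
        warnings.warn(
            f"SOC labels not in the known vocabulary: {sorted(unknown)}",
            stacklevel=2,
        )
    return records.loc[records["soc_term"].isin(socs)].copy()


def _in_scope_genes(records: pd.DataFrame, socs: Set[str]) -> Set[str]:
    if records.empty:
        return set()
    kept = records.loc[records["soc_term"].isin(socs), "gene_id"]
    return set(kept.astype(str))


def select_sotp(
    genetic: pd.DataFrame,
    pharmacological: pd.DataFrame,
    in_scope_socs: Iterable[str] = DEFAULT_IN_SCOPE_SOCS,
    gwas_p_threshold: float | None = None,
) -> EvidencePanel:
    """Build the off-target panel from genetic and pharmacological evidence.

    Panel members are the union of in-scope genes from both tables; the
    evidence class of each member follows from set membership, so the result
    is independent of row order and of duplicated rows.

    Parameters
    ----------
    genetic, pharmacological
        Evidence tables with columns ``gene_id``, ``source``, ``soc_term``
        and optionally ``p_value``.
    in_scope_socs
        SOC labels defining safety scope.
    gwas_p_threshold
        If given and a ``p_value`` column is present in the genetic table,
        rows with ``p_value >= threshold`` are dropped before linking
        (genome-wide significance pre-filter; the conventional cut-off is
        5e-8).
    """
    for tbl in (genetic, pharmacological):
        if not tbl.empty:
            _validate_evidence(tbl)
    socs = set(in_scope_socs)
    if gwas_p_threshold is not None and "p_value" in genetic.columns:
        genetic = genetic.loc[
            genetic["p_value"].isna() | (genetic["p_value"] < gwas_p_threshold)
        ]
    g = _in_scope_genes(genetic, socs)
    p = _in_scope_genes(pharmacological, socs)
    evidence_class: Dict[str, str] = {}
    for gene in g | p:
        if gene in g and gene in p:
            evidence_class[gene] = "both"
        elif gene in g:
            evidence_class[gene] = "genetic_only"
        else:
            evidence_class[gene] = "pharmacological_only"
    return EvidencePanel(members=frozenset(g | p), evidence_class=evidence_class)


def venn_decompose(panel: EvidencePanel) -> Tuple[int, int, int, int]:
    """Return ``(genetic_only, pharmacological_only, both, total)`` counts."""
    counts = {"genetic_only": 0, "pharmacological_only": 0, "both": 0}
    for cls in panel.evidence_class.values():
        counts[cls] += 1
    total = sum(counts.values())
    assert total == len(panel.members)
    return (
        counts["genetic_only"],
        counts["pharmacological_only"],
        counts["both"],
        total,
    )
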