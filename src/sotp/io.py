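"""Readers and writers for the pipeline's tabular and sequence formats.

Tables are plain TSV. The protein-group reader understands the MaxQuant
``proteinGroups.txt`` dialect, where flag columns mark positives with "+".
Missing intensities are accepted as empty fields or "NaN" and written as
empty fields.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .panel import EvidencePanel, venn_decompose
from .quant import SampleDesign

__all__ = [
    "read_evidence",
    "write_evidence",
    "read_expression",
    "write_expression",
    "read_protein_groups",
    "read_peptides",
    "read_design",
    "read_fasta",
    "write_fasta",
    "read_gene_list",
    "write_panel",
]

_MAXQUANT_COLUMNS = {
    "Protein IDs": "group_id",
    "Gene names": "gene_id",
    "Reverse": "is_reverse",
    "Potential contaminant": "is_contaminant",
    "Only identified by site": "only_by_site",
    "Unique peptides": "unique_peptide_count",
    "Sequence": "sequence",
}


def read_evidence(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str})


def write_evidence(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def _plus_flag(series: pd.Series) -> pd.Series:
    return series.fillna("").astype(str).str.strip().eq("+")


def read_protein_groups(path: str | Path) -> pd.DataFrame:
    """Read a MaxQuant-dialect ``proteinGroups`` TSV.

    "+"-marked flag columns become booleans; intensity columns keep their
    ``Intensity <sample>`` / ``LFQ intensity <sample>`` names with NaN for
    missing values.
    """
    df = pd.read_csv(path, sep="\t", na_values=["", "NaN"])
    for src, dst in _MAXQUANT_COLUMNS.items():
        if src in df.columns:
            if dst in ("is_reverse", "is_contaminant", "only_by_site"):
                df[dst] = _plus_flag(df[src])
            else:
                df[dst] = df[src]
    for flag in ("is_reverse", "is_contaminant", "only_by_site"):
        if flag not in df.columns:
            df[flag] = False
    return df


def read_peptides(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["", "NaN"])


def read_design(path: str | Path) -> SampleDesign:
    """Read a sample-design TSV with columns sample_id, cell_line[, replicate]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "cell_line"}
    if not required.issubset(df.columns):
        raise ValueError(f"design table must have columns {sorted(required)}")
    replicate_of = {}
    if "replicate" in df.columns:
        replicate_of = {
            s: int(r) for s, r in zip(df["sample_id"], df["replicate"])
        }
    return SampleDesign(
        sample_ids=list(df["sample_id"]),
        cell_line_of=dict(zip(df["sample_id"], df["cell_line"])),
        replicate_of=replicate_of,
    )


def read_fasta(path: str | Path) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Iterable[Tuple[str, str]], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def read_gene_list(path: str | Path) -> List[str]:
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]


def write_panel(panel: EvidencePanel, out_dir: str | Path) -> None:
    """Write the panel TSV plus a JSON Venn summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel.to_frame().to_csv(out / "panel.tsv", sep="\t", index=False)
    g, p, b, total = venn_decompose(panel)
    summary = {
        "genetic_only": g,
        "pharmacological_only": p,
        "both": b,
        "total": total,
    }
    (out / "panel_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
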