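"""Synthetic fixture generators for every pipeline stage.

Each generator emulates the statistical structure of one real input: Venn-
structured evidence tables, sparse expression over many cell lines, peptide
intensity matrices with intensity-dependent missingness, divergent ortholog
sequence pairs, and secretome predictor-score tables with planted category
counts. All randomness flows from ``config.seed`` through independent
deterministic substreams, so one config reproduces the whole fixture set
byte-for-byte. Alongside each noisy observable the generators retain the
underlying truth for parameter-recovery tests.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import ConfigurationError, SimulationConfig
from .orthologs import AMINO_ACIDS
from .panel import DEFAULT_IN_SCOPE_SOCS, KNOWN_OUT_OF_SCOPE_SOCS

__all__ = [
    "generate_evidence_tables",
    "generate_expression_matrix",
    "generate_peptide_intensities",
    "generate_ortholog_pairs",
    "generate_secretome_scores",
]

_IN_SCOPE = sorted(DEFAULT_IN_SCOPE_SOCS)

# Stream offsets keep the generators' substreams independent of each other
# while still deriving from the single master seed.
_STREAMS = {
    "evidence": 1,
    "expression": 2,
    "peptides": 3,
    "orthologs": 4,
    "secretome": 5,
}


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], config.seed % (2**31)])


def gene_ids(n: int) -> List[str]:
    return [f"G{i:06d}" for i in range(1, n + 1)]


def generate_evidence_tables(
    config: SimulationConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Emit genetic and pharmacological evidence tables with a planted Venn.

    Exactly ``venn_counts[0]`` genes carry in-scope evidence only in the
    genetic table, ``venn_counts[1]`` only in the pharmacological table and
    ``venn_counts[2]`` in both; all remaining genes receive only
    out-of-scope SOC annotations, so the downstream panel has the planted
    Venn structure regardless of seed.
    """
    rng = _rng(config, "evidence")
    g_only, p_only, both = config.venn_counts
    genes = np.array(gene_ids(config.n_genes))
    perm = rng.permutation(config.n_genes)
    g_set = genes[perm[:g_only]]
    p_set = genes[perm[g_only : g_only + p_only]]
    b_set = genes[perm[g_only + p_only : g_only + p_only + both]]
    rest = genes[perm[g_only + p_only + both :]]

    def in_scope_rows(ids: np.ndarray, source: str) -> pd.DataFrame:
        socs = rng.choice(_IN_SCOPE, size=len(ids))
        return pd.DataFrame({"gene_id": ids, "source": source, "soc_term": socs})

    genetic_parts = [in_scope_rows(g_set, "genetic"), in_scope_rows(b_set, "genetic")]
    pharm_parts = [
        in_scope_rows(p_set, "pharmacological"),
        in_scope_rows(b_set, "pharmacological"),
    ]
    # Background genes: out-of-scope annotations only, split between sources.
    if len(rest):
        to_genetic = rng.random(len(rest)) < 0.5
        out_socs = rng.choice(KNOWN_OUT_OF_SCOPE_SOCS, size=len(rest))
        bg = pd.DataFrame({"gene_id": rest, "soc_term": out_socs})
        genetic_parts.append(
            bg[to_genetic].assign(source="genetic")[["gene_id", "source", "soc_term"]]
        )
        pharm_parts.append(
            bg[~to_genetic].assign(source="pharmacological")[
                ["gene_id", "source", "soc_term"]
            ]
        )
    genetic = pd.concat(genetic_parts, ignore_index=True)
    pharm = pd.concat(pharm_parts, ignore_index=True)
    # Shuffle row order; panel construction must not depend on it.
    genetic = genetic.sample(frac=1.0, random_state=int(rng.integers(2**31)))
    pharm = pharm.sample(frac=1.0, random_state=int(rng.integers(2**31)))
    return genetic.reset_index(drop=True), pharm.reset_index(drop=True)


def generate_expression_matrix(config: SimulationConfig) -> pd.DataFrame:
    """Sparse FPKM-like expression matrix, genes as rows, cell lines as columns.

    Values are emitted in FPKQ-like units: with probability
    ``expression_sparsity`` a gene is expressed in a line (log-normal value
    >= 1), otherwise it receives a small positive background value < 1, so
    the expressed indicator at threshold 1 has the configured sparsity on
    the emitted matrix.
    """
    if config.n_cell_lines < 1 or config.n_genes < 1:
        raise ConfigurationError("need at least one gene and one cell line")
    rng = _rng(config, "expression")
    shape = (config.n_genes, config.n_cell_lines)
    expressed = rng.random(shape) < config.expression_sparsity
    values = np.where(
        expressed,
        np.maximum(2.0 ** rng.normal(3.5, 1.5, shape), 1.0),
        rng.uniform(0.01, 0.99, shape),
    )
    lines = [f"CL{i:04d}" for i in range(1, config.n_cell_lines + 1)]
    return pd.DataFrame(values, index=gene_ids(config.n_genes), columns=lines)


def _censor_mask(
    log2_intensity: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean mask of cells to censor (True = missing)."""
    if config.missing_fraction == 0.0:
        return np.zeros_like(log2_intensity, dtype=bool)
    if config.missingness_mode == "MCAR":
        return rng.random(log2_intensity.shape) < config.missing_fraction
    # Intensity-dependent: logistic censoring on log2 intensity. The
    # midpoint is placed at the quantile equal to missing_fraction so the
    # realized fraction is close to the requested one for steep slopes.
    midpoint = np.quantile(log2_intensity, config.missing_fraction)
    p = 1.0 / (1.0 + np.exp(config.censor_slope * (log2_intensity - midpoint)))
    return rng.random(log2_intensity.shape) < p


def generate_peptide_intensities(
    config: SimulationConfig,
    n_proteins: int = 100,
    peptides_per_protein: Tuple[int, int] = (3, 10),
    n_samples: int = 6,
    profile_log_sd: float = 1.0,
    noise_log_sd: float = 0.2,
    sample_ids: Optional[List[str]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Peptide intensity table plus the true protein profiles behind it.

    The generative model: each protein has a log-normal base abundance and a
    per-sample profile (log2 deviations with SD ``profile_log_sd``); each
    peptide has a fixed ionization factor; observed intensity = protein
    abundance x ionization factor x log-normal noise, then censored per
    ``missingness_mode``. With ``noise_log_sd=0`` and no missingness every
    peptide ratio between two samples equals the true protein ratio exactly.

    Returns
    -------
    peptides
        MaxQuant-``peptides.txt``-dialect table: ``Sequence``, ``Proteins``,
        ``Unique`` and one ``Intensity <sample>`` column per sample
        (missing cells are NaN).
    truth
        True protein abundance per sample (linear scale), proteins as rows.
    """
    if n_proteins < 1 or n_samples < 1:
        raise ConfigurationError("n_proteins and n_samples must be positive")
    lo, hi = peptides_per_protein
    if lo < 1 or hi < lo:
        raise ConfigurationError("peptides_per_protein must be a positive range")
    rng = _rng(config, "peptides")
    if sample_ids is None:
        sample_ids = [f"S{i:02d}" for i in range(1, n_samples + 1)]
    proteins = [f"P{i:05d}" for i in range(1, n_proteins + 1)]

    base = rng.normal(config.intensity_log_mean, config.intensity_log_sd, n_proteins)
    profile = base[:, None] + rng.normal(0.0, profile_log_sd, (n_proteins, n_samples))
    truth = pd.DataFrame(2.0**profile, index=proteins, columns=sample_ids)

    n_peps = rng.integers(lo, hi + 1, n_proteins)
    rows = []
    log2_cells = []
    for p_idx, prot in enumerate(proteins):
        for k in range(n_peps[p_idx]):
            ionization = rng.normal(0.0, 1.5)
            noise = rng.normal(0.0, noise_log_sd, n_samples)
            log2_int = profile[p_idx] + ionization + noise
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=9)) + "K"
            rows.append((f"{seq}", prot))
            log2_cells.append(log2_int)
    log2_mat = np.array(log2_cells)
    censored = _censor_mask(log2_mat, config, rng)
    intensities = 2.0**log2_mat
    intensities[censored] = np.nan

    peptides = pd.DataFrame(rows, columns=["Sequence", "Proteins"])
    peptides["Unique"] = "yes"
    for j, s in enumerate(sample_ids):
        peptides[f"Intensity {s}"] = intensities[:, j]
    return peptides, truth


def _mutate_sequence(
    seq: str, rate: float, indel_rate: float, rng: np.random.Generator
) -> str:
    residues = list(seq)
    alphabet = list(AMINO_ACIDS)
    for i, r in enumerate(residues):
        if rng.random() < rate:
            choices = [x for x in alphabet if x != r]
            residues[i] = choices[int(rng.integers(len(choices)))]
    if indel_rate > 0 and rng.random() < indel_rate and len(residues) > 2:
        length = int(rng.geometric(0.5))
        pos = int(rng.integers(1, len(residues)))
        if rng.random() < 0.5:
            insert = [alphabet[int(rng.integers(20))] for _ in range(length)]
            residues[pos:pos] = insert
        else:
            del residues[pos : pos + length]
    return "".join(residues)


def generate_ortholog_pairs(
    config: SimulationConfig,
    sequence_length: int = 200,
) -> List[Tuple[str, str, str, str]]:
    """Simulated (human_id, human sequence, ortholog sequence, species) tuples.

    Species labels cycle over rat, dog and macaque with species-specific
    substitution rates from ``config.species_rates`` (macaque lowest by
    default) so the expected similarity ordering macaque > dog ~ rat holds.
    Indels are inserted with probability ``config.indel_rate`` per sequence,
    with geometric lengths.
    """
    rng = _rng(config, "orthologs")
    species_cycle = ["rat", "dog", "macaque"]
    pairs = []
    for i in range(config.n_ortholog_pairs):
        human = "".join(rng.choice(list(AMINO_ACIDS), size=sequence_length))
        species = species_cycle[i % len(species_cycle)]
        rate = config.species_rates.get(species, config.substitution_rate)
        ortholog = _mutate_sequence(human, rate, config.indel_rate, rng)
        pairs.append((f"H{i + 1:05d}", human, ortholog, species))
    return pairs


_CATEGORIES = ("classical", "nonclassical", "membrane", "exosome", "unclassified")


def generate_secretome_scores(config: SimulationConfig) -> pd.DataFrame:
    """Predictor-score table whose classification cascade yields planted counts.

    Scores are constructed per category: classical proteins carry the
    UniProt keyword or a signal-peptide probability >= 0.9; nonclassical
    proteins fail the classical test but have NNscore >= 0.5; membrane
    proteins have >= 1 predicted transmembrane helix; exosome proteins only
    match the exosome catalogue; unclassified proteins fail everything.
    """
    counts = dict(config.category_counts)
    unknown = set(counts) - set(_CATEGORIES)
    if unknown:
        raise ConfigurationError(f"unknown secretion categories: {sorted(unknown)}")
    rng = _rng(config, "secretome")
    total = sum(counts.values())
    records: List[Dict] = []
    for category in _CATEGORIES:
        for _ in range(counts.get(category, 0)):
            rec = {
                "keyword_secreted": False,
                "signalp_score": rng.uniform(0.0, 0.89),
                "nnscore": rng.uniform(0.0, 0.49),
                "tm_helix_count": 0,
                "exocarta_member": False,
                "true_category": category,
            }
            if category == "classical":
                if rng.random() < 0.5:
                    rec["keyword_secreted"] = True
                else:
                    rec["signalp_score"] = rng.uniform(0.9, 1.0)
            elif category == "nonclassical":
                rec["nnscore"] = rng.uniform(0.5, 1.0)
            elif category == "membrane":
                rec["tm_helix_count"] = int(rng.integers(1, 13))
            elif category == "exosome":
                rec["exocarta_member"] = True
            records.append(rec)
    columns = [
        "keyword_secreted",
        "signalp_score",
        "nnscore",
        "tm_helix_count",
        "exocarta_member",
        "true_category",
    ]
    df = pd.DataFrame.from_records(records, columns=columns)
    if total:
        df = df.iloc[rng.permutation(total)].reset_index(drop=True)
    df.insert(0, "protein_id", [f"P{i:05d}" for i in range(1, total + 1)])
    return df
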