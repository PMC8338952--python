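"""Simulation configuration for the synthetic fixture generators.

A single :class:`SimulationConfig` drives every generator in
:mod:`sotp.simulate` so that one seed reproduces the whole fixture set
byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Tuple

__all__ = ["SimulationConfig", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Raised when simulation parameters are inconsistent or out of range."""


#: Default per-species substitution rates. Macaque is given the lowest rate so
#: that the expected similarity ordering macaque > dog ~ rat holds in fixtures,
#: mirroring the relative conservation of the three common tox species.
DEFAULT_SPECIES_RATES: Mapping[str, float] = {
    "macaque": 0.02,
    "dog": 0.10,
    "rat": 0.10,
}

#: Default secretion-category counts (classical, nonclassical, membrane,
#: exosome, unclassified) for the secretome score generator.
DEFAULT_CATEGORY_COUNTS: Mapping[str, int] = {
    "classical": 694,
    "nonclassical": 986,
    "membrane": 122,
    "exosome": 983,
    "unclassified": 361,
}


@dataclass
class SimulationConfig:
    """Parameters controlling all synthetic fixture generators.

    Parameters
    ----------
    seed
        Master seed; identical seed plus identical config gives
        byte-identical outputs.
    n_genes
        Size of the simulated gene universe.
    venn_counts
        ``(genetics_only, pharmacology_only, both)`` gene counts for the
        evidence tables.
    n_cell_lines
        Number of cell lines in the expression matrix.
    expression_sparsity
        Probability that a given gene is expressed (FPKQ >= 1) in a given
        cell line.
    intensity_log_mean, intensity_log_sd
        Mean and SD of the log2 peptide/protein intensity distribution.
    missing_fraction
        Probability that a peptide intensity cell is censored.
    missingness_mode
        ``"MCAR"`` (uniform) or ``"intensity_dependent"`` (logistic censoring
        on log2 intensity, preferentially removing low-intensity cells).
    censor_midpoint_quantile, censor_slope
        Logistic censoring curve parameters for intensity-dependent
        missingness: the midpoint sits at this quantile of the log2
        intensities and the slope is in units of 1/log2-intensity.
    n_ortholog_pairs
        Number of (human, ortholog) sequence pairs to simulate.
    substitution_rate
        Baseline per-residue substitution probability for ortholog
        divergence; per-species overrides come from ``species_rates``.
    indel_rate
        Per-sequence probability of inserting one geometric-length indel.
    species_rates
        Mapping species -> substitution rate.
    category_counts
        Mapping secretion category -> planted protein count.
    """

    seed: int = 0
    n_genes: int = 20000
    venn_counts: Tuple[int, int, int] = (2423, 248, 142)
    n_cell_lines: int = 932
    expression_sparsity: float = 0.55
    intensity_log_mean: float = 25.0
    intensity_log_sd: float = 2.5
    missing_fraction: float = 0.1
    missingness_mode: str = "intensity_dependent"
    censor_midpoint_quantile: float = 0.15
    censor_slope: float = 1.0
    n_ortholog_pairs: int = 300
    substitution_rate: float = 0.10
    indel_rate: float = 0.1
    species_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_RATES)
    )
    category_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_COUNTS)
    )

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_cell_lines": self.n_cell_lines,
            "n_ortholog_pairs": self.n_ortholog_pairs,
        }
        for name, value in counts.items():
            if value < 0:
                raise ConfigurationError(f"{name} must be non-negative, got {value}")
        if len(self.venn_counts) != 3 or any(c < 0 for c in self.venn_counts):
            raise ConfigurationError(
                f"venn_counts must be three non-negative counts, got {self.venn_counts}"
            )
        if sum(self.venn_counts) > self.n_genes:
            raise ConfigurationError(
                f"venn_counts sum to {sum(self.venn_counts)} which exceeds "
                f"n_genes={self.n_genes}"
            )
        probs = {
            "expression_sparsity": self.expression_sparsity,
            "missing_fraction": self.missing_fraction,
            "substitution_rate": self.substitution_rate,
            "indel_rate": self.indel_rate,
            "censor_midpoint_quantile": self.censor_midpoint_quantile,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value}")
        for species, rate in self.species_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(
                    f"species_rates[{species!r}] must lie in [0, 1], got {rate}"
                )
        if self.missingness_mode not in ("MCAR", "intensity_dependent"):
            raise ConfigurationError(
                "missingness_mode must be 'MCAR' or 'intensity_dependent', "
                f"got {self.missingness_mode!r}"
            )
        if any(c < 0 for c in self.category_counts.values()):
            raise ConfigurationError("category_counts must be non-negative")
        if self.intensity_log_sd < 0:
            raise ConfigurationError("intensity_log_sd must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["venn_counts"] = list(self.venn_counts)
        d["species_rates"] = dict(self.species_rates)
        d["category_counts"] = dict(self.category_counts)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "venn_counts" in d:
            d["venn_counts"] = tuple(d["venn_counts"])
        return cls(**d)
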