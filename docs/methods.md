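# Methods

This note documents the models, rules and numerical choices implemented in
`sotp`, and what the synthetic-data generators do and do not emulate.

## Off-target panel construction (`sotp.panel`)

The selected off-target proteome (SOTP) is the union of genes carrying
genetic or pharmacological evidence annotated to safety-relevant MedDRA
System Organ Classes. The default in-scope SOC set maps the informal
"heart, vascular, nervous, respiratory, mental" scope to the five MedDRA
SOC names *Cardiac disorders*, *Vascular disorders*, *Nervous system
disorders*, *Respiratory, thoracic and mediastinal disorders* and
*Psychiatric disorders*. The exact strings are a documented default and can
be overridden, since SOC vocabularies evolve; unknown labels warn rather
than fail.

Panel membership is pure set algebra: a gene is `genetic_only`,
`pharmacological_only` or `both` according to which filtered tables it
appears in, so the result is independent of row order and of duplicated
rows. A gene qualifies as `both` if it carries in-scope evidence in either
source (union-then-classify); requiring in-scope terms from both sources
independently is a stricter alternative we did not adopt. Genome-wide
association pre-filtering (p < 5e-8) is exposed as an optional column
filter applied before linking, because it logically belongs upstream of the
evidence tables.

## Ortholog similarity (`sotp.orthologs`)

Human-versus-species similarity is computed from one optimal global
alignment per pair: the number of identical alignment columns divided by
the total alignment length, gap columns included, so indels reduce
similarity. Scores lie in [0, 1]; 0 is reserved for "ortholog not found"
and 1 requires a gap-free, all-identical alignment. When several orthologs
exist for one human protein the maximum similarity is kept by default
("first" is available), since no aggregation rule is canonical.

The aligner is an in-package Needleman-Wunsch with Gotoh's three-state
affine-gap recursion. The default scoring is BLOSUM62 with gap open -10 and
extend -0.5 (a gap of length L costs `open + (L-1)*extend`), a common
default for global protein alignment; the similarity value depends on which
optimal alignment is produced, so the scheme is pinned and configurable. A
linear (match/mismatch/gap) scheme exists for oracle testing. Traceback
tie-breaking is deterministic: diagonal over up (gap in the second
sequence) over left. Tests cross-check optimal scores against an
independent memoized recursion and against Biopython's `PairwiseAligner`
under the identical scheme.

## Cell-line selection (`sotp.celllines`)

Expression columns are scaled so each cell line's 70th percentile equals 10
(FPKQ units). The percentile uses linear interpolation between order
statistics (numpy default, the "type 7" rule) — the rule must be pinned for
bit-reproducibility. A column whose 70th percentile is zero has no defined
scale and raises an error naming the column. Genes with FPKQ >= 1
(inclusive) are called expressed.

Cell lines are ranked by greedy maximum coverage: each step adds the line
covering the most not-yet-covered target genes, with ties broken
lexicographically by identifier so results are deterministic and invariant
to column order. Greedy maximum coverage is within (1 - 1/e) of the optimal
k-subset; a brute-force optimizer over all k-subsets (budgeted) serves as
the test oracle on small instances. Target genes absent from the matrix can
never be covered; they are reported and excluded from the coverage
denominator by default (a flag includes them), because the denominator
convention materially changes quoted coverage percentages. The experimental
panel is the union of the greedy top-k for the off-target panel and the
greedy top-k for the whole protein-coding set (k = 3 by default, so two
rankings sharing two lines give a four-line panel).

## Label-free quantification (`sotp.quant`)

Protein groups flagged as contaminant, decoy (reverse) or
identified-only-by-site are dropped; surviving groups need at least one
unique peptide and at least two valid LFQ values within one cell line.

MaxLFQ-lite reconstructs per-protein abundance profiles from peptide
evidence: for every sample pair sharing at least one peptide, the protein
log2 ratio is the median of the shared-peptide log2 ratios (the median
protects against outlier peptides); the profile is the least-squares
solution of the resulting pairwise ratio system, solved per connected
component of the sample-sharing graph. The system fixes only ratios, so an
anchor is required: each component's profile is rescaled so its summed
intensity equals the protein's summed raw peptide intensity over those
samples. Samples in no shared pair remain missing. With noiseless,
proportional peptides the reconstruction is exact to solver precision.

iBAQ divides summed protein intensity by the number of theoretical tryptic
peptides — fully tryptic fragments (cleave after K/R, not before P, zero
missed cleavages) of length 6-30. The minimum of 6 matches the search-side
minimum peptide length; 30 is the conventional iBAQ maximum, configurable.
iBAQ is linear in intensity and proportional to molar amount under the
equal-ionization assumption. Dynamic range is log10(max/min) over
quantified values.

"Match between runs" is out of scope: it operates on raw MS1 features,
which this package never sees; the simulator emulates its effect only as
reduced missingness.

## Statistics (`sotp.stats`)

**Imputation.** Missing log2 intensities are drawn from
Normal(mean_obs − 1.8·sd_obs, (0.3·sd_obs)²), statistics taken per sample
column by default (the common Perseus-style choice; a whole-matrix mode
exists). This places imputed values in the left tail, reflecting that
label-free missingness is mostly abundance-dependent. Observed cells are
untouched and results are deterministic given a seed. An
sklearn-compatible `DownshiftImputer` wraps the same model.

**Two-sample test.** The SAM-moderated statistic is
(mean₁ − mean₂) / (pooled SE + s0) with s0 = 2 by default; s0 damps
statistics inflated by near-zero variances. The null distribution comes
from group-label permutations (all distinct assignments when at most
`n_permutations`, else a seeded random subset; the observed labeling is
excluded). The q-value for protein i is
(1 + median over permutations of #{|t_perm| ≥ |t(i)|}) / (1 + #{|t_obs| ≥
|t(i)|}), clipped to [0, 1] and monotonized in |t|. The add-one continuity
correction follows the same logic as never-zero permutation p-values
(Phipson & Smyth): with few distinct permutations (3v3 gives only 19) a
raw median of zero would otherwise declare cost-free discoveries and break
false-discovery control; with the correction the measured full-null FDP is
0 across 20 simulated replicates while 4-fold spikes at replicate SD 0.3
are all detected.

**Multi-group test.** One-way ANOVA per protein across cell lines with
Benjamini-Hochberg q-values, significant at q ≤ 0.01. A protein is
*enriched* in a line when its mean log2 intensity exceeds the mean of all
other lines' samples by at least log2(2) and the ANOVA q passes — the
one-vs-rest reading of "≥ 2-fold enriched"; one-vs-each-other-line is a
stricter alternative not implemented.

**Projections.** Rows are z-scored to mean 0, SD 1 (population SD);
zero-variance rows are dropped with a warning. Protein clustering is
Euclidean distance with Ward linkage (scipy); sample PCA is SVD-based
(scikit-learn) with orthonormal loadings and non-increasing explained
variance summing to the total.

## Secretome classification (`sotp.secretome`)

A strict precedence cascade assigns exactly one category: classical
(UniProt "Signal"/"Secreted" keyword or signal-peptide probability ≥ 0.9),
else nonclassical (NNscore ≥ 0.5), else membrane (≥ 1 predicted
transmembrane helix), else exosome (exosome-catalogue member), else
unclassified. Thresholds are inclusive; missing scores count as below
threshold; the precedence order is configurable. The predictors themselves
(SignalP, SecretomeP, TMHMM) are upstream tools whose scores are inputs.
Note that a strictly exclusive cascade over the reference component counts
694/986/122/983 of 3146 gives a combined secreted fraction of 2785/3146 =
88.5%, marginally below a sometimes-quoted 88.7%; overlapping category
accounting would be needed to reconcile the difference, and we keep the
cascade exclusive.

## Coverage reports (`sotp.report`)

All accounting is gene-centric (protein groups collapsed to gene IDs
first). Panel coverage is |quantified ∩ panel| / |panel|; sharing
distributions tally, for each category gene quantified anywhere, the number
of cell lines it appears in; organ-class coverage averages per-organ
coverage without weighting by set size. Percentages are rounded to integers
for display only — files and return values carry full precision.

## Synthetic data (`sotp.simulate`)

One `SimulationConfig` drives all generators through independent
deterministic substreams of a single seed (identical config + seed gives
byte-identical outputs). The defaults mirror the study conditions the
pipeline targets: a 20,000-gene universe with Venn evidence counts
(2423, 248, 142); 932 cell lines; secretome category counts
{694, 986, 122, 983, 361}; species substitution rates macaque 0.02 <
rat = dog 0.10 so the expected cross-species similarity ordering holds.
Expression sparsity over cell lines is a free parameter (default 0.55) —
it is not calibrated against any public expression compendium and mainly
controls coverage-curve shape in tests.

The peptide simulator draws protein log2 base abundances from
Normal(25, 2.5), per-sample profile deviations (SD 1), fixed per-peptide
ionization factors (log2 SD 1.5) and multiplicative log-normal noise;
intensity-dependent missingness uses a logistic censoring curve on log2
intensity with midpoint at the `missing_fraction` quantile, which makes
the realized missing fraction approximately the requested one for steep
slopes while censoring preferentially low intensities. True profiles are
retained for parameter-recovery tests. Ortholog divergence is per-residue
substitution to a different residue plus at most one geometric-length
indel per sequence. The expression generator emits values directly in
FPKQ-like units so the configured sparsity holds on the emitted matrix at
the threshold of 1; the subsequent 70th-percentile rescale shifts
individual calls only marginally.

What passing tests on these fixtures show: the algorithms implement their
stated rules exactly, the estimators recover planted parameters, and the
statistical procedures are calibrated under their own generative
assumptions. What they do not show: robustness to real-data pathologies
the simulator omits — correlated peptides, shared/razor peptides across
protein groups, batch effects, non-normal intensity distributions, search
engine identification errors, and biological covariance between genes.

## Problem sizes

Tests and the reproduction script run at desk scale by design: evidence
tables over a 20,000-gene universe, expression matrices up to 1000 x 20,
imputation at 5000 x 12, null-calibration studies with 1000 proteins x 6
samples x 20 replicates, 10,000 tiny alignment pairs against the
brute-force oracle, and 200 random coverage instances with at most 12
lines. These sizes give Monte-Carlo standard errors comfortably inside the
stated tolerances (e.g. the imputation downshift estimate at 30%
missingness of 5000 x 12 has SE ≈ 0.002 observed-SD units against a ±0.02
tolerance).
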