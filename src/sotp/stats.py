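"""Differential statistics and QC projections for LFQ proteome matrices.

Covers the Perseus-style chain: down-shifted-normal imputation of missing
log2 intensities, the SAM-moderated two-sample t-test with permutation-based
FDR, one-way ANOVA with Benjamini-Hochberg control across cell lines,
per-line enrichment calls, and z-score/Ward-clustering/PCA projections.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from math import comb
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.stats import f_oneway
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .quant import SampleDesign

__all__ = [
    "impute_missing",
    "DownshiftImputer",
    "sam_test",
    "multi_group_test",
    "enriched_proteins",
    "zscore_and_project",
    "ProjectionResult",
]


def _observed_stats(values: np.ndarray, label: str) -> Tuple[float, float]:
    obs = values[~np.isnan(values)]
    if obs.size < 2:
        raise ValueError(
            f"{label} has {obs.size} observed value(s); need >= 2 to "
            "estimate the imputation distribution"
        )
    return float(obs.mean()), float(obs.std(ddof=1))


def impute_missing(
    matrix: pd.DataFrame,
    width: float = 0.3,
    shift: float = 1.8,
    seed: Optional[int] = None,
    per_sample: bool = True,
) -> pd.DataFrame:
    """Impute missing log2 intensities from a down-shifted normal.

    Each missing cell is drawn from Normal(mean_obs - shift * sd_obs,
    (width * sd_obs)^2), where mean_obs and sd_obs come from the observed
    values of the same sample column (``per_sample=True``, the common
    Perseus default) or of the whole matrix. Mimics the left-censored
    missingness of label-free data: absent proteins are assigned plausible
    low abundances. Observed cells are returned untouched and the result is
    deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    values = matrix.to_numpy(dtype=float).copy()
    missing = np.isnan(values)
    if per_sample:
        for j, col in enumerate(matrix.columns):
            mean, sd = _observed_stats(values[:, j], f"sample {col!r}")
            n_miss = int(missing[:, j].sum())
            if n_miss:
                values[missing[:, j], j] = rng.normal(
                    mean - shift * sd, width * sd, n_miss
                )
    else:
        mean, sd = _observed_stats(values.ravel(), "matrix")
        n_miss = int(missing.sum())
        if n_miss:
            values[missing] = rng.normal(mean - shift * sd, width * sd, n_miss)
    return pd.DataFrame(values, index=matrix.index, columns=matrix.columns)


class DownshiftImputer(TransformerMixin, BaseEstimator):
    """sklearn-style transformer wrapping :func:`impute_missing`.

    Fitted attributes: ``means_`` and ``sds_`` of the observed values per
    column (or scalars when ``per_sample=False``).
    """

    def __init__(
        self,
        width: float = 0.3,
        shift: float = 1.8,
        per_sample: bool = True,
        random_state: Optional[int] = None,
    ) -> None:
        self.width = width
        self.shift = shift
        self.per_sample = per_sample
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.per_sample:
            self.means_ = np.array(
                [_observed_stats(X[:, j], f"column {j}")[0] for j in range(X.shape[1])]
            )
            self.sds_ = np.array(
                [_observed_stats(X[:, j], f"column {j}")[1] for j in range(X.shape[1])]
            )
        else:
            mean, sd = _observed_stats(X.ravel(), "matrix")
            self.means_, self.sds_ = np.array([mean]), np.array([sd])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float).copy()
        rng = np.random.default_rng(self.random_state)
        missing = np.isnan(X)
        for j in range(X.shape[1]):
            idx = 0 if not self.per_sample else j
            mean, sd = self.means_[idx], self.sds_[idx]
            n_miss = int(missing[:, j].sum())
            if n_miss:
                X[missing[:, j], j] = rng.normal(
                    mean - self.shift * sd, self.width * sd, n_miss
                )
        return X


def _sam_statistic(
    values: np.ndarray, mask1: np.ndarray, mask2: np.ndarray, s0: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Moderated t: (mean1 - mean2) / (pooled SE + s0). Returns (t, log2FC)."""
    g1, g2 = values[:, mask1], values[:, mask2]
    n1, n2 = g1.shape[1], g2.shape[1]
    m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
    v1, v2 = g1.var(axis=1, ddof=1), g2.var(axis=1, ddof=1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    return diff / (se + s0), diff


def _label_permutations(
    n: int, n1: int, observed: Tuple[int, ...], n_permutations: int, rng
) -> List[Tuple[int, ...]]:
    total = comb(n, n1)
    if total - 1 < 2:
        raise ValueError("fewer than 2 distinct label permutations available")
    if total <= n_permutations + 1:
        perms = [c for c in combinations(range(n), n1) if c != observed]
    else:
        chosen: set = set()
        while len(chosen) < n_permutations:
            pick = tuple(sorted(rng.choice(n, size=n1, replace=False).tolist()))
            if pick != observed:
                chosen.add(pick)
        perms = sorted(chosen)
    return perms


def sam_test(
    matrix: pd.DataFrame,
    design: SampleDesign,
    groups: Tuple[str, str],
    s0: float = 2.0,
    n_permutations: int = 1000,
    fdr: float = 0.05,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """SAM-moderated two-sample t-test with permutation-based FDR.

    The statistic is (mean1 - mean2) / (pooled SE + s0); the fudge factor
    s0 damps large statistics arising from near-zero variances. The null
    distribution comes from group-label permutations: all distinct
    assignments when their number is at most ``n_permutations``, otherwise
    a seeded random subset. For each protein i,
    q(i) = (1 + median over permutations of #{|t_perm| >= |t(i)|}) divided
    by (1 + #{|t_obs| >= |t(i)|}), clipped to [0, 1] and monotonized in
    |t|. The add-one continuity correction (in the spirit of Phipson and
    Smyth's never-zero permutation p-values) keeps the estimate calibrated
    when few distinct permutations exist, where a raw zero median would
    otherwise declare cost-free discoveries.

    Requires a complete (post-imputation) matrix.
    """
    line1, line2 = groups
    s1 = design.samples_of(line1)
    s2 = design.samples_of(line2)
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("each group needs at least 2 samples")
    cols = s1 + s2
    missing = [c for c in cols if c not in matrix.columns]
    if missing:
        raise ValueError(f"matrix lacks sample columns: {missing}")
    values = matrix[cols].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("matrix contains missing values; impute first")
    n, n1 = len(cols), len(s1)
    observed_labels = tuple(range(n1))
    mask1 = np.zeros(n, dtype=bool)
    mask1[list(observed_labels)] = True
    t_obs, log2fc = _sam_statistic(values, mask1, ~mask1, s0)

    rng = np.random.default_rng(seed)
    perms = _label_permutations(n, n1, observed_labels, n_permutations, rng)
    t_null = np.empty((len(perms), values.shape[0]))
    for p, labels in enumerate(perms):
        m = np.zeros(n, dtype=bool)
        m[list(labels)] = True
        t_null[p], _ = _sam_statistic(values, m, ~m, s0)

    abs_obs = np.abs(t_obs)
    abs_null_sorted = np.sort(np.abs(t_null), axis=1)
    # obs_count(i): proteins at least as extreme as i in the observed data.
    order = np.argsort(-abs_obs, kind="stable")
    obs_sorted = np.sort(abs_obs)
    n_prot = len(abs_obs)
    q = np.empty(n_prot)
    for i in range(n_prot):
        thr = abs_obs[i]
        obs_count = n_prot - np.searchsorted(obs_sorted, thr, side="left")
        # per-permutation counts of null statistics >= thr
        per_perm = np.array(
            [
                t_null.shape[1]
                - np.searchsorted(abs_null_sorted[p], thr, side="left")
                for p in range(len(perms))
            ]
        )
        q[i] = (np.median(per_perm) + 1.0) / (obs_count + 1.0)
    q = np.clip(q, 0.0, 1.0)
    # Monotonize: q must be non-decreasing as |t| decreases.
    q_sorted = q[order]
    q_mono = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_final = np.empty(n_prot)
    q_final[order] = q_mono

    return pd.DataFrame(
        {
            "group_id": matrix.index,
            "log2_fold_change": log2fc,
            "statistic": t_obs,
            "q_value": q_final,
            "significant": q_final <= fdr,
        }
    ).set_index("group_id")


def multi_group_test(
    matrix: pd.DataFrame,
    design: SampleDesign,
    fdr: float = 0.01,
) -> pd.DataFrame:
    """One-way ANOVA across all cell lines with Benjamini-Hochberg control."""
    lines = design.cell_lines
    if len(lines) < 2:
        raise ValueError("need at least 2 cell lines")
    group_cols = [design.samples_of(line) for line in lines]
    if any(len(c) < 2 for c in group_cols):
        raise ValueError("each cell line needs at least 2 replicates")
    arrays = [matrix[cols].to_numpy(dtype=float) for cols in group_cols]
    if any(np.isnan(a).any() for a in arrays):
        raise ValueError("matrix contains missing values; impute first")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant rows yield NaN F, handled below
        f_stat, p = f_oneway(*[a.T for a in arrays])
    p = np.where(np.isnan(p), 1.0, p)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            "group_id": matrix.index,
            "f_statistic": f_stat,
            "p_value": p,
            "q_value": q,
            "significant": q <= fdr,
        }
    ).set_index("group_id")


def enriched_proteins(
    matrix: pd.DataFrame,
    design: SampleDesign,
    fc_threshold: float = 2.0,
    fdr: float = 0.01,
) -> Dict[str, List[str]]:
    """Cell-line-enriched proteins: >= fc_threshold vs the rest, ANOVA q <= fdr.

    A protein is enriched in line L when its mean log2 intensity in L
    exceeds the mean over all other lines' samples by at least
    log2(fc_threshold) and the across-lines ANOVA q-value passes.
    """
    anova = multi_group_test(matrix, design, fdr=fdr)
    passing = set(anova.index[anova["significant"]])
    log_fc_min = np.log2(fc_threshold)
    out: Dict[str, List[str]] = {}
    for line in design.cell_lines:
        own = design.samples_of(line)
        rest = [s for s in design.sample_ids if design.cell_line_of[s] != line]
        diff = matrix[own].mean(axis=1) - matrix[rest].mean(axis=1)
        hits = [
            str(g) for g in matrix.index[(diff >= log_fc_min)] if g in passing
        ]
        out[line] = hits
    return out


class ProjectionResult:
    """Row-z-scored matrix with Ward tree and PCA of the samples."""

    def __init__(
        self,
        zscored: pd.DataFrame,
        tree: np.ndarray,
        pca_coordinates: pd.DataFrame,
        explained_variance: np.ndarray,
        dropped_rows: List[str],
    ) -> None:
        self.zscored = zscored
        self.tree = tree
        self.pca_coordinates = pca_coordinates
        self.explained_variance = explained_variance
        self.dropped_rows = dropped_rows


def zscore_and_project(
    matrix: pd.DataFrame,
    design: Optional[SampleDesign] = None,
) -> ProjectionResult:
    """Row z-scores, Ward/Euclidean protein clustering, and sample PCA.

    Each protein row is scaled to mean 0 and SD 1 (population SD);
    zero-variance rows are dropped with a warning. The hierarchical tree is
    a scipy linkage matrix (Euclidean distance, Ward linkage) over protein
    rows. PCA treats samples as observations via singular value
    decomposition of the z-scored matrix; explained variances are
    non-increasing and sum to the total variance.
    """
    values = matrix.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("matrix contains missing values; impute first")
    sd = values.std(axis=1, ddof=0)
    zero_var = sd == 0
    if zero_var.any():
        dropped = [str(g) for g in matrix.index[zero_var]]
        warnings.warn(
            f"dropping {len(dropped)} zero-variance row(s) before z-scoring",
            stacklevel=2,
        )
        values = values[~zero_var]
        index = matrix.index[~zero_var]
    else:
        dropped = []
        index = matrix.index
    z = (values - values.mean(axis=1, keepdims=True)) / values.std(
        axis=1, ddof=0, keepdims=True
    )
    zscored = pd.DataFrame(z, index=index, columns=matrix.columns)
    tree = linkage(z, method="ward", metric="euclidean")
    n_samples = z.shape[1]
    pca = PCA(n_components=min(n_samples, z.shape[0]), svd_solver="full")
    coords = pca.fit_transform(z.T)
    pca_coords = pd.DataFrame(
        coords,
        index=matrix.columns,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return ProjectionResult(
        zscored=zscored,
        tree=tree,
        pca_coordinates=pca_coords,
        explained_variance=pca.explained_variance_,
        dropped_rows=dropped,
    )
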