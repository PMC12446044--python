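"""Paired metagenome (MG) vs metatranscriptome (MT) contrast machinery.

Module-level TPM aggregation, rank-based two-sample and k-sample tests,
rarefaction, Shannon alpha diversity, Bray-Curtis distances and ANOSIM.
The MG-vs-MT contrasts are unpaired rank-sum tests by default; a paired
signed-rank variant is available. Decisions use raw p-values at the 0.05
level; Benjamini-Hochberg adjusted values are reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, ModuleCatalog, TaxonTable

logger = logging.getLogger(__name__)


@dataclass
class ComparisonResult:
    feature_id: str
    group_a_values: np.ndarray
    group_b_values: np.ndarray
    statistic: float
    p_value: float
    test_name: Literal["wilcoxon_rank_sum", "kruskal_wallis", "wilcoxon_signed_rank"]
    p_adjusted: float = np.nan


@dataclass
class DiversityResult:
    sample_id: str
    shannon: float
    rarefaction_depth: int | None = None
    seed: int | None = None


def aggregate_module_tpm(
    expr: ExpressionMatrix, catalog: ModuleCatalog, module_id: str
) -> np.ndarray:
    """Per-sample total TPM over all genes annotated to ``module_id``.

    A gene annotated to two modules contributes its TPM to both totals.
    Annotated genes absent from the matrix contribute 0.
    """
    genes = set(catalog.genes_in_module(module_id))
    rows = [i for i, g in enumerate(expr.gene_ids) if g in genes]
    if not rows:
        return np.zeros(expr.n_samples)
    return expr.values[rows].sum(axis=0)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses exact null enumeration when the pooled size is at most 20 and
    there are no ties, otherwise the tie-corrected normal approximation
    with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("wilcoxon_rank_sum: empty group")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Paired two-sided Wilcoxon signed-rank test (optional paired variant)."""
    res = stats.wilcoxon(np.asarray(x, float), np.asarray(y, float))
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p on k-1 df.

    All-identical observations give H = 0, p = 1 by convention.
    """
    if len(groups) < 2:
        raise ValueError("kruskal_wallis: need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("kruskal_wallis: empty group")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    res = stats.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone in the raw p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def rarefy_counts(
    counts: pd.DataFrame, depth: int, seed: int
) -> pd.DataFrame:
    """Subsample each sample (column) to ``depth`` reads without replacement.

    Every returned column sums exactly to ``depth``; samples with fewer
    than ``depth`` total reads are dropped with a logged warning. The draw
    is a multivariate hypergeometric per column, deterministic for a fixed
    seed.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    values = counts.to_numpy()
    if np.any(values < 0):
        raise ValueError("counts must be nonnegative")
    int_values = np.rint(values).astype(np.int64)
    rng = np.random.default_rng(seed)
    totals = int_values.sum(axis=0)
    keep = totals >= depth
    if not keep.all():
        dropped = [c for c, k in zip(counts.columns, keep) if not k]
        logger.warning("rarefaction: dropping %d sample(s) below depth: %s", len(dropped), dropped)
    out = {}
    for j, col in enumerate(counts.columns):
        if keep[j]:
            out[col] = rng.multivariate_hypergeometric(int_values[:, j], depth)
    return pd.DataFrame(out, index=counts.index, dtype=np.int64)


def shannon_index(fractions, base: float = 2.0) -> float:
    """Shannon entropy ``H = -sum p log_base p`` (bits for base 2).

    ``fractions`` must be nonnegative and sum to 1 within 1e-6; the 0*log 0
    terms are treated as 0.
    """
    p = np.asarray(fractions, dtype=float)
    if p.size and p.min() < 0:
        raise ValueError("shannon_index: negative fraction")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"shannon_index: fractions sum to {p.sum()}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(base))


def shannon_per_sample(
    table: TaxonTable | pd.DataFrame, base: float = 2.0
) -> pd.Series:
    """Shannon index for every sample column of an abundance table."""
    frame = table.to_frame() if isinstance(table, TaxonTable) else table
    values = frame.to_numpy(dtype=float)
    sums = values.sum(axis=0)
    if np.any(sums <= 0):
        raise ValueError("shannon_per_sample: sample with zero total abundance")
    fractions = values / sums
    return pd.Series(
        [shannon_index(fractions[:, j], base=base) for j in range(frame.shape[1])],
        index=frame.columns,
        name="shannon",
    )


def bray_curtis(table: TaxonTable | pd.DataFrame | np.ndarray) -> np.ndarray:
    """Samples x samples Bray-Curtis dissimilarity matrix.

    ``d(i,j) = sum |x_i - x_j| / sum (x_i + x_j)``; a pair of all-zero
    samples is defined as distance 0 with a logged warning.
    """
    if isinstance(table, TaxonTable):
        values = table.abundance
    elif isinstance(table, pd.DataFrame):
        values = table.to_numpy(dtype=float)
    else:
        values = np.asarray(table, dtype=float)
    if values.shape[1] < 2:
        raise ValueError("bray_curtis: need at least 2 samples")
    X = values.T  # samples x taxa
    from scipy.spatial.distance import pdist, squareform

    with np.errstate(invalid="ignore"):
        dist = squareform(pdist(X, metric="braycurtis"))
    if np.isnan(dist).any():
        logger.warning("bray_curtis: all-zero sample pair(s); distance set to 0")
        dist = np.nan_to_num(dist, nan=0.0)
    np.fill_diagonal(dist, 0.0)
    return dist


def anosim(
    dist: np.ndarray,
    labels,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Analysis of Similarities on a precomputed distance matrix.

    ``R = (mean between-group rank - mean within-group rank) / (M/2)`` with
    ``M = n(n-1)/2`` pairwise distances ranked with midrank ties;
    ``p = (1 + #{permuted R >= observed R}) / (1 + n_permutations)`` under
    random relabelling, so the smallest attainable p is
    ``1/(1 + n_permutations)``.
    """
    dist = np.asarray(dist, dtype=float)
    labels = np.asarray(labels)
    n = labels.size
    if dist.shape != (n, n):
        raise ValueError("anosim: distance matrix / label length mismatch")
    groups, counts = np.unique(labels, return_counts=True)
    if groups.size < 2:
        raise ValueError("anosim: need at least 2 groups")
    if counts.min() < 2:
        small = groups[counts < 2]
        raise ValueError(f"anosim: group(s) of size 1: {list(small)}")
    iu = np.triu_indices(n, k=1)
    ranks = stats.rankdata(dist[iu])
    half_m = n * (n - 1) / 4.0

    def r_stat(lab: np.ndarray) -> float:
        within = lab[iu[0]] == lab[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / half_m

    observed = r_stat(labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        if r_stat(rng.permutation(labels)) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return float(observed), float(p)


# ---------------------------------------------------------------------------
# table-level drivers
# ---------------------------------------------------------------------------


def compare_features(
    features_a: pd.DataFrame,
    features_b: pd.DataFrame,
    paired: bool = False,
) -> list[ComparisonResult]:
    """Row-wise MG-vs-MT contrasts for two feature x sample tables.

    Rows (features) present in both tables are tested; results carry raw
    and BH-adjusted p-values. Unpaired rank-sum by default; ``paired=True``
    switches to the signed-rank test (columns must then align).
    """
    shared = [f for f in features_a.index if f in features_b.index]
    if not shared:
        raise ValueError("compare_features: no shared features")
    results: list[ComparisonResult] = []
    for feat in shared:
        a = features_a.loc[feat].to_numpy(dtype=float)
        b = features_b.loc[feat].to_numpy(dtype=float)
        if paired:
            stat, p = wilcoxon_signed_rank(a, b)
            name = "wilcoxon_signed_rank"
        else:
            stat, p = wilcoxon_rank_sum(a, b)
            name = "wilcoxon_rank_sum"
        results.append(ComparisonResult(feat, a, b, stat, p, name))
    adjusted = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, adjusted):
        r.p_adjusted = float(q)
    return results


def comparison_table(results: list[ComparisonResult]) -> pd.DataFrame:
    """Flatten ComparisonResults to a report DataFrame."""
    return pd.DataFrame(
        {
            "feature": [r.feature_id for r in results],
            "mean_a": [float(np.mean(r.group_a_values)) for r in results],
            "mean_b": [float(np.mean(r.group_b_values)) for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "test": [r.test_name for r in results],
        }
    ).set_index("feature")
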