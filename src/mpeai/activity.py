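"""Methanogenesis Pathway Expression Activity Index (MPEAI).

The index summarizes, per sample, the coordinated expression of the genes
annotated to the four KEGG methanogenesis modules (M00356, M00357, M00563,
M00567) in a gene-level TPM matrix. It is a weighted Z-score gene-set
score computed in four steps:

1. *Filter*: retain genes with TPM > 1 in at least 10% of samples.
2. *Standardize*: per gene g, ``Z_{g,s} = (E_{g,s} - mu_g) / sigma_g`` with
   mean and sample standard deviation (ddof=1) taken across samples.
   Zero-variance genes are dropped (their Z-score is undefined).
3. *Weight*: inverse-variance weights ``w_g = 1 / (sigma_g^2 + eps)`` with
   ``eps = 1e-6`` guarding against division by zero, so genes with stable
   expression dominate the score.
4. *Aggregate and normalize*: raw per-sample activity
   ``A_s = sum_g Z_{g,s} w_g / sum_g w_g`` over the module gene set, then
   cross-sample normalization ``A~_s = (A_s - mu_A) / sigma_A``.

The normalized score therefore has mean 0 and standard deviation 1 across
the scored cohort; positive values mark samples whose methanogenesis
machinery is transcribed above the cohort average.

:class:`MethanogenesisActivityIndex` packages the four steps as a
scikit-learn transformer (samples x genes orientation) so the index can sit
inside sklearn pipelines; :func:`compute_mpeai` is the equivalent
one-call function on the genes x samples :class:`~mpeai.io.ExpressionMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import METHANOGENESIS_MODULES, ExpressionMatrix, ModuleCatalog


@dataclass
class GeneStandardization:
    """Per-gene Z-score transform of an expression matrix.

    ``z`` is genes x samples; every retained row has mean 0 and sample
    standard deviation 1 (ddof=1). Genes with zero variance across samples
    are excluded and listed in ``dropped_zero_variance``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    mu: np.ndarray
    sigma: np.ndarray
    z: np.ndarray
    dropped_zero_variance: list[str] = field(default_factory=list)


@dataclass
class GeneWeights:
    """Inverse-variance gene weights ``w_g = 1 / (sigma_g^2 + epsilon)``."""

    gene_ids: list[str]
    w: np.ndarray
    epsilon: float = 1e-6


@dataclass
class ActivityProfile:
    """Per-sample raw activity ``A_s`` and normalized MPEAI ``A~_s``.

    ``params`` records every knob that produced the score (TPM threshold,
    sample fraction, epsilon, modules) so a run is auditable.
    """

    sample_ids: list[str]
    raw: np.ndarray
    normalized: np.ndarray
    mu_A: float
    sigma_A: float
    gene_count: int
    params: dict
    dropped_zero_variance: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"raw_activity": self.raw, "mpeai": self.normalized},
            index=pd.Index(self.sample_ids, name="sample_id"),
        )


# ---------------------------------------------------------------------------
# stage functions
# ---------------------------------------------------------------------------


def filter_expressed_genes(
    expr: ExpressionMatrix,
    tpm_threshold: float = 1.0,
    sample_fraction: float = 0.10,
) -> list[str]:
    """Return genes with TPM strictly above ``tpm_threshold`` in at least
    ``sample_fraction`` of samples.

    The comparison is strict on TPM (a gene at exactly 1.0 everywhere is
    dropped) and inclusive on the proportion (1 of 10 samples passes at
    fraction 0.10). Order follows the input matrix.
    """
    if expr.n_samples == 0:
        raise ValueError("filter_expressed_genes: empty sample set")
    if not 0 <= sample_fraction <= 1:
        raise ValueError("sample_fraction must be in [0, 1]")
    counts = (expr.values > tpm_threshold).sum(axis=1)
    keep = counts / expr.n_samples >= sample_fraction
    return [g for g, k in zip(expr.gene_ids, keep) if k]


def standardize_genes(expr: ExpressionMatrix) -> GeneStandardization:
    """Z-score each gene across samples with sample sd (ddof=1).

    Genes whose expression is constant across samples have an undefined
    Z-score; they are excluded and reported in ``dropped_zero_variance``.
    """
    if expr.n_samples < 2:
        raise ValueError(
            "standardize_genes: need at least 2 samples (sd undefined)"
        )
    mu = expr.values.mean(axis=1)
    sigma = expr.values.std(axis=1, ddof=1)
    keep = sigma > 0
    dropped = [g for g, k in zip(expr.gene_ids, keep) if not k]
    z = (expr.values[keep] - mu[keep, None]) / sigma[keep, None]
    return GeneStandardization(
        gene_ids=[g for g, k in zip(expr.gene_ids, keep) if k],
        sample_ids=list(expr.sample_ids),
        mu=mu[keep],
        sigma=sigma[keep],
        z=z,
        dropped_zero_variance=dropped,
    )


def compute_weights(
    standardization: GeneStandardization, epsilon: float = 1e-6
) -> GeneWeights:
    """Inverse-variance weights from the standardization's per-gene sigma."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    w = 1.0 / (standardization.sigma**2 + epsilon)
    return GeneWeights(list(standardization.gene_ids), w, epsilon)


def compute_raw_activity(
    standardization: GeneStandardization, weights: GeneWeights
) -> np.ndarray:
    """Weight-normalized average of Z-scores over the pathway gene set:
    ``A_s = sum_g Z_{g,s} w_g / sum_g w_g``."""
    if standardization.gene_ids != weights.gene_ids:
        raise ValueError("compute_raw_activity: mismatched gene sets")
    if not standardization.gene_ids:
        raise ValueError("compute_raw_activity: no pathway genes after filtering")
    return weights.w @ standardization.z / weights.w.sum()


def normalize_activity(raw: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Cross-sample normalization ``A~_s = (A_s - mu_A) / sigma_A``.

    Returns ``(normalized, mu_A, sigma_A)``; ``sigma_A`` uses ddof=1,
    matching the gene standardization convention.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size < 2:
        raise ValueError("normalize_activity: need at least 2 samples")
    mu_A = float(raw.mean())
    sigma_A = float(raw.std(ddof=1))
    if sigma_A == 0:
        raise ValueError(
            "normalize_activity: degenerate activity: zero variance across samples"
        )
    return (raw - mu_A) / sigma_A, mu_A, sigma_A


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class MethanogenesisActivityIndex(TransformerMixin, BaseEstimator):
    """Weighted Z-score pathway activity index as a sklearn transformer.

    ``fit`` learns the gene set (expression filter plus optional module
    restriction), per-gene means/sds, inverse-variance weights and the
    cross-sample location/scale of the raw activity; ``transform`` maps a
    samples x genes table to a single activity column. ``fit_transform`` on
    one cohort reproduces the index definition exactly, and ``transform``
    on held-out samples scores them on the fitted scale.

    Parameters
    ----------
    catalog : ModuleCatalog or None
        Gene -> module annotation. When given, the gene set is restricted
        to genes annotated to ``modules``.
    modules : iterable of str or None
        Module IDs to pool into the gene set; defaults to the four
        methanogenesis modules when a catalog is supplied.
    tpm_threshold : float, default 1.0
        Expression filter: TPM must exceed this (strictly).
    sample_fraction : float, default 0.10
        Minimum fraction of samples (inclusive) passing the TPM threshold.
    epsilon : float, default 1e-6
        Variance floor in the inverse-variance weights.

    Attributes
    ----------
    gene_ids_ : list of str
        Genes contributing to the index, in input column order.
    mu_, sigma_ : ndarray
        Per-gene mean and sample sd (ddof=1).
    weights_ : ndarray
        Inverse-variance weights ``1 / (sigma_^2 + epsilon)``.
    dropped_zero_variance_ : list of str
        Genes excluded because their expression is constant.
    mu_A_, sigma_A_ : float
        Mean and sd of the raw activity on the fitted cohort.
    """

    def __init__(
        self,
        catalog: ModuleCatalog | None = None,
        modules=None,
        tpm_threshold: float = 1.0,
        sample_fraction: float = 0.10,
        epsilon: float = 1e-6,
    ):
        self.catalog = catalog
        self.modules = modules
        self.tpm_threshold = tpm_threshold
        self.sample_fraction = sample_fraction
        self.epsilon = epsilon

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(X, columns=[str(i) for i in range(X.shape[1])])

    def fit(self, X, y=None):
        """Learn gene set, standardization, weights and activity scale.

        ``X`` is samples x genes (DataFrame columns are gene IDs).
        """
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        frame = self._as_frame(X)
        if frame.shape[0] < 2:
            raise ValueError("need at least 2 samples to fit the index")
        expr = ExpressionMatrix(
            gene_ids=[str(c) for c in frame.columns],
            sample_ids=[str(i) for i in range(frame.shape[0])],
            values=frame.to_numpy(dtype=float).T,
            layer="MT",
        )
        genes = filter_expressed_genes(expr, self.tpm_threshold, self.sample_fraction)
        if self.catalog is not None:
            wanted = self.modules if self.modules is not None else (
                frozenset(self.catalog.module_ids) & METHANOGENESIS_MODULES
                or self.catalog.module_ids
            )
            annotated = self.catalog.genes_in_any(wanted)
            genes = [g for g in genes if g in annotated]
        if not genes:
            raise ValueError("no pathway genes after filtering")
        std = standardize_genes(expr.subset_genes(genes))
        if not std.gene_ids:
            raise ValueError("no pathway genes after filtering (all zero-variance)")
        weights = compute_weights(std, self.epsilon)
        raw = compute_raw_activity(std, weights)
        _, self.mu_A_, self.sigma_A_ = normalize_activity(raw)
        self.gene_ids_ = std.gene_ids
        self.mu_ = std.mu
        self.sigma_ = std.sigma
        self.weights_ = weights.w
        self.dropped_zero_variance_ = std.dropped_zero_variance
        self.n_features_in_ = frame.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Score samples on the fitted index; returns shape (n_samples, 1)."""
        check_is_fitted(self, "gene_ids_")
        frame = self._as_frame(X)
        missing = [g for g in self.gene_ids_ if g not in frame.columns]
        if missing:
            raise ValueError(f"missing fitted genes in input: {missing[:5]}")
        values = frame[self.gene_ids_].to_numpy(dtype=float)
        z = (values - self.mu_) / self.sigma_
        raw = z @ self.weights_ / self.weights_.sum()
        return ((raw - self.mu_A_) / self.sigma_A_)[:, None]


def compute_mpeai(
    expr: ExpressionMatrix,
    catalog: ModuleCatalog | None = None,
    modules=None,
    tpm_threshold: float = 1.0,
    sample_fraction: float = 0.10,
    epsilon: float = 1e-6,
) -> ActivityProfile:
    """Run the full index on a genes x samples expression matrix.

    Composition: expression filter -> module restriction -> per-gene
    Z-scores -> inverse-variance weights -> weighted average -> cross-sample
    normalization. The returned :class:`ActivityProfile` records every
    parameter and the final gene count.
    """
    est = MethanogenesisActivityIndex(
        catalog=catalog,
        modules=modules,
        tpm_threshold=tpm_threshold,
        sample_fraction=sample_fraction,
        epsilon=epsilon,
    )
    frame = expr.to_frame().T
    normalized = est.fit_transform(frame).ravel()
    values = frame[est.gene_ids_].to_numpy(dtype=float)
    raw = ((values - est.mu_) / est.sigma_) @ est.weights_ / est.weights_.sum()
    used_modules = sorted(modules) if modules is not None else (
        sorted(frozenset(catalog.module_ids) & METHANOGENESIS_MODULES or catalog.module_ids)
        if catalog is not None
        else None
    )
    return ActivityProfile(
        sample_ids=list(expr.sample_ids),
        raw=raw,
        normalized=normalized,
        mu_A=est.mu_A_,
        sigma_A=est.sigma_A_,
        gene_count=len(est.gene_ids_),
        params={
            "tpm_threshold": tpm_threshold,
            "sample_fraction": sample_fraction,
            "epsilon": epsilon,
            "modules": used_modules,
            "layer": expr.layer,
        },
        dropped_zero_variance=est.dropped_zero_variance_,
    )


def write_activity(profile: ActivityProfile, tsv_path, json_path=None) -> None:
    """Write ``sample_id / raw_activity / mpeai`` TSV plus a JSON sidecar
    holding mu_A, sigma_A, gene count, dropped genes and parameters."""
    import json

    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\traw_activity\tmpeai\n")
        for sid, a, n in zip(profile.sample_ids, profile.raw, profile.normalized):
            fh.write(f"{sid}\t{float(a)!r}\t{float(n)!r}\n")
    if json_path is not None:
        meta = {
            "mu_A": profile.mu_A,
            "sigma_A": profile.sigma_A,
            "gene_count": profile.gene_count,
            "dropped_zero_variance": profile.dropped_zero_variance,
            "params": profile.params,
        }
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_activity(tsv_path) -> pd.DataFrame:
    """Read an activity TSV back as a DataFrame indexed by sample_id."""
    return pd.read_csv(
        tsv_path, sep="\t", index_col="sample_id", float_precision="round_trip"
    )
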