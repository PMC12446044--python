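"""Random-Forest discovery of taxa that drive pathway activity.

A regression forest predicts the normalized activity index from per-sample
taxon relative abundances (mtry = 3 candidate features per split,
ntree = 10,000 by default, matching common microbiome practice of small
mtry with a very large ensemble). Taxa are ranked by total node-impurity
decrease (the regression IncNodePurity), the top-k are screened with
Pearson correlation against the index, and taxa with significant negative
correlations (r < 0, p <= 0.05) become mitigation candidates. Because top
hits are often GTDB placeholder names without cultured representatives, a
second pass excludes uncultivated taxa and repeats the ranking and screen.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.utils.validation import check_is_fitted

from .activity import ActivityProfile
from .compare import bh_adjust
from .io import TaxonTable

logger = logging.getLogger(__name__)

# GTDB placeholder conventions: species epithet "sp" + >=9-digit genome
# accession, or an alphanumeric placeholder genus token (UBA1240, RUG023...).
UNCULTIVATED_EPITHET = re.compile(r"^sp\d{9,}$")
UNCULTIVATED_GENUS = re.compile(r"^[A-Z]{2,}[0-9]+(_[A-Z])?$")


@dataclass
class DriverReport:
    """Ranked driver table for one analysis pass.

    ``table`` has one row per ranked taxon with columns: importance, rank,
    pearson_r, pearson_p, p_adjusted, uncultivated, candidate. Ranks are a
    gap-free permutation of 1..k. ``candidate`` marks significant negative
    correlations (r < 0, raw p <= alpha), the mitigation-candidate rule.
    """

    pass_name: Literal["all_taxa", "cultivated_only"]
    table: pd.DataFrame
    alpha: float = 0.05


class DriverForest(RegressorMixin, BaseEstimator):
    """Random-forest regressor with node-purity taxon importances.

    Thin sklearn estimator around :class:`RandomForestRegressor` that fixes
    the analysis conventions: ``mtry`` is an absolute number of candidate
    features per split, importance is the *total* decrease in node variance
    summed over all trees (nonnegative; the regression analogue of R's
    IncNodePurity) rather than sklearn's normalized mean, and one master
    ``random_state`` seeds per-tree streams so any ``ntree`` is
    reproducible. ``importance="permutation"`` switches to permutation
    importance on the training data.

    Attributes (after fit): ``importances_`` (per-feature node-purity
    importance), ``feature_names_in_`` when fit on a DataFrame, and the
    underlying ``forest_``.
    """

    def __init__(
        self,
        mtry: int = 3,
        ntree: int = 10_000,
        importance: Literal["impurity", "permutation"] = "impurity",
        random_state: int | None = None,
    ):
        self.mtry = mtry
        self.ntree = ntree
        self.importance = importance
        self.random_state = random_state

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X_arr = X.to_numpy(dtype=float)
        else:
            X_arr = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.all(y == y[0]):
            raise ValueError("constant response: activity has no variance")
        self.forest_ = RandomForestRegressor(
            n_estimators=self.ntree,
            max_features=min(self.mtry, X_arr.shape[1]),
            random_state=self.random_state,
        ).fit(X_arr, y)
        if self.importance == "impurity":
            imp = np.zeros(X_arr.shape[1])
            for tree in self.forest_.estimators_:
                imp += tree.tree_.compute_feature_importances(normalize=False)
            # per-tree values are weighted by node sample fraction; scale by
            # n to report total variance decrease in response units
            self.importances_ = imp * X_arr.shape[0]
        else:
            from sklearn.inspection import permutation_importance

            res = permutation_importance(
                self.forest_, X_arr, y, n_repeats=10, random_state=self.random_state
            )
            self.importances_ = np.maximum(res.importances_mean, 0.0)
        return self

    def predict(self, X):
        check_is_fitted(self, "forest_")
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        return self.forest_.predict(np.asarray(X, dtype=float))


def _aligned_abundance(taxa: TaxonTable, activity: ActivityProfile) -> pd.DataFrame:
    """Samples x taxa abundance aligned to the activity sample order."""
    taxa_samples = set(taxa.sample_ids)
    act_samples = set(activity.sample_ids)
    if taxa_samples != act_samples:
        diff = sorted(taxa_samples.symmetric_difference(act_samples))
        raise ValueError(f"sample sets differ between taxa and activity: {diff}")
    return taxa.to_frame().T.loc[list(activity.sample_ids)]


def fit_rf_importance(
    taxa: TaxonTable,
    activity: ActivityProfile,
    mtry: int = 3,
    ntree: int = 10_000,
    seed: int | None = None,
) -> pd.Series:
    """Node-purity importance of every taxon for predicting the index."""
    X = _aligned_abundance(taxa, activity)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 samples for the random forest")
    est = DriverForest(mtry=mtry, ntree=ntree, random_state=seed)
    est.fit(X, activity.normalized)
    return pd.Series(est.importances_, index=X.columns, name="importance")


def rank_top_features(importance: pd.Series, k: int = 30) -> list[str]:
    """Top-k feature names by descending importance.

    Ties break by lexicographic name so the ranking is deterministic. If k
    exceeds the number of features, all are returned with a logged note.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > importance.size:
        logger.info("rank_top_features: k=%d > %d taxa; returning all", k, importance.size)
    order = sorted(importance.index, key=lambda t: (-importance[t], t))
    return order[:k]


def pearson_screen(
    taxa: TaxonTable,
    activity: ActivityProfile,
    candidates: Sequence[str],
) -> pd.DataFrame:
    """Pearson r (and two-sided t-test p) of each candidate vs the index.

    p comes from ``t = r sqrt(n-2) / sqrt(1-r^2)`` on n-2 degrees of
    freedom. A zero-variance abundance vector has undefined r; it is
    reported as NaN with a warning, never silently 0.
    """
    X = _aligned_abundance(taxa, activity)
    if X.shape[0] < 3:
        raise ValueError("pearson_screen: need at least 3 shared samples")
    missing = [c for c in candidates if c not in X.columns]
    if missing:
        raise ValueError(f"unknown candidate taxa: {missing[:5]}")
    y = np.asarray(activity.normalized, dtype=float)
    rows = []
    for taxon in candidates:
        x = X[taxon].to_numpy(dtype=float)
        if np.all(x == x[0]):
            logger.warning("pearson_screen: %r has zero variance; r undefined", taxon)
            rows.append((taxon, np.nan, np.nan))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((taxon, float(r), float(p)))
    return pd.DataFrame(rows, columns=["taxon", "pearson_r", "pearson_p"]).set_index("taxon")


def flag_uncultivated(
    taxon_names: Sequence[str],
    epithet_pattern: re.Pattern = UNCULTIVATED_EPITHET,
    genus_pattern: re.Pattern = UNCULTIVATED_GENUS,
) -> np.ndarray:
    """True where a GTDB name denotes an uncultivated lineage.

    A taxon is flagged when its species epithet is a genome-accession
    placeholder (``sp`` + >=9 digits, e.g. "Treponema_D sp004554075") or
    its genus token is an alphanumeric placeholder (e.g. "UBA2810",
    "RUG023"). Binomials with Latin epithets ("Treponema_D succinifaciens")
    are treated as cultivated. Patterns are configurable.
    """
    flags = np.zeros(len(taxon_names), dtype=bool)
    for i, name in enumerate(taxon_names):
        tokens = str(name).split()
        genus = tokens[0] if tokens else ""
        epithet = tokens[-1] if len(tokens) > 1 else ""
        flags[i] = bool(
            epithet_pattern.match(epithet) or genus_pattern.match(genus)
        )
    return flags


def _one_pass(
    taxa: TaxonTable,
    activity: ActivityProfile,
    pass_name: str,
    mtry: int,
    ntree: int,
    top_k: int,
    seed: int | None,
    alpha: float,
    flags: pd.Series,
) -> DriverReport:
    importance = fit_rf_importance(taxa, activity, mtry=mtry, ntree=ntree, seed=seed)
    top = rank_top_features(importance, k=top_k)
    screen = pearson_screen(taxa, activity, top)
    table = pd.DataFrame(
        {
            "importance": importance[top].to_numpy(),
            "rank": np.arange(1, len(top) + 1),
            "pearson_r": screen["pearson_r"].to_numpy(),
            "pearson_p": screen["pearson_p"].to_numpy(),
        },
        index=pd.Index(top, name="taxon"),
    )
    table["p_adjusted"] = bh_adjust(table["pearson_p"].to_numpy())
    table["uncultivated"] = flags[top].to_numpy()
    table["candidate"] = (table["pearson_r"] < 0) & (table["pearson_p"] <= alpha)
    return DriverReport(pass_name=pass_name, table=table, alpha=alpha)


def discover_drivers(
    taxa: TaxonTable,
    activity: ActivityProfile,
    mtry: int = 3,
    ntree: int = 10_000,
    top_k: int = 30,
    seed: int | None = None,
    alpha: float = 0.05,
) -> tuple[DriverReport, DriverReport]:
    """Two-pass driver discovery.

    Pass 1 ranks all taxa and Pearson-screens the top-k. Pass 2 removes
    taxa flagged uncultivated (GTDB placeholders), refits the forest and
    repeats ranking and screening, yielding candidates amenable to
    cultivation-based follow-up.
    """
    flags = pd.Series(flag_uncultivated(taxa.taxon_names), index=taxa.taxon_names)
    pass1 = _one_pass(
        taxa, activity, "all_taxa", mtry, ntree, top_k, seed, alpha, flags
    )
    cultivated = [t for t in taxa.taxon_names if not flags[t]]
    if len(cultivated) < 2:
        raise ValueError("cultivated-only pass needs at least 2 cultivated taxa")
    keep = [i for i, t in enumerate(taxa.taxon_names) if not flags[t]]
    taxa2 = TaxonTable(
        taxon_names=cultivated,
        sample_ids=list(taxa.sample_ids),
        abundance=taxa.abundance[keep],
        layer=taxa.layer,
        uncultivated=np.zeros(len(cultivated), dtype=bool),
    )
    pass2 = _one_pass(
        taxa2, activity, "cultivated_only", mtry, ntree, top_k, seed, alpha, flags
    )
    return pass1, pass2


def driver_table(reports: Sequence[DriverReport]) -> pd.DataFrame:
    """Concatenate pass reports into one flat output table."""
    frames = []
    for rep in reports:
        frame = rep.table.reset_index()
        frame.insert(0, "pass", rep.pass_name)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
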