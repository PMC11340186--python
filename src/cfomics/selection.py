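"""Training-cohort marker selection.

Each omics matrix is first filtered univariately (two-sided Wilcoxon
rank-sum per feature with Benjamini-Hochberg adjustment), then — for
methylation and end motif — reduced to a fixed marker count by random-forest
impurity importance. CNV uses the univariate filter only. Selection must
only ever see training samples; the pipeline enforces this by fitting
selection before any validation data is touched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DataError
from .matrix import FeatureMatrix

#: per-omics retained-marker targets
DEFAULT_N_SELECT = {"methylation": 23, "endmotif": 14, "cnv": 34}


@dataclass(frozen=True)
class SelectionConfig:
    univariate_alpha: float = 0.05
    n_select: dict = field(default_factory=lambda: dict(DEFAULT_N_SELECT))
    rf_trees: int = 500
    rf_seed: int = 0

    def validate(self) -> None:
        if not 0 < self.univariate_alpha <= 1:
            raise ConfigurationError("univariate_alpha must be in (0, 1]")
        if any(v < 1 for v in self.n_select.values()):
            raise ConfigurationError("n_select counts must be >= 1")
        if self.rf_trees < 1:
            raise ConfigurationError("rf_trees must be >= 1")


def univariate_filter(
    matrix: FeatureMatrix, labels: np.ndarray, alpha: float = 0.05
) -> pd.DataFrame:
    """Rank-sum test per feature with BH adjustment.

    Returns one row per feature (statistic, pvalue, p_adjusted, keep),
    sorted by feature id. Constant features get p=1 by convention.
    """
    labels = np.asarray(labels)
    if min((labels == 1).sum(), (labels == 0).sum()) < 2:
        raise DataError("need >= 2 samples per class for the univariate filter")
    X = matrix.values.to_numpy(dtype=float)
    case, ctrl = X[labels == 1], X[labels == 0]
    stat = np.zeros(X.shape[1])
    pval = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.all(col == col[0]):
            continue  # constant feature: p = 1 by convention
        res = stats.ranksums(case[:, j], ctrl[:, j])
        stat[j], pval[j] = res.statistic, res.pvalue
    _, p_adj, _, _ = multipletests(pval, method="fdr_bh")
    return pd.DataFrame({
        "feature_id": matrix.feature_ids,
        "statistic": stat,
        "pvalue": pval,
        "p_adjusted": p_adj,
        "keep": p_adj < alpha,
    })


def rf_select(
    matrix: FeatureMatrix,
    labels: np.ndarray,
    n_select: int,
    rf_trees: int = 500,
    rf_seed: int = 0,
) -> pd.DataFrame:
    """Top features by random-forest mean-decrease-in-impurity importance.

    Deterministic given rf_seed; importance ties break lexicographically on
    feature id. If fewer features than requested survive upstream, all are
    returned with a warning.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise DataError("labels contain a single class")
    feats = list(matrix.feature_ids)
    if len(feats) <= n_select:
        if len(feats) < n_select:
            warnings.warn(
                f"only {len(feats)} features available; n_select={n_select}",
                stacklevel=2,
            )
        return pd.DataFrame({
            "feature_id": feats,
            "importance": np.nan,
            "rank": np.arange(1, len(feats) + 1),
        })
    rf = RandomForestClassifier(
        n_estimators=rf_trees, random_state=rf_seed, n_jobs=1
    )
    # canonical row order: selection is invariant to input sample order
    order = np.argsort(np.asarray(matrix.sample_ids, dtype=object))
    rf.fit(matrix.values.to_numpy(dtype=float)[order], labels[order])
    imp = pd.DataFrame({"feature_id": feats, "importance": rf.feature_importances_})
    imp = imp.sort_values(
        ["importance", "feature_id"], ascending=[False, True], kind="stable"
    ).head(n_select)
    imp["rank"] = np.arange(1, len(imp) + 1)
    return imp.reset_index(drop=True)


def select_markers(
    matrix: FeatureMatrix,
    labels: np.ndarray,
    config: SelectionConfig = SelectionConfig(),
) -> pd.DataFrame:
    """Full selection path for one omics: univariate filter, then RF ranking.

    CNV skips the RF step (univariate filter only, capped at its n_select by
    adjusted p-value). Returns the selected features with their statistics.
    """
    config.validate()
    uni = univariate_filter(matrix, labels, alpha=config.univariate_alpha)
    surviving = uni.loc[uni["keep"], "feature_id"].tolist()
    target = config.n_select.get(matrix.omics, max(len(surviving), 1))
    candidates = uni[uni["keep"]]
    if not surviving:
        # nothing passes (e.g. a signal-free cohort): fall back to the
        # smallest raw p-values so downstream modeling stays defined
        warnings.warn(
            f"no {matrix.omics} feature passes the univariate filter; "
            "falling back to smallest raw p-values", stacklevel=2,
        )
        candidates = uni.sort_values(["pvalue", "feature_id"], kind="stable")
        surviving = candidates["feature_id"].head(max(target, 1) * 3).tolist()
    if matrix.omics == "cnv":
        kept = (
            candidates
            .sort_values(["p_adjusted", "pvalue", "feature_id"], kind="stable")
            .head(target)
            .copy()
        )
        kept["importance"] = np.nan
        kept["rank"] = np.arange(1, len(kept) + 1)
        return kept[["feature_id", "statistic", "pvalue", "p_adjusted", "importance", "rank"]]
    ranked = rf_select(
        matrix.restrict(surviving), labels, target,
        rf_trees=config.rf_trees, rf_seed=config.rf_seed,
    )
    out = ranked.merge(uni, on="feature_id", how="left")
    return out[["feature_id", "statistic", "pvalue", "p_adjusted", "importance", "rank"]]
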