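"""Per-omics logistic sub-models and the stacked integrated classifier.

Each omics feature block feeds a ridge-stabilized logistic regression fitted
on z-standardized training features. Out-of-fold probabilities from a
stratified tenfold partition — never in-fold fits — are stacked together
with the binary mutation score into a second logistic regression (the
integrated model), so the combiner is trained on honestly cross-validated
inputs. Decision cutoffs default to the Youden-index maximizer on the
training out-of-fold scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigurationError, DataError
from .matrix import FeatureMatrix

INTEGRATED_INPUTS = ("p_methylation", "p_endmotif", "p_cnv", "mutation_score")


@dataclass(frozen=True)
class CVPartition:
    """Stratified fold assignment over the training samples."""

    k: int
    assignments: dict  # sample_id -> fold index
    stratified: bool
    seed: int

    def fold_ids(self, fold: int) -> list[str]:
        return [s for s, f in self.assignments.items() if f == fold]


@dataclass
class SubModel:
    """One omics logistic model with its frozen preprocessing."""

    omics: str
    features: list[str]
    mean: np.ndarray
    sd: np.ndarray
    coef: np.ndarray
    intercept: float
    l2: float
    cutoff: float | None = None


@dataclass
class IntegratedModel:
    """Logistic combiner over the three sub-model probabilities + mutation score."""

    coef: np.ndarray  # aligned to INTEGRATED_INPUTS
    intercept: float
    l2: float
    cutoff: float | None = None
    cv: CVPartition | None = None


def make_cv_partition(labels: pd.Series, k: int = 10, seed: int = 0) -> CVPartition:
    """Stratified k-fold assignment; per-fold class counts differ by <= 1.

    ``labels`` is indexed by sample_id with values in {0, 1} (or case/control
    strings). Classes smaller than k are rejected.
    """
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    y = _as_binary(labels)
    counts = pd.Series(y).value_counts()
    if len(counts) < 2 or counts.min() < k:
        raise DataError(f"each class needs >= k={k} samples for k-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    ids = np.asarray(labels.index)
    assignments = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        for i in test_idx:
            assignments[str(ids[i])] = fold
    return CVPartition(k=k, assignments=assignments, stratified=True, seed=seed)


def _as_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "OUS":
        return (arr == "case").astype(int)
    uniq = set(np.unique(arr).tolist())
    if not uniq <= {0, 1}:
        raise DataError(f"labels must be binary, got values {sorted(uniq)[:5]}")
    return arr.astype(int)


def _fit_logistic(X: np.ndarray, y: np.ndarray, l2: float) -> tuple[np.ndarray, float]:
    """Ridge-penalized ML logistic fit; penalty strength lambda = l2 * n."""
    n = X.shape[0]
    C = 1.0 / (l2 * n) if l2 > 0 else np.inf
    clf = LogisticRegression(
        C=C, solver="newton-cholesky", tol=1e-12, max_iter=500
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=UserWarning)
        try:
            clf.fit(X, y)
        except Warning as w:  # convergence failures surface as warnings
            raise DataError(f"logistic fit did not converge: {w}") from w
    return clf.coef_.ravel().copy(), float(clf.intercept_[0])


def fit_submodel(
    matrix: FeatureMatrix,
    labels: pd.Series,
    features: list[str],
    l2: float = 1e-4,
) -> SubModel:
    """Fit one omics logistic model on z-standardized training features.

    Zero-variance features are dropped at fit time (their z-score is
    undefined); the small ridge penalty keeps the fit defined under complete
    separation.
    """
    y = _as_binary(labels)
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise DataError("need >= 2 samples per class to fit a sub-model")
    sub = matrix.restrict(features)
    X = sub.values.loc[list(labels.index)].to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    # relative floor so constant features survive float round-off as zeros
    keep = sd > 1e-9 * np.maximum(1.0, np.abs(mean))
    if not keep.any():
        raise DataError("all selected features have zero variance")
    kept = [f for f, k in zip(features, keep) if k]
    Xz = (X[:, keep] - mean[keep]) / sd[keep]
    coef, intercept = _fit_logistic(Xz, y, l2)
    return SubModel(
        omics=matrix.omics, features=kept, mean=mean[keep], sd=sd[keep],
        coef=coef, intercept=intercept, l2=l2,
    )


def predict_submodel(model: SubModel, matrix: FeatureMatrix) -> pd.Series:
    """Probability of case for each sample under a fitted sub-model."""
    X = matrix.restrict(model.features).values.to_numpy(dtype=float)
    z = (X - model.mean) / model.sd
    logit = z @ model.coef + model.intercept
    return pd.Series(1.0 / (1.0 + np.exp(-logit)), index=matrix.sample_ids)


def cross_val_probs(
    matrix: FeatureMatrix,
    labels: pd.Series,
    partition: CVPartition,
    features: list[str],
    l2: float = 1e-4,
) -> pd.Series:
    """Out-of-fold probability for every training sample.

    Standardization and coefficients are re-fit for each fold on the other
    k-1 folds; the feature list is fixed (selection performed upstream on the
    full training cohort).
    """
    ids = list(labels.index)
    unknown = [s for s in ids if s not in partition.assignments]
    if unknown:
        raise DataError(f"samples missing from CV partition: {unknown[:5]}")
    probs = pd.Series(np.nan, index=ids, dtype=float)
    for fold in range(partition.k):
        test_ids = [s for s in ids if partition.assignments[s] == fold]
        train_ids = [s for s in ids if partition.assignments[s] != fold]
        y_train = labels.loc[train_ids]
        if len(set(_as_binary(y_train))) < 2:
            raise DataError(
                f"fold {fold} leaves a single-class training set; use fewer folds"
            )
        model = fit_submodel(
            matrix.subset_samples(train_ids), y_train, features, l2=l2
        )
        probs.loc[test_ids] = predict_submodel(
            model, matrix.subset_samples(test_ids)
        ).to_numpy()
    if probs.isna().any():
        raise DataError("some samples received no out-of-fold probability")
    return probs


def stack_inputs(
    p_meth: pd.Series, p_motif: pd.Series, p_cnv: pd.Series, mut_score: pd.Series
) -> pd.DataFrame:
    """Aligned 4-column input table for the integrated model."""
    df = pd.DataFrame({
        "p_methylation": p_meth,
        "p_endmotif": p_motif,
        "p_cnv": p_cnv,
        "mutation_score": mut_score,
    })
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise DataError(f"stack inputs not aligned; missing for {bad[:5]}")
    if not set(np.unique(df["mutation_score"])) <= {0, 1}:
        raise DataError("mutation_score must be 0 or 1")
    return df


def fit_integrated(
    inputs: pd.DataFrame,
    labels: pd.Series,
    l2: float = 1e-4,
    partition: CVPartition | None = None,
) -> tuple[IntegratedModel, pd.Series | None]:
    """Fit the integrated logistic model on out-of-fold sub-model inputs.

    When a partition is given, integrated out-of-fold probabilities are also
    computed by re-fitting the combiner per fold on the same partition, and
    returned for training-cohort evaluation.
    """
    df = inputs[list(INTEGRATED_INPUTS)]
    y = _as_binary(labels.loc[df.index])
    coef, intercept = _fit_logistic(df.to_numpy(dtype=float), y, l2)
    model = IntegratedModel(coef=coef, intercept=intercept, l2=l2, cv=partition)

    oof = None
    if partition is not None:
        oof = pd.Series(np.nan, index=df.index, dtype=float)
        for fold in range(partition.k):
            test = [s for s in df.index if partition.assignments[s] == fold]
            train = [s for s in df.index if partition.assignments[s] != fold]
            c, b = _fit_logistic(
                df.loc[train].to_numpy(dtype=float), _as_binary(labels.loc[train]), l2
            )
            logit = df.loc[test].to_numpy(dtype=float) @ c + b
            oof.loc[test] = 1.0 / (1.0 + np.exp(-logit))
    return model, oof


def predict_integrated(model: IntegratedModel, inputs: pd.DataFrame) -> pd.Series:
    df = inputs[list(INTEGRATED_INPUTS)]
    logit = df.to_numpy(dtype=float) @ model.coef + model.intercept
    return pd.Series(1.0 / (1.0 + np.exp(-logit)), index=df.index)


def choose_cutoff(
    probs: pd.Series | np.ndarray,
    labels,
    method: str = "youden",
    specificity_target: float = 0.95,
) -> float:
    """Decision threshold on out-of-fold probabilities (call = prob >= cutoff).

    "youden" maximizes sensitivity + specificity - 1 over the observed
    scores, ties resolved to the smallest cutoff; "specificity_floor" takes
    the smallest observed cutoff whose specificity reaches the target.
    """
    p = np.asarray(probs, dtype=float)
    y = _as_binary(labels)
    if len(p) != len(y):
        raise DataError("probs and labels length mismatch")
    candidates = np.unique(p)
    if len(candidates) == 1:
        warnings.warn("all scores identical; degenerate cutoff", stacklevel=2)
        return float(candidates[0])
    n_case, n_ctrl = (y == 1).sum(), (y == 0).sum()
    best_t, best_j = None, -np.inf
    for t in candidates:
        call = p >= t
        sens = (call & (y == 1)).sum() / n_case
        spec = (~call & (y == 0)).sum() / n_ctrl
        if method == "youden":
            j = sens + spec - 1.0
            if j > best_j + 1e-12:
                best_t, best_j = t, j
        elif method == "specificity_floor":
            if spec >= specificity_target:
                return float(t)
        else:
            raise ConfigurationError(f"unknown cutoff method {method!r}")
    if method == "specificity_floor":
        warnings.warn("specificity target unattainable; using max score", stacklevel=2)
        return float(candidates[-1])
    return float(best_t)
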