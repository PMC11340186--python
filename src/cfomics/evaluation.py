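"""Classifier evaluation: ROC/AUC with confidence intervals, binomial
sensitivity/specificity, per-stage sensitivity, and single-marker baselines.

The AUC point estimate is the Mann-Whitney concordance (ties counted 1/2);
its default confidence interval is analytic DeLong, with a stratified
percentile bootstrap as the alternative. Proportions carry exact
Clopper-Pearson intervals by default (Wilson selectable) and are rendered to
one decimal percent with half-up rounding in reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.proportion import proportion_confint

from .errors import DataError
from .stack import _as_binary


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    method: str
    n_cases: int
    n_controls: int
    curve: pd.DataFrame  # columns fpr, tpr


@dataclass
class BinaryPerf:
    sensitivity: float
    specificity: float
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]
    n_cases: int
    n_controls: int
    by_stage: pd.DataFrame | None = None  # stage, positives, total, rate


def percent(x: float, decimals: int = 1) -> float:
    """Render a fraction as a percentage rounded half-up (0.419 -> 41.9)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x) * 100)).quantize(q, rounding=ROUND_HALF_UP))


def roc_auc(scores, labels) -> ROCResult:
    """AUC as pairwise concordance plus the empirical ROC curve (no CI yet)."""
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise DataError("both classes must be present to compute an AUC")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, _ = roc_curve(y, s)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return ROCResult(auc=auc, ci_low=np.nan, ci_high=np.nan, method="point",
                     n_cases=n1, n_controls=n0, curve=curve)


def _delong_variance(scores: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """DeLong AUC and variance via midrank structural components."""
    pos, neg = scores[y == 1], scores[y == 0]
    m, n = len(pos), len(neg)
    combined = np.concatenate([pos, neg])
    rank_all = stats.rankdata(combined)
    rank_pos = stats.rankdata(pos)
    rank_neg = stats.rankdata(neg)
    # V10[i] = P(neg < pos_i) + 0.5 P(neg == pos_i)
    v10 = (rank_all[:m] - rank_pos) / n
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m
    auc = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def auc_ci(
    scores, labels, method: str = "delong", level: float = 0.95,
    seed: int = 0, n_boot: int = 2000,
) -> tuple[float, float]:
    """Confidence interval for the AUC, clipped to [0, 1].

    "delong" uses the analytic variance; a degenerate variance (e.g. perfect
    separation) falls back to [auc, 1.0] with a warning. "bootstrap" draws
    stratified resamples and takes percentile bounds (seed-deterministic).
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    if method == "delong":
        auc, var = _delong_variance(s, y)
        if var <= 0:
            warnings.warn("degenerate DeLong variance; CI set to [auc, 1.0]",
                          stacklevel=2)
            return (auc, 1.0)
        z = stats.norm.ppf(0.5 + level / 2)
        half = z * np.sqrt(var)
        return (max(0.0, auc - half), min(1.0, auc + half))
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos_idx, neg_idx = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            take = np.concatenate([
                rng.choice(pos_idx, size=len(pos_idx), replace=True),
                rng.choice(neg_idx, size=len(neg_idx), replace=True),
            ])
            aucs[b] = roc_auc_score(y[take], s[take])
        lo, hi = np.quantile(aucs, [(1 - level) / 2, 0.5 + level / 2])
        return (max(0.0, float(lo)), min(1.0, float(hi)))
    raise DataError(f"unknown CI method {method!r}")


def roc_with_ci(scores, labels, method: str = "delong", level: float = 0.95,
                seed: int = 0) -> ROCResult:
    res = roc_auc(scores, labels)
    res.ci_low, res.ci_high = auc_ci(scores, labels, method=method,
                                     level=level, seed=seed)
    res.method = method
    return res


def proportion(
    successes: int, total: int, method: str = "clopper-pearson", level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Exact rate with a binomial confidence interval.

    Returns ``(rate, (low, high))``; rate is successes/total exactly.
    """
    if total <= 0:
        raise DataError("total must be > 0")
    if not 0 <= successes <= total:
        raise DataError("successes must be in [0, total]")
    stats_method = {"clopper-pearson": "beta", "wilson": "wilson"}.get(method)
    if stats_method is None:
        raise DataError(f"unknown proportion CI method {method!r}")
    lo, hi = proportion_confint(successes, total, alpha=1 - level, method=stats_method)
    return successes / total, (float(lo), float(hi))


def binary_performance(
    calls, labels, stages: pd.Series | None = None,
    ci_method: str = "clopper-pearson",
) -> BinaryPerf:
    """Sensitivity/specificity of binary calls with binomial CIs.

    ``stages`` (indexed like the samples, values I-IV or none) adds the
    per-stage sensitivity table over case samples only.
    """
    c = np.asarray(calls).astype(int)
    y = _as_binary(labels)
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise DataError("both classes required")
    tp = int((c[y == 1] == 1).sum())
    tn = int((c[y == 0] == 0).sum())
    sens, sens_ci = proportion(tp, n1, method=ci_method)
    spec, spec_ci = proportion(tn, n0, method=ci_method)
    by_stage = None
    if stages is not None:
        by_stage = stage_stratified_sensitivity(c, y, np.asarray(stages))
    return BinaryPerf(sens, spec, sens_ci, spec_ci, n1, n0, by_stage)


def stage_stratified_sensitivity(calls, labels, stages) -> pd.DataFrame:
    """Per-stage (positives, total, rate) over case samples only.

    Stages with no cases are omitted. Rates are exact fractions; the
    ``rate_percent`` column applies the one-decimal half-up rendering.
    """
    c = np.asarray(calls).astype(int)
    y = _as_binary(labels)
    st = np.asarray(stages, dtype=object)
    rows = []
    for stage in ("I", "II", "III", "IV"):
        in_stage = (st == stage) & (y == 1)
        total = int(in_stage.sum())
        if total == 0:
            continue
        pos = int(c[in_stage].sum())
        rate, ci = proportion(pos, total)
        rows.append({"stage": stage, "positives": pos, "total": total,
                     "rate": rate, "rate_percent": percent(rate),
                     "ci_low": ci[0], "ci_high": ci[1]})
    return pd.DataFrame(rows)


def single_marker_eval(
    values, labels, threshold: float, stages=None
) -> tuple[BinaryPerf, ROCResult]:
    """Threshold a single continuous biomarker and evaluate it like a model.

    A sample is called positive when its value is >= threshold; used for
    protein-marker (CEA-style) baselines.
    """
    v = np.asarray(values, dtype=float)
    calls = (v >= threshold).astype(int)
    perf = binary_performance(calls, labels, stages=stages)
    roc = roc_with_ci(v, labels)
    return perf, roc


def performance_report(
    scores: pd.Series, labels: pd.Series, cutoff: float,
    stages: pd.Series | None = None, seed: int = 0,
) -> dict:
    """JSON-ready metrics block for one model on one cohort."""
    roc = roc_with_ci(scores, labels, seed=seed)
    calls = (np.asarray(scores, dtype=float) >= cutoff).astype(int)
    perf = binary_performance(calls, labels, stages=stages)
    out = {
        "auc": roc.auc, "auc_ci": [roc.ci_low, roc.ci_high],
        "cutoff": cutoff,
        "sensitivity": perf.sensitivity,
        "sensitivity_percent": percent(perf.sensitivity),
        "sensitivity_ci": list(perf.sens_ci),
        "specificity": perf.specificity,
        "specificity_percent": percent(perf.specificity),
        "specificity_ci": list(perf.spec_ci),
        "n_cases": perf.n_cases, "n_controls": perf.n_controls,
    }
    if perf.by_stage is not None and len(perf.by_stage):
        out["by_stage"] = perf.by_stage.to_dict(orient="records")
    return out
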