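"""Targeted DNA methylation features.

The methylation level (beta) of a marker is the fraction of methylated
molecules among all molecules covering it. Markers with coverage below a
floor are treated as missing and imputed with the training-cohort per-marker
median; imputation medians are persisted so validation cohorts reuse them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import DataError
from .matrix import FeatureMatrix

DEFAULT_MIN_MOLECULES = 10


def methylation_level(
    methylated: int, unmethylated: int, min_molecules: int = DEFAULT_MIN_MOLECULES
) -> float:
    """Beta value methylated/(methylated+unmethylated), NaN below coverage floor.

    Raises DataError for negative or non-integer counts.
    """
    for name, v in (("methylated", methylated), ("unmethylated", unmethylated)):
        if not float(v).is_integer() or v < 0:
            raise DataError(f"{name} count must be a non-negative integer, got {v!r}")
    total = methylated + unmethylated
    if total == 0 or total < min_molecules:
        return float("nan")
    return methylated / total


def build_methylation_matrix(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    min_molecules: int = DEFAULT_MIN_MOLECULES,
    impute_medians: pd.Series | None = None,
) -> tuple[FeatureMatrix, pd.Series]:
    """Assemble the samples x markers beta matrix with median imputation.

    When ``impute_medians`` is None the medians are fitted from this (training)
    cohort; pass the fitted Series to process a validation cohort without
    leakage. Markers missing in every sample are dropped with a warning.
    Returns ``(matrix, medians_used)``.
    """
    required = {"sample_id", "marker_id", "methylated", "unmethylated"}
    if not required.issubset(counts.columns):
        raise DataError(f"methylation table must have columns {sorted(required)}")
    known = set(samples["sample_id"])
    stray = set(counts["sample_id"]) - known
    if stray:
        raise DataError(f"counts reference unknown samples: {sorted(stray)[:5]}")
    dup = counts.duplicated(subset=["sample_id", "marker_id"])
    if dup.any():
        pairs = counts.loc[dup, ["sample_id", "marker_id"]].values.tolist()
        raise DataError(f"duplicate (sample, marker) pairs: {pairs[:5]}")
    neg = (counts[["methylated", "unmethylated"]] < 0).any(axis=1)
    if neg.any():
        raise DataError("negative molecule counts in methylation table")

    total = counts["methylated"] + counts["unmethylated"]
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = counts["methylated"] / total
    beta = beta.where(total >= max(min_molecules, 1), np.nan)

    wide = (
        counts.assign(beta=beta)
        .pivot(index="sample_id", columns="marker_id", values="beta")
        .reindex(index=list(samples["sample_id"]))
        .sort_index(axis=1)
    )
    wide.columns.name = None
    wide.index.name = None

    all_missing = wide.columns[wide.isna().all(axis=0)]
    if impute_medians is None and len(all_missing):
        warnings.warn(
            f"dropping {len(all_missing)} markers with no coverage in any sample",
            stacklevel=2,
        )
        wide = wide.drop(columns=all_missing)

    if impute_medians is None:
        medians = wide.median(axis=0, skipna=True)
    else:
        medians = impute_medians
        wide = wide.reindex(columns=medians.index)
    mask = wide.isna()
    filled = wide.fillna(medians)
    if filled.isna().any().any():
        raise DataError("markers remain NaN after imputation (no median available)")
    return FeatureMatrix(filled, "methylation", mask), medians
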