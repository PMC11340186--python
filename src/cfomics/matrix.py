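"""Samples-by-features container shared by all omics extractors."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

VALID_OMICS = ("methylation", "endmotif", "cnv")


@dataclass
class FeatureMatrix:
    """A numeric samples x features table tagged with its omics of origin.

    ``values`` holds the (possibly imputed) numbers; ``missing`` marks the
    entries that were absent before imputation. No NaN is allowed outside
    the missing mask.
    """

    values: pd.DataFrame
    omics: str
    missing: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.omics not in VALID_OMICS:
            raise DataError(f"unknown omics tag {self.omics!r}")
        if self.missing is None:
            self.missing = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        if self.missing.shape != self.values.shape:
            raise DataError("missing mask shape differs from values")
        nan_outside = self.values.isna().to_numpy() & ~self.missing.to_numpy()
        if nan_outside.any():
            raise DataError("NaN present outside the missing mask")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    def restrict(self, feature_ids: list[str]) -> "FeatureMatrix":
        """View restricted to (and ordered by) the given features."""
        missing_cols = [f for f in feature_ids if f not in self.values.columns]
        if missing_cols:
            raise DataError(f"features not in matrix: {missing_cols[:5]}")
        return FeatureMatrix(
            self.values[feature_ids].copy(), self.omics,
            self.missing[feature_ids].copy(),
        )

    def subset_samples(self, sample_ids: list[str]) -> "FeatureMatrix":
        absent = [s for s in sample_ids if s not in self.values.index]
        if absent:
            raise DataError(f"samples not in matrix: {absent[:5]}")
        return FeatureMatrix(
            self.values.loc[sample_ids].copy(), self.omics,
            self.missing.loc[sample_ids].copy(),
        )

    def to_tsv(self, path) -> None:
        self.values.rename_axis("sample_id").to_csv(path, sep="\t")


def align_labels(matrix: FeatureMatrix, samples: pd.DataFrame) -> np.ndarray:
    """Binary label vector (case=1) aligned to the matrix row order."""
    lab = samples.set_index("sample_id")["label"]
    missing = [s for s in matrix.sample_ids if s not in lab.index]
    if missing:
        raise DataError(f"samples absent from sample sheet: {missing[:5]}")
    return (lab.loc[matrix.sample_ids] == "case").to_numpy().astype(int)
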