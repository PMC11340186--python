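"""Arm-level copy-number features from shallow-WGS bin counts.

A transparent surrogate for HMM-based CNV callers: per-sample GC correction
(stratified median normalization), log2 ratio to a panel-of-normals
reference, per-sample median centering, and length-weighted arm averaging.
It produces relative arm dosage features, not absolute copy calls or tumor
fractions; median centering assumes less than half the genome is altered.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError
from .matrix import FeatureMatrix

BIN_KEY = ["chrom", "start", "end"]
DEFAULT_MIN_BINS = 10


def gc_correct(bins: pd.DataFrame, n_strata: int = 10, min_distinct_gc: int = 5) -> pd.Series:
    """Divide each bin count by the smoothed median count of its GC stratum.

    Strata are GC deciles; stratum medians are smoothed with a centered
    rolling median and linearly interpolated at each bin's GC. The result is
    scale-free (multiplying all counts by c>0 leaves it unchanged) and
    centred near 1.
    """
    for col in ("gc", "count"):
        if col not in bins.columns:
            raise DataError(f"bin table must have a {col!r} column")
    gc = bins["gc"].to_numpy(dtype=float)
    count = bins["count"].to_numpy(dtype=float)
    if (count < 0).any():
        raise DataError("negative bin counts")
    if not (count > 0).any():
        raise DataError("all bin counts are zero")
    if len(np.unique(gc)) < min_distinct_gc:
        raise DataError(
            f"need >= {min_distinct_gc} distinct GC values, got {len(np.unique(gc))}"
        )
    # decile strata on GC ranks; duplicate edges collapse for degenerate inputs
    quantiles = np.quantile(gc, np.linspace(0, 1, n_strata + 1))
    edges = np.unique(quantiles)
    if len(edges) <= 2:
        med = np.median(count)
        return pd.Series(count / med, index=bins.index, name="corrected")
    stratum = np.clip(np.searchsorted(edges, gc, side="right") - 1, 0, len(edges) - 2)
    centers, medians = [], []
    for s in range(len(edges) - 1):
        in_s = stratum == s
        if not in_s.any():
            continue
        centers.append(np.median(gc[in_s]))
        medians.append(np.median(count[in_s]))
    medians = pd.Series(medians).rolling(3, center=True, min_periods=1).median().to_numpy()
    expected = np.interp(gc, centers, medians)
    if (expected <= 0).any():
        raise DataError("GC stratum median is zero; cannot correct")
    return pd.Series(count / expected, index=bins.index, name="corrected")


def panel_of_normals(control_bins: pd.DataFrame) -> pd.DataFrame:
    """Per-bin median of GC-corrected values across control samples.

    ``control_bins`` holds stacked bin tables (sample_id column). Returns the
    bin grid with a ``reference`` column.
    """
    parts = []
    for sid, sub in control_bins.groupby("sample_id", observed=True):
        sub = sub.reset_index(drop=True)
        parts.append(sub[BIN_KEY].assign(value=gc_correct(sub).to_numpy()))
    stacked = pd.concat(parts, ignore_index=True)
    # keep the bin-grid order of first occurrence so downstream alignment
    # with per-sample tables stays positional
    ref = (
        stacked.groupby(BIN_KEY, sort=False)["value"]
        .median().rename("reference").reset_index()
    )
    return ref.reset_index(drop=True)


def arm_log2_ratios(
    corrected: pd.DataFrame,
    reference: pd.DataFrame,
    arm_table: pd.DataFrame,
    min_bins: int = DEFAULT_MIN_BINS,
) -> pd.Series:
    """Length-weighted mean log2(sample/reference) per chromosome arm.

    ``corrected`` needs BIN_KEY plus a ``corrected`` column on exactly the
    reference's bin grid; per-sample median centering sets the genome-wide
    median log2 ratio to 0. Arms with fewer than ``min_bins`` usable bins are
    dropped.
    """
    sample_vals, ref_vals, grid = _aligned_values(corrected, reference)
    usable = (sample_vals > 0) & (ref_vals > 0)
    if not usable.any():
        raise DataError("no usable bins after filtering nonpositive values")
    chrom = grid[0][usable]
    start = grid[1][usable]
    end = grid[2][usable]
    log2r = np.log2(sample_vals[usable] / ref_vals[usable])
    log2r = log2r - np.median(log2r)

    # assign each bin to the arm containing its start
    arm_vals = {}
    for row in arm_table.itertuples(index=False):
        in_arm = (chrom == row.chrom) & (start >= row.start) & (start < row.end)
        if in_arm.sum() < max(min_bins, 1):
            continue
        weights = (end[in_arm] - start[in_arm]).astype(float)
        arm_vals[row.arm_id] = float(np.average(log2r[in_arm], weights=weights))
    if not arm_vals:
        raise DataError("no arm had enough usable bins")
    return pd.Series(arm_vals, name="log2_ratio")


def _aligned_values(corrected: pd.DataFrame, reference: pd.DataFrame):
    """Align a sample's corrected bins to the reference grid (fast path when
    both are already on the identical sorted grid, merge otherwise)."""
    same = len(corrected) == len(reference) and all(
        np.array_equal(corrected[c].to_numpy(), reference[c].to_numpy())
        for c in ("start", "chrom")
    )
    if same:
        grid = tuple(reference[c].to_numpy() for c in ("chrom", "start", "end"))
        return (corrected["corrected"].to_numpy(dtype=float),
                reference["reference"].to_numpy(dtype=float), grid)
    merged = reference.merge(corrected, on=BIN_KEY, how="outer", indicator=True)
    mismatch = merged[merged["_merge"] != "both"]
    if len(mismatch):
        first = mismatch.iloc[0]
        raise DataError(
            "bin grid mismatch with reference; first differing bin "
            f"{first['chrom']}:{int(first['start'])}-{int(first['end'])}"
        )
    merged = merged.sort_values(BIN_KEY, kind="stable")
    grid = tuple(merged[c].to_numpy() for c in ("chrom", "start", "end"))
    return (merged["corrected"].to_numpy(dtype=float),
            merged["reference"].to_numpy(dtype=float), grid)


def sample_arm_features(
    bins: pd.DataFrame,
    reference: pd.DataFrame,
    arm_table: pd.DataFrame,
    min_bins: int = DEFAULT_MIN_BINS,
) -> pd.Series:
    """GC-correct one sample's bin table and summarize to arm log2 ratios."""
    bins = bins.reset_index(drop=True)
    corr = bins[BIN_KEY].assign(corrected=gc_correct(bins).to_numpy())
    return arm_log2_ratios(corr, reference, arm_table, min_bins=min_bins)


def build_cnv_matrix(
    arm_features: dict[str, pd.Series], samples: pd.DataFrame
) -> FeatureMatrix:
    """Samples x arms matrix; arms absent for a sample are imputed 0 with mask."""
    missing_samples = [s for s in samples["sample_id"] if s not in arm_features]
    if missing_samples:
        raise DataError(f"no arm features for samples: {missing_samples[:5]}")
    values = pd.DataFrame(
        {sid: arm_features[sid] for sid in samples["sample_id"]}
    ).T.sort_index(axis=1)
    values.index.name = None
    mask = values.isna()
    return FeatureMatrix(values.fillna(0.0), "cnv", mask)
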