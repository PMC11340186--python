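"""Chromosome-arm definitions and bin grids for arm-level copy-number features.

Coordinates are an approximate GRCh37 autosome map at 1 Mb resolution:
arm boundaries are taken from rounded centromere midpoints, which is
sufficient for arm-level summaries (the acrocentric short arms 13p, 14p,
15p, 21p and 22p carry no usable sequence and are excluded by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# (chrom, length_mb, centromere_mb) -- rounded GRCh37 values
_AUTOSOMES = [
    ("chr1", 249, 125), ("chr2", 243, 93), ("chr3", 198, 91),
    ("chr4", 191, 50), ("chr5", 181, 48), ("chr6", 171, 60),
    ("chr7", 159, 60), ("chr8", 146, 45), ("chr9", 141, 49),
    ("chr10", 136, 40), ("chr11", 135, 53), ("chr12", 134, 36),
    ("chr13", 115, 18), ("chr14", 107, 17), ("chr15", 103, 19),
    ("chr16", 90, 37), ("chr17", 81, 24), ("chr18", 78, 17),
    ("chr19", 59, 27), ("chr20", 63, 28), ("chr21", 48, 13),
    ("chr22", 51, 15),
]

#: short arms with no assayable sequence content
ACROCENTRIC_P_ARMS = frozenset({"13p", "14p", "15p", "21p", "22p"})

MB = 1_000_000


def default_arm_table(exclude_acrocentric_p: bool = True) -> pd.DataFrame:
    """Arm definition table with columns arm_id, chrom, start, end (bp, 0-based half-open)."""
    rows = []
    for chrom, length, cen in _AUTOSOMES:
        num = chrom[3:]
        rows.append((f"{num}p", chrom, 0, cen * MB))
        rows.append((f"{num}q", chrom, cen * MB, length * MB))
    arms = pd.DataFrame(rows, columns=["arm_id", "chrom", "start", "end"])
    if exclude_acrocentric_p:
        arms = arms[~arms["arm_id"].isin(ACROCENTRIC_P_ARMS)].reset_index(drop=True)
    return arms


def make_bin_grid(arm_table: pd.DataFrame, bin_size: int = MB) -> pd.DataFrame:
    """Tile each arm with fixed-size bins (last partial bin per arm dropped).

    Returns columns chrom, start, end, arm_id.
    """
    frames = []
    for row in arm_table.itertuples(index=False):
        starts = np.arange(row.start, row.end - bin_size + 1, bin_size, dtype=np.int64)
        if len(starts) == 0:
            continue
        frames.append(pd.DataFrame({
            "chrom": row.chrom,
            "start": starts,
            "end": starts + bin_size,
            "arm_id": row.arm_id,
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_bin_gc(n_bins: int, seed: int = 20240822) -> np.ndarray:
    """Deterministic per-bin GC fractions emulating the genome's GC landscape.

    GC varies smoothly along the grid (isochore-like autocorrelation) around a
    genome-wide mean of ~0.41. The seed is a fixed constant: GC is a property
    of the bin grid, not of any cohort.
    """
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, 0.012, size=n_bins)
    walk = np.cumsum(steps)
    # mean-revert the walk so GC stays in a realistic band
    walk -= np.linspace(walk[0], walk[-1], n_bins)
    gc = 0.41 + 0.05 * np.tanh(walk) + rng.normal(0.0, 0.015, size=n_bins)
    return np.clip(gc, 0.28, 0.62)
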