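"""Extract the four omics feature sets for both cohorts.

Builds methylation beta matrices (median-imputed from training), 256-motif
frequency matrices, GC-corrected arm-level CNV log2 ratios against a
training-control panel of normals, and binary mutation scores. Writes the
matrices under scratch/run-default/features and a per-omics signal summary
(case-vs-control separation) to results/02_feature_summary.tsv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import importlib

common = importlib.import_module("00_common")

import numpy as np
import pandas as pd

from cfomics.workbench import Run, run_pipeline


def main() -> None:
    run_pipeline(common.RUN_DIR, common.CONFIG, common.SEED, stages=["features"])
    run = Run(common.RUN_DIR, common.CONFIG, common.SEED)
    feats = run._read_features("train")
    y = (feats.labels == "case").to_numpy()
    rows = []
    for omics, m in feats.matrices.items():
        X = m.values.to_numpy(dtype=float)
        case_mean = X[y].mean(axis=0)
        ctrl_mean = X[~y].mean(axis=0)
        pooled_sd = X.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.abs(case_mean - ctrl_mean) / pooled_sd
        rows.append({
            "omics": omics, "n_features": X.shape[1],
            "median_effect_size_d": float(np.nanmedian(d)),
            "max_effect_size_d": float(np.nanmax(d)),
            "fraction_missing": float(m.missing.to_numpy().mean()),
        })
        print(f"{omics}: {X.shape[1]} features, median |d| "
              f"{np.nanmedian(d):.3f}, max |d| {np.nanmax(d):.3f}")
    mut = feats.mut_scores.loc[feats.labels.index].to_numpy()
    print(f"mutation score positivity: cases {mut[y].mean():.3f}, "
          f"controls {mut[~y].mean():.3f}")
    out = common.results_dir() / "02_feature_summary.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
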