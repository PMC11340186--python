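"""Simulate the two-arm study cohorts (training 93 CRC / 96 healthy,
validation 89 / 95) and summarize their composition.

Writes the full cohort tables (fragments, methylation counts, bins,
mutation calls) under scratch/run-default and a compact cohort summary to
results/01_cohort_summary.tsv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import importlib

common = importlib.import_module("00_common")

import pandas as pd

from cfomics.workbench import run_pipeline


def main() -> None:
    run_pipeline(common.RUN_DIR, common.CONFIG, common.SEED, stages=["simulate"])
    rows = []
    for role in ("train", "validation"):
        samples = pd.read_csv(common.RUN_DIR / f"cohorts/{role}/samples.tsv",
                              sep="\t")
        cases = samples[samples["label"] == "case"]
        row = {
            "cohort": role,
            "n_cases": len(cases),
            "n_controls": (samples["label"] == "control").sum(),
            "median_tumor_fraction": cases["tumor_fraction"].median(),
        }
        for stage, count in cases["stage"].value_counts().items():
            row[f"stage_{stage}"] = count
        rows.append(row)
        print(f"{role}: {row['n_cases']} cases / {row['n_controls']} controls, "
              f"median tf {row['median_tumor_fraction']:.3f}, stages "
              + dict(cases["stage"].value_counts()).__repr__())
    out = common.results_dir() / "01_cohort_summary.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
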