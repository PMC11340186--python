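"""Select markers on the training cohort only.

Rank-sum + Benjamini-Hochberg univariate filtering per omics, then
random-forest importance ranking for methylation and end motifs (CNV keeps
the univariate ranking). Targets mirror the assay design: 23 methylation
markers, 14 end motifs, 34 chromosome arms. Writes the selected markers to
results/03_selected_markers.tsv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import importlib

common = importlib.import_module("00_common")

import pandas as pd

from cfomics.workbench import run_pipeline


def main() -> None:
    run_pipeline(common.RUN_DIR, common.CONFIG, common.SEED, stages=["select"])
    parts = []
    for omics in ("methylation", "endmotif", "cnv"):
        t = pd.read_csv(common.RUN_DIR / f"selection/{omics}.tsv", sep="\t")
        t.insert(0, "omics", omics)
        parts.append(t)
        print(f"{omics}: kept {len(t)} markers "
              f"(top: {', '.join(t['feature_id'].head(5))})")
    out = common.results_dir() / "03_selected_markers.tsv"
    pd.concat(parts, ignore_index=True).to_csv(out, sep="\t", index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
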