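"""Train the per-omics logistic sub-models and the stacked integrated model.

Tenfold stratified cross-validation on the training cohort produces
out-of-fold probabilities; those (plus the binary mutation score) feed the
integrated logistic model. Youden-index cutoffs are chosen on the
out-of-fold scores. Writes the frozen bundle under scratch/run-default/model
and the training-cohort CV performance to results/04_training_cv_metrics.tsv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import importlib

common = importlib.import_module("00_common")

import json

import pandas as pd

from cfomics.workbench import run_pipeline


def main() -> None:
    run_pipeline(common.RUN_DIR, common.CONFIG, common.SEED,
                 stages=["train", "predict", "evaluate"])
    metrics = json.loads((common.RUN_DIR / "metrics.json").read_text())
    rows = []
    for model in ("methylation", "endmotif", "cnv", "integrated"):
        m = metrics["train"][model]
        rows.append({
            "model": model, "cv_auc": m["auc"],
            "ci_low": m["auc_ci"][0], "ci_high": m["auc_ci"][1],
            "cutoff": m["cutoff"],
            "cv_sensitivity_percent": m["sensitivity_percent"],
            "cv_specificity_percent": m["specificity_percent"],
        })
        print(f"{model:12s} CV AUC {m['auc']:.3f} "
              f"({m['auc_ci'][0]:.3f}-{m['auc_ci'][1]:.3f}), cutoff "
              f"{m['cutoff']:.2f}, sens {m['sensitivity_percent']}%, "
              f"spec {m['specificity_percent']}%")
    out = common.results_dir() / "04_training_cv_metrics.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
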