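"""Evaluate the frozen multiomics model on the held-out validation cohort.

Reports validation AUCs with DeLong 95% CIs for the integrated model and
each single-omics model, sensitivity/specificity at the training-chosen
cutoffs with Clopper-Pearson CIs, per-stage sensitivity, and the per-gene
mutation detection table. Writes results/05_validation_metrics.json and
results/05_stage_sensitivity.tsv.
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
                 stages=["predict", "evaluate", "report"])
    metrics = json.loads((common.RUN_DIR / "metrics.json").read_text())
    val = metrics["validation"]
    print(f"validation cohort: {val['n_cases']} cases / {val['n_controls']} controls")
    for model in ("integrated", "methylation", "endmotif", "cnv"):
        m = val[model]
        print(f"{model:12s} AUC {m['auc']:.3f} "
              f"({m['auc_ci'][0]:.3f}-{m['auc_ci'][1]:.3f}); "
              f"sens {m['sensitivity_percent']}%, spec {m['specificity_percent']}%")
    stage = pd.DataFrame(val["integrated"].get("by_stage", []))
    if len(stage):
        print("integrated sensitivity by stage:")
        for _, r in stage.iterrows():
            print(f"  stage {r['stage']}: {r['rate_percent']}% "
                  f"({int(r['positives'])}/{int(r['total'])})")
    mut = val["mutation"]
    print(f"mutation score positivity: cases {mut['case_positive_percent']}%, "
          f"controls {mut['control_positive_percent']}%")

    outdir = common.results_dir()
    (outdir / "05_validation_metrics.json").write_text(
        json.dumps(val, indent=1, sort_keys=True))
    stage.to_csv(outdir / "05_stage_sensitivity.tsv", sep="\t", index=False)
    print(f"wrote {outdir / '05_validation_metrics.json'}")


if __name__ == "__main__":
    main()
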