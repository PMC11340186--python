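"""Shared locations and config for the numbered analysis drivers.

All drivers operate on one staged run: bulky intermediates (fragment tables,
bin counts) live under scratch/run-default, small result tables under
results/. Run the drivers in order; each prints what it found.
"""

from pathlib import Path

from cfomics.pipeline import study_config_for_seed

ROOT = Path(__file__).resolve().parent.parent
RUN_DIR = ROOT / "scratch" / "run-default"
RESULTS = ROOT / "results"

SEED = 1
CONFIG = study_config_for_seed(SEED)


def results_dir() -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS
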