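import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cfomics.synthetic import SimulationConfig, generate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_sim_config(**overrides) -> SimulationConfig:
    """Tiny cohort for fast unit tests (seconds, not minutes)."""
    defaults = dict(
        n_cases=12, n_controls=12,
        n_meth_markers=12, n_informative_meth=6, meth_depth=150.0,
        n_fragments=3000,
        n_cnv_arms=39, n_altered_arms=5, bin_size=10_000_000,
        bin_depth=150.0,
        seed=7,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_bundle():
    return generate_cohort(small_sim_config(), prefix="T")


@pytest.fixture()
def samples_sheet(small_bundle):
    return small_bundle.samples


def small_study_config(seed=0, **overrides):
    """Reduced-scale end-to-end study: larger effects, small cohorts."""
    from dataclasses import replace
    from cfomics.pipeline import StudyConfig
    from cfomics.selection import SelectionConfig

    base = seed % (2**28)
    panel = base * 4 + 3
    sim = dict(
        n_cases=25, n_controls=25,
        n_meth_markers=15, n_informative_meth=8, meth_depth=200.0,
        n_fragments=4000,
        n_cnv_arms=39, n_altered_arms=6, bin_size=10_000_000,
        bin_depth=500.0, nb_dispersion=2000.0,
        # strong, late-stage-like tumor fractions so every omics carries
        # signal at this small cohort size
        tf_by_stage={"I": (np.log(0.05), 0.5), "II": (np.log(0.10), 0.5),
                     "III": (np.log(0.15), 0.5), "IV": (np.log(0.25), 0.5)},
    )
    cfg = StudyConfig(
        train_sim=small_sim_config(**sim, seed=base * 4 + 1, panel_seed=panel),
        val_sim=small_sim_config(**sim, seed=base * 4 + 2, panel_seed=panel),
        selection=SelectionConfig(
            n_select={"methylation": 5, "endmotif": 5, "cnv": 5},
            rf_trees=50, rf_seed=base),
        cv_k=5, cv_seed=base, cnv_min_bins=1,
    )
    return replace(cfg, **overrides) if overrides else cfg


def toy_samples(n_case=3, n_ctrl=3, prefix="s"):
    rows = []
    for i in range(n_case):
        rows.append((f"{prefix}_case{i}", "case", "II", 0.05))
    for i in range(n_ctrl):
        rows.append((f"{prefix}_ctrl{i}", "control", "none", 0.0))
    return pd.DataFrame(rows, columns=["sample_id", "label", "stage", "tumor_fraction"])
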