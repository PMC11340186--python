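"""Generator contracts: determinism, closed-form expectations, calibration."""

import numpy as np
import pandas as pd
import pytest

from cfomics.errors import ConfigurationError
from cfomics.synthetic import (
    CRC_ARM_EVENTS, SampleTruth, SimulationConfig, _sample_stream, all_motifs,
    draw_marker_params, generate_cohort, null_config, simulate_bin_counts,
    simulate_fragment_motifs, simulate_methylation_counts, simulate_mutations,
)

from conftest import small_sim_config


class TestCohortAssembly:
    def test_sample_counts_and_stage_distribution(self, small_bundle):
        samples = small_bundle.samples
        assert len(samples) == 24
        assert (samples["label"] == "case").sum() == 12
        cases = samples[samples["label"] == "case"]
        assert set(cases["stage"]) <= {"I", "II", "III", "IV"}
        ctrls = samples[samples["label"] == "control"]
        assert (ctrls["stage"] == "none").all()
        assert (ctrls["tumor_fraction"] == 0).all()
        assert (cases["tumor_fraction"] > 0).all()

    def test_same_seed_reproduces_byte_identical_tables(self):
        cfg = small_sim_config()
        a = generate_cohort(cfg, prefix="T")
        b = generate_cohort(cfg, prefix="T")
        for name in ("samples", "fragments", "methylation", "bins", "mutations"):
            assert getattr(a, name).to_csv() == getattr(b, name).to_csv()

    def test_growing_the_cohort_preserves_existing_samples(self):
        small = generate_cohort(small_sim_config(n_controls=6), prefix="T")
        big = generate_cohort(small_sim_config(n_controls=12), prefix="T")
        sid = "T_ctrl_0003"
        for name in ("methylation", "bins"):
            a = getattr(small, name).query("sample_id == @sid").reset_index(drop=True)
            b = getattr(big, name).query("sample_id == @sid").reset_index(drop=True)
            pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize("field,value", [
        ("n_cases", 0),
        ("stage_proportions", (0.5, 0.5, 0.2, 0.1)),
        ("control_mutation_fp_rate", 1.5),
        ("n_informative_meth", 99),
    ])
    def test_invalid_config_names_offending_field(self, field, value):
        cfg = small_sim_config(**{field: value})
        with pytest.raises(ConfigurationError):
            cfg.validate()


class TestMethylationSimulator:
    def test_zero_tumor_fraction_recovers_baseline_beta(self):
        cfg = small_sim_config(n_meth_markers=4, n_informative_meth=4)
        params = draw_marker_params(cfg)
        truth = SampleTruth("s", "control", "none", 0.0)
        rng = np.random.default_rng(0)
        counts = simulate_methylation_counts(truth, params, 1e5, rng)
        beta = counts["methylated"] / (counts["methylated"] + counts["unmethylated"])
        assert np.allclose(beta, params.meth_baseline, atol=0.005)

    def test_tumor_effect_is_linear_in_tumor_fraction(self):
        # beta = baseline + tf * effect, here 0.2 * 0.3 = +0.06
        cfg = small_sim_config(n_meth_markers=3, n_informative_meth=3)
        params = draw_marker_params(cfg)
        params.meth_effect[:] = 0.3
        truth = SampleTruth("s", "case", "II", 0.2)
        rng = np.random.default_rng(1)
        counts = simulate_methylation_counts(truth, params, 2e5, rng)
        beta = counts["methylated"] / (counts["methylated"] + counts["unmethylated"])
        assert np.allclose(beta, params.meth_baseline + 0.06, atol=0.01)

    def test_saturated_case_reaches_effect_level(self):
        cfg = small_sim_config(n_meth_markers=2, n_informative_meth=2)
        params = draw_marker_params(cfg)
        params.meth_baseline[:] = 0.0
        params.meth_effect[:] = 0.5
        truth = SampleTruth("s", "case", "IV", 1.0)
        counts = simulate_methylation_counts(truth, params, 2e5,
                                             np.random.default_rng(2))
        beta = counts["methylated"] / (counts["methylated"] + counts["unmethylated"])
        assert np.allclose(beta, 0.5, atol=0.01)


class TestMotifSimulator:
    def _profiles(self, delta=0.002):
        # tumor profile shifts CCCA up by delta, spread evenly off the rest
        base = np.full(256, 1 / 256)
        tumor = base - delta / 255
        idx = all_motifs().index("CCCA")
        tumor[idx] = 1 / 256 + delta
        return base, tumor, idx

    def test_pure_mixtures_converge_to_each_endpoint(self):
        ctrl, tumor, idx = self._profiles(0.01)
        rng = np.random.default_rng(3)
        f0 = simulate_fragment_motifs(
            SampleTruth("a", "control", "none", 0.0), ctrl, tumor, 200_000, rng)
        freq0 = f0["motif5"].value_counts(normalize=True)["CCCA"]
        assert freq0 == pytest.approx(1 / 256, abs=5e-4)
        f1 = simulate_fragment_motifs(
            SampleTruth("b", "case", "IV", 1.0), ctrl, tumor, 200_000, rng)
        freq1 = f1["motif5"].value_counts(normalize=True)["CCCA"]
        assert freq1 == pytest.approx(1 / 256 + 0.01, abs=7e-4)

    def test_half_mixture_hits_profile_midpoint(self):
        ctrl, tumor, idx = self._profiles(0.01)
        rng = np.random.default_rng(4)
        f = simulate_fragment_motifs(
            SampleTruth("c", "case", "II", 0.5), ctrl, tumor, 400_000, rng)
        freq = f["motif5"].value_counts(normalize=True)["CCCA"]
        assert freq == pytest.approx(1 / 256 + 0.005, abs=5e-4)

    def test_invalid_profile_rejected(self):
        bad = np.full(256, 1 / 200)
        with pytest.raises(ConfigurationError, match="probability vector"):
            simulate_fragment_motifs(
                SampleTruth("d", "control", "none", 0.0), bad, bad, 10,
                np.random.default_rng(0))


class TestBinSimulator:
    def test_control_sample_has_flat_arms(self):
        # high NB size so only the mean structure is visible
        cfg = small_sim_config(gc_bias_strength=0.0, bin_depth=5000.0,
                               nb_dispersion=5000.0)
        params = draw_marker_params(cfg)
        truth = SampleTruth("s", "control", "none", 0.0)
        bins = simulate_bin_counts(truth, params, cfg, np.random.default_rng(5))
        arm_means = bins.assign(arm=params.bins["arm_id"].to_numpy()).groupby(
            "arm")["count"].mean()
        log2r = np.log2(arm_means / arm_means.median())
        assert np.abs(log2r).max() < 0.05

    def test_single_copy_gain_scales_depth_by_expected_ratio(self):
        # one-copy gain at tf=0.2: expected depth ratio 1 + 0.2*(3/2-1) = 1.1
        cfg = small_sim_config(gc_bias_strength=0.0, bin_depth=20000.0,
                               n_altered_arms=1, nb_dispersion=5000.0)
        params = draw_marker_params(cfg)
        gained_arm = next(iter(params.arm_copies))  # 8q gain
        assert params.arm_copies[gained_arm] == 3
        truth = SampleTruth("s", "case", "III", 0.2)
        bins = simulate_bin_counts(truth, params, cfg, np.random.default_rng(6))
        arm = params.bins["arm_id"].to_numpy()
        gained = bins["count"].to_numpy()[arm == gained_arm].mean()
        neutral = bins["count"].to_numpy()[arm != gained_arm].mean()
        assert np.log2(gained / neutral) == pytest.approx(np.log2(1.1), abs=0.02)


class TestMutationSimulator:
    def test_zero_fp_rate_means_no_positive_controls(self):
        cfg = small_sim_config(control_mutation_fp_rate=0.0)
        from cfomics.mutations import mutation_score

        for i in range(30):
            truth = SampleTruth(f"c{i}", "control", "none", 0.0)
            calls = simulate_mutations(truth, cfg, np.random.default_rng(i))
            assert mutation_score(calls) == 0

    def test_saturating_response_makes_every_case_positive(self):
        cfg = small_sim_config(mutation_tp_rate_at_tf=1e-9)
        from cfomics.mutations import mutation_score

        for i in range(20):
            truth = SampleTruth(f"p{i}", "case", "III", 0.05)
            calls = simulate_mutations(truth, cfg, np.random.default_rng(i))
            assert mutation_score(calls) == 1

    def test_control_positivity_matches_calibrated_rate(self):
        # expectation 9.4%; binomial mean over 50 seeds x 40 controls
        cfg = small_sim_config()
        from cfomics.mutations import mutation_score

        hits, total = 0, 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            for i in range(40):
                truth = SampleTruth(f"c{seed}_{i}", "control", "none", 0.0)
                hits += mutation_score(simulate_mutations(truth, cfg, rng))
                total += 1
        assert abs(hits / total - 0.094) < 0.03

    def test_empty_gene_panel_rejected(self):
        cfg = small_sim_config()
        with pytest.raises(ConfigurationError, match="gene_panel"):
            simulate_mutations(SampleTruth("x", "control", "none", 0.0), cfg,
                               np.random.default_rng(0), gene_panel={})


class TestTumorFractionMonotonicity:
    def test_every_channel_auc_is_nondecreasing_in_tumor_fraction(self):
        """Scaling the per-stage tumor-fraction locations up a 5-point grid
        must not degrade any sub-model's validation AUC (Spearman rho >= 0
        on the seed-averaged AUCs)."""
        from dataclasses import replace
        from scipy.stats import spearmanr
        from conftest import small_study_config
        from cfomics.pipeline import run_study

        scales = [0.25, 0.5, 1.0, 2.0, 4.0]
        base_tf = {"I": (np.log(0.01), 0.5), "II": (np.log(0.02), 0.5),
                   "III": (np.log(0.04), 0.5), "IV": (np.log(0.08), 0.5)}
        aucs = {o: np.zeros((len(scales), 10))
                for o in ("methylation", "endmotif", "cnv")}
        for si, scale in enumerate(scales):
            tf = {st: (mu + np.log(scale), sd) for st, (mu, sd) in base_tf.items()}
            for seed in range(10):
                cfg = small_study_config(seed=seed)
                cfg = replace(
                    cfg,
                    train_sim=replace(cfg.train_sim, tf_by_stage=tf),
                    val_sim=replace(cfg.val_sim, tf_by_stage=tf),
                )
                import warnings as _w
                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    res = run_study(seed=seed, config=cfg, with_gene_table=False)
                for o in aucs:
                    aucs[o][si, seed] = res["val_metrics"][o]["auc"]
        for o, grid in aucs.items():
            rho = spearmanr(scales, grid.mean(axis=1)).statistic
            assert rho >= 0, (o, grid.mean(axis=1))


def test_null_config_cases_carry_vanishing_tumor_fraction():
    cfg = null_config(n_cases=5, n_controls=5, seed=3)
    bundle = generate_cohort(cfg, prefix="N")
    cases = bundle.samples[bundle.samples["label"] == "case"]
    assert (cases["tumor_fraction"] < 1e-10).all()


def test_per_sample_streams_are_independent_of_each_other():
    a = _sample_stream(1, "s1").integers(0, 1 << 30, 5)
    b = _sample_stream(1, "s2").integers(0, 1 << 30, 5)
    a2 = _sample_stream(1, "s1").integers(0, 1 << 30, 5)
    assert np.array_equal(a, a2)
    assert not np.array_equal(a, b)
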