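"""ROC/AUC, confidence intervals, proportions and stage-wise sensitivity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cfomics.errors import DataError
from cfomics.evaluation import (
    auc_ci, binary_performance, percent, proportion, roc_auc, roc_with_ci,
    single_marker_eval, stage_stratified_sensitivity,
)


def pairwise_auc(scores, y):
    """Brute-force concordance: P(case score > control score) + 0.5 ties."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestAuc:
    def test_three_by_three_example_counts_pairs(self):
        scores = [0.9, 0.8, 0.4, 0.7, 0.3, 0.1]
        y = [1, 1, 1, 0, 0, 0]
        res = roc_auc(scores, y)
        assert res.auc == pytest.approx(8 / 9)
        assert res.auc == pytest.approx(pairwise_auc(scores, y))

    def test_perfect_and_reversed_separation(self):
        y = [1, 1, 0, 0]
        assert roc_auc([0.9, 0.8, 0.2, 0.1], y).auc == 1.0
        assert roc_auc([0.1, 0.2, 0.8, 0.9], y).auc == 0.0

    def test_label_independent_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(2000)
        y = rng.integers(0, 2, 2000)
        assert roc_auc(scores, y).auc == pytest.approx(0.5, abs=0.05)

    def test_matches_pairwise_oracle_with_ties(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(6, 50))
            scores = rng.integers(0, 5, n) / 4  # heavy ties
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            assert roc_auc(scores, y).auc == pytest.approx(
                pairwise_auc(scores, y), abs=1e-12)

    def test_curve_is_monotone_from_origin_to_one(self):
        rng = np.random.default_rng(1)
        res = roc_auc(rng.random(50), rng.integers(0, 2, 50))
        c = res.curve
        assert c.iloc[0].tolist() == [0.0, 0.0]
        assert c.iloc[-1].tolist() == [1.0, 1.0]
        assert (c.diff().dropna() >= 0).all().all()

    @given(st.integers(0, 2**31 - 1))
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=30)
        y = np.r_[np.ones(15), np.zeros(15)].astype(int)
        a1 = roc_auc(scores, y).auc
        a2 = roc_auc(np.exp(2 * scores), y).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            roc_auc([0.1, 0.2], [1, 1])


class TestAucCi:
    def test_delong_interval_brackets_auc(self):
        rng = np.random.default_rng(2)
        y = np.r_[np.ones(60), np.zeros(60)].astype(int)
        scores = rng.normal(size=120) + y
        res = roc_with_ci(scores, y)
        assert res.ci_low <= res.auc <= res.ci_high
        assert 0 <= res.ci_low and res.ci_high <= 1

    def test_delong_coverage_near_nominal_under_null(self):
        # AUC=0.5 truth; 95% CI should cover it ~95% of the time
        cover = 0
        n_sim = 200
        for seed in range(n_sim):
            rng = np.random.default_rng(seed)
            y = np.r_[np.ones(100), np.zeros(100)].astype(int)
            scores = rng.normal(size=200)
            lo, hi = auc_ci(scores, y)
            cover += lo <= 0.5 <= hi
        assert cover / n_sim > 0.90

    def test_bootstrap_is_seed_deterministic(self):
        rng = np.random.default_rng(3)
        y = np.r_[np.ones(30), np.zeros(30)].astype(int)
        scores = rng.normal(size=60) + 0.8 * y
        a = auc_ci(scores, y, method="bootstrap", seed=11)
        b = auc_ci(scores, y, method="bootstrap", seed=11)
        assert a == b

    def test_delong_and_bootstrap_agree_on_fixture(self):
        rng = np.random.default_rng(4)
        y = np.r_[np.ones(80), np.zeros(80)].astype(int)
        scores = rng.normal(size=160) + 1.2 * y
        d = auc_ci(scores, y, method="delong")
        b = auc_ci(scores, y, method="bootstrap", seed=0)
        assert d[0] == pytest.approx(b[0], abs=0.02)
        assert d[1] == pytest.approx(b[1], abs=0.02)

    def test_degenerate_perfect_separation_warns(self):
        y = np.array([1, 1, 1, 0, 0, 0])
        with pytest.warns(UserWarning, match="degenerate"):
            lo, hi = auc_ci([0.9, 0.8, 0.7, 0.3, 0.2, 0.1], y)
        assert (lo, hi) == (1.0, 1.0)


class TestProportion:
    @pytest.mark.parametrize("k,n,expected", [
        (12, 15, 80.0),
        (39, 93, 41.9),
        (9, 96, 9.4),
        (33, 37, 89.2),
        (36, 36, 100.0),
        (4, 15, 26.7),
        (23, 37, 62.2),
        (20, 36, 55.6),
        (18, 93, 19.4),
        (22, 93, 23.7),
        (16, 93, 17.2),
        (3, 93, 3.2),
    ])
    def test_rendering_matches_one_decimal_percent_convention(self, k, n, expected):
        rate, _ = proportion(k, n)
        assert percent(rate) == expected

    def test_clopper_pearson_zero_successes_closed_form(self):
        # upper bound for 0/10 is 1 - 0.025**(1/10)
        rate, (lo, hi) = proportion(0, 10)
        assert rate == 0.0
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** (1 / 10), abs=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(DataError):
            proportion(1, 0)
        with pytest.raises(DataError):
            proportion(5, 3)

    def test_wilson_alternative_available(self):
        _, (lo, hi) = proportion(8, 10, method="wilson")
        assert 0 < lo < 0.8 < hi < 1


class TestStageSensitivity:
    def test_printed_stage_table_reproduced(self):
        # 12/15, 33/37, 36/36, 1/1 -> 80.0, 89.2, 100.0, 100.0
        stages = (["I"] * 15 + ["II"] * 37 + ["III"] * 36 + ["IV"] * 1
                  + ["none"] * 10)
        y = [1] * 89 + [0] * 10
        calls = ([1] * 12 + [0] * 3 + [1] * 33 + [0] * 4 + [1] * 36 + [1]
                 + [0] * 10)
        table = stage_stratified_sensitivity(calls, y, stages)
        assert table.set_index("stage")["rate_percent"].tolist() == [
            80.0, 89.2, 100.0, 100.0]
        assert table["total"].tolist() == [15, 37, 36, 1]

    def test_empty_stage_omitted(self):
        table = stage_stratified_sensitivity(
            [1, 0], [1, 1], ["I", "I"])
        assert table["stage"].tolist() == ["I"]

    def test_controls_do_not_enter_sensitivity(self):
        table = stage_stratified_sensitivity(
            [1, 1, 1], [1, 0, 0], ["I", "I", "I"])
        assert table.iloc[0]["total"] == 1


class TestSingleMarker:
    def test_threshold_extremes(self):
        vals = [5.0, 7.0, 1.0, 2.0]
        y = [1, 1, 0, 0]
        perf_lo, _ = single_marker_eval(vals, y, threshold=0.0)
        assert perf_lo.sensitivity == 1.0 and perf_lo.specificity == 0.0
        perf_hi, _ = single_marker_eval(vals, y, threshold=100.0)
        assert perf_hi.sensitivity == 0.0 and perf_hi.specificity == 1.0

    def test_stagewise_rates_follow_threshold(self):
        vals = [10, 1, 1, 1, 10, 1]
        y = [1, 1, 1, 1, 0, 0]
        stages = ["I", "I", "I", "I", "none", "none"]
        perf, roc = single_marker_eval(vals, y, threshold=5.0,
                                       stages=stages)
        assert perf.by_stage.iloc[0]["rate_percent"] == 25.0
        assert perf.specificity == 0.5


def test_percent_rounds_half_up():
    # 0.0625*100 = 6.25 exactly; half-up gives 6.3 (banker's would give 6.2)
    assert percent(0.0625) == 6.3
    assert percent(0.93243) == 93.2
    assert percent(1.0) == 100.0
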