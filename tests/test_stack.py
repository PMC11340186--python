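"""Logistic sub-models, cross-validation, stacking and cutoffs."""

import numpy as np
import pandas as pd
import pytest

from cfomics.errors import ConfigurationError, DataError
from cfomics.matrix import FeatureMatrix
from cfomics.stack import (
    choose_cutoff, cross_val_probs, fit_integrated, fit_submodel,
    make_cv_partition, predict_integrated, predict_submodel, stack_inputs,
)
from sklearn.metrics import roc_auc_score


def labelled_matrix(n_case, n_ctrl, n_feat, seed, effect=0.0, omics="methylation"):
    rng = np.random.default_rng(seed)
    n = n_case + n_ctrl
    X = rng.normal(size=(n, n_feat))
    X[:n_case] += effect
    ids = [f"s{i:03d}" for i in range(n)]
    values = pd.DataFrame(X, index=ids,
                          columns=[f"f{j:02d}" for j in range(n_feat)])
    labels = pd.Series(["case"] * n_case + ["control"] * n_ctrl, index=ids)
    return FeatureMatrix(values, omics), labels


def irls_logistic(X, y, lam, tol=1e-12, max_iter=200):
    """Independent ridge-IRLS fit (intercept unpenalized)."""
    n, p = X.shape
    Xb = np.hstack([np.ones((n, 1)), X])
    beta = np.zeros(p + 1)
    pen = np.eye(p + 1) * lam
    pen[0, 0] = 0.0
    for _ in range(max_iter):
        eta = Xb @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1.0 - mu)
        grad = Xb.T @ (y - mu) - pen @ beta
        H = (Xb * W[:, None]).T @ Xb + pen
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta[0], beta[1:]


class TestCvPartition:
    def test_tenfold_folds_are_class_balanced(self):
        # 93 cases / 96 controls in 10 folds: 9-10 of each per fold
        labels = pd.Series(["case"] * 93 + ["control"] * 96,
                           index=[f"s{i}" for i in range(189)])
        part = make_cv_partition(labels, k=10, seed=0)
        df = pd.DataFrame({"fold": pd.Series(part.assignments),
                           "label": labels})
        counts = df.groupby(["fold", "label"]).size().unstack()
        assert counts["case"].between(9, 10).all()
        assert counts["control"].between(9, 10).all()
        assert counts.sum().sum() == 189

    def test_degenerate_k_rejected(self):
        labels = pd.Series(["case"] * 5 + ["control"] * 5)
        with pytest.raises(ConfigurationError):
            make_cv_partition(labels, k=1)

    def test_class_smaller_than_k_rejected(self):
        labels = pd.Series(["case"] * 4 + ["control"] * 20,
                           index=[f"s{i}" for i in range(24)])
        with pytest.raises(DataError, match="k="):
            make_cv_partition(labels, k=10)

    def test_same_seed_reproduces_assignment(self):
        labels = pd.Series(["case"] * 30 + ["control"] * 30,
                           index=[f"s{i}" for i in range(60)])
        a = make_cv_partition(labels, k=5, seed=3)
        b = make_cv_partition(labels, k=5, seed=3)
        assert a.assignments == b.assignments


class TestSubmodel:
    def test_coefficients_match_independent_irls_oracle(self):
        matrix, labels = labelled_matrix(10, 10, 3, seed=0, effect=1.0)
        l2 = 1e-4
        model = fit_submodel(matrix, labels, matrix.feature_ids, l2=l2)
        X = matrix.values.to_numpy()
        Xz = (X - model.mean) / model.sd
        y = (labels == "case").to_numpy().astype(float)
        b0, coef = irls_logistic(Xz, y, lam=l2 * len(y))
        assert np.allclose(model.coef, coef, atol=1e-6)
        assert model.intercept == pytest.approx(b0, abs=1e-6)

    def test_separable_feature_drives_training_auc_to_one(self):
        matrix, labels = labelled_matrix(15, 15, 1, seed=1, effect=8.0)
        model = fit_submodel(matrix, labels, matrix.feature_ids)
        probs = predict_submodel(model, matrix)
        y = (labels == "case").astype(int)
        assert roc_auc_score(y, probs) == 1.0

    def test_zero_variance_features_dropped(self):
        matrix, labels = labelled_matrix(10, 10, 3, seed=2, effect=0.5)
        matrix.values["f01"] = 4.2
        model = fit_submodel(matrix, labels, matrix.feature_ids)
        assert model.features == ["f00", "f02"]

    def test_needs_both_classes(self):
        matrix, labels = labelled_matrix(10, 10, 2, seed=3)
        with pytest.raises(DataError):
            fit_submodel(matrix, labels.replace("control", "case"),
                         matrix.feature_ids)


class TestCrossValProbs:
    def test_every_sample_gets_one_probability_in_unit_interval(self):
        matrix, labels = labelled_matrix(25, 25, 4, seed=4, effect=0.8)
        part = make_cv_partition(labels, k=5, seed=0)
        probs = cross_val_probs(matrix, labels, part, matrix.feature_ids)
        assert probs.index.tolist() == labels.index.tolist()
        assert ((probs > 0) & (probs < 1)).all()

    def test_oof_probabilities_do_not_use_in_fold_information(self):
        # on pure-noise data, in-fold (leaky) training scores separate much
        # better than out-of-fold scores
        matrix, labels = labelled_matrix(30, 30, 40, seed=5, effect=0.0)
        part = make_cv_partition(labels, k=5, seed=1)
        oof = cross_val_probs(matrix, labels, part, matrix.feature_ids)
        full = fit_submodel(matrix, labels, matrix.feature_ids)
        leaky = predict_submodel(full, matrix)
        y = (labels == "case").astype(int)
        assert roc_auc_score(y, leaky) - roc_auc_score(y, oof) > 0.2

    def test_partition_missing_samples_rejected(self):
        matrix, labels = labelled_matrix(10, 10, 2, seed=6)
        part = make_cv_partition(labels.iloc[:16], k=4, seed=0)
        with pytest.raises(DataError, match="missing from CV partition"):
            cross_val_probs(matrix, labels, part, matrix.feature_ids)


class TestIntegrated:
    def _inputs(self, n_case, n_ctrl, seed, perfect=False):
        rng = np.random.default_rng(seed)
        n = n_case + n_ctrl
        ids = [f"s{i:03d}" for i in range(n)]
        labels = pd.Series(["case"] * n_case + ["control"] * n_ctrl, index=ids)
        y = (labels == "case").to_numpy().astype(float)
        def noise():
            return np.clip(rng.uniform(0.05, 0.95, n), 1e-6, 1 - 1e-6)
        p_meth = np.clip(0.8 * y + 0.1 + rng.normal(0, 0.02, n), 0.001, 0.999) \
            if perfect else noise()
        df = pd.DataFrame({
            "p_methylation": p_meth, "p_endmotif": noise(), "p_cnv": noise(),
            "mutation_score": rng.integers(0, 2, n),
        }, index=ids)
        return df, labels

    def test_one_strong_submodel_dominates_stack(self):
        df, labels = self._inputs(40, 40, seed=7, perfect=True)
        part = make_cv_partition(labels, k=5, seed=2)
        model, oof = fit_integrated(df, labels, partition=part)
        y = (labels == "case").astype(int)
        auc_meth = roc_auc_score(y, df["p_methylation"])
        auc_int = roc_auc_score(y, oof)
        assert auc_int >= auc_meth - 0.02

    def test_all_null_inputs_give_chance_auc(self):
        aucs = []
        for seed in range(5):
            df, labels = self._inputs(50, 50, seed=seed)
            part = make_cv_partition(labels, k=5, seed=seed)
            _, oof = fit_integrated(df, labels, partition=part)
            y = (labels == "case").astype(int)
            aucs.append(roc_auc_score(y, oof))
        assert 0.38 < np.mean(aucs) < 0.62

    def test_duplicated_input_column_still_converges(self):
        df, labels = self._inputs(20, 20, seed=8, perfect=True)
        df["p_endmotif"] = df["p_methylation"]  # exact collinearity
        model, _ = fit_integrated(df, labels)
        assert np.isfinite(model.coef).all()

    def test_non_binary_mutation_score_rejected(self):
        df, labels = self._inputs(10, 10, seed=9)
        df["mutation_score"] = df["mutation_score"].astype(float)
        df.loc[df.index[0], "mutation_score"] = 0.5
        with pytest.raises(DataError, match="mutation_score"):
            stack_inputs(df["p_methylation"], df["p_endmotif"], df["p_cnv"],
                         df["mutation_score"])

    def test_prediction_is_monotone_in_positive_coefficient_input(self):
        df, labels = self._inputs(40, 40, seed=10, perfect=True)
        model, _ = fit_integrated(df, labels)
        assert model.coef[0] > 0  # methylation drives the labels here
        grid = df.iloc[[0] * 50].copy()
        grid["p_methylation"] = np.linspace(0.01, 0.99, 50)
        preds = predict_integrated(model, grid)
        assert (np.diff(preds) > 0).all()


class TestChooseCutoff:
    def brute_force_youden(self, probs, y):
        best_t, best_j = None, -np.inf
        for t in sorted(set(probs)):
            call = np.asarray(probs) >= t
            sens = (call & (y == 1)).sum() / (y == 1).sum()
            spec = (~call & (y == 0)).sum() / (y == 0).sum()
            j = sens + spec - 1
            if j > best_j + 1e-12:
                best_t, best_j = t, j
        return best_t

    def test_worked_six_point_set_matches_exhaustive_search(self):
        probs = np.array([0.1, 0.2, 0.4, 0.3, 0.7, 0.8])
        y = np.array([0, 0, 0, 1, 1, 1])
        cut = choose_cutoff(probs, y)
        assert cut == self.brute_force_youden(probs, y)
        assert cut == pytest.approx(0.3)  # ties at J=2/3 resolve to smallest

    def test_random_score_sets_match_exhaustive_search(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(6, 40))
            probs = rng.random(n).round(2)
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            assert choose_cutoff(probs, y) == self.brute_force_youden(probs, y)

    def test_perfect_separation_gives_perfect_calls(self):
        probs = np.array([0.9, 0.95, 0.92, 0.05, 0.1, 0.02])
        y = np.array([1, 1, 1, 0, 0, 0])
        cut = choose_cutoff(probs, y)
        assert cut == pytest.approx(0.9)  # smallest observed case score
        calls = probs >= cut
        assert (calls == y.astype(bool)).all()

    def test_degenerate_identical_scores_warn(self):
        with pytest.warns(UserWarning, match="degenerate"):
            cut = choose_cutoff(np.full(6, 0.4), np.array([1, 1, 1, 0, 0, 0]))
        assert cut == 0.4

    def test_specificity_floor_method(self):
        probs = np.array([0.1, 0.2, 0.4, 0.3, 0.7, 0.8])
        y = np.array([0, 0, 0, 1, 1, 1])
        cut = choose_cutoff(probs, y, method="specificity_floor",
                            specificity_target=1.0)
        assert cut == pytest.approx(0.7)
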