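"""End-to-end orchestration: simulation -> features -> selection -> stacked
training -> prediction -> evaluation.

Everything fitted on the training cohort (imputation medians, the
panel-of-normals reference, marker selection, standardization,
coefficients, cutoffs) is frozen inside the trained study object and reused
verbatim on validation cohorts, so no validation information leaks into the
model. ``run_study`` is the single entry point the analysis drivers, the
tests and the acceptance script share.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .cnv import build_cnv_matrix, panel_of_normals, sample_arm_features
from .endmotif import build_motif_matrix
from .errors import ConfigurationError, DataError
from .evaluation import percent, performance_report, roc_with_ci
from .genome import default_arm_table
from .matrix import FeatureMatrix
from .methylation import build_methylation_matrix
from .mutations import MutationFilterConfig, cohort_mutation_scores, gene_detection_table
from .selection import SelectionConfig, select_markers
from .stack import (
    CVPartition, IntegratedModel, SubModel, choose_cutoff, cross_val_probs,
    fit_integrated, fit_submodel, make_cv_partition, predict_integrated,
    predict_submodel, stack_inputs,
)
from .synthetic import CohortBundle, SimulationConfig, generate_cohort

OMICS = ("methylation", "endmotif", "cnv")


@dataclass(frozen=True)
class StudyConfig:
    """Everything one training+validation study run depends on."""

    train_sim: SimulationConfig = field(default_factory=SimulationConfig)
    val_sim: SimulationConfig = field(
        default_factory=lambda: SimulationConfig(n_cases=89, n_controls=95)
    )
    filter: MutationFilterConfig = field(default_factory=MutationFilterConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    cv_k: int = 10
    cv_seed: int = 0
    l2: float = 1e-4
    cutoff_method: str = "youden"
    min_molecules: int = 10
    cnv_min_bins: int = 10
    nested_selection: bool = False

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def study_config_for_seed(seed: int, **overrides) -> StudyConfig:
    """Default study at a given root seed (train/validation decorrelated,
    shared latent panel)."""
    base = int(seed) % (2**28)
    panel = base * 4 + 3
    cfg = StudyConfig(**overrides)
    return replace(
        cfg,
        train_sim=replace(cfg.train_sim, seed=base * 4 + 1, panel_seed=panel),
        val_sim=replace(cfg.val_sim, seed=base * 4 + 2, panel_seed=panel),
        selection=replace(cfg.selection, rf_seed=base),
        cv_seed=base,
    )


@dataclass
class CohortFeatures:
    """Feature matrices plus mutation scores for one cohort."""

    samples: pd.DataFrame
    matrices: dict  # omics -> FeatureMatrix
    mut_scores: pd.Series

    @property
    def labels(self) -> pd.Series:
        return pd.Series(
            self.samples["label"].to_numpy(), index=self.samples["sample_id"].to_numpy()
        )

    @property
    def stages(self) -> pd.Series:
        return pd.Series(
            self.samples["stage"].to_numpy(), index=self.samples["sample_id"].to_numpy()
        )


@dataclass
class TrainedStudy:
    """Frozen multiomics model bundle plus training-cohort artifacts."""

    config: StudyConfig
    submodels: dict  # omics -> SubModel
    integrated: IntegratedModel
    selection_tables: dict  # omics -> DataFrame
    meth_medians: pd.Series
    pon_reference: pd.DataFrame
    arm_table: pd.DataFrame
    partition: CVPartition
    oof: pd.DataFrame  # per-training-sample oof probs + mut score + integrated
    train_features: CohortFeatures


def extract_features(
    bundle: CohortBundle,
    config: StudyConfig,
    meth_medians: pd.Series | None = None,
    pon_reference: pd.DataFrame | None = None,
    arm_table: pd.DataFrame | None = None,
) -> tuple[CohortFeatures, pd.Series, pd.DataFrame]:
    """Build all omics matrices for a cohort.

    With ``meth_medians``/``pon_reference`` unset this is a training cohort:
    medians are fitted on it and the panel of normals is built from its
    controls. Returns ``(features, medians, reference)`` for freezing.
    """
    samples = bundle.samples
    if arm_table is None:
        arm_table = default_arm_table().iloc[: config.train_sim.n_cnv_arms]

    meth, medians = build_methylation_matrix(
        bundle.methylation, samples,
        min_molecules=config.min_molecules, impute_medians=meth_medians,
    )
    motif = build_motif_matrix(bundle.fragments, samples)

    if pon_reference is None:
        controls = samples.loc[samples["label"] == "control", "sample_id"]
        ctrl_bins = bundle.bins[bundle.bins["sample_id"].isin(set(controls))]
        pon_reference = panel_of_normals(ctrl_bins)
    arm_feats = {}
    for sid, sub in bundle.bins.groupby("sample_id", observed=True):
        arm_feats[str(sid)] = sample_arm_features(
            sub, pon_reference, arm_table, min_bins=config.cnv_min_bins
        )
    cnv = build_cnv_matrix(arm_feats, samples)

    mut = cohort_mutation_scores(bundle.mutations, samples, config.filter)
    feats = CohortFeatures(
        samples=samples,
        matrices={"methylation": meth, "endmotif": motif, "cnv": cnv},
        mut_scores=mut,
    )
    return feats, medians, pon_reference


def train_stack(
    train: CohortFeatures,
    config: StudyConfig,
    meth_medians: pd.Series,
    pon_reference: pd.DataFrame,
    arm_table: pd.DataFrame,
) -> TrainedStudy:
    """Select markers, fit sub-models with tenfold CV, stack, choose cutoffs."""
    labels = train.labels
    partition = make_cv_partition(labels, k=config.cv_k, seed=config.cv_seed)

    selection_tables, submodels, oof_probs = {}, {}, {}
    for omics in OMICS:
        matrix = train.matrices[omics]
        y = np.asarray((labels == "case").astype(int))
        sel = select_markers(matrix, y, config.selection)
        selection_tables[omics] = sel
        feats = sel["feature_id"].tolist()
        if config.nested_selection:
            oof = _nested_oof(matrix, labels, partition, config)
        else:
            oof = cross_val_probs(matrix, labels, partition, feats, l2=config.l2)
        model = fit_submodel(matrix, labels, feats, l2=config.l2)
        model.cutoff = choose_cutoff(oof, labels, method=config.cutoff_method)
        submodels[omics] = model
        oof_probs[omics] = oof

    inputs = stack_inputs(
        oof_probs["methylation"], oof_probs["endmotif"], oof_probs["cnv"],
        train.mut_scores.loc[labels.index],
    )
    integrated, oof_int = fit_integrated(
        inputs, labels, l2=config.l2, partition=partition
    )
    integrated.cutoff = choose_cutoff(oof_int, labels, method=config.cutoff_method)

    oof_table = inputs.copy()
    oof_table["p_integrated_oof"] = oof_int
    return TrainedStudy(
        config=config, submodels=submodels, integrated=integrated,
        selection_tables=selection_tables, meth_medians=meth_medians,
        pon_reference=pon_reference, arm_table=arm_table,
        partition=partition, oof=oof_table, train_features=train,
    )


def _nested_oof(matrix, labels, partition, config) -> pd.Series:
    """Out-of-fold probabilities with marker selection re-run inside each fold."""
    ids = list(labels.index)
    probs = pd.Series(np.nan, index=ids, dtype=float)
    for fold in range(partition.k):
        train_ids = [s for s in ids if partition.assignments[s] != fold]
        test_ids = [s for s in ids if partition.assignments[s] == fold]
        sub = matrix.subset_samples(train_ids)
        y = np.asarray((labels.loc[train_ids] == "case").astype(int))
        sel = select_markers(sub, y, config.selection)["feature_id"].tolist()
        model = fit_submodel(sub, labels.loc[train_ids], sel, l2=config.l2)
        probs.loc[test_ids] = predict_submodel(
            model, matrix.subset_samples(test_ids)
        ).to_numpy()
    return probs


def predict_cohort(
    study: TrainedStudy, features: CohortFeatures, missing_policy: str = "fail"
) -> pd.DataFrame:
    """Per-sample probabilities and binary calls under the frozen bundle.

    ``missing_policy`` decides what happens when a sample lacks one of the
    omics blocks: "fail" aborts the run (default), "skip" drops the sample
    with a warning and continues with the rest.
    """
    if missing_policy not in ("fail", "skip"):
        raise ConfigurationError("missing_policy must be 'fail' or 'skip'")
    sheet_ids = list(features.samples["sample_id"])
    covered = set(features.mut_scores.index)
    for omics in OMICS:
        covered &= set(features.matrices[omics].sample_ids)
    missing = [s for s in sheet_ids if s not in covered]
    if missing:
        if missing_policy == "fail":
            raise DataError(
                f"samples missing at least one omics block: {missing[:5]}"
            )
        warnings.warn(
            f"skipping {len(missing)} samples missing an omics block: "
            f"{missing[:5]}", stacklevel=2,
        )
        sheet_ids = [s for s in sheet_ids if s in covered]
    probs = {}
    for omics in OMICS:
        sub = features.matrices[omics].subset_samples(sheet_ids)
        probs[omics] = predict_submodel(study.submodels[omics], sub)
    inputs = stack_inputs(
        probs["methylation"], probs["endmotif"], probs["cnv"],
        features.mut_scores.loc[sheet_ids],
    )
    p_int = predict_integrated(study.integrated, inputs)
    out = inputs.copy()
    out.insert(0, "sample_id", out.index)
    out["p_integrated"] = p_int
    out["call"] = (p_int >= study.integrated.cutoff).astype(int)
    for omics in OMICS:
        out[f"call_{omics}"] = (
            inputs[f"p_{omics}"] >= study.submodels[omics].cutoff
        ).astype(int)
    return out.reset_index(drop=True)


def evaluate_cohort(
    study: TrainedStudy,
    features: CohortFeatures,
    predictions: pd.DataFrame,
    seed: int = 0,
) -> dict:
    """Metrics block for one cohort: integrated + per-omics + mutation score."""
    pred = predictions.set_index("sample_id")
    labels = features.labels.loc[pred.index]
    stages = features.stages.loc[pred.index]
    report = {
        "n_cases": int((labels == "case").sum()),
        "n_controls": int((labels == "control").sum()),
        "integrated": performance_report(
            pred["p_integrated"], labels, study.integrated.cutoff,
            stages=stages, seed=seed,
        ),
    }
    for omics in OMICS:
        report[omics] = performance_report(
            pred[f"p_{omics}"], labels, study.submodels[omics].cutoff,
            stages=stages, seed=seed,
        )
    mut = pred["mutation_score"]
    report["mutation"] = {
        "case_positive_rate": float(mut[labels == "case"].mean()),
        "case_positive_percent": percent(float(mut[labels == "case"].mean())),
        "control_positive_rate": float(mut[labels == "control"].mean()),
        "control_positive_percent": percent(float(mut[labels == "control"].mean())),
    }
    return report


def evaluate_training_oof(study: TrainedStudy, seed: int = 0) -> dict:
    """Training-cohort metrics from out-of-fold probabilities (honest CV)."""
    feats = study.train_features
    labels = feats.labels.loc[study.oof.index]
    stages = feats.stages.loc[study.oof.index]
    report = {
        "n_cases": int((labels == "case").sum()),
        "n_controls": int((labels == "control").sum()),
        "integrated": performance_report(
            study.oof["p_integrated_oof"], labels, study.integrated.cutoff,
            stages=stages, seed=seed,
        ),
    }
    for omics in OMICS:
        report[omics] = performance_report(
            study.oof[f"p_{omics}"], labels, study.submodels[omics].cutoff,
            stages=stages, seed=seed,
        )
    return report


def run_study(
    seed: int = 0, config: StudyConfig | None = None, with_gene_table: bool = True
) -> dict:
    """Run the full default study and return a results dictionary.

    Returns keys: ``study`` (TrainedStudy), ``train_metrics`` (out-of-fold),
    ``val_metrics``, ``predictions`` (validation table), ``gene_table``.
    """
    if config is None:
        config = study_config_for_seed(seed)
    _check_cohort_configs(config)
    train_bundle = generate_cohort(config.train_sim, prefix="TR")
    val_bundle = generate_cohort(config.val_sim, prefix="VA")
    overlap = set(train_bundle.samples["sample_id"]) & set(val_bundle.samples["sample_id"])
    if overlap:
        raise DataError(f"train/validation cohorts overlap: {sorted(overlap)[:5]}")

    arm_table = default_arm_table().iloc[: config.train_sim.n_cnv_arms]
    train_feats, medians, pon = extract_features(train_bundle, config,
                                                 arm_table=arm_table)
    study = train_stack(train_feats, config, medians, pon, arm_table)

    val_feats, _, _ = extract_features(
        val_bundle, config, meth_medians=medians, pon_reference=pon,
        arm_table=arm_table,
    )
    predictions = predict_cohort(study, val_feats)
    out = {
        "study": study,
        "train_metrics": evaluate_training_oof(study, seed=seed),
        "val_metrics": evaluate_cohort(study, val_feats, predictions, seed=seed),
        "predictions": predictions,
        "val_features": val_feats,
        "train_bundle": train_bundle,
        "val_bundle": val_bundle,
    }
    if with_gene_table:
        out["gene_table"] = gene_detection_table(
            train_bundle.mutations, train_bundle.samples, config.filter
        )
    return out


def _check_cohort_configs(config: StudyConfig) -> None:
    config.train_sim.validate()
    config.val_sim.validate()
    if config.train_sim.panel_seed != config.val_sim.panel_seed:
        raise ConfigurationError(
            "train and validation cohorts must share panel_seed (one biology)"
        )
    if config.train_sim.seed == config.val_sim.seed:
        raise ConfigurationError(
            "train and validation cohorts must use different sampling seeds"
        )


def ablate_combinations(study: TrainedStudy, val_features: CohortFeatures,
                        seed: int = 0) -> pd.DataFrame:
    """Validation AUC of every non-empty subset of the four stacked inputs."""
    from itertools import combinations

    labels_tr = study.train_features.labels.loc[study.oof.index]
    val_pred = predict_cohort(study, val_features)
    val_inputs = val_pred.set_index("sample_id")[list(study.oof.columns[:4])]
    labels_val = val_features.labels.loc[val_inputs.index]
    rows = []
    cols = list(study.oof.columns[:4])
    for r in range(1, 5):
        for combo in combinations(cols, r):
            Xtr = study.oof[list(combo)].to_numpy(dtype=float)
            y = np.asarray((labels_tr == "case").astype(int))
            from .stack import _fit_logistic

            coef, b = _fit_logistic(Xtr, y, study.config.l2)
            p_val = 1.0 / (1.0 + np.exp(-(val_inputs[list(combo)].to_numpy() @ coef + b)))
            auc = roc_with_ci(p_val, labels_val, seed=seed)
            rows.append({"inputs": "+".join(combo), "n_inputs": r,
                         "val_auc": auc.auc, "ci_low": auc.ci_low,
                         "ci_high": auc.ci_high})
    return pd.DataFrame(rows).sort_values(
        ["n_inputs", "val_auc"], ascending=[True, False]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# serialization


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in sorted(obj, key=str)] if isinstance(
            obj, (set, frozenset)) else [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def study_to_json(study: TrainedStudy) -> str:
    """Serialize the frozen model bundle to a deterministic JSON document."""
    def _sub(m: SubModel) -> dict:
        return {
            "omics": m.omics, "features": m.features,
            "mean": m.mean.tolist(), "sd": m.sd.tolist(),
            "coef": m.coef.tolist(), "intercept": m.intercept,
            "l2": m.l2, "cutoff": m.cutoff,
        }

    doc = {
        "format": "cfomics-model-bundle-v1",
        "config_hash": study.config.config_hash(),
        "arm_table": study.arm_table.to_dict(orient="list"),
        "submodels": {o: _sub(m) for o, m in study.submodels.items()},
        "integrated": {
            "coef": study.integrated.coef.tolist(),
            "intercept": study.integrated.intercept,
            "l2": study.integrated.l2,
            "cutoff": study.integrated.cutoff,
        },
        "cv": {
            "k": study.partition.k, "seed": study.partition.seed,
            "stratified": study.partition.stratified,
            "assignments": dict(sorted(study.partition.assignments.items())),
        },
        "meth_imputation_medians": {
            k: float(v) for k, v in study.meth_medians.items()
        },
        "panel_of_normals": study.pon_reference.to_dict(orient="list"),
        "selected_markers": {
            o: t["feature_id"].tolist() for o, t in study.selection_tables.items()
        },
    }
    return json.dumps(_jsonable(doc), sort_keys=True, indent=1)


def study_from_json(doc: str, config: StudyConfig | None = None) -> TrainedStudy:
    """Rebuild the frozen bundle (enough state to predict and evaluate)."""
    d = json.loads(doc)
    if d.get("format") != "cfomics-model-bundle-v1":
        raise DataError("not a cfomics model bundle")
    submodels = {}
    for omics, m in d["submodels"].items():
        submodels[omics] = SubModel(
            omics=m["omics"], features=list(m["features"]),
            mean=np.asarray(m["mean"], dtype=float),
            sd=np.asarray(m["sd"], dtype=float),
            coef=np.asarray(m["coef"], dtype=float),
            intercept=float(m["intercept"]), l2=float(m["l2"]),
            cutoff=float(m["cutoff"]),
        )
    integ = IntegratedModel(
        coef=np.asarray(d["integrated"]["coef"], dtype=float),
        intercept=float(d["integrated"]["intercept"]),
        l2=float(d["integrated"]["l2"]),
        cutoff=float(d["integrated"]["cutoff"]),
    )
    partition = CVPartition(
        k=int(d["cv"]["k"]),
        assignments={k: int(v) for k, v in d["cv"]["assignments"].items()},
        stratified=bool(d["cv"]["stratified"]), seed=int(d["cv"]["seed"]),
    )
    sel_tables = {
        o: pd.DataFrame({"feature_id": feats})
        for o, feats in d["selected_markers"].items()
    }
    return TrainedStudy(
        config=config if config is not None else StudyConfig(),
        submodels=submodels, integrated=integ, selection_tables=sel_tables,
        meth_medians=pd.Series(d["meth_imputation_medians"]).sort_index(),
        pon_reference=pd.DataFrame(d["panel_of_normals"]),
        arm_table=pd.DataFrame(d["arm_table"]),
        partition=partition, oof=pd.DataFrame(), train_features=None,
    )
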