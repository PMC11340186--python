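"""Stage-wise run orchestration with provenance.

A run directory holds one study: simulated (or user-supplied) cohort tables,
feature matrices, selected markers, the frozen model bundle, predictions and
metrics, plus a manifest recording the config hash, seeds, and a checksum of
every artifact. Stages declare their upstream artifacts; re-running a stage
whose inputs and config are unchanged is a no-op unless forced.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import replace
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, DataError
from .matrix import FeatureMatrix
from .mutations import MutationFilterConfig, gene_detection_table
from .pipeline import (
    StudyConfig, ablate_combinations, evaluate_cohort, evaluate_training_oof,
    extract_features, predict_cohort, study_config_for_seed, study_from_json,
    study_to_json, train_stack, CohortFeatures,
)
from .selection import SelectionConfig
from .synthetic import CohortBundle, SimulationConfig, generate_cohort

log = logging.getLogger("cfomics")

STAGES = ("simulate", "features", "select", "train", "predict", "evaluate",
          "report", "ablate")

#: artifacts each stage requires (relative to the run dir) and produces
STAGE_DEPS = {
    "simulate": ([], ["cohorts/train/samples.tsv", "cohorts/validation/samples.tsv"]),
    "features": (["cohorts/train/samples.tsv"], ["features/train_methylation.tsv"]),
    "select": (["features/train_methylation.tsv"], ["selection/methylation.tsv"]),
    "train": (["features/train_methylation.tsv", "selection/methylation.tsv"],
              ["model/bundle.json"]),
    "predict": (["model/bundle.json", "cohorts/validation/samples.tsv"],
                ["predictions.tsv"]),
    "evaluate": (["predictions.tsv"], ["metrics.json"]),
    "report": (["metrics.json", "predictions.tsv", "model/bundle.json"],
               ["report.tsv", "roc_points.tsv"]),
    "ablate": (["model/bundle.json"], ["ablation.tsv"]),
}

_COHORT_TABLES = ("samples", "fragments", "methylation", "bins", "mutations")


def study_config_from_dict(doc: dict, seed: int | None = None) -> StudyConfig:
    """Build a StudyConfig from a (YAML-loaded) nested mapping of overrides."""
    doc = dict(doc or {})
    base = study_config_for_seed(seed) if seed is not None else StudyConfig()

    def _sub(cfg, key, cls):
        over = doc.pop(key, None)
        if not over:
            return cfg
        for field_name in over:
            if field_name not in cls.__dataclass_fields__:
                raise ConfigurationError(f"{key}.{field_name} is not a known option")
        if cls is MutationFilterConfig:
            for f in ("allowed_effects", "gene_panel"):
                if f in over:
                    over[f] = frozenset(over[f])
        return replace(cfg, **over)

    base = replace(
        base,
        train_sim=_sub(base.train_sim, "train_sim", SimulationConfig),
        val_sim=_sub(base.val_sim, "val_sim", SimulationConfig),
        filter=_sub(base.filter, "filter", MutationFilterConfig),
        selection=_sub(base.selection, "selection", SelectionConfig),
    )
    for field_name in doc:
        if field_name not in StudyConfig.__dataclass_fields__:
            raise ConfigurationError(f"{field_name} is not a known option")
    return replace(base, **doc)


def load_run_config(path: str | Path | None, seed: int) -> StudyConfig:
    doc = {}
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
    return study_config_from_dict(doc, seed=seed)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Run:
    """One run directory and its manifest."""

    def __init__(self, out_dir: str | Path, config: StudyConfig, seed: int):
        self.dir = Path(out_dir)
        self.config = config
        self.seed = seed
        self.manifest_path = self.dir / "manifest.json"

    # -- manifest -----------------------------------------------------------
    def _load_manifest(self) -> dict:
        if self.manifest_path.exists():
            return json.loads(self.manifest_path.read_text())
        return {"config_hash": self.config.config_hash(), "seed": self.seed,
                "version": __version__, "artifacts": {}}

    def _record(self, manifest: dict, stage: str, paths: list[Path]) -> None:
        for p in paths:
            manifest["artifacts"][str(p.relative_to(self.dir))] = {
                "sha256": _sha256(p), "stage": stage,
            }
        manifest["config_hash"] = self.config.config_hash()
        manifest["seed"] = self.seed
        manifest["version"] = __version__
        self.manifest_path.parent.mkdir(parents=True, exist_ok=True)
        self.manifest_path.write_text(json.dumps(manifest, sort_keys=True, indent=1))

    def _uptodate(self, stage: str, manifest: dict) -> bool:
        if manifest.get("config_hash") != self.config.config_hash():
            return False
        _, outputs = STAGE_DEPS[stage]
        return all((self.dir / o).exists() for o in outputs)

    # -- IO helpers ---------------------------------------------------------
    def _write_tsv(self, rel: str, df: pd.DataFrame, index: bool = False) -> Path:
        p = self.dir / rel
        p.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(p, sep="\t", index=index)
        return p

    def _read_cohort(self, role: str) -> CohortBundle:
        base = self.dir / "cohorts" / role
        tables = {}
        for name in _COHORT_TABLES:
            p = base / f"{name}.tsv"
            if not p.exists():
                raise DataError(f"missing artifact {p}; run the simulate stage first")
            tables[name] = pd.read_csv(p, sep="\t")
        return CohortBundle(params=None, **tables)

    def _read_matrix(self, role: str, omics: str) -> FeatureMatrix:
        vals = pd.read_csv(self.dir / f"features/{role}_{omics}.tsv", sep="\t",
                           index_col=0)
        mask = pd.read_csv(self.dir / f"features/{role}_{omics}_mask.tsv", sep="\t",
                           index_col=0).astype(bool)
        vals.index = vals.index.astype(str)
        mask.index = mask.index.astype(str)
        return FeatureMatrix(vals, omics, mask)

    def _read_features(self, role: str) -> CohortFeatures:
        samples = pd.read_csv(self.dir / f"cohorts/{role}/samples.tsv", sep="\t")
        matrices = {o: self._read_matrix(role, o)
                    for o in ("methylation", "endmotif", "cnv")}
        mut = pd.read_csv(self.dir / f"features/{role}_mut_scores.tsv", sep="\t",
                          index_col=0)["mut_score"]
        mut.index = mut.index.astype(str)
        return CohortFeatures(samples=samples, matrices=matrices, mut_scores=mut)

    # -- stages -------------------------------------------------------------
    def run(self, stages: list[str], force: bool = False) -> None:
        unknown = [s for s in stages if s not in STAGES]
        if unknown:
            raise ConfigurationError(f"unknown stages: {unknown}")
        manifest = self._load_manifest()
        ordered = [s for s in STAGES if s in stages]
        for stage in ordered:
            deps, _ = STAGE_DEPS[stage]
            for dep in deps:
                if not (self.dir / dep).exists():
                    producer = next(
                        s for s, (_, outs) in STAGE_DEPS.items() if dep in outs
                    )
                    raise DataError(
                        f"stage {stage!r} needs {dep}; run stage {producer!r} first"
                    )
            if not force and self._uptodate(stage, manifest):
                log.info("stage %s up to date; skipping (use --force to rerun)", stage)
                continue
            t0 = time.perf_counter()
            written = getattr(self, f"_stage_{stage}")()
            self._record(manifest, stage, written)
            log.info("stage %s done in %.1fs (%d artifacts)", stage,
                     time.perf_counter() - t0, len(written))

    def _stage_simulate(self) -> list[Path]:
        cfg = self.config
        written = []
        for role, sim, prefix in (("train", cfg.train_sim, "TR"),
                                  ("validation", cfg.val_sim, "VA")):
            bundle = generate_cohort(sim, prefix=prefix)
            for name in _COHORT_TABLES:
                written.append(
                    self._write_tsv(f"cohorts/{role}/{name}.tsv", getattr(bundle, name))
                )
        train_ids = set(pd.read_csv(self.dir / "cohorts/train/samples.tsv",
                                    sep="\t")["sample_id"])
        val_ids = set(pd.read_csv(self.dir / "cohorts/validation/samples.tsv",
                                  sep="\t")["sample_id"])
        if train_ids & val_ids:
            raise DataError("train and validation cohorts overlap")
        return written

    def _stage_features(self) -> list[Path]:
        written = []
        train = self._read_cohort("train")
        feats, medians, pon = extract_features(train, self.config)
        written += self._write_features("train", feats)
        written.append(self._write_tsv(
            "features/meth_medians.tsv",
            medians.rename("median").rename_axis("marker_id").reset_index()))
        written.append(self._write_tsv("features/panel_of_normals.tsv", pon))
        val = self._read_cohort("validation")
        vfeats, _, _ = extract_features(
            val, self.config, meth_medians=medians, pon_reference=pon)
        written += self._write_features("validation", vfeats)
        return written

    def _write_features(self, role: str, feats: CohortFeatures) -> list[Path]:
        written = []
        for omics, m in feats.matrices.items():
            written.append(self._write_tsv(
                f"features/{role}_{omics}.tsv",
                m.values.rename_axis("sample_id"), index=True))
            written.append(self._write_tsv(
                f"features/{role}_{omics}_mask.tsv",
                m.missing.rename_axis("sample_id"), index=True))
        written.append(self._write_tsv(
            f"features/{role}_mut_scores.tsv",
            feats.mut_scores.rename_axis("sample_id").reset_index()))
        return written

    def _stage_select(self) -> list[Path]:
        from .selection import select_markers
        import numpy as np

        feats = self._read_features("train")
        y = np.asarray((feats.labels == "case").astype(int))
        written = []
        for omics, m in feats.matrices.items():
            table = select_markers(m, y, self.config.selection)
            written.append(self._write_tsv(f"selection/{omics}.tsv", table))
        return written

    def _stage_train(self) -> list[Path]:
        feats = self._read_features("train")
        medians = pd.read_csv(self.dir / "features/meth_medians.tsv", sep="\t",
                              index_col=0)["median"]
        pon = pd.read_csv(self.dir / "features/panel_of_normals.tsv", sep="\t")
        from .genome import default_arm_table

        arm_table = default_arm_table().iloc[: self.config.train_sim.n_cnv_arms]
        study = train_stack(feats, self.config, medians, pon, arm_table)
        p = self.dir / "model/bundle.json"
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_text(study_to_json(study))
        oof = self._write_tsv("model/oof.tsv",
                              study.oof.rename_axis("sample_id"), index=True)
        return [p, oof]

    def _stage_predict(self) -> list[Path]:
        study = study_from_json((self.dir / "model/bundle.json").read_text(),
                                config=self.config)
        vfeats = self._read_features("validation")
        pred = predict_cohort(study, vfeats)
        return [self._write_tsv("predictions.tsv", pred)]

    def _stage_evaluate(self) -> list[Path]:
        study = study_from_json((self.dir / "model/bundle.json").read_text(),
                                config=self.config)
        study.oof = pd.read_csv(self.dir / "model/oof.tsv", sep="\t", index_col=0)
        study.oof.index = study.oof.index.astype(str)
        study.train_features = self._read_features("train")
        vfeats = self._read_features("validation")
        pred = pd.read_csv(self.dir / "predictions.tsv", sep="\t")
        pred["sample_id"] = pred["sample_id"].astype(str)
        metrics = {
            "train": evaluate_training_oof(study, seed=self.seed),
            "validation": evaluate_cohort(study, vfeats, pred, seed=self.seed),
        }
        train_cohort = self._read_cohort("train")
        metrics["gene_detection_train"] = gene_detection_table(
            train_cohort.mutations, train_cohort.samples, self.config.filter
        ).to_dict(orient="records")
        p = self.dir / "metrics.json"
        p.write_text(json.dumps(metrics, sort_keys=True, indent=1))
        return [p]

    def _stage_report(self) -> list[Path]:
        metrics = json.loads((self.dir / "metrics.json").read_text())
        rows = []
        for cohort in ("train", "validation"):
            for model in ("integrated", "methylation", "endmotif", "cnv"):
                m = metrics[cohort][model]
                rows.append({
                    "cohort": cohort, "model": model, "auc": m["auc"],
                    "auc_ci_low": m["auc_ci"][0], "auc_ci_high": m["auc_ci"][1],
                    "sensitivity_percent": m["sensitivity_percent"],
                    "specificity_percent": m["specificity_percent"],
                    "cutoff": m["cutoff"],
                })
        written = [self._write_tsv("report.tsv", pd.DataFrame(rows))]
        written.append(self._write_tsv("roc_points.tsv", self._roc_points()))
        return written

    def _roc_points(self) -> pd.DataFrame:
        """ROC curves (fpr, tpr per threshold) for plotting, both cohorts."""
        from .evaluation import roc_auc

        pred = pd.read_csv(self.dir / "predictions.tsv", sep="\t")
        pred["sample_id"] = pred["sample_id"].astype(str)
        val_labels = pd.read_csv(
            self.dir / "cohorts/validation/samples.tsv", sep="\t"
        ).set_index("sample_id")["label"]
        oof = pd.read_csv(self.dir / "model/oof.tsv", sep="\t", index_col=0)
        oof.index = oof.index.astype(str)
        train_labels = pd.read_csv(
            self.dir / "cohorts/train/samples.tsv", sep="\t"
        ).set_index("sample_id")["label"]
        score_cols = {"integrated": "p_integrated", "methylation": "p_methylation",
                      "endmotif": "p_endmotif", "cnv": "p_cnv"}
        parts = []
        for model, col in score_cols.items():
            tcol = "p_integrated_oof" if model == "integrated" else col
            for cohort, scores, labels in (
                ("train", oof[tcol], train_labels.loc[oof.index]),
                ("validation", pred.set_index("sample_id")[col],
                 val_labels.loc[pred["sample_id"]]),
            ):
                curve = roc_auc(scores, labels).curve
                curve.insert(0, "model", model)
                curve.insert(0, "cohort", cohort)
                parts.append(curve)
        return pd.concat(parts, ignore_index=True)

    def _stage_ablate(self) -> list[Path]:
        study = study_from_json((self.dir / "model/bundle.json").read_text(),
                                config=self.config)
        study.oof = pd.read_csv(self.dir / "model/oof.tsv", sep="\t", index_col=0)
        study.oof.index = study.oof.index.astype(str)
        study.train_features = self._read_features("train")
        vfeats = self._read_features("validation")
        table = ablate_combinations(study, vfeats, seed=self.seed)
        return [self._write_tsv("ablation.tsv", table)]


def run_pipeline(
    out_dir: str | Path,
    config: StudyConfig,
    seed: int,
    stages: list[str] | None = None,
    force: bool = False,
) -> Path:
    """Execute the requested stages (default: all) into ``out_dir``."""
    run = Run(out_dir, config, seed)
    run.run(list(stages) if stages else list(STAGES), force=force)
    return Path(out_dir)
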