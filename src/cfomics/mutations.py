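"""Mutation eligibility filtering and the binary per-sample mutation score.

Candidate calls are filtered on effect class, hotspot/COSMIC recurrence,
variant allele frequency and supporting reads; a sample's mutation score is
1 iff at least one call survives. Rejected calls carry the first failing
criterion, evaluated in a fixed order, so diagnostics are deterministic.
Thresholds are configuration: the defaults are stringent values typical for
cfDNA driver panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

EFFECT_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift", "splice", "synonymous", "other"}
)

CALL_COLUMNS = [
    "sample_id", "gene", "chrom", "pos", "ref", "alt", "effect_class",
    "vaf", "alt_reads", "depth", "cosmic_count", "hotspot",
]

#: rejection reasons in evaluation order
REASONS = ("gene_panel", "mutation_type", "hotspot_cosmic", "vaf", "alt_reads")


@dataclass(frozen=True)
class MutationFilterConfig:
    allowed_effects: frozenset = frozenset({"missense", "nonsense", "frameshift", "splice"})
    min_cosmic_count: int = 3
    require_hotspot_for_missense: bool = True
    min_vaf: float = 0.001
    min_alt_reads: int = 3
    gene_panel: frozenset = frozenset(
        {"APC", "TP53", "KRAS", "PIK3CA", "FBXW7", "BRAF", "ACVR2A"}
    )

    def validate(self) -> None:
        if self.min_cosmic_count < 0 or self.min_alt_reads < 0 or self.min_vaf < 0:
            raise ConfigurationError("filter thresholds must be non-negative")
        unknown = self.allowed_effects - EFFECT_CLASSES
        if unknown:
            raise ConfigurationError(f"unknown effect classes: {sorted(unknown)}")


def validate_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Check CandidateMutation schema and internal consistency."""
    missing = [c for c in CALL_COLUMNS if c not in calls.columns]
    if missing:
        raise DataError(f"mutation table missing columns: {missing}")
    unknown = set(calls["effect_class"]) - EFFECT_CLASSES
    if unknown:
        raise DataError(f"unknown effect_class values: {sorted(unknown)}")
    if (calls["alt_reads"] > calls["depth"]).any():
        raise DataError("alt_reads exceeds depth")
    with np.errstate(invalid="ignore", divide="ignore"):
        implied = calls["alt_reads"] / calls["depth"].replace(0, np.nan)
    off = (calls["vaf"] - implied).abs() > 0.005
    if off.fillna(False).any():
        raise DataError("vaf inconsistent with alt_reads/depth beyond +/-0.005")
    return calls


def filter_eligible(
    calls: pd.DataFrame, config: MutationFilterConfig = MutationFilterConfig()
) -> pd.DataFrame:
    """Annotate each call with eligibility and the first failing criterion.

    Returns the input plus ``eligible`` (bool) and ``reason`` (rejection
    reason or "pass"). A call passes iff its gene is on the panel, its effect
    class is allowed, it is recurrent (hotspot OR COSMIC count >= threshold,
    with hotspot additionally required for missense when configured), and its
    VAF and supporting reads clear the floors.
    """
    config.validate()
    calls = validate_calls(calls.copy())

    in_panel = calls["gene"].isin(config.gene_panel)
    effect_ok = calls["effect_class"].isin(config.allowed_effects)
    hotspot = calls["hotspot"].astype(bool)
    recurrent = hotspot | (calls["cosmic_count"] >= config.min_cosmic_count)
    if config.require_hotspot_for_missense:
        recurrent = recurrent & (~(calls["effect_class"] == "missense") | hotspot)
    vaf_ok = calls["vaf"] >= config.min_vaf
    reads_ok = calls["alt_reads"] >= config.min_alt_reads

    reason = np.full(len(calls), "pass", dtype=object)
    # later criteria overwrite earlier ones only where still unset, so assign
    # in reverse order of precedence
    for name, ok in [
        ("alt_reads", reads_ok), ("vaf", vaf_ok), ("hotspot_cosmic", recurrent),
        ("mutation_type", effect_ok), ("gene_panel", in_panel),
    ]:
        reason[~ok.to_numpy()] = name
    calls["eligible"] = reason == "pass"
    calls["reason"] = reason
    return calls


def mutation_score(
    calls: pd.DataFrame, config: MutationFilterConfig = MutationFilterConfig()
) -> int:
    """1 iff the sample has at least one eligible call, else 0."""
    if len(calls) == 0:
        return 0
    return int(filter_eligible(calls, config)["eligible"].any())


def cohort_mutation_scores(
    calls: pd.DataFrame,
    samples: pd.DataFrame,
    config: MutationFilterConfig = MutationFilterConfig(),
) -> pd.Series:
    """Binary mutation score per sample (0 for samples with no calls)."""
    scores = pd.Series(0, index=list(samples["sample_id"]), dtype=int, name="mut_score")
    if len(calls):
        flagged = filter_eligible(calls, config)
        positive = flagged.loc[flagged["eligible"], "sample_id"].unique()
        scores.loc[[s for s in positive if s in scores.index]] = 1
    return scores


def gene_detection_table(
    calls: pd.DataFrame,
    samples: pd.DataFrame,
    config: MutationFilterConfig = MutationFilterConfig(),
) -> pd.DataFrame:
    """Per-gene and overall positivity by study arm.

    One row per panel gene plus an "overall" row (= mutation score
    positivity); columns give positive counts, totals and rates for cases
    and controls separately.
    """
    labels = samples.set_index("sample_id")["label"]
    n_case = int((labels == "case").sum())
    n_ctrl = int((labels == "control").sum())
    flagged = filter_eligible(calls, config) if len(calls) else calls.assign(
        eligible=pd.Series(dtype=bool))
    eligible = flagged[flagged["eligible"]] if len(flagged) else flagged

    def _row(gene: str, positives: pd.Series) -> dict:
        pos_labels = labels.loc[[s for s in positives if s in labels.index]]
        k_case = int((pos_labels == "case").sum())
        k_ctrl = int((pos_labels == "control").sum())
        return {
            "gene": gene,
            "case_positive": k_case, "case_total": n_case,
            "case_rate": k_case / n_case if n_case else 0.0,
            "control_positive": k_ctrl, "control_total": n_ctrl,
            "control_rate": k_ctrl / n_ctrl if n_ctrl else 0.0,
        }

    rows = []
    for gene in sorted(config.gene_panel):
        pos = eligible.loc[eligible["gene"] == gene, "sample_id"].unique() if len(eligible) else []
        rows.append(_row(gene, pd.Series(pos)))
    overall = eligible["sample_id"].unique() if len(eligible) else []
    rows.append(_row("overall", pd.Series(overall)))
    return pd.DataFrame(rows)
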