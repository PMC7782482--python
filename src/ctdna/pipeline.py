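"""End-to-end orchestration: QC gate -> filter cascade -> source
classification -> burden metrics -> heterogeneity/clonality -> pathway
statistics -> actionability -> (optional) survival.

Stages run in fixed order; each stage appends to the cohort provenance log
and, when an output directory is given, writes its table as TSV. Re-running
with the same inputs reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import actionability as _actionability
from . import burden as _burden
from . import filters as _filters
from . import heterogeneity as _het
from . import pathways as _pathways
from . import sources as _sources
from . import survival as _survival
from .io import apply_sample_qc, variants_to_frame
from .models import CohortTable


class QCConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_depth: float = 1000.0
    max_contamination: float = 0.01


class FilterConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    population_threshold: float = 0.01
    fusion_window_bp: int = 5


class BurdenConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    panel_mb: float = 1.09
    af_floor: float = 0.005
    ci_method: str = "wald"


class PathwayConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    catalog_path: Optional[str] = None
    q_threshold: float = 0.1


class ActionabilityConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kb_path: Optional[str] = None
    excluded_types: List[str] = Field(
        default=list(_actionability.DEFAULT_EXCLUDED_TYPES)
    )


class SurvivalConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    threshold_rule: str = _survival.MUTATIONS_GT_2


class PipelineConfig(BaseModel):
    """Validated configuration for :func:`run_pipeline`.

    Unknown keys are rejected by name at validation time.
    """

    model_config = ConfigDict(extra="forbid")
    qc: QCConfig = Field(default_factory=QCConfig)
    filters: FilterConfig = Field(default_factory=FilterConfig)
    burden: BurdenConfig = Field(default_factory=BurdenConfig)
    pathways: PathwayConfig = Field(default_factory=PathwayConfig)
    actionability: ActionabilityConfig = Field(default_factory=ActionabilityConfig)
    survival: SurvivalConfig = Field(default_factory=SurvivalConfig)


@dataclass
class PipelineResult:
    cohort: CohortTable  # QC'd, cascade-filtered
    qc_exclusions: pd.DataFrame
    filter_decisions: pd.DataFrame
    source_labels: pd.DataFrame
    burden: pd.DataFrame
    sensitivity: pd.DataFrame
    heterogeneity: pd.DataFrame
    clonality: pd.DataFrame
    pathway_pairs: pd.DataFrame
    actionability: pd.DataFrame
    survival: dict

    def tables(self) -> dict:
        return {
            "qc_exclusions": self.qc_exclusions,
            "filter_decisions": self.filter_decisions,
            "source_labels": self.source_labels,
            "burden": self.burden,
            "sensitivity": self.sensitivity,
            "heterogeneity": self.heterogeneity,
            "clonality": self.clonality,
            "pathway_pairs": self.pathway_pairs,
            "actionability": self.actionability,
        }


def run_pipeline(
    cohort: CohortTable,
    config: Optional[PipelineConfig] = None,
    followup: Optional[Sequence[_survival.FollowUpRecord]] = None,
    outdir=None,
) -> PipelineResult:
    """Run every interpretation stage over a matched cohort.

    Any stage failure aborts with the stage name and cause. When ``outdir``
    is given, every table is written there as TSV (and the survival summary
    as JSON) along with the provenance log.
    """
    config = config or PipelineConfig()
    stage = "sample_qc"
    try:
        cohort, exclusions = apply_sample_qc(
            cohort, config.qc.min_depth, config.qc.max_contamination
        )
        qc_frame = pd.DataFrame(
            [{"sample_id": e.sample_id, "reason": e.reason} for e in exclusions],
            columns=["sample_id", "reason"],
        )

        stage = "filter_cascade"
        cohort, decisions = _filters.apply_filter_cascade(
            cohort, population_threshold=config.filters.population_threshold
        )
        decisions_frame = _filters.decisions_to_frame(decisions)

        stage = "source_classification"
        labels = _sources.classify_cohort(cohort)
        cohort.log(f"source_classification: {len(labels)} plasma variants labeled")
        labels_frame = _sources.labels_to_frame(labels)
        label_map = _sources.labels_to_map(labels)

        stage = "burden_metrics"
        burden_rows = _burden.burden_table(
            cohort, labels, panel_mb=config.burden.panel_mb,
            af_floor=config.burden.af_floor,
        )
        burden_frame = _burden.burden_to_frame(burden_rows)
        sensitivity_rows = _burden.sensitivity_by_group(
            cohort, burden_rows, grouping="cancer_type",
            ci_method=config.burden.ci_method,
        ) + _burden.sensitivity_by_group(
            cohort, burden_rows, grouping="overall",
            ci_method=config.burden.ci_method,
        )
        sensitivity_frame = _burden.sensitivity_to_frame(sensitivity_rows)
        cohort.log(
            f"burden_metrics: {sum(r.detected for r in burden_rows)}/"
            f"{len(burden_rows)} plasma samples with detected ctDNA"
        )

        stage = "heterogeneity_clonality"
        by_sample = {
            s: vs
            for s, vs in cohort.variants_by_sample().items()
            if s in {r.sample_id for r in burden_rows}
        }
        het_rows = _het.sample_math_scores(by_sample, label_map)
        clon_records = _het.cohort_clonality(by_sample, label_map)
        het_frame = _het.heterogeneity_to_frame(het_rows)
        clon_frame = _het.clonality_to_frame(clon_records)
        cohort.log(
            f"heterogeneity: MATH computed for "
            f"{sum(1 for r in het_rows if r.math is not None)} samples"
        )

        stage = "pathway_analysis"
        catalog = _pathways.load_pathway_catalog(config.pathways.catalog_path)
        matrix = _pathways.pathway_alteration_matrix(cohort, catalog, labels)
        if len(matrix) and matrix.to_numpy().any():
            pair_results = _pathways.pairwise_pathway_tests(
                matrix, q_threshold=config.pathways.q_threshold
            )
            pathway_frame = _pathways.pair_results_to_frame(pair_results)
        else:
            pathway_frame = _pathways.pair_results_to_frame([])
        cohort.log(f"pathway_analysis: {len(matrix)} samples in alteration matrix")

        stage = "actionability"
        kb = _actionability.load_kb(config.actionability.kb_path)
        try:
            act_frame = _actionability.actionability_summary(
                cohort, kb, labels,
                excluded_types=config.actionability.excluded_types,
            )
        except ValueError:
            act_frame = pd.DataFrame(
                columns=["cancer_type", "n_samples", "n_actionable",
                         "frac_actionable"]
            )
        cohort.log(f"actionability: {len(act_frame)} summary rows")

        stage = "survival_analysis"
        if followup:
            comparison = _survival.logrank_compare(
                followup, threshold_rule=config.survival.threshold_rule
            )
            survival_summary = _survival.comparison_to_dict(comparison)
        else:
            survival_summary = {}
        cohort.log(
            "survival_analysis: "
            + ("done" if followup else "skipped (no follow-up table)")
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    result = PipelineResult(
        cohort=cohort,
        qc_exclusions=qc_frame,
        filter_decisions=decisions_frame,
        source_labels=labels_frame,
        burden=burden_frame,
        sensitivity=sensitivity_frame,
        heterogeneity=het_frame,
        clonality=clon_frame,
        pathway_pairs=pathway_frame,
        actionability=act_frame,
        survival=survival_summary,
    )
    if outdir is not None:
        write_result(result, outdir)
    return result


def write_result(result: PipelineResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    variants_to_frame(result.cohort.variants).to_csv(
        outdir / "filtered_variants.tsv", sep="\t", index=False
    )
    for name, frame in result.tables().items():
        frame.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    (outdir / "survival.json").write_text(
        json.dumps(result.survival, indent=2, sort_keys=True) + "\n"
    )
    (outdir / "provenance.log").write_text(
        "".join(l + "\n" for l in result.cohort.provenance)
    )
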