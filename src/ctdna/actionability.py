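"""Therapeutic actionability leveling from a local knowledge base.

Evidence tiers follow the OncoKB-style convention: Level 1, an
FDA-recognized biomarker for an FDA-approved drug in the matching cancer
type; Level 2, a standard-care biomarker; Level 3, a biomarker with
compelling clinical evidence; Level 4, compelling biological evidence only.
Levels 2 and 3 carry an A/B suffix: A when the sample's cancer type matches
the evidence scope, B otherwise. Level 4 entries are ignored — their
clinical implication is unclear. A mutation matching several entries takes
the highest level, and a sample's level is its best mutation's level.

The knowledge base ships as a small editable TSV of well-known exemplar
entries for testing; real analyses should supply a fuller curated export.
No live database queries are performed, so absolute actionable fractions
depend on the supplied knowledge base.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd

from .models import CohortTable, Compartment, VariantCall, VariantClass, VariantKey
from .sources import WBC_MATCHED, SourceLabel, labels_to_map

#: ordering of sample/variant levels, best first. The B scope of a stronger
#: evidence tier outranks the A scope of a weaker tier (1 > 2A > 2B > 3A > 3B),
#: matching how stacked per-sample level summaries are reported.
LEVEL_ORDER = ("1", "2A", "2B", "3A", "3B", "none")
_LEVEL_RANK = {lvl: i for i, lvl in enumerate(LEVEL_ORDER)}

PATTERN_KINDS = ("protein_change", "positional_class", "alteration_class")

#: default cancer-type exclusions for cohort summaries: samples whose
#: histology cannot anchor type-scoped evidence.
DEFAULT_EXCLUDED_TYPES = ("histology-unknown lung", "unknown primary")


@dataclass
class ActionabilityEntry:
    gene: str
    pattern: str
    pattern_kind: str
    cancer_type: str  # "*" = any type
    base_level: int
    drugs: List[str]

    def __post_init__(self) -> None:
        if self.base_level not in (1, 2, 3, 4):
            raise ValueError(f"base_level must be 1-4, got {self.base_level}")
        if not self.pattern:
            raise ValueError("entry pattern must be non-empty")
        if self.pattern_kind not in PATTERN_KINDS:
            raise ValueError(f"unknown pattern_kind {self.pattern_kind!r}")


@dataclass
class LevelCall:
    sample_id: str
    key: VariantKey
    level: str  # "1" | "2A" | "2B" | "3A" | "3B" | "none"
    matched_entry: Optional[ActionabilityEntry] = None


def load_kb(path=None) -> List[ActionabilityEntry]:
    """Load and validate an actionability knowledge-base TSV.

    Columns: gene, pattern, pattern_kind, cancer_type, level, drugs
    (semicolon-separated). Malformed rows raise at load time, naming the row.
    """
    if path is None:
        ref = resources.files("ctdna.data") / "actionability_kb.tsv"
        with resources.as_file(ref) as p:
            frame = pd.read_csv(p, sep="\t")
    else:
        frame = pd.read_csv(path, sep="\t")
    required = {"gene", "pattern", "pattern_kind", "cancer_type", "level", "drugs"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"knowledge base missing column(s): {sorted(missing)}")
    entries = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            entries.append(
                ActionabilityEntry(
                    gene=str(row.gene),
                    pattern=str(row.pattern),
                    pattern_kind=str(row.pattern_kind),
                    cancer_type=str(row.cancer_type),
                    base_level=int(row.level),
                    drugs=[d for d in str(row.drugs).split(";") if d],
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed knowledge-base row at line {i}: {exc}") from exc
    return entries


def _entry_matches(entry: ActionabilityEntry, variant: VariantCall) -> bool:
    if entry.gene != variant.gene:
        return False
    if entry.pattern_kind == "protein_change":
        return variant.protein_change == entry.pattern
    if entry.pattern_kind == "positional_class":
        return variant.positional_class == entry.pattern
    # alteration_class
    if entry.pattern == "amplification":
        return variant.variant_class == VariantClass.CNV and (
            variant.copy_number is None or variant.copy_number > 2
        )
    if entry.pattern == "fusion":
        return variant.variant_class == VariantClass.REARRANGEMENT
    if entry.pattern == "truncating":
        return variant.consequence.value in ("nonsense", "frameshift")
    return False


def _entry_level(entry: ActionabilityEntry, cancer_type: str) -> str:
    type_match = entry.cancer_type == "*" or entry.cancer_type == cancer_type
    if entry.base_level == 1:
        # an FDA-approved-drug biomarker applied outside its approved type is
        # standard-care evidence elsewhere, hence 2B; configurable by editing
        # the knowledge base instead
        return "1" if type_match else "2B"
    if entry.base_level == 2:
        return "2A" if type_match else "2B"
    if entry.base_level == 3:
        return "3A" if type_match else "3B"
    return "none"  # level 4 ignored


def best_level(levels: Iterable[str]) -> str:
    best = "none"
    for lvl in levels:
        if _LEVEL_RANK[lvl] < _LEVEL_RANK[best]:
            best = lvl
    return best


def annotate_variant(
    variant: VariantCall,
    cancer_type: str,
    kb: Sequence[ActionabilityEntry],
) -> LevelCall:
    """Best evidence level for one variant across all matching entries.

    Level 4 entries never contribute. No matching entry yields "none".
    """
    best = "none"
    best_entry = None
    for entry in kb:
        if entry.base_level == 4:
            continue
        if not _entry_matches(entry, variant):
            continue
        lvl = _entry_level(entry, cancer_type)
        if _LEVEL_RANK[lvl] < _LEVEL_RANK[best]:
            best, best_entry = lvl, entry
    return LevelCall(variant.sample_id, variant.key, best, best_entry)


def sample_level(calls: Sequence[LevelCall]) -> str:
    """A sample's level is the highest level among its variant calls."""
    return best_level(c.level for c in calls)


def actionability_summary(
    cohort: CohortTable,
    kb: Sequence[ActionabilityEntry],
    labels: Optional[Sequence[SourceLabel]] = None,
    excluded_types: Sequence[str] = DEFAULT_EXCLUDED_TYPES,
) -> pd.DataFrame:
    """Per-cancer-type actionability fractions by highest sample level.

    Only plasma samples with >=1 retained non-CH alteration enter the
    denominator; CH (WBC-matched) variants are ineligible for matching.
    Configured cancer types (default: histology-unknown lung, unknown
    primary) are excluded. Returns one row per type plus a ``total`` row.
    """
    label_map = labels_to_map(labels) if labels is not None else None
    by_sample = cohort.variants_by_sample()
    per_type: Dict[str, List[str]] = {}
    for s in cohort.samples.values():
        if s.compartment != Compartment.PLASMA:
            continue
        ctype = cohort.patient_of(s.sample_id).cancer_type
        if ctype in excluded_types:
            continue
        pool = [
            v
            for v in by_sample[s.sample_id]
            if label_map is None
            or label_map.get((v.sample_id, v.key)) != WBC_MATCHED
        ]
        if not pool:
            continue
        calls = [annotate_variant(v, ctype, kb) for v in pool]
        per_type.setdefault(ctype, []).append(sample_level(calls))
    if not per_type:
        raise ValueError("no eligible samples (detected, non-excluded) to summarize")
    rows = []
    all_levels: List[str] = []
    for ctype in sorted(per_type):
        levels = per_type[ctype]
        all_levels.extend(levels)
        rows.append(_summary_row(ctype, levels))
    rows.append(_summary_row("total", all_levels))
    return pd.DataFrame(rows)


def _summary_row(label: str, levels: List[str]) -> dict:
    n = len(levels)
    row = {"cancer_type": label, "n_samples": n}
    n_actionable = sum(1 for l in levels if l != "none")
    for lvl in LEVEL_ORDER[:-1]:
        k = sum(1 for l in levels if l == lvl)
        row[f"n_level_{lvl}"] = k
        row[f"frac_level_{lvl}"] = k / n
    row["n_actionable"] = n_actionable
    row["frac_actionable"] = n_actionable / n
    return row
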