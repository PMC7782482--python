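"""Post-calling filter cascade for plasma variant tables.

The cascade removes, in fixed order: (1) germline variants — AF >= 30% in
both cfDNA and matched WBC gDNA, with an exception for truncating events in
the 15 canonical clonal-hematopoiesis genes; (2) synonymous variants;
(3) variants at low total depth (<500x in cfDNA/tissue, <200x in WBC);
(4) variants with too few high-quality supporting reads (mapping quality
>30 and base quality >30; minimum 5 for cfDNA/tissue, 2 for WBC); and
(5) variants present in >1% of samples in population SNP databases. The
survivors are labeled high-confidence somatic mutations.

Also implements the rearrangement support rule: candidate fusion fragments
sharing breakpoint orientation and proximity cluster into events, and only
events backed by >=2 unique fragments are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Tuple

from .models import (
    CohortTable,
    Compartment,
    Consequence,
    VariantCall,
    VariantClass,
    VariantKey,
)

#: The 15 canonical clonal-hematopoiesis genes.
CH_GENES_15 = frozenset(
    {
        "DNMT3A", "TET2", "ASXL1", "PPM1D", "TP53", "JAK2", "RUNX1", "SF3B1",
        "SRSF2", "IDH1", "IDH2", "U2AF1", "CBL", "ATM", "CHEK2",
    }
)

#: The 10 canonical CH-related genes observed among WBC-matched variants and
#: plasma-only variants of unknown source in trio-sequenced patients.
CH_GENES_10_INVOLVED = frozenset(
    {"DNMT3A", "TP53", "TET2", "ASXL1", "PPM1D", "ATM", "JAK2", "SF3B1",
     "CHEK2", "CBL"}
)

GERMLINE_AF_THRESHOLD = 0.30

# depth / high-quality-read minima per compartment
DEPTH_MINIMUM = {
    Compartment.PLASMA: 500,
    Compartment.TISSUE: 500,
    Compartment.WBC: 200,
}
HQ_READS_MINIMUM = {
    Compartment.PLASMA: 5,
    Compartment.TISSUE: 5,
    Compartment.WBC: 2,
}

#: Consequences that rescue a high-AF variant from the germline rule when it
#: falls in a canonical CH gene: frameshift indels plus truncating SNVs
#: (stop-gain and canonical splice-disrupting substitutions).
TRUNCATING_CONSEQUENCES = frozenset(
    {Consequence.FRAMESHIFT, Consequence.NONSENSE, Consequence.SPLICE_SITE}
)


class FilterRule(str, Enum):
    GERMLINE = "germline"
    SYNONYMOUS = "synonymous"
    LOW_DEPTH = "low_depth"
    LOW_HQ_READS = "low_hq_reads"
    POPULATION_DB = "population_db"
    FUSION_SUPPORT = "fusion_support"
    NONE = "none"


@dataclass
class FilterDecision:
    sample_id: str
    key: VariantKey
    verdict: str  # "retained" | "removed"
    rule: FilterRule

    @property
    def retained(self) -> bool:
        return self.verdict == "retained"


def _decision(variant: VariantCall, rule: FilterRule) -> FilterDecision:
    verdict = "retained" if rule == FilterRule.NONE else "removed"
    return FilterDecision(variant.sample_id, variant.key, verdict, rule)


def germline_filter(
    plasma_variant: VariantCall,
    wbc_variant: Optional[VariantCall],
    ch_genes: frozenset = CH_GENES_15,
    af_threshold: float = GERMLINE_AF_THRESHOLD,
    rescue_consequences: frozenset = TRUNCATING_CONSEQUENCES,
) -> FilterDecision:
    """Remove germline variants: AF >= 30% in both cfDNA and WBC gDNA.

    Truncating alterations (frameshift indels, stop-gain or splice-disrupting
    SNVs) in one of the 15 canonical CH genes are exempt — somatic truncating
    CH clones can reach high AF in both compartments. A variant with no WBC
    counterpart is retained.
    """
    if wbc_variant is not None and wbc_variant.key != plasma_variant.key:
        raise ValueError(
            f"identity key mismatch: plasma {plasma_variant.key} vs "
            f"WBC {wbc_variant.key}"
        )
    if wbc_variant is None:
        return _decision(plasma_variant, FilterRule.NONE)
    both_high = (
        plasma_variant.af >= af_threshold and wbc_variant.af >= af_threshold
    )
    rescued = (
        plasma_variant.consequence in rescue_consequences
        and plasma_variant.gene in ch_genes
    )
    if both_high and not rescued:
        return _decision(plasma_variant, FilterRule.GERMLINE)
    return _decision(plasma_variant, FilterRule.NONE)


def quality_filter(
    variant: VariantCall, compartment: Compartment
) -> FilterDecision:
    """Remove synonymous variants, then low-depth, then low-HQ-read variants.

    Depth minima: 500x for cfDNA and tissue gDNA, 200x for WBC gDNA. HQ-read
    minima (MQ>30, BQ>30): 5 for cfDNA/tissue, 2 for WBC.
    """
    compartment = Compartment(compartment)
    if variant.consequence == Consequence.SYNONYMOUS:
        return _decision(variant, FilterRule.SYNONYMOUS)
    if variant.depth < DEPTH_MINIMUM[compartment]:
        return _decision(variant, FilterRule.LOW_DEPTH)
    if variant.hq_reads < HQ_READS_MINIMUM[compartment]:
        return _decision(variant, FilterRule.LOW_HQ_READS)
    return _decision(variant, FilterRule.NONE)


def population_filter(
    variant: VariantCall, threshold: float = 0.01
) -> FilterDecision:
    """Remove variants present in >1% of samples in population SNP databases.

    ``population_max_frequency`` is the maximum frequency across the consulted
    databases (dbSNP, 1000G, ESP6500, ExAC, plus any in-house background
    column). Unknown frequency retains the variant.
    """
    pmf = variant.population_max_frequency
    if pmf is not None and pmf > threshold:
        return _decision(variant, FilterRule.POPULATION_DB)
    return _decision(variant, FilterRule.NONE)


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------


def filter_variant(
    plasma_variant: VariantCall,
    wbc_lookup: Dict[VariantKey, VariantCall],
    compartment: Compartment = Compartment.PLASMA,
    population_threshold: float = 0.01,
    ch_genes: frozenset = CH_GENES_15,
) -> FilterDecision:
    """Run one variant through the cascade; first failing rule wins.

    Order: germline -> synonymous -> depth -> hq_reads -> population.
    """
    d = germline_filter(plasma_variant, wbc_lookup.get(plasma_variant.key),
                        ch_genes=ch_genes)
    if not d.retained:
        return d
    d = quality_filter(plasma_variant, compartment)
    if not d.retained:
        return d
    return population_filter(plasma_variant, threshold=population_threshold)


def apply_filter_cascade(
    cohort: CohortTable,
    population_threshold: float = 0.01,
    ch_genes: frozenset = CH_GENES_15,
) -> Tuple[CohortTable, List[FilterDecision]]:
    """Apply the cascade to every plasma variant of a matched cohort.

    Every plasma sample must have at least one WBC sample from the same
    patient (its variant table may be empty). Non-plasma variants pass
    through untouched; decisions are recorded for every plasma variant and
    the surviving plasma set is labeled high-confidence somatic in the
    provenance log.
    """
    by_sample = cohort.variants_by_sample()
    # index WBC variants per patient
    wbc_by_patient: Dict[str, Dict[VariantKey, VariantCall]] = {}
    for s in cohort.samples.values():
        if s.compartment == Compartment.WBC:
            lut = wbc_by_patient.setdefault(s.patient_id, {})
            for v in by_sample[s.sample_id]:
                lut[v.key] = v

    decisions: List[FilterDecision] = []
    kept: List[VariantCall] = []
    for s in cohort.samples.values():
        if s.compartment != Compartment.PLASMA:
            kept.extend(by_sample[s.sample_id])
            continue
        if not cohort.matched_samples(s.patient_id, Compartment.WBC):
            raise ValueError(
                f"plasma sample {s.sample_id} has no matched WBC sample"
            )
        lut = wbc_by_patient.get(s.patient_id, {})
        for v in by_sample[s.sample_id]:
            d = filter_variant(
                v, lut, Compartment.PLASMA,
                population_threshold=population_threshold, ch_genes=ch_genes,
            )
            decisions.append(d)
            if d.retained:
                kept.append(v)
    out = cohort.replace_variants(kept)
    n_removed = sum(1 for d in decisions if not d.retained)
    out.log(
        f"filter_cascade: {n_removed} plasma variants removed, "
        f"{sum(1 for d in decisions if d.retained)} high-confidence somatic retained"
    )
    return out, decisions


def decisions_to_frame(decisions: Iterable[FilterDecision]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "sample_id": d.sample_id,
                "chrom": d.key[0],
                "pos": d.key[1],
                "ref": d.key[2],
                "alt": d.key[3],
                "verdict": d.verdict,
                "rule": d.rule.value,
            }
            for d in decisions
        ]
    )


# ---------------------------------------------------------------------------
# rearrangement clustering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Breakpoint:
    chrom: str
    pos: int
    orientation: str  # "+" or "-"

    def __post_init__(self):
        if self.orientation not in ("+", "-"):
            raise ValueError(f"orientation must be + or -, got {self.orientation!r}")


@dataclass(frozen=True)
class FusionFragment:
    fragment_id: str
    breakpoint_a: Breakpoint
    breakpoint_b: Breakpoint


@dataclass
class FusionEvent:
    fragments: list
    support: int  # unique fragment ids

    @property
    def breakpoint_a(self) -> Breakpoint:
        return self.fragments[0].breakpoint_a

    @property
    def breakpoint_b(self) -> Breakpoint:
        return self.fragments[0].breakpoint_b


def _compatible(f: FusionFragment, g: FusionFragment, window_bp: int) -> bool:
    def near(a: Breakpoint, b: Breakpoint) -> bool:
        return (
            a.chrom == b.chrom
            and a.orientation == b.orientation
            and abs(a.pos - b.pos) <= window_bp
        )

    return near(f.breakpoint_a, g.breakpoint_a) and near(f.breakpoint_b, g.breakpoint_b)


def cluster_fusions(
    fragments: Iterable[FusionFragment], window_bp: int = 5
) -> List[FusionEvent]:
    """Cluster candidate fusion fragments and keep events with >=2 fragments.

    Fragments join a cluster when both breakpoints share chromosome and
    orientation and lie within ``window_bp`` of each other (single-linkage).
    Events supported by >=2 unique fragment ids are high-confidence fusions.
    """
    frags = list(fragments)
    n = len(frags)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _compatible(frags[i], frags[j], window_bp):
                parent[find(i)] = find(j)

    clusters: Dict[int, list] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(frags[i])
    events = []
    for members in clusters.values():
        support = len({f.fragment_id for f in members})
        if support >= 2:
            events.append(FusionEvent(fragments=members, support=support))
    events.sort(key=lambda e: (e.breakpoint_a.chrom, e.breakpoint_a.pos))
    return events
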