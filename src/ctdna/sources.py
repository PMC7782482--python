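"""Biological source classification of plasma variants and CH summaries.

A plasma variant found in the matched WBC table is WBC-matched (treated as a
clonal-hematopoiesis variant); otherwise, if found in matched tumor tissue it
is biopsy-matched (tumor-derived); a plasma-only variant in a complete
plasma/WBC/tissue trio is a VUSO (variant of unknown source). Without tissue
data a plasma-only variant is unresolved.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .filters import CH_GENES_10_INVOLVED
from .models import (
    CohortTable,
    Compartment,
    VariantCall,
    VariantKey,
)

WBC_MATCHED = "wbc_matched"
BIOPSY_MATCHED = "biopsy_matched"
VUSO = "vuso"
UNRESOLVED = "unresolved"

LABELS = (WBC_MATCHED, BIOPSY_MATCHED, VUSO, UNRESOLVED)


@dataclass
class SourceLabel:
    sample_id: str
    key: VariantKey
    label: str


def classify_source(
    plasma_variants: Sequence[VariantCall],
    wbc_variants: Sequence[VariantCall],
    tissue_variants: Optional[Sequence[VariantCall]] = None,
    compartments: Optional[Dict[str, Compartment]] = None,
) -> List[SourceLabel]:
    """Label each plasma variant by its likely biological source.

    Precedence: a variant present in plasma, WBC and tissue is WBC-matched —
    conservative for tumor-burden metrics, since any blood-lineage evidence
    disqualifies a variant from the tumor-derived set. ``tissue_variants=None``
    means no tissue was sequenced, so plasma-only variants are unresolved
    rather than VUSO.

    ``compartments`` (sample_id -> Compartment) is optional; when given, each
    input table is checked against it and a mislabeled compartment raises.
    """
    if compartments:
        checks = [
            (plasma_variants, Compartment.PLASMA),
            (wbc_variants, Compartment.WBC),
            (tissue_variants or [], Compartment.TISSUE),
        ]
        for table, expected in checks:
            for v in table:
                actual = compartments.get(v.sample_id)
                if actual is not None and actual != expected:
                    raise ValueError(
                        f"sample {v.sample_id} is {actual.value}, expected "
                        f"{expected.value}"
                    )
    wbc_keys = {v.key for v in wbc_variants}
    tissue_keys = {v.key for v in tissue_variants} if tissue_variants is not None else None
    labels = []
    for v in plasma_variants:
        if v.key in wbc_keys:
            label = WBC_MATCHED
        elif tissue_keys is not None and v.key in tissue_keys:
            label = BIOPSY_MATCHED
        elif tissue_keys is not None:
            label = VUSO
        else:
            label = UNRESOLVED
        labels.append(SourceLabel(v.sample_id, v.key, label))
    return labels


def classify_cohort(cohort: CohortTable) -> List[SourceLabel]:
    """Run :func:`classify_source` per plasma sample across a cohort."""
    by_sample = cohort.variants_by_sample()
    wbc_by_patient: Dict[str, list] = {}
    tissue_by_patient: Dict[str, list] = {}
    tissue_patients = set()
    for s in cohort.samples.values():
        if s.compartment == Compartment.WBC:
            wbc_by_patient.setdefault(s.patient_id, []).extend(by_sample[s.sample_id])
        elif s.compartment == Compartment.TISSUE:
            tissue_patients.add(s.patient_id)
            tissue_by_patient.setdefault(s.patient_id, []).extend(
                by_sample[s.sample_id]
            )
    labels: List[SourceLabel] = []
    for s in cohort.samples.values():
        if s.compartment != Compartment.PLASMA:
            continue
        tissue = (
            tissue_by_patient.get(s.patient_id, [])
            if s.patient_id in tissue_patients
            else None
        )
        labels.extend(
            classify_source(
                by_sample[s.sample_id],
                wbc_by_patient.get(s.patient_id, []),
                tissue,
            )
        )
    return labels


def labels_to_map(labels: Iterable[SourceLabel]) -> Dict[Tuple[str, VariantKey], str]:
    return {(l.sample_id, l.key): l.label for l in labels}


def ch_positive_samples(labels: Iterable[SourceLabel]) -> set:
    return {l.sample_id for l in labels if l.label == WBC_MATCHED}


# ---------------------------------------------------------------------------
# CH prevalence by age
# ---------------------------------------------------------------------------


@dataclass
class AgeBinSummary:
    age_bin: str
    n_patients: int
    ch_positive: int
    prevalence: float
    sem: float


def ch_prevalence_by_age(
    cohort: CohortTable,
    labels: Sequence[SourceLabel],
    bin_edges: Sequence[float] = (0, 40, 50, 60, 70, 80, 130),
) -> Tuple[List[AgeBinSummary], int]:
    """CH carrier prevalence per age bin, with binomial SEM.

    A patient is a CH carrier if any of their plasma variants is WBC-matched.
    Bins are half-open [lo, hi). Patients with unknown age are excluded and
    counted in the second return value.
    """
    edges = list(bin_edges)
    if edges != sorted(edges) or len(set(edges)) != len(edges):
        raise ValueError(f"bin edges must be strictly increasing: {edges}")
    if len(edges) < 2:
        raise ValueError("need at least two bin edges")
    ch_samples = ch_positive_samples(labels)
    ch_patients = {
        cohort.samples[s].patient_id for s in ch_samples if s in cohort.samples
    }
    plasma_patients = {
        s.patient_id
        for s in cohort.samples.values()
        if s.compartment == Compartment.PLASMA
    }
    n_unknown_age = 0
    bins = [[0, 0] for _ in range(len(edges) - 1)]  # [n, ch+]
    for pid in plasma_patients:
        age = cohort.patients[pid].age_years
        if age is None:
            n_unknown_age += 1
            continue
        for i in range(len(edges) - 1):
            if edges[i] <= age < edges[i + 1]:
                bins[i][0] += 1
                if pid in ch_patients:
                    bins[i][1] += 1
                break
    out = []
    for i, (n, k) in enumerate(bins):
        p = k / n if n else float("nan")
        sem = math.sqrt(p * (1 - p) / n) if n else float("nan")
        out.append(
            AgeBinSummary(
                age_bin=f"[{edges[i]:g},{edges[i+1]:g})",
                n_patients=n,
                ch_positive=k,
                prevalence=p,
                sem=sem,
            )
        )
    return out, n_unknown_age


# ---------------------------------------------------------------------------
# AF comparison (Mann-Whitney U)
# ---------------------------------------------------------------------------


@dataclass
class RankSumResult:
    u_statistic: float
    p_value: float
    median_a: float
    median_b: float
    method: str


def _exact_enumeration_p(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided exact Mann-Whitney p by enumerating group assignments.

    Handles ties via midranks; feasible only for small pooled sizes.
    """
    pooled = list(a) + list(b)
    n_a = len(a)
    ranks = stats.rankdata(pooled)
    u_obs = float(np.sum(ranks[:n_a]) - n_a * (n_a + 1) / 2)
    center = n_a * len(b) / 2
    dev_obs = abs(u_obs - center)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        u = float(np.sum(ranks[list(idx)]) - n_a * (n_a + 1) / 2)
        total += 1
        if abs(u - center) >= dev_obs - 1e-12:
            count += 1
    return u_obs, count / total


_EXACT_ENUM_MAX_POOLED = 14


def compare_af_groups(
    group_a_afs: Sequence[float], group_b_afs: Sequence[float]
) -> RankSumResult:
    """Two-sided Mann-Whitney U comparison of two AF groups.

    Small samples use an exact null distribution (full enumeration when ties
    are present and the pooled size permits, otherwise the exact rank-sum
    distribution); larger samples use the normal approximation with tie
    correction.
    """
    a = [float(x) for x in group_a_afs]
    b = [float(x) for x in group_b_afs]
    if not a or not b:
        raise ValueError("both AF groups must be non-empty")
    has_ties = len(set(a + b)) < len(a) + len(b)
    small = max(len(a), len(b)) <= 25
    if small and has_ties and len(a) + len(b) <= _EXACT_ENUM_MAX_POOLED:
        u, p = _exact_enumeration_p(a, b)
        method = "exact_enumeration"
    elif small and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        u, p, method = float(res.statistic), float(res.pvalue), "exact"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        u, p, method = float(res.statistic), float(res.pvalue), "asymptotic"
    return RankSumResult(
        u_statistic=u,
        p_value=min(1.0, p),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        method=method,
    )


# ---------------------------------------------------------------------------
# CH-gene enrichment (chi-square on a 2x2)
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    table: list  # [[wbc_in, wbc_out], [vuso_in, vuso_out]]
    chi2: float
    p_value: float


def ch_gene_enrichment(
    labels: Sequence[SourceLabel],
    variants: Sequence[VariantCall],
    ch_genes: frozenset = CH_GENES_10_INVOLVED,
    correction: bool = False,
) -> EnrichmentResult:
    """Chi-square test: are WBC-matched variants enriched in CH-related genes
    relative to VUSOs?

    Builds the 2x2 of (label in {wbc_matched, vuso}) x (gene in/out of the
    10 involved CH genes). No continuity correction by default.
    """
    gene_by_id = {(v.sample_id, v.key): v.gene for v in variants}
    counts = {WBC_MATCHED: [0, 0], VUSO: [0, 0]}
    for l in labels:
        if l.label not in counts:
            continue
        gene = gene_by_id.get((l.sample_id, l.key))
        if gene is None:
            continue
        counts[l.label][0 if gene in ch_genes else 1] += 1
    table = [counts[WBC_MATCHED], counts[VUSO]]
    if sum(table[0]) == 0 or sum(table[1]) == 0:
        raise ValueError(
            "both wbc_matched and vuso classes must be non-empty for enrichment"
        )
    if sum(r[0] for r in table) == 0 or sum(r[1] for r in table) == 0:
        raise ValueError("degenerate margin: all variants on one side of the gene set")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return EnrichmentResult(table=table, chi2=float(chi2), p_value=float(p))


def labels_to_frame(labels: Iterable[SourceLabel]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "sample_id": l.sample_id,
                "chrom": l.key[0],
                "pos": l.key[1],
                "ref": l.key[2],
                "alt": l.key[3],
                "label": l.label,
            }
            for l in labels
        ],
        columns=["sample_id", "chrom", "pos", "ref", "alt", "label"],
    )
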