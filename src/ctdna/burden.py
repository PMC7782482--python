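"""Circulating tumor burden: detection calls, sensitivity with confidence
intervals, maximal AF, blood tumor mutational burden (bTMB) and its
high/low classification.

bTMB counts "competent" mutations — somatic (non-germline, non-CH), coding
nonsynonymous SNVs/indels including +/-2 splice positions, with AF >= 0.5% —
divided by the panel-covered genomic territory (1.09 Mb by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import (
    CohortTable,
    Compartment,
    Consequence,
    VariantCall,
    VariantClass,
)
from .sources import WBC_MATCHED, SourceLabel, labels_to_map

PANEL_MB = 1.09
BTMB_AF_FLOOR = 0.005

#: consequences counting as coding nonsynonymous (incl. +/-2 splice)
COMPETENT_CONSEQUENCES = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT,
        Consequence.INFRAME_INDEL,
        Consequence.SPLICE_SITE,
    }
)

SMALL_VARIANT_CLASSES = frozenset({VariantClass.SNV, VariantClass.INDEL})


@dataclass
class BurdenMetrics:
    sample_id: str
    detected: bool
    max_af: Optional[float]  # None when no non-CH SNV/indel retained
    n_mutations: int  # competent mutation count (bTMB numerator)
    btmb: float
    btmb_class: str  # "high" | "low" | "unknown"


@dataclass
class SensitivityEstimate:
    group: str
    n: int
    k_detected: int
    sensitivity: float
    ci_low: float
    ci_high: float


def _non_ch(
    variants: Sequence[VariantCall],
    label_map: Optional[Dict] = None,
) -> List[VariantCall]:
    if label_map is None:
        return list(variants)
    return [
        v
        for v in variants
        if label_map.get((v.sample_id, v.key)) != WBC_MATCHED
    ]


def detection_call(
    variants: Sequence[VariantCall], label_map: Optional[Dict] = None
) -> bool:
    """True iff >=1 somatic alteration of any class remains after CH removal."""
    return len(_non_ch(variants, label_map)) > 0


def max_af(
    variants: Sequence[VariantCall], label_map: Optional[Dict] = None
) -> Optional[float]:
    """Maximal AF across retained non-CH SNV/indels; None when none remain."""
    afs = [
        v.af
        for v in _non_ch(variants, label_map)
        if v.variant_class in SMALL_VARIANT_CLASSES
    ]
    return max(afs) if afs else None


def compute_btmb(
    variants: Sequence[VariantCall],
    label_map: Optional[Dict] = None,
    panel_mb: float = PANEL_MB,
    af_floor: float = BTMB_AF_FLOOR,
) -> float:
    """bTMB = competent mutations / panel megabases.

    Competent: non-CH SNV/indel with a coding nonsynonymous consequence
    (incl. +/-2 splice) and AF >= ``af_floor``.
    """
    if panel_mb <= 0:
        raise ValueError(f"panel_mb must be positive, got {panel_mb}")
    n = count_competent(variants, label_map, af_floor)
    return n / panel_mb


def count_competent(
    variants: Sequence[VariantCall],
    label_map: Optional[Dict] = None,
    af_floor: float = BTMB_AF_FLOOR,
) -> int:
    return sum(
        1
        for v in _non_ch(variants, label_map)
        if v.variant_class in SMALL_VARIANT_CLASSES
        and v.consequence in COMPETENT_CONSEQUENCES
        and v.af >= af_floor
    )


def btmb_cutoff(values: Sequence[float]) -> float:
    """High/low bTMB cut-off: the cohort's 75th percentile.

    Linear interpolation between closest ranks; requires >=4 detected
    samples. Classification uses ``btmb >= cutoff`` as high, so the top
    quartile is called high when values are distinct.
    """
    vals = [float(v) for v in values]
    if len(vals) < 4:
        raise ValueError(
            f"need >=4 detected samples to place a bTMB cut-off, got {len(vals)}"
        )
    return float(np.percentile(vals, 75, method="linear"))


def classify_btmb(btmb: float, cutoff: float, detected: bool = True) -> str:
    if not detected:
        return "unknown"
    return "high" if btmb >= cutoff else "low"


# ---------------------------------------------------------------------------
# cohort-level burden table
# ---------------------------------------------------------------------------


def burden_table(
    cohort: CohortTable,
    labels: Sequence[SourceLabel],
    panel_mb: float = PANEL_MB,
    af_floor: float = BTMB_AF_FLOOR,
) -> List[BurdenMetrics]:
    """Per-plasma-sample burden metrics after CH removal.

    The bTMB cut-off is the 75th percentile over detected samples; samples
    without detected ctDNA get class "unknown". With <4 detected samples no
    cut-off can be placed and every class is "unknown".
    """
    if panel_mb <= 0:
        raise ValueError(f"panel_mb must be positive, got {panel_mb}")
    label_map = labels_to_map(labels)
    by_sample = cohort.variants_by_sample()
    rows = []
    for s in cohort.samples.values():
        if s.compartment != Compartment.PLASMA:
            continue
        variants = by_sample[s.sample_id]
        detected = detection_call(variants, label_map)
        n = count_competent(variants, label_map, af_floor)
        rows.append(
            BurdenMetrics(
                sample_id=s.sample_id,
                detected=detected,
                max_af=max_af(variants, label_map),
                n_mutations=n,
                btmb=n / panel_mb,
                btmb_class="unknown",
            )
        )
    detected_btmb = [r.btmb for r in rows if r.detected]
    if len(detected_btmb) >= 4:
        cutoff = btmb_cutoff(detected_btmb)
        for r in rows:
            r.btmb_class = classify_btmb(r.btmb, cutoff, r.detected)
    return rows


def burden_to_frame(rows: Iterable[BurdenMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "detected": r.detected,
                "max_af": r.max_af,
                "n_mutations": r.n_mutations,
                "btmb": r.btmb,
                "btmb_class": r.btmb_class,
            }
            for r in rows
        ],
        columns=["sample_id", "detected", "max_af", "n_mutations", "btmb",
                 "btmb_class"],
    )


# ---------------------------------------------------------------------------
# detection sensitivity
# ---------------------------------------------------------------------------


def wald_interval(k: int, n: int, z: float = 1.959963984540054) -> Tuple[float, float]:
    """Wald 95% binomial interval p +/- z*sqrt(p(1-p)/n), clamped to [0,1]."""
    p = k / n
    half = z * math.sqrt(p * (1 - p) / n)
    return max(0.0, p - half), min(1.0, p + half)


def wilson_interval(k: int, n: int, z: float = 1.959963984540054) -> Tuple[float, float]:
    p = k / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return max(0.0, center - half), min(1.0, center + half)


def sensitivity_by_group(
    cohort: CohortTable,
    burden: Sequence[BurdenMetrics],
    grouping: str = "overall",
    ci_method: str = "wald",
) -> List[SensitivityEstimate]:
    """Detection sensitivity (k detected / n samples) with 95% CI per group.

    ``grouping`` is ``"cancer_type"``, ``"stage"`` or ``"overall"``. Groups
    with n = 0 are omitted.
    """
    if grouping not in ("cancer_type", "stage", "overall"):
        raise ValueError(f"unknown grouping {grouping!r}")
    interval = {"wald": wald_interval, "wilson": wilson_interval}[ci_method]
    groups: Dict[str, List[bool]] = {}
    for r in burden:
        patient = cohort.patient_of(r.sample_id)
        if grouping == "overall":
            key = "overall"
        elif grouping == "cancer_type":
            key = patient.cancer_type
        else:
            key = patient.clinical_stage.value
        groups.setdefault(key, []).append(r.detected)
    out = []
    for key in sorted(groups):
        flags = groups[key]
        n, k = len(flags), sum(flags)
        lo, hi = interval(k, n)
        out.append(
            SensitivityEstimate(
                group=key, n=n, k_detected=k, sensitivity=k / n,
                ci_low=lo, ci_high=hi,
            )
        )
    return out


def sensitivity_to_frame(rows: Iterable[SensitivityEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": r.group,
                "n": r.n,
                "k_detected": r.k_detected,
                "sensitivity": r.sensitivity,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
            }
            for r in rows
        ],
        columns=["group", "n", "k_detected", "sensitivity", "ci_low", "ci_high"],
    )
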