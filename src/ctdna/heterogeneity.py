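"""Mutant-allele tumor heterogeneity (MATH) and copy-number-corrected
mutation clonality.

MATH = 148.26 x MAD / median over a sample's mutant allele fractions. The
148.26 factor is 100 x 1.4826, i.e. the normal-consistency constant is
already folded in, so the MAD here is the *raw* median absolute deviation —
median(|AF_i - median(AF)|) — NOT the scaled MAD most statistics libraries
return by default.

Clonality first transforms each AF for local copy number (AF / log2(CN) for
amplified loci, untouched for CN <= 2 or unknown), then normalizes by the
sample's maximal transformed AF, giving values in (0, 1] with the top
variant at exactly 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .models import VariantCall, VariantClass, VariantKey
from .sources import WBC_MATCHED

MATH_FACTOR = 148.26  # = 100 x 1.4826

#: common driver genes tracked across clonality bins
DRIVER_GENES_9 = frozenset(
    {"TP53", "EGFR", "PIK3CA", "KRAS", "APC", "RB1", "NF1", "ERBB2", "BRAF"}
)


@dataclass
class HeterogeneityResult:
    sample_id: str
    math: Optional[float]  # None when not computable
    n_afs_used: int
    median_af: Optional[float]
    mad_af: Optional[float]
    reason: Optional[str] = None  # set when math is None


def math_score(
    afs: Sequence[float], sample_id: str = ""
) -> HeterogeneityResult:
    """MATH = 148.26 x MAD / median of the sample's mutant AFs.

    MAD is the raw (unscaled) median absolute deviation. Fewer than two AFs
    yields an unknown result with a reason; a zero median is an error since
    the ratio is undefined.
    """
    vals = [float(a) for a in afs]
    if any(a <= 0 for a in vals):
        raise ValueError("AFs must be positive for MATH")
    if len(vals) < 2:
        return HeterogeneityResult(
            sample_id=sample_id,
            math=None,
            n_afs_used=len(vals),
            median_af=vals[0] if vals else None,
            mad_af=None,
            reason="fewer than 2 mutant AFs",
        )
    med = float(np.median(vals))
    if med == 0:
        raise ValueError("median AF is zero; MATH undefined")
    mad = float(np.median([abs(a - med) for a in vals]))
    return HeterogeneityResult(
        sample_id=sample_id,
        math=MATH_FACTOR * mad / med,
        n_afs_used=len(vals),
        median_af=med,
        mad_af=mad,
    )


def transform_af(af: float, copy_number: Optional[float]) -> float:
    """Copy-number transformation of an AF: AF / log2(CN) for amplified loci.

    At high copy number the AF-CN relationship is log-linear, hence the
    log2 divisor. For copy-number loss (CN < 2), neutral loci (CN = 2, where
    log2(CN) = 1 anyway) and unknown CN the transformation is skipped and the
    AF passes through unchanged.
    """
    if not (0 < af <= 1):
        raise ValueError(f"af must be in (0,1], got {af}")
    if copy_number is None:
        return af
    if copy_number <= 0:
        raise ValueError(f"copy_number must be positive, got {copy_number}")
    if copy_number <= 2:
        return af
    return af / math.log2(copy_number)


@dataclass
class ClonalityRecord:
    sample_id: str
    key: VariantKey
    gene: str
    af: float
    copy_number: Optional[float]
    transformed_af: float
    clonality: float


def clonality(variants: Sequence[VariantCall]) -> List[ClonalityRecord]:
    """Per-variant clonality: transformed AF / maximal transformed AF.

    Operates on one sample's SNV/indel variants with AF > 0. The maximum-AF
    variant (after transformation) has clonality exactly 1; ties all land
    at 1.
    """
    eligible = [
        v
        for v in variants
        if v.variant_class in (VariantClass.SNV, VariantClass.INDEL) and v.af > 0
    ]
    if not eligible:
        raise ValueError("clonality requires >=1 SNV/indel with AF > 0")
    transformed = [transform_af(v.af, v.copy_number) for v in eligible]
    top = max(transformed)
    return [
        ClonalityRecord(
            sample_id=v.sample_id,
            key=v.key,
            gene=v.gene,
            af=v.af,
            copy_number=v.copy_number,
            transformed_af=t,
            clonality=t / top,
        )
        for v, t in zip(eligible, transformed)
    ]


def clonality_bins(
    records: Sequence[ClonalityRecord],
    driver_genes: frozenset = DRIVER_GENES_9,
    bin_width: float = 0.1,
) -> pd.DataFrame:
    """Mutation counts and driver-gene fraction per clonality bin.

    Bins are [0, w), [w, 2w), ..., with the top bin closed ([1-w, 1]) so the
    maximal variant lands in a bin. Returns a DataFrame with one row per bin.
    """
    if not records:
        raise ValueError("no clonality records to bin")
    n_bins_f = 1.0 / bin_width
    n_bins = round(n_bins_f)
    if abs(n_bins_f - n_bins) > 1e-9 or n_bins < 1:
        raise ValueError(f"bin_width {bin_width} does not divide 1")
    counts = [0] * n_bins
    drivers = [0] * n_bins
    for r in records:
        idx = min(int(r.clonality / bin_width), n_bins - 1)
        counts[idx] += 1
        if r.gene in driver_genes:
            drivers[idx] += 1
    rows = []
    for i in range(n_bins):
        lo, hi = i * bin_width, (i + 1) * bin_width
        closing = "]" if i == n_bins - 1 else ")"
        rows.append(
            {
                "bin": f"[{lo:g},{hi:g}{closing}",
                "bin_low": lo,
                "bin_high": hi,
                "n_mutations": counts[i],
                "n_driver": drivers[i],
                "driver_fraction": drivers[i] / counts[i] if counts[i] else 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort-level helpers
# ---------------------------------------------------------------------------


def sample_math_scores(
    variants_by_sample: Dict[str, list],
    label_map: Optional[Dict] = None,
) -> List[HeterogeneityResult]:
    """MATH per plasma sample over retained non-CH SNV/indel AFs."""
    out = []
    for sample_id, variants in variants_by_sample.items():
        afs = [
            v.af
            for v in variants
            if v.variant_class in (VariantClass.SNV, VariantClass.INDEL)
            and v.af > 0
            and (
                label_map is None
                or label_map.get((v.sample_id, v.key)) != WBC_MATCHED
            )
        ]
        out.append(math_score(afs, sample_id=sample_id))
    return out


def cohort_clonality(
    variants_by_sample: Dict[str, list],
    label_map: Optional[Dict] = None,
) -> List[ClonalityRecord]:
    """Clonality records across samples, skipping samples with no eligible
    variants. CH (WBC-matched) variants are excluded before normalization."""
    records: List[ClonalityRecord] = []
    for sample_id, variants in variants_by_sample.items():
        pool = [
            v
            for v in variants
            if label_map is None
            or label_map.get((v.sample_id, v.key)) != WBC_MATCHED
        ]
        eligible = [
            v
            for v in pool
            if v.variant_class in (VariantClass.SNV, VariantClass.INDEL)
            and v.af > 0
        ]
        if eligible:
            records.extend(clonality(eligible))
    return records


def heterogeneity_to_frame(rows: Iterable[HeterogeneityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "math": r.math,
                "n_afs_used": r.n_afs_used,
                "median_af": r.median_af,
                "mad_af": r.mad_af,
                "reason": r.reason,
            }
            for r in rows
        ],
        columns=["sample_id", "math", "n_afs_used", "median_af", "mad_af", "reason"],
    )


def clonality_to_frame(records: Iterable[ClonalityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "chrom": r.key[0],
                "pos": r.key[1],
                "ref": r.key[2],
                "alt": r.key[3],
                "gene": r.gene,
                "af": r.af,
                "copy_number": r.copy_number,
                "transformed_af": r.transformed_af,
                "clonality": r.clonality,
            }
            for r in records
        ],
        columns=["sample_id", "chrom", "pos", "ref", "alt", "gene", "af",
                 "copy_number", "transformed_af", "clonality"],
    )
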