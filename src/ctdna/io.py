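"""Readers and writers for variant tables and clinical metadata, plus the
sample-level QC gate.

Two on-disk dialects are supported for variants:

* VCF 4.2 — single-sample files; per-variant annotations live in INFO
  (``GENE``, ``VCLASS``, ``CSQ``, ``CN``, ``POPMAX``, ``PCHANGE``, ``PCLASS``)
  and read evidence in FORMAT (``DP``, ``HQ``, ``AF``, ``AD``). When ``AF``
  is absent it is computed as alt-supporting reads / depth.
* TSV — one row per variant with a documented header (``VARIANT_COLUMNS``).

Samples and patients travel as TSV with the headers documented below.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Tuple

import pandas as pd

from .models import (
    CohortTable,
    Compartment,
    Consequence,
    Gender,
    PatientRecord,
    SampleRecord,
    Stage,
    VariantCall,
    VariantClass,
)

VARIANT_COLUMNS = [
    "sample_id",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_class",
    "consequence",
    "af",
    "depth",
    "hq_reads",
    "copy_number",
    "population_max_frequency",
    "protein_change",
    "positional_class",
]

SAMPLE_COLUMNS = [
    "sample_id",
    "patient_id",
    "compartment",
    "mean_depth",
    "contamination_rate",
    "cfdna_concentration",
    "collection_date",
]

PATIENT_COLUMNS = ["patient_id", "age_years", "gender", "cancer_type", "clinical_stage"]

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="HGNC gene symbol">
##INFO=<ID=VCLASS,Number=1,Type=String,Description="Variant class">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Coding consequence">
##INFO=<ID=CN,Number=1,Type=Float,Description="Local copy number">
##INFO=<ID=POPMAX,Number=1,Type=Float,Description="Max population database frequency">
##INFO=<ID=PCHANGE,Number=1,Type=String,Description="Protein change">
##INFO=<ID=PCLASS,Number=1,Type=String,Description="Positional alteration class">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FORMAT=<ID=HQ,Number=1,Type=Integer,Description="High-quality supporting reads (MQ>30, BQ>30)">
##FORMAT=<ID=AD,Number=1,Type=Integer,Description="Alt-supporting reads">
##FORMAT=<ID=AF,Number=1,Type=Float,Description="Allele fraction">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def _none_if_nan(x):
    if x is None:
        return None
    if isinstance(x, float) and math.isnan(x):
        return None
    if isinstance(x, str) and x in ("", ".", "NA", "nan"):
        return None
    return x


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------


def read_variant_table(path, format: str = "tsv") -> List[VariantCall]:
    """Read one variant table into a list of :class:`VariantCall`.

    ``format`` is ``"vcf"`` or ``"tsv"``. Unknown optional fields are left
    as None; AF missing from a VCF record is computed as AD/DP. Malformed
    records raise :class:`ValueError` naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown variant table format: {format!r}")


def _read_tsv(path: Path) -> List[VariantCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    required = [c for c in VARIANT_COLUMNS if c not in
                ("copy_number", "population_max_frequency", "protein_change",
                 "positional_class")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        try:
            out.append(
                VariantCall(
                    sample_id=str(row.sample_id),
                    gene=str(row.gene),
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    ref=str(row.ref),
                    alt=str(row.alt),
                    variant_class=VariantClass(row.variant_class),
                    consequence=Consequence(row.consequence),
                    af=float(row.af),
                    depth=int(row.depth),
                    hq_reads=int(row.hq_reads),
                    copy_number=_opt_float(getattr(row, "copy_number", None)),
                    population_max_frequency=_opt_float(
                        getattr(row, "population_max_frequency", None)
                    ),
                    protein_change=_opt_str(getattr(row, "protein_change", None)),
                    positional_class=_opt_str(getattr(row, "positional_class", None)),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed record at line {i}: {exc}") from exc
    return out


def _opt_float(x) -> Optional[float]:
    x = _none_if_nan(x)
    return None if x is None else float(x)


def _opt_str(x) -> Optional[str]:
    x = _none_if_nan(x)
    return None if x is None else str(x)


def _read_vcf(path: Path) -> List[VariantCall]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if len(vcf.samples) != 1:
        raise ValueError(
            f"{path}: expected a single-sample VCF, found samples {vcf.samples}"
        )
    sample_id = vcf.samples[0]
    out = []
    for i, rec in enumerate(vcf, start=1):
        try:
            if len(rec.ALT) != 1:
                raise ValueError("multi-allelic records must be split")
            depth = _fmt_scalar(rec, "DP")
            hq = _fmt_scalar(rec, "HQ")
            af = _fmt_scalar(rec, "AF", float)
            if af is None:
                ad = _fmt_scalar(rec, "AD")
                if ad is None or not depth:
                    raise ValueError("neither AF nor AD/DP present")
                af = ad / depth
            out.append(
                VariantCall(
                    sample_id=sample_id,
                    gene=str(rec.INFO.get("GENE", "unknown")),
                    chrom=str(rec.CHROM),
                    pos=int(rec.POS),
                    ref=str(rec.REF),
                    alt=str(rec.ALT[0]),
                    variant_class=VariantClass(rec.INFO.get("VCLASS", "SNV")),
                    consequence=Consequence(rec.INFO.get("CSQ", "other")),
                    af=float(af),
                    depth=int(depth or 0),
                    hq_reads=int(hq or 0),
                    copy_number=_opt_float(rec.INFO.get("CN")),
                    population_max_frequency=_opt_float(rec.INFO.get("POPMAX")),
                    protein_change=_opt_str(rec.INFO.get("PCHANGE")),
                    positional_class=_opt_str(rec.INFO.get("PCLASS")),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed VCF record #{i}: {exc}") from exc
    return out


def _fmt_scalar(rec, tag: str, cast=int):
    try:
        arr = rec.format(tag)
    except KeyError:
        return None
    if arr is None:
        return None
    val = arr[0][0] if getattr(arr[0], "__len__", None) else arr[0]
    if val is None or (isinstance(val, float) and math.isnan(val)) or val < 0:
        return None
    return cast(val)


def variants_to_frame(variants: Iterable[VariantCall]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": v.sample_id,
            "gene": v.gene,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "variant_class": v.variant_class.value,
            "consequence": v.consequence.value,
            "af": v.af,
            "depth": v.depth,
            "hq_reads": v.hq_reads,
            "copy_number": v.copy_number,
            "population_max_frequency": v.population_max_frequency,
            "protein_change": v.protein_change,
            "positional_class": v.positional_class,
        }
        for v in variants
    ]
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def write_variant_table(variants: Iterable[VariantCall], path, format: str = "tsv"):
    path = Path(path)
    if format == "tsv":
        variants_to_frame(variants).to_csv(path, sep="\t", index=False)
        return
    if format == "vcf":
        _write_vcf(list(variants), path)
        return
    raise ValueError(f"unknown variant table format: {format!r}")


def _write_vcf(variants: List[VariantCall], path: Path) -> None:
    sample_ids = {v.sample_id for v in variants}
    if len(sample_ids) > 1:
        raise ValueError("VCF output is single-sample; split variants by sample first")
    sample = sample_ids.pop() if sample_ids else "SAMPLE"
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(sample=sample))
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            info = [f"GENE={v.gene}", f"VCLASS={v.variant_class.value}",
                    f"CSQ={v.consequence.value}"]
            if v.copy_number is not None:
                info.append(f"CN={v.copy_number:g}")
            if v.population_max_frequency is not None:
                info.append(f"POPMAX={v.population_max_frequency:g}")
            if v.protein_change:
                info.append(f"PCHANGE={v.protein_change}")
            if v.positional_class:
                info.append(f"PCLASS={v.positional_class}")
            ad = int(round(v.af * v.depth))
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
                f"{';'.join(info)}\tDP:HQ:AD:AF\t"
                f"{v.depth}:{v.hq_reads}:{ad}:{v.af:.6g}\n"
            )


# ---------------------------------------------------------------------------
# clinical metadata
# ---------------------------------------------------------------------------


def read_samples(path) -> List[SampleRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str})
    missing = [c for c in ("sample_id", "patient_id", "compartment", "mean_depth")
               if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    return [
        SampleRecord(
            sample_id=str(r.sample_id),
            patient_id=str(r.patient_id),
            compartment=Compartment(r.compartment),
            mean_depth=float(r.mean_depth),
            contamination_rate=_opt_float(getattr(r, "contamination_rate", None)),
            cfdna_concentration=_opt_float(getattr(r, "cfdna_concentration", None)),
            collection_date=_opt_str(getattr(r, "collection_date", None)),
        )
        for r in df.itertuples(index=False)
    ]


def read_patients(path) -> List[PatientRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    missing = [c for c in ("patient_id",) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    out = []
    for r in df.itertuples(index=False):
        age = _opt_float(getattr(r, "age_years", None))
        out.append(
            PatientRecord(
                patient_id=str(r.patient_id),
                age_years=age,
                gender=Gender(_none_if_nan(getattr(r, "gender", None)) or "unknown"),
                cancer_type=str(_none_if_nan(getattr(r, "cancer_type", None))
                               or "unknown"),
                clinical_stage=Stage(
                    _none_if_nan(getattr(r, "clinical_stage", None)) or "unknown"
                ),
            )
        )
    return out


def samples_to_frame(samples: Iterable[SampleRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "patient_id": s.patient_id,
                "compartment": s.compartment.value,
                "mean_depth": s.mean_depth,
                "contamination_rate": s.contamination_rate,
                "cfdna_concentration": s.cfdna_concentration,
                "collection_date": s.collection_date,
            }
            for s in samples
        ],
        columns=SAMPLE_COLUMNS,
    )


def patients_to_frame(patients: Iterable[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "age_years": p.age_years,
                "gender": p.gender.value,
                "cancer_type": p.cancer_type,
                "clinical_stage": p.clinical_stage.value,
            }
            for p in patients
        ],
        columns=PATIENT_COLUMNS,
    )


def write_cohort(cohort: CohortTable, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    patients_to_frame(cohort.patients.values()).to_csv(
        outdir / "patients.tsv", sep="\t", index=False
    )
    samples_to_frame(cohort.samples.values()).to_csv(
        outdir / "samples.tsv", sep="\t", index=False
    )
    variants_to_frame(cohort.variants).to_csv(
        outdir / "variants.tsv", sep="\t", index=False
    )
    (outdir / "provenance.log").write_text("".join(l + "\n" for l in cohort.provenance))


def read_cohort(indir) -> CohortTable:
    indir = Path(indir)
    patients = read_patients(indir / "patients.tsv")
    samples = read_samples(indir / "samples.tsv")
    variants = read_variant_table(indir / "variants.tsv", format="tsv")
    prov_path = indir / "provenance.log"
    provenance = (
        prov_path.read_text().splitlines() if prov_path.exists() else []
    )
    return CohortTable.build(patients, samples, variants, provenance)


# ---------------------------------------------------------------------------
# sample-level QC gate
# ---------------------------------------------------------------------------


@dataclass
class QCExclusion:
    sample_id: str
    reason: str


def apply_sample_qc(
    cohort: CohortTable,
    min_depth: float = 1000.0,
    max_contamination: float = 0.01,
) -> Tuple[CohortTable, List[QCExclusion]]:
    """Exclude plasma samples with insufficient depth or abnormal contamination.

    Plasma samples below ``min_depth`` mean coverage or above
    ``max_contamination`` cfDNA contamination are dropped together with their
    variants. Samples with unknown QC fields are retained but flagged in the
    report. The gate is idempotent.
    """
    if not cohort.samples:
        raise ValueError("cannot QC an empty cohort")
    exclusions: List[QCExclusion] = []
    keep = {}
    for s in cohort.samples.values():
        if s.compartment == Compartment.PLASMA:
            if s.mean_depth < min_depth:
                exclusions.append(QCExclusion(s.sample_id, "insufficient depth"))
                continue
            if s.contamination_rate is not None and s.contamination_rate > max_contamination:
                exclusions.append(QCExclusion(s.sample_id, "abnormal contamination"))
                continue
            if s.contamination_rate is None:
                exclusions.append(
                    QCExclusion(s.sample_id, "retained: contamination unknown")
                )
        keep[s.sample_id] = s
    variants = [v for v in cohort.variants if v.sample_id in keep]
    patients = cohort.patients.values()
    out = CohortTable.build(patients, keep.values(), variants, cohort.provenance)
    n_removed = sum(1 for e in exclusions if not e.reason.startswith("retained"))
    out.log(
        f"sample_qc: min_depth={min_depth} max_contamination={max_contamination} "
        f"removed={n_removed}"
    )
    return out, exclusions
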