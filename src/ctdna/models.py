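"""Core data model for matched plasma / WBC / tissue variant cohorts.

Allele fractions are stored as fractions in [0, 1] everywhere; percent
formatting is a presentation-layer concern. Genomic coordinates are
1-based with ref/alt anchored as in VCF; indel keys are left-trimmed
before cross-compartment identity matching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional


class Compartment(str, Enum):
    PLASMA = "plasma_cfDNA"
    WBC = "wbc_gDNA"
    TISSUE = "tissue_gDNA"


class VariantClass(str, Enum):
    SNV = "SNV"
    INDEL = "indel"
    CNV = "CNV"
    REARRANGEMENT = "rearrangement"


class Consequence(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_SITE = "splice_site"
    SYNONYMOUS = "synonymous"
    PROMOTER = "promoter"
    OTHER = "other"


class Stage(str, Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    UNKNOWN = "unknown"


class Gender(str, Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


VariantKey = tuple  # (chrom, pos, ref, alt) after left-trim normalization


def normalize_variant_key(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Left-trim a (chrom, pos, ref, alt) identity to its minimal anchored form.

    Shared suffix bases are dropped first, then shared prefix bases (keeping at
    least one base on each side and advancing ``pos`` per trimmed prefix base).
    This is reference-free normalization: it cannot left-shift through repeat
    tracts, but it makes equivalent VCF spellings of the same indel compare
    equal, which is all cross-compartment matching requires.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return (str(chrom), int(pos), ref, alt)


@dataclass
class PatientRecord:
    patient_id: str
    age_years: Optional[float] = None  # None = unknown
    gender: Gender = Gender.UNKNOWN
    cancer_type: str = "unknown"
    clinical_stage: Stage = Stage.UNKNOWN

    def __post_init__(self) -> None:
        if self.age_years is not None and not (0 <= self.age_years < 130):
            raise ValueError(
                f"patient {self.patient_id}: age_years {self.age_years} out of range"
            )
        self.gender = Gender(self.gender)
        self.clinical_stage = Stage(self.clinical_stage)


@dataclass
class SampleRecord:
    sample_id: str
    patient_id: str
    compartment: Compartment
    mean_depth: float
    contamination_rate: Optional[float] = None  # None = unknown
    cfdna_concentration: Optional[float] = None  # ng/ml
    collection_date: Optional[str] = None

    def __post_init__(self) -> None:
        self.compartment = Compartment(self.compartment)
        if self.mean_depth <= 0:
            raise ValueError(f"sample {self.sample_id}: mean_depth must be positive")
        if self.contamination_rate is not None and not (
            0 <= self.contamination_rate <= 1
        ):
            raise ValueError(
                f"sample {self.sample_id}: contamination_rate must be in [0,1]"
            )


@dataclass
class VariantCall:
    """One called alteration in one sample compartment.

    ``hq_reads`` counts variant-supporting reads with mapping quality >30 and
    base quality >30. ``copy_number`` and ``population_max_frequency`` are
    None when unknown; they are never fabricated. ``protein_change`` and
    ``positional_class`` (e.g. ``e19del``) are optional annotations consumed
    by actionability matching.
    """

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: VariantClass
    consequence: Consequence
    af: float
    depth: int
    hq_reads: int
    copy_number: Optional[float] = None
    population_max_frequency: Optional[float] = None
    protein_change: Optional[str] = None
    positional_class: Optional[str] = None

    def __post_init__(self) -> None:
        self.variant_class = VariantClass(self.variant_class)
        self.consequence = Consequence(self.consequence)
        if not (0 <= self.af <= 1):
            raise ValueError(f"af {self.af} outside [0,1] for {self.gene}")
        if self.depth < 0 or self.hq_reads < 0:
            raise ValueError("depth and hq_reads must be non-negative")
        if self.hq_reads > self.depth:
            raise ValueError(
                f"hq_reads {self.hq_reads} exceeds depth {self.depth} for {self.gene}"
            )
        if self.population_max_frequency is not None and not (
            0 <= self.population_max_frequency <= 1
        ):
            raise ValueError("population_max_frequency outside [0,1]")

    @property
    def key(self) -> VariantKey:
        return normalize_variant_key(self.chrom, self.pos, self.ref, self.alt)


@dataclass
class CohortTable:
    """Referentially checked container for patients, samples and variants.

    ``provenance`` is an append-only log of the processing steps applied so
    far; pipeline stages must only ever extend it.
    """

    patients: dict = field(default_factory=dict)  # patient_id -> PatientRecord
    samples: dict = field(default_factory=dict)  # sample_id -> SampleRecord
    variants: list = field(default_factory=list)  # list[VariantCall]
    provenance: list = field(default_factory=list)

    @classmethod
    def build(
        cls,
        patients: Iterable[PatientRecord],
        samples: Iterable[SampleRecord],
        variants: Iterable[VariantCall],
        provenance: Optional[list] = None,
    ) -> "CohortTable":
        pt = {}
        for p in patients:
            if p.patient_id in pt:
                raise ValueError(f"duplicate patient_id {p.patient_id}")
            pt[p.patient_id] = p
        sm = {}
        for s in samples:
            if s.sample_id in sm:
                raise ValueError(f"duplicate sample_id {s.sample_id}")
            if s.patient_id not in pt:
                raise ValueError(
                    f"sample {s.sample_id} references unknown patient {s.patient_id}"
                )
            sm[s.sample_id] = s
        vs = list(variants)
        for v in vs:
            if v.sample_id not in sm:
                raise ValueError(
                    f"variant {v.gene} {v.chrom}:{v.pos} references unknown sample "
                    f"{v.sample_id}"
                )
        return cls(pt, sm, vs, list(provenance or []))

    def log(self, message: str) -> None:
        self.provenance.append(message)

    # -- convenience views ---------------------------------------------------

    def samples_of(self, compartment: Compartment) -> list:
        return [s for s in self.samples.values() if s.compartment == compartment]

    def variants_for_sample(self, sample_id: str) -> list:
        return [v for v in self.variants if v.sample_id == sample_id]

    def variants_by_sample(self) -> dict:
        out: dict = {s: [] for s in self.samples}
        for v in self.variants:
            out[v.sample_id].append(v)
        return out

    def matched_samples(
        self, patient_id: str, compartment: Compartment
    ) -> list:
        return [
            s
            for s in self.samples.values()
            if s.patient_id == patient_id and s.compartment == compartment
        ]

    def patient_of(self, sample_id: str) -> PatientRecord:
        return self.patients[self.samples[sample_id].patient_id]

    def replace_variants(self, variants: list) -> "CohortTable":
        return CohortTable.build(
            self.patients.values(), self.samples.values(), variants, self.provenance
        )

    def __iter__(self) -> Iterator[VariantCall]:
        return iter(self.variants)
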