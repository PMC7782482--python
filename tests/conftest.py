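import pytest

from ctdna.models import (
    CohortTable,
    Compartment,
    PatientRecord,
    SampleRecord,
    VariantCall,
)


def make_variant(
    sample_id="S1-PL",
    gene="KRAS",
    chrom="12",
    pos=25398284,
    ref="C",
    alt="T",
    variant_class="SNV",
    consequence="missense",
    af=0.10,
    depth=2000,
    hq_reads=150,
    **kwargs,
):
    return VariantCall(
        sample_id=sample_id,
        gene=gene,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        variant_class=variant_class,
        consequence=consequence,
        af=af,
        depth=depth,
        hq_reads=hq_reads,
        **kwargs,
    )


@pytest.fixture
def trio_cohort_factory():
    """Build a one-patient trio cohort from plasma/WBC/tissue variant lists."""

    def build(plasma=(), wbc=(), tissue=None, patient_kwargs=None):
        patient = PatientRecord("P1", 60, "female", "NSCLC", "IV",
                                **(patient_kwargs or {}))
        samples = [
            SampleRecord("P1-PL", "P1", Compartment.PLASMA, 4429.0,
                         contamination_rate=0.001),
            SampleRecord("P1-WBC", "P1", Compartment.WBC, 423.0),
        ]
        variants = list(plasma) + list(wbc)
        if tissue is not None:
            samples.append(SampleRecord("P1-TIS", "P1", Compartment.TISSUE, 1808.0))
            variants += list(tissue)
        return CohortTable.build([patient], samples, variants)

    return build
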