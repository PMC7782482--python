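"""Source classification, CH-by-age prevalence, AF comparison, enrichment."""

import itertools

import numpy as np
import pytest

from ctdna.filters import CH_GENES_10_INVOLVED
from ctdna.models import Compartment
from ctdna.sources import (
    BIOPSY_MATCHED,
    UNRESOLVED,
    VUSO,
    WBC_MATCHED,
    SourceLabel,
    ch_gene_enrichment,
    ch_prevalence_by_age,
    classify_cohort,
    classify_source,
    compare_af_groups,
)

from conftest import make_variant


def _pl(pos, **kw):
    return make_variant(sample_id="P1-PL", pos=pos, **kw)


def _wb(pos, **kw):
    return make_variant(sample_id="P1-WBC", pos=pos, depth=423, hq_reads=100, **kw)


def _ti(pos, **kw):
    return make_variant(sample_id="P1-TIS", pos=pos, depth=1808, hq_reads=200, **kw)


class TestClassifySource:
    def test_plasma_and_wbc_is_wbc_matched(self):
        labels = classify_source([_pl(100)], [_wb(100)], [_ti(999)])
        assert labels[0].label == WBC_MATCHED

    def test_plasma_and_tissue_only_is_biopsy_matched(self):
        labels = classify_source([_pl(100)], [_wb(999)], [_ti(100)])
        assert labels[0].label == BIOPSY_MATCHED

    def test_plasma_only_in_complete_trio_is_vuso(self):
        labels = classify_source([_pl(100)], [_wb(999)], [_ti(888)])
        assert labels[0].label == VUSO

    def test_wbc_precedence_over_tissue(self):
        # present in all three compartments: blood evidence wins
        labels = classify_source([_pl(100)], [_wb(100)], [_ti(100)])
        assert labels[0].label == WBC_MATCHED

    def test_without_tissue_plasma_only_is_unresolved(self):
        labels = classify_source([_pl(100), _pl(200)], [_wb(100)], None)
        assert [l.label for l in labels] == [WBC_MATCHED, UNRESOLVED]

    def test_mislabeled_compartment_rejected(self):
        comps = {"P1-PL": Compartment.WBC}
        with pytest.raises(ValueError, match="P1-PL"):
            classify_source([_pl(100)], [], None, compartments=comps)

    def test_every_trio_variant_gets_exactly_one_label(self):
        plasma = [_pl(p) for p in range(100, 150)]
        wbc = [_wb(p) for p in range(100, 110)]
        tissue = [_ti(p) for p in range(105, 130)]
        labels = classify_source(plasma, wbc, tissue)
        assert len(labels) == len(plasma)
        counts = {lab: 0 for lab in (WBC_MATCHED, BIOPSY_MATCHED, VUSO)}
        for l in labels:
            counts[l.label] += 1
        assert sum(counts.values()) == len(plasma)
        assert counts[WBC_MATCHED] == 10  # 100-109
        assert counts[BIOPSY_MATCHED] == 20  # 110-129
        assert counts[VUSO] == 20  # 130-149


class TestPrevalenceByAge:
    def _cohort(self, trio_factory, ages, ch_flags):
        from ctdna.models import CohortTable, PatientRecord, SampleRecord

        patients, samples, variants = [], [], []
        for i, (age, is_ch) in enumerate(zip(ages, ch_flags)):
            pid = f"P{i}"
            patients.append(PatientRecord(pid, age, "female", "NSCLC", "IV"))
            samples.append(SampleRecord(f"{pid}-PL", pid, Compartment.PLASMA, 4000))
            samples.append(SampleRecord(f"{pid}-WBC", pid, Compartment.WBC, 423))
            if is_ch:
                variants.append(make_variant(sample_id=f"{pid}-PL", pos=100))
                variants.append(
                    make_variant(sample_id=f"{pid}-WBC", pos=100, depth=423,
                                 hq_reads=100)
                )
        return CohortTable.build(patients, samples, variants)

    def test_zero_carriers_gives_zero_prevalence(self, trio_cohort_factory):
        cohort = self._cohort(trio_cohort_factory, [30, 50, 85], [False] * 3)
        labels = classify_cohort(cohort)
        bins, _ = ch_prevalence_by_age(cohort, labels, (0, 40, 80, 130))
        assert all(b.prevalence == 0 for b in bins if b.n_patients)

    def test_single_bin_recovers_overall_fraction(self, trio_cohort_factory):
        cohort = self._cohort(trio_cohort_factory, [30, 50, 70, 85],
                              [True, False, True, False])
        labels = classify_cohort(cohort)
        bins, _ = ch_prevalence_by_age(cohort, labels, (0, 130))
        assert bins[0].n_patients == 4
        assert bins[0].prevalence == pytest.approx(0.5)
        assert bins[0].sem == pytest.approx(np.sqrt(0.25 / 4))

    def test_unknown_age_excluded_and_counted(self, trio_cohort_factory):
        cohort = self._cohort(trio_cohort_factory, [30, None, 85],
                              [True, True, False])
        labels = classify_cohort(cohort)
        bins, n_unknown = ch_prevalence_by_age(cohort, labels, (0, 130))
        assert n_unknown == 1
        assert bins[0].n_patients == 2

    def test_unordered_edges_rejected(self, trio_cohort_factory):
        cohort = self._cohort(trio_cohort_factory, [30], [False])
        with pytest.raises(ValueError, match="increasing"):
            ch_prevalence_by_age(cohort, [], (40, 0, 130))


class TestCompareAFGroups:
    def test_identical_groups_give_p_one(self):
        res = compare_af_groups([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert res.p_value == pytest.approx(1.0)

    def test_singletons_exact_p_is_one(self):
        # only two orderings exist and both are equally extreme
        res = compare_af_groups([0.1], [0.2])
        assert res.p_value == pytest.approx(1.0)
        assert res.method in ("exact", "exact_enumeration")

    def test_fully_separated_groups_highly_significant(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0.001, 0.01, 20)
        b = rng.uniform(0.05, 0.3, 20)
        res = compare_af_groups(a, b)
        assert res.p_value < 0.001
        assert res.median_a < res.median_b

    def test_exact_enumeration_matches_scipy_on_untied_data(self):
        from scipy.stats import mannwhitneyu

        a, b = [0.11, 0.32, 0.45], [0.21, 0.28]
        ours = compare_af_groups(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert ours.p_value == pytest.approx(float(ref.pvalue))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_af_groups([], [0.1])


def _chi2_oracle(table):
    """Direct chi-square formula on a 2x2 (no continuity correction)."""
    (a, b), (c, d) = table
    n = a + b + c + d
    row = [a + b, c + d]
    col = [a + c, b + d]
    chi2 = 0.0
    for i, obs_row in enumerate(table):
        for j, obs in enumerate(obs_row):
            exp = row[i] * col[j] / n
            chi2 += (obs - exp) ** 2 / exp
    from scipy.stats import chi2 as chi2_dist

    return chi2, float(chi2_dist.sf(chi2, df=1))


def _labels_and_variants(n_wbc_in, n_wbc_out, n_vuso_in, n_vuso_out):
    labels, variants = [], []
    pos = itertools.count(1000)
    specs = [
        (WBC_MATCHED, "DNMT3A", n_wbc_in), (WBC_MATCHED, "CSMD3", n_wbc_out),
        (VUSO, "TP53", n_vuso_in), (VUSO, "LRP1B", n_vuso_out),
    ]
    for label, gene, n in specs:
        for _ in range(n):
            v = make_variant(sample_id="P1-PL", gene=gene, pos=next(pos))
            variants.append(v)
            labels.append(SourceLabel("P1-PL", v.key, label))
    return labels, variants


class TestCHGeneEnrichment:
    def test_reconstructed_study_counts_reach_reported_significance(self):
        # 27.5% of 316 WBC-matched vs 14.9% of 161 VUSOs in the 10 CH genes
        labels, variants = _labels_and_variants(87, 229, 24, 137)
        res = ch_gene_enrichment(labels, variants)
        assert res.table == [[87, 229], [24, 137]]
        chi2_ref, p_ref = _chi2_oracle(res.table)
        assert res.chi2 == pytest.approx(chi2_ref)
        assert res.p_value == pytest.approx(p_ref)
        assert 0.0005 < res.p_value < 0.01  # the reported 0.002-level signal

    def test_equal_proportions_give_p_one(self):
        labels, variants = _labels_and_variants(10, 30, 10, 30)
        res = ch_gene_enrichment(labels, variants)
        assert res.p_value == pytest.approx(1.0)

    def test_empty_vuso_class_rejected(self):
        labels, variants = _labels_and_variants(10, 30, 0, 0)
        with pytest.raises(ValueError):
            ch_gene_enrichment(labels, variants)
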