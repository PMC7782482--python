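"""Synthetic cohort generator: determinism, planted structure, follow-up."""

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

from ctdna.filters import CH_GENES_15, apply_filter_cascade
from ctdna.io import apply_sample_qc, variants_to_frame
from ctdna.models import Compartment, normalize_variant_key
from ctdna.simulate import (
    GeneratorConfig,
    ch_probability,
    detection_probabilities,
    generate_cohort,
    generate_followup,
)


class TestConfig:
    def test_unknown_key_rejected_by_name(self):
        with pytest.raises(ValidationError, match="typo_field"):
            GeneratorConfig(typo_field=1)

    def test_invalid_mix_rejected(self):
        with pytest.raises(ValidationError, match="sum to 1"):
            GeneratorConfig(stage_mix={"I": 0.5, "IV": 0.6})

    def test_detection_table_hits_overall_target(self):
        cfg = GeneratorConfig()
        probs = detection_probabilities(cfg)
        expected = sum(
            cfg.cancer_type_mix[t] * cfg.stage_mix[s] * probs[(t, s)]
            for t in cfg.cancer_type_mix
            for s in cfg.stage_mix
        )
        assert expected == pytest.approx(cfg.overall_detection, abs=1e-6)

    def test_stage_ordering_of_detection(self):
        probs = detection_probabilities(GeneratorConfig())
        assert probs[("NSCLC", "I")] < probs[("NSCLC", "III")] < probs[("NSCLC", "IV")]

    def test_ch_curve_passes_through_anchors(self):
        cfg = GeneratorConfig()
        (a1, p1), (a2, p2) = cfg.ch_anchor_young, cfg.ch_anchor_old
        assert ch_probability(a1, cfg) == pytest.approx(p1, rel=1e-9)
        assert ch_probability(a2, cfg) == pytest.approx(p2, rel=1e-9)
        assert ch_probability(60, cfg) > p1  # monotone increasing


class TestGenerateCohort:
    def test_fixed_seed_reproduces_identical_tables(self):
        cfg = GeneratorConfig(n_patients=40, seed=123)
        c1, t1 = generate_cohort(cfg)
        c2, t2 = generate_cohort(cfg)
        pd.testing.assert_frame_equal(
            variants_to_frame(c1.variants), variants_to_frame(c2.variants)
        )
        pd.testing.assert_frame_equal(t1.variants, t2.variants)
        pd.testing.assert_frame_equal(t1.samples, t2.samples)

    def test_different_seeds_differ(self):
        c1, _ = generate_cohort(GeneratorConfig(n_patients=40, seed=1))
        c2, _ = generate_cohort(GeneratorConfig(n_patients=40, seed=2))
        assert not variants_to_frame(c1.variants).equals(
            variants_to_frame(c2.variants)
        )

    def test_ch_af_mass_mostly_below_ten_percent(self):
        cohort, truth = generate_cohort(GeneratorConfig(n_patients=400, seed=5))
        ch_keys = {
            (r.sample_id, normalize_variant_key(r.chrom, r.pos, r.ref, r.alt))
            for r in truth.variants[truth.variants.true_source == "ch"].itertuples()
        }
        afs = [
            v.af
            for v in cohort.variants
            if (v.sample_id, v.key) in ch_keys
        ]
        assert len(afs) > 50
        assert np.mean(np.asarray(afs) < 0.10) >= 0.90

    def test_ch_genes_dominate_planted_ch(self):
        cohort, truth = generate_cohort(GeneratorConfig(n_patients=300, seed=8))
        ch_keys = {
            (r.sample_id, normalize_variant_key(r.chrom, r.pos, r.ref, r.alt))
            for r in truth.variants[truth.variants.true_source == "ch"].itertuples()
        }
        genes = {v.gene for v in cohort.variants if (v.sample_id, v.key) in ch_keys}
        assert genes <= CH_GENES_15

    def test_germline_plants_removed_by_cascade(self):
        cohort, truth = generate_cohort(GeneratorConfig(n_patients=150, seed=9))
        cohort, _ = apply_sample_qc(cohort)
        filtered, _ = apply_filter_cascade(cohort)
        germ = truth.variants[truth.variants.true_source == "germline"]
        germ_keys = {
            (r.sample_id, normalize_variant_key(r.chrom, r.pos, r.ref, r.alt))
            for r in germ.itertuples()
        }
        surviving = [
            v for v in filtered.variants
            if v.sample_id.endswith("-PL") and (v.sample_id, v.key) in germ_keys
        ]
        assert surviving == []

    def test_detection_truth_matches_planted_variants(self):
        cohort, truth = generate_cohort(GeneratorConfig(n_patients=150, seed=10))
        tumor_samples = set(
            truth.variants.loc[truth.variants.true_source == "tumor", "sample_id"]
        )
        detected = set(
            truth.samples.loc[truth.samples.true_detected, "sample_id"]
        )
        assert tumor_samples == detected

    def test_depth_medians_near_configured_values(self):
        cohort, _ = generate_cohort(GeneratorConfig(n_patients=300, seed=11))
        by_comp = {}
        for s in cohort.samples.values():
            by_comp.setdefault(s.compartment, []).append(s.mean_depth)
        assert np.median(by_comp[Compartment.PLASMA]) == pytest.approx(4429, rel=0.15)
        assert np.median(by_comp[Compartment.WBC]) == pytest.approx(423, rel=0.15)
        assert np.median(by_comp[Compartment.TISSUE]) == pytest.approx(1808, rel=0.15)

    def test_tissue_fraction_zero_yields_no_tissue_samples(self):
        cohort, _ = generate_cohort(
            GeneratorConfig(n_patients=30, seed=1, tissue_fraction=0.0)
        )
        assert not [s for s in cohort.samples.values()
                    if s.compartment == Compartment.TISSUE]


class TestGenerateFollowup:
    def test_deterministic_for_fixed_seed(self):
        r1 = generate_followup((20, 20), 2.65, seed=4)
        r2 = generate_followup((20, 20), 2.65, seed=4)
        assert [(r.patient_id, r.pfs_days, r.event) for r in r1] == \
               [(r.patient_id, r.pfs_days, r.event) for r in r2]

    def test_days_bounded_and_top_clips_censored(self):
        recs = generate_followup((500, 500), 2.65, seed=4)
        assert all(4 <= r.pfs_days <= 1198 for r in recs)
        top = [r for r in recs if r.pfs_days == 1198]
        assert top and all(not r.event for r in top)

    def test_arm_sizes_and_mutation_labels(self):
        recs = generate_followup((30, 50), 2.0, seed=1)
        low = [r for r in recs if r.n_mutations <= 2]
        high = [r for r in recs if r.n_mutations > 2]
        assert len(low) == 30 and len(high) == 50

    def test_null_hr_gives_uniformish_p(self):
        from ctdna.survival import logrank_compare

        ps = []
        for rep in range(40):
            recs = generate_followup((40, 40), 1.0, seed=600 + rep)
            ps.append(logrank_compare(recs, "mutations_gt_2").logrank_p)
        # under the null, small p-values occur at their nominal rate
        assert 0 <= np.mean(np.asarray(ps) < 0.05) <= 0.15
        assert np.median(ps) > 0.2

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError):
            generate_followup((0, 10), 2.0, seed=1)

    def test_nonpositive_hr_rejected(self):
        with pytest.raises(ValueError):
            generate_followup((10, 10), 0.0, seed=1)
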