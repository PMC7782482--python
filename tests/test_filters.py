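"""Filter cascade rules, ordering, and the fusion support rule."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from ctdna.filters import (
    CH_GENES_15,
    Breakpoint,
    FilterRule,
    FusionFragment,
    apply_filter_cascade,
    cluster_fusions,
    germline_filter,
    population_filter,
    quality_filter,
)
from ctdna.models import Compartment

from conftest import make_variant


class TestGermlineFilter:
    def test_high_af_in_both_compartments_removed(self):
        pl = make_variant(gene="EGFR", af=0.40)
        wb = make_variant(sample_id="S1-WBC", gene="EGFR", af=0.35, depth=423,
                          hq_reads=100)
        d = germline_filter(pl, wb)
        assert d.verdict == "removed" and d.rule == FilterRule.GERMLINE

    def test_truncating_ch_gene_variant_rescued(self):
        pl = make_variant(gene="DNMT3A", chrom="2", pos=25457242, ref="CAG",
                          alt="C", variant_class="indel",
                          consequence="frameshift", af=0.38)
        wb = make_variant(sample_id="S1-WBC", gene="DNMT3A", chrom="2",
                          pos=25457242, ref="CAG", alt="C",
                          variant_class="indel", consequence="frameshift",
                          af=0.42, depth=423, hq_reads=100)
        d = germline_filter(pl, wb)
        assert d.verdict == "retained"

    def test_missense_ch_gene_variant_not_rescued(self):
        pl = make_variant(gene="TP53", chrom="17", pos=1, af=0.45)
        wb = make_variant(sample_id="S1-WBC", gene="TP53", chrom="17", pos=1,
                          af=0.48, depth=423, hq_reads=100)
        assert germline_filter(pl, wb).rule == FilterRule.GERMLINE

    def test_absent_wbc_counterpart_retained(self):
        assert germline_filter(make_variant(af=0.31), None).verdict == "retained"

    def test_high_af_one_compartment_only_retained(self):
        pl = make_variant(af=0.40)
        wb = make_variant(sample_id="S1-WBC", af=0.05, depth=423, hq_reads=20)
        assert germline_filter(pl, wb).verdict == "retained"

    def test_mismatched_keys_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            germline_filter(make_variant(pos=100), make_variant(pos=101))


class TestQualityFilter:
    @pytest.mark.parametrize(
        "kwargs,compartment,rule",
        [
            (dict(depth=450, hq_reads=40), Compartment.PLASMA, FilterRule.LOW_DEPTH),
            (dict(depth=800, hq_reads=4), Compartment.PLASMA, FilterRule.LOW_HQ_READS),
            (dict(consequence="synonymous", depth=2000, hq_reads=100),
             Compartment.PLASMA, FilterRule.SYNONYMOUS),
            (dict(depth=150, hq_reads=10), Compartment.WBC, FilterRule.LOW_DEPTH),
            (dict(depth=250, hq_reads=1), Compartment.WBC, FilterRule.LOW_HQ_READS),
            (dict(depth=450, hq_reads=40), Compartment.TISSUE, FilterRule.LOW_DEPTH),
        ],
    )
    def test_failing_variants_removed_with_first_rule(self, kwargs, compartment, rule):
        d = quality_filter(make_variant(**kwargs), compartment)
        assert d.verdict == "removed" and d.rule == rule

    def test_wbc_thresholds_are_looser(self):
        # 250x / 2 HQ reads passes for WBC but would fail for plasma
        v = make_variant(depth=250, hq_reads=2)
        assert quality_filter(v, Compartment.WBC).verdict == "retained"
        assert quality_filter(v, Compartment.PLASMA).verdict == "removed"

    def test_synonymous_removed_before_depth_check(self):
        v = make_variant(consequence="synonymous", depth=100, hq_reads=1)
        assert quality_filter(v, Compartment.PLASMA).rule == FilterRule.SYNONYMOUS


class TestPopulationFilter:
    @pytest.mark.parametrize(
        "pmf,verdict",
        [(0.012, "removed"), (0.005, "retained"), (None, "retained"),
         (0.01, "retained")],  # strictly greater than 1%
    )
    def test_threshold(self, pmf, verdict):
        d = population_filter(make_variant(population_max_frequency=pmf))
        assert d.verdict == verdict


def _cascade_fixture(trio_cohort_factory):
    """10-variant fixture: each cascade rule fires exactly once."""
    mk = make_variant
    plasma = [
        # 1. germline: AF >= 0.30 in both compartments
        mk(sample_id="P1-PL", gene="EGFR", chrom="7", pos=100, af=0.40,
           depth=2000, hq_reads=150),
        # 2. synonymous
        mk(sample_id="P1-PL", gene="KRAS", chrom="12", pos=200,
           consequence="synonymous", depth=2000, hq_reads=150),
        # 3. low depth (<500x plasma)
        mk(sample_id="P1-PL", gene="TP53", chrom="17", pos=300, depth=450,
           hq_reads=40),
        # 4. low HQ reads (<5 plasma)
        mk(sample_id="P1-PL", gene="BRAF", chrom="7", pos=400, depth=800,
           hq_reads=4),
        # 5. population DB (>1%)
        mk(sample_id="P1-PL", gene="APC", chrom="5", pos=500,
           population_max_frequency=0.02, depth=2000, hq_reads=150),
        # retained: clean somatic
        mk(sample_id="P1-PL", gene="PIK3CA", chrom="3", pos=600, af=0.08,
           depth=2000, hq_reads=150),
        # retained: germline-exception truncating CH-gene variant
        mk(sample_id="P1-PL", gene="DNMT3A", chrom="2", pos=700, ref="CAG",
           alt="C", variant_class="indel", consequence="frameshift", af=0.38,
           depth=2000, hq_reads=150),
        # retained: high plasma AF but absent from WBC
        mk(sample_id="P1-PL", gene="NF1", chrom="17", pos=800, af=0.35,
           depth=2000, hq_reads=150),
        # retained: exactly at depth threshold (500x passes)
        mk(sample_id="P1-PL", gene="RB1", chrom="13", pos=900, depth=500,
           hq_reads=20),
        # retained: population frequency below threshold
        mk(sample_id="P1-PL", gene="MET", chrom="7", pos=1000,
           population_max_frequency=0.004, depth=2000, hq_reads=150),
    ]
    wbc = [
        mk(sample_id="P1-WBC", gene="EGFR", chrom="7", pos=100, af=0.45,
           depth=423, hq_reads=100),
        mk(sample_id="P1-WBC", gene="DNMT3A", chrom="2", pos=700, ref="CAG",
           alt="C", variant_class="indel", consequence="frameshift", af=0.42,
           depth=423, hq_reads=100),
    ]
    return trio_cohort_factory(plasma=plasma, wbc=wbc)


EXPECTED_VERDICTS = {
    100: FilterRule.GERMLINE,
    200: FilterRule.SYNONYMOUS,
    300: FilterRule.LOW_DEPTH,
    400: FilterRule.LOW_HQ_READS,
    500: FilterRule.POPULATION_DB,
    600: FilterRule.NONE,
    700: FilterRule.NONE,
    800: FilterRule.NONE,
    900: FilterRule.NONE,
    1000: FilterRule.NONE,
}


class TestFilterCascade:
    def test_each_rule_fires_exactly_once_on_engineered_fixture(
        self, trio_cohort_factory
    ):
        cohort = _cascade_fixture(trio_cohort_factory)
        out, decisions = apply_filter_cascade(cohort)
        plasma_decisions = {d.key[1]: d.rule for d in decisions}
        assert plasma_decisions == EXPECTED_VERDICTS
        removed = [d for d in decisions if not d.retained]
        assert len(removed) == 5
        assert len({d.rule for d in removed}) == 5
        retained_plasma = [v for v in out.variants if v.sample_id == "P1-PL"]
        assert len(retained_plasma) == 5

    def test_all_passing_fixture_keeps_everything(self, trio_cohort_factory):
        plasma = [make_variant(sample_id="P1-PL", pos=p, depth=2000,
                               hq_reads=150) for p in (100, 200, 300)]
        cohort = trio_cohort_factory(plasma=plasma)
        _, decisions = apply_filter_cascade(cohort)
        assert all(d.retained for d in decisions)

    def test_cascade_is_deterministic(self, trio_cohort_factory):
        c1 = _cascade_fixture(trio_cohort_factory)
        c2 = _cascade_fixture(trio_cohort_factory)
        _, d1 = apply_filter_cascade(c1)
        _, d2 = apply_filter_cascade(c2)
        assert [(d.key, d.rule) for d in d1] == [(d.key, d.rule) for d in d2]

    def test_plasma_without_matched_wbc_rejected(self, trio_cohort_factory):
        cohort = _cascade_fixture(trio_cohort_factory)
        wbc_free = cohort.replace_variants(
            [v for v in cohort.variants if v.sample_id != "P1-WBC"]
        )
        wbc_free.samples.pop("P1-WBC")
        with pytest.raises(ValueError, match="P1-PL"):
            apply_filter_cascade(wbc_free)

    def test_tightening_population_threshold_is_monotone(self, trio_cohort_factory):
        plasma = [
            make_variant(sample_id="P1-PL", pos=100 * i,
                         population_max_frequency=f, depth=2000, hq_reads=150)
            for i, f in enumerate([0.001, 0.004, 0.008, 0.015, 0.03], start=1)
        ]
        cohort = trio_cohort_factory(plasma=plasma)
        previous = None
        for thr in (0.05, 0.01, 0.005, 0.002, 0.0005):
            out, _ = apply_filter_cascade(cohort, population_threshold=thr)
            kept = {v.key for v in out.variants}
            if previous is not None:
                assert kept <= previous
            previous = kept

    @settings(max_examples=50, deadline=None)
    @given(
        af_pl=st.floats(0.0, 1.0), af_wb=st.floats(0.0, 1.0),
        gene=st.sampled_from(sorted(CH_GENES_15) + ["EGFR", "KRAS"]),
        consequence=st.sampled_from(
            ["missense", "nonsense", "frameshift", "splice_site", "other"]
        ),
    )
    def test_germline_exception_only_rescues_truncating_ch_variants(
        self, af_pl, af_wb, gene, consequence
    ):
        pl = make_variant(gene=gene, consequence=consequence, af=af_pl)
        wb = make_variant(sample_id="S1-WBC", gene=gene,
                          consequence=consequence, af=af_wb, depth=423,
                          hq_reads=100)
        d = germline_filter(pl, wb)
        if d.retained and af_pl >= 0.30 and af_wb >= 0.30:
            assert gene in CH_GENES_15
            assert consequence in ("frameshift", "nonsense", "splice_site")


def _brute_force_clusters(fragments, window_bp):
    """Independent oracle: transitive closure over pairwise compatibility."""
    def near(a, b):
        return (a.chrom == b.chrom and a.orientation == b.orientation
                and abs(a.pos - b.pos) <= window_bp)

    def compat(f, g):
        return near(f.breakpoint_a, g.breakpoint_a) and near(
            f.breakpoint_b, g.breakpoint_b)

    clusters = []
    for f in fragments:
        hits = [c for c in clusters if any(compat(f, g) for g in c)]
        merged = [f] + [g for c in hits for g in c]
        clusters = [c for c in clusters if c not in hits] + [merged]
    return clusters


def _frag(fid, pa, pb, oa="+", ob="-", ca="2", cb="5"):
    return FusionFragment(fid, Breakpoint(ca, pa, oa), Breakpoint(cb, pb, ob))


class TestFusionClustering:
    def test_three_close_fragments_form_one_event(self):
        frags = [_frag("f1", 1000, 2000), _frag("f2", 1002, 2001),
                 _frag("f3", 1003, 1998)]
        events = cluster_fusions(frags, window_bp=5)
        assert len(events) == 1 and events[0].support == 3
        oracle = _brute_force_clusters(frags, 5)
        assert len(oracle) == 1 and len(oracle[0]) == 3

    def test_lone_fragment_yields_no_event(self):
        assert cluster_fusions([_frag("f1", 1000, 2000)]) == []

    def test_opposite_orientation_splits_clusters(self):
        frags = [_frag("f1", 1000, 2000, oa="+"), _frag("f2", 1001, 2000, oa="-")]
        assert cluster_fusions(frags) == []
        assert len(_brute_force_clusters(frags, 5)) == 2

    def test_duplicate_fragment_ids_do_not_fake_support(self):
        frags = [_frag("f1", 1000, 2000), _frag("f1", 1001, 2001)]
        assert cluster_fusions(frags) == []  # one unique fragment id

    @settings(max_examples=30, deadline=None)
    @given(
        positions=st.lists(
            st.tuples(st.integers(1000, 1040), st.integers(2000, 2040)),
            min_size=2, max_size=8,
        )
    )
    def test_clustering_matches_brute_force_oracle(self, positions):
        frags = [_frag(f"f{i}", pa, pb) for i, (pa, pb) in enumerate(positions)]
        events = cluster_fusions(frags, window_bp=5)
        oracle = [c for c in _brute_force_clusters(frags, 5)
                  if len({f.fragment_id for f in c}) >= 2]
        assert sorted(e.support for e in events) == sorted(
            len({f.fragment_id for f in c}) for c in oracle
        )
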