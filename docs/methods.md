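# Methods

This note documents the models, formulas, numerical conventions and design
choices behind the `ctdna` toolkit, and what its synthetic cohorts do and do
not establish about real plasma sequencing data.

## Problem setting

Deep targeted sequencing of plasma cell-free DNA (cfDNA) reports somatic
variant calls that mix four biological sources: tumor-derived DNA (ctDNA),
clonal hematopoiesis (CH) from expanded blood-cell clones, residual germline
heterozygous background, and technical noise. Because CH variants circulate
at low allele fractions — exactly where ctDNA signal lives — they confound
tumor-burden estimates unless each plasma sample is paired with white-blood-
cell (WBC) genomic DNA from the same draw and variants present in both
compartments are subtracted before interpretation.

## Filter cascade

After variant calling, plasma variants pass through a fixed-order cascade;
a removed variant is attributed to the **first** failing rule:

1. **Germline** — allele fraction (AF) ≥ 30% in *both* cfDNA and matched WBC
   gDNA. Exception: frameshift indels and truncating SNVs (stop-gain or
   canonical splice-disrupting substitutions) in one of the 15 canonical CH
   genes (*DNMT3A, TET2, ASXL1, PPM1D, TP53, JAK2, RUNX1, SF3B1, SRSF2,
   IDH1, IDH2, U2AF1, CBL, ATM, CHEK2*) are retained, since truncating CH
   clones can reach germline-like fractions in both compartments.
   "Truncating SNV" is not a standard consequence term; we interpret it as
   stop-gain plus splice-disrupting SNVs, configurable via
   `rescue_consequences`.
2. **Synonymous** — silent variants are dropped.
3. **Depth** — total depth below 500× (cfDNA, tissue) or 200× (WBC).
4. **High-quality support** — fewer than 5 (cfDNA/tissue) or 2 (WBC)
   supporting reads with mapping quality > 30 and base quality > 30.
5. **Population databases** — frequency above 1% in any consulted SNP
   database. The per-variant `population_max_frequency` field is the maximum
   across whatever databases the caller consulted (dbSNP, 1000G, ESP6500,
   ExAC, an in-house background panel, …); the toolkit does not ship or
   reimplement any of these resources. Unknown frequency retains the
   variant.

Cross-compartment identity uses `(chrom, pos, ref, alt)` after reference-
free left-trimming of shared prefix/suffix bases. This equates differently
anchored spellings of the same indel but cannot shift calls through repeat
tracts; matched compartments processed by the same caller are normalized
consistently in practice. Whether the germline 30% rule should use copy-
number-adjusted AF is unspecified upstream; raw AF is used.

Rearrangements: candidate fusion fragments cluster by single linkage when
both breakpoints share chromosome and orientation within a proximity window
(default 5 bp, configurable — the window size is a design choice, not an
upstream constant); only clusters with ≥ 2 unique fragment identifiers
become high-confidence fusion events.

Sample-level QC precedes everything: plasma samples with mean depth < 1000×
or cfDNA contamination > 1% are excluded. Contamination and plasma/WBC
identity-mismatch estimation are out of scope; QC consumes precomputed
values and retains (but flags) samples where they are unknown.

## Source classification

For patients with a complete plasma/WBC/tissue trio, each retained plasma
variant is labeled:

* **wbc_matched** — also present in WBC (treated as CH);
* **biopsy_matched** — present in tumor tissue but not WBC (tumor-derived);
* **vuso** — plasma-only (variant of unknown source).

A variant present in all three compartments is labeled `wbc_matched`: any
blood-lineage evidence conservatively disqualifies it from tumor-burden
metrics. Without tissue, plasma-only variants are `unresolved` rather than
`vuso`.

CH prevalence by age is summarized per half-open age bin with binomial SEM
√(p(1−p)/n); patients of unknown age are excluded and counted. AF contrasts
between groups use the two-sided Mann–Whitney U test: full enumeration of
group assignments with midranks when ties are present and the pooled size is
≤ 14; the exact rank-sum null distribution for untied samples of ≤ 25 per
group; the normal approximation with tie correction otherwise. CH-gene
enrichment between WBC-matched variants and VUSOs is a chi-square test on
the 2×2 of label × membership in the 10 CH genes observed in those classes
(*DNMT3A, TP53, TET2, ASXL1, PPM1D, ATM, JAK2, SF3B1, CHEK2, CBL*), without
continuity correction by default.

## Burden metrics

* **Detection** — a plasma sample is ctDNA-positive iff ≥ 1 retained
  non-CH alteration of any class (SNV, indel, CNV, rearrangement) remains.
* **Sensitivity** — per-group k/n with a Wald 95% interval
  p ± 1.96·√(p(1−p)/n) clamped to [0, 1]; this reproduces the shape of
  reported group intervals (e.g. 91.1% with CI 88.5–93.7 at n ≈ 460).
  Wilson intervals are available and preferable near boundaries.
* **Maximal AF** — maximum across retained non-CH SNV/indels; unknown when
  none remain.
* **bTMB** — blood tumor mutational burden: the count of *competent*
  mutations divided by the panel's covered territory (1.09 Mb). Competent
  means: non-CH SNV/indel, coding nonsynonymous consequence (missense,
  stop-gain, frameshift, in-frame indel, or ±2 splice), AF ≥ 0.5%.
  Whether non-coding panel territory should be excluded from the
  denominator is unspecified; the fixed 1.09 Mb is used as printed.
* **bTMB class** — the cohort cut-off is the 75th percentile of bTMB over
  detected samples (linear interpolation between closest ranks; ≥ 4
  detected samples required); a sample is *high* iff bTMB ≥ cut-off, so
  with distinct values the top quartile is high. Undetected samples are
  classed *unknown*, not *low*.

## Heterogeneity and clonality

**MATH** (mutant-allele tumor heterogeneity) is

    MATH = 148.26 × MAD / median

over a plasma sample's retained non-CH SNV/indel AFs (minimum 2). The
148.26 factor equals 100 × 1.4826, i.e. the normal-consistency constant is
already inside it, so MAD here is the **raw** median absolute deviation —
`median(|AF_i − median(AF)|)` — *not* the scaled MAD that `scipy` and R
return by default. Using a scaled MAD would double-count the constant and
inflate every score by 48%.

**Clonality** normalizes each AF for local copy number and for the sample's
dominant clone:

    transformed AF = AF / log2(CN)    for CN > 2
    transformed AF = AF               for CN ≤ 2 or unknown
    clonality      = transformed AF / max(transformed AF in sample)

The log2 divisor reflects the approximately log-linear AF–copy-number
relationship for amplified loci; for copy-number loss the transformation is
skipped. CN = 2 is a no-op either way (log2 2 = 1), so the loss boundary is
inclusive without consequence. Clonality lies in (0, 1] with the top variant
(or ties) at exactly 1. Binned summaries use [0, 0.1), …, [0.9, 1.0] — the
top bin closed so the maximum lands in a bin — and report the fraction of
mutations in nine common driver genes (*TP53, EGFR, PIK3CA, KRAS, APC, RB1,
NF1, ERBB2, BRAF*) per bin. MATH and clonality are computed after CH
removal.

## Pathway co-alteration

Alterations map onto ten canonical signaling pathways (cell cycle, Hippo,
Myc, Notch, Nrf2, PI3K, RTK-RAS, TGFbeta, p53, Wnt) through a bundled,
editable gene–pathway–role catalog; a gene may belong to several pathways,
and genes absent from a user's panel simply never match. For each unordered
pathway pair the association ratio is the conditional-fraction form

    ratio = P(B altered | A altered) / P(B altered | A wild-type)

i.e. a relative risk; the upstream one-line definition ("percentage of
mutant samples / percentage of wild-type samples") is ambiguous about
conditioning, and this reading is symmetric in direction (ratio > 1 for
(A,B) iff for (B,A)). Significance is a two-sided Fisher exact test on the
2×2, with Benjamini–Hochberg q values over all 45 unordered pairs; pairs
with q < 0.1 are called co-occurring (ratio > 1) or mutually exclusive
(ratio < 1). Degenerate pairs (a pathway altered in all or no samples) get
p = 1 and an undefined ratio.

## Actionability

A local knowledge base maps (gene, alteration pattern, cancer type) to
evidence levels 1–4 with associated drugs. Patterns match in three kinds:
exact protein change (`L858R`), positional class (`e19del`), or alteration
class (`amplification`, `fusion`, `truncating`). Levels follow the OncoKB-
style ladder: Level 1 (FDA-recognized biomarker for an approved drug in the
matching type), Level 2 (standard care), Level 3 (compelling clinical
evidence), Level 4 (biological evidence only — ignored entirely). Levels 2
and 3 get suffix A when the sample's cancer type matches the entry's scope,
B otherwise. A Level-1 entry matched outside its approved type is reported
as 2B (an FDA-approved drug biomarker off-indication is standard-care-grade
evidence elsewhere); this cross-type mapping is a package convention, since
the tier definitions only specify A/B for levels 2–3.

A variant takes its best level over all matching entries; a sample takes its
best variant. The ordering is 1 > 2A > 2B > 3A > 3B > none: the B scope of a
stronger tier outranks the A scope of a weaker one, matching how stacked
per-sample level summaries are conventionally reported; the ordering is a
single table (`LEVEL_ORDER`) if a deployment prefers otherwise. CH-labeled
variants are ineligible. Cohort summaries include only samples with ≥ 1
retained non-CH alteration and exclude configurable histology-unanchored
types (default: histology-unknown lung, unknown primary). Absolute
actionable fractions depend entirely on the supplied knowledge base; the
bundled TSV is a small exemplar set for testing, not a curation.

## Survival

Progression-free survival (days from sampling to first progression) is
compared between burden strata — > 2 vs ≤ 2 ctDNA mutations, or maximal AF
> 1% vs ≤ 1%, or a custom split. Kaplan–Meier medians (first time the
survival estimate drops to ≤ 0.5; flagged undefined when the curve never
crosses) are reported in months at 30.44 days/month. The hazard ratio is
the O/E (Mantel–Haenszel-style) ratio from the log-rank table,

    HR = (O_high / E_high) / (O_low / E_low),
    95% CI = exp(ln HR ± 1.96 · √(1/E_high + 1/E_low)),

the quantity graphing software prints as a "log-rank hazard ratio", with
the high-burden stratum in the numerator. Ties use the pooled
hypergeometric expectation at each distinct event time. This estimator is
mildly attenuated toward 1 for hazard ratios away from unity (≈ 10% at
HR ≈ 2.6 with ~70 events per arm); `cox_hazard_ratio` provides the
partial-likelihood alternative and is used as an independent cross-check in
the test suite.

## Synthetic cohort generator

The generator emits matched plasma/WBC(/tissue) variant tables plus a
ground-truth table that the pipeline never reads. Defaults encode the study
conditions the pipeline is validated against:

* **CH(age)** — carrier probability is logistic in age, anchored so the
  *binned* prevalence is 9.1% under 40 years and 23.1% over 80. Because a
  bin's prevalence is the curve averaged over the ages that fall in it, the
  anchors sit at the expected within-bin ages under the default age
  distribution (Normal(60, 13) truncated to [18, 95]): 34.4 y and 85.4 y.
  Carriers get 1 + Poisson(0.7) CH variants in the 15 CH genes, co-planted
  in plasma and WBC at Beta(2, 40) AF clipped to [0.008, 0.28] — ≥ 90% of
  the mass below 10% AF, the floor high enough to clear both compartments'
  HQ-read thresholds, the ceiling below the 30% germline rule so planted CH
  is never subtracted as germline.
* **Detection** — per-(type, stage) Bernoulli with stage-ordered base rates
  multiplied by mild type effects, iteratively rescaled so the mix-weighted
  mean equals the configured overall 73.5%. Tumor variants (and the
  plasma-only noise analogs of VUSOs, at 3% of somatic variants) are
  planted only in detected samples, so the configured probability is
  exactly the realized detection rate.
* **Tumor burden** — each detected sample draws a per-sample maximal AF
  (log-normal, stage-ordered medians 0.012–0.05, clipped to [0.008, 0.6])
  and a competent mutation count max(1, round(LogNormal(ln 3.6, 1.106))).
  The count distribution is calibrated so the detected-sample upper
  quartile of bTMB sits at ≈ 8.7 mutations/Mb; since the numerator is an
  integer, the quartile is quantized at k/1.09 and lands at 8.26 or 9.17
  depending on the seed (mean ≈ 8.9). Competent-tier clonality concentrates
  near 1 (Beta(5, 1.5) clipped ≥ 0.25, the top variant fixed at 1);
  a subclonal tier of Poisson(0.7 × count) extra mutations draws clonality
  near 0 (Beta(1.2, 12)), producing the near-bimodal clonality histogram.
  AF = clonality × maximal AF, floored at 0.5% for the competent tier.
  The probability that a mutation falls in the nine driver genes
  interpolates linearly from 9.5% in the bottom clonality decile to 47.1%
  in the top one, with per-type driver weights (EGFR-heavy NSCLC, APC/KRAS
  colorectal, PIK3CA breast, TP53/RB1 SCLC).
* **Copy number** — 10% of tumor mutations sit on an amplification
  (CN ~ U(2.5, 8)); their *observed* plasma AF is inflated by log2(CN) so
  the pipeline's transform recovers the planted clonality.
* **Germline** — Poisson(3) heterozygous SNVs per patient at
  Normal(0.5, 0.05) AF truncated to [0.3, 0.7] in every compartment, in
  non-CH filler genes (missense or synonymous), with population-database
  frequencies of 2–40%; the cascade's germline rule removes all of them.
* **Depths** — log-normal per compartment with medians 4429× (plasma),
  423× (WBC), 1808× (tissue), clipped to realistic ranges; HQ supporting
  reads are 86–95% of alt reads, deterministic given AF and depth.
* **Actionable plants** — configurable per-type planting of knowledge-base
  alterations (defaults: EGFR e19del at 18% and L858R at 12% of detected
  NSCLC; PIK3CA H1047R at 15% of detected breast).
* **Follow-up** — exponential PFS per arm with the low-burden median at
  12.8 months and the configured hazard ratio; times above 1198 days are
  administratively censored at the boundary (clipping them to events would
  bias the HR), times under 4 days floored.

All randomness flows from one `numpy` generator seeded by the config, so a
fixed config reproduces byte-identical tables.

**What passing tests do and do not show.** The generator plants variants at
the variant-table level with clean compartment membership: no sequencing
error model, no barcode families, no tissue-vs-plasma caller discordance,
no CH variants below the WBC detection limit, and no contamination
structure. Recall-1.0 source classification on synthetic trios therefore
validates the matching logic, not the real-world completeness of WBC
screening — in real data, CH clones under the WBC depth floor escape
subtraction (that is precisely why the VUSO class exists). Likewise the
calibration tests show the estimators are unbiased at realistic sample
sizes, not that the defaults describe any particular cohort.

## Numerical conventions and degenerate inputs

* AFs are fractions in [0, 1] everywhere; percent only at presentation.
* Percentiles use linear interpolation between closest ranks.
* MATH needs ≥ 2 AFs (else unknown, with reason); zero median is an error.
* Clonality needs ≥ 1 SNV/indel with AF > 0; ties at the maximum all get 1.
* Wald intervals are clamped to [0, 1] and degenerate (width 0) at k = 0 or
  k = n; Wilson is the alternative when that matters.
* Fisher/BH: degenerate pathway pairs contribute p = 1 to the BH family.
* Identical survival strata short-circuit to p = 1 exactly (the log-rank
  statistic is identically zero; the χ² approximation would return NaN).
* Empty strata, empty AF groups, all-censored medians, unknown compartments,
  malformed knowledge-base rows and unknown config keys raise immediately
  with the offending name.

## Known limitations

* No read-level simulation (FASTQ/BAM) and no caller integration; the
  toolkit starts at variant tables.
* The contamination and plasma/WBC identity-mismatch estimators are not
  implemented; QC consumes precomputed values.
* The bundled pathway catalog and actionability knowledge base are compact
  editable snapshots for testing, not curated resources.
* The O/E hazard ratio inherits the attenuation noted above; for inference
  at large effect sizes prefer the Cox alternative.
* bTMB uses the fixed 1.09 Mb denominator; no AF-corrected variant is
  provided.
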