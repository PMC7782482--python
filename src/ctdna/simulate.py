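"""Seeded generator of matched plasma/WBC/tissue variant tables with the
statistical structure the analysis pipeline assumes, plus ground truth for
every planted variant.

What the generator emulates, per patient:

* age-dependent clonal hematopoiesis — a logistic CH(age) curve anchored at
  ~9.1% prevalence below age 40 rising to ~23.1% above 80, with CH variants
  co-planted in plasma and WBC at low AF (a Beta distribution with most
  mass below 10% AF) and genes biased to the 15 canonical CH genes;
* germline heterozygous background — variants near 50% AF in plasma, WBC
  and tissue;
* stage-dependent ctDNA detectability — per (cancer type, stage) detection
  probabilities rescaled so the cohort-wide detection fraction equals the
  configured overall target (73.5% by default);
* near-bimodal mutation clonality — a clonal tier concentrated near 1 and a
  subclonal tier near 0, with AF = clonality x a per-sample maximal-AF draw
  whose stage-ordered medians make stage IV more detectable;
* driver-gene usage tied to clonality — the probability that a mutation
  falls in a common driver gene interpolates from ~47% in the top clonality
  decile down to ~9.5% in the bottom one;
* rare plasma-only noise variants (the VUSO analog) and optional planted
  actionable alterations (e.g. EGFR e19del in a configurable fraction of
  NSCLC samples).

Ground truth (true source per variant, true detection per sample, true
clonality) is emitted alongside the tables and is never consumed by the
pipeline itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .filters import CH_GENES_15
from .heterogeneity import DRIVER_GENES_9
from .models import (
    CohortTable,
    Compartment,
    Consequence,
    PatientRecord,
    SampleRecord,
    VariantCall,
    VariantClass,
)
from .survival import FollowUpRecord

_BASES = ("A", "C", "G", "T")

#: filler (non-driver, non-CH) panel genes for passengers and germline hets
FILLER_GENES = tuple(
    ["CSMD3", "LRP1B", "FAT3", "ZFHX4", "SPTA1", "KMT2D", "ARID1A", "ARID2",
     "SMARCA4", "SETD2", "BCOR", "CIC", "DOT1L", "EPHA3", "EPHB1", "GRIN2A",
     "KDR", "MTUS2", "PCLO", "PREX2", "RELN", "TRRAP", "USH2A", "XIRP2",
     "ZNF521", "PKHD1", "SDK1", "COL11A1", "DNAH9", "MUC16"]
)

_CH_GENE_WEIGHTS = {
    "DNMT3A": 0.28, "TET2": 0.15, "TP53": 0.11, "ASXL1": 0.08, "PPM1D": 0.07,
    "ATM": 0.06, "JAK2": 0.05, "SF3B1": 0.04, "CHEK2": 0.03, "CBL": 0.02,
    "RUNX1": 0.02, "SRSF2": 0.03, "IDH1": 0.02, "IDH2": 0.02, "U2AF1": 0.02,
}
assert abs(sum(_CH_GENE_WEIGHTS.values()) - 1.0) < 1e-9
assert set(_CH_GENE_WEIGHTS) == set(CH_GENES_15)

#: per-type driver-gene draw weights (within the 9 common drivers)
_DRIVER_WEIGHTS_BY_TYPE = {
    "NSCLC": {"EGFR": 0.35, "TP53": 0.30, "KRAS": 0.10, "PIK3CA": 0.07,
              "BRAF": 0.05, "ERBB2": 0.05, "RB1": 0.03, "NF1": 0.03,
              "APC": 0.02},
    "colorectal": {"APC": 0.30, "TP53": 0.28, "KRAS": 0.25, "PIK3CA": 0.09,
                   "BRAF": 0.04, "NF1": 0.02, "RB1": 0.01, "ERBB2": 0.005,
                   "EGFR": 0.005},
    "breast": {"PIK3CA": 0.35, "TP53": 0.35, "ERBB2": 0.10, "APC": 0.05,
               "KRAS": 0.05, "RB1": 0.04, "NF1": 0.03, "EGFR": 0.02,
               "BRAF": 0.01},
    "SCLC": {"TP53": 0.50, "RB1": 0.35, "PIK3CA": 0.05, "KRAS": 0.03,
             "EGFR": 0.02, "APC": 0.02, "NF1": 0.01, "ERBB2": 0.01,
             "BRAF": 0.01},
}
_DRIVER_WEIGHTS_DEFAULT = {"TP53": 0.45, "KRAS": 0.15, "PIK3CA": 0.12,
                           "APC": 0.08, "EGFR": 0.06, "RB1": 0.05, "NF1": 0.04,
                           "ERBB2": 0.03, "BRAF": 0.02}


class ActionablePlant(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cancer_type: str
    gene: str
    pattern: str
    pattern_kind: str  # protein_change | positional_class
    rate: float = Field(ge=0, le=1)


class GeneratorConfig(BaseModel):
    """Configuration of the synthetic trio generator.

    Defaults reproduce the study conditions the analysis was designed for:
    CH prevalence anchors 9.1% (age ~35) and 23.1% (age ~83); overall
    detection 73.5% with stage-ordered detectability; plasma/WBC/tissue
    median depths 4429x / 423x / 1808x; ~3% plasma-only noise variants; and
    a competent-mutation count distribution whose upper quartile, divided by
    the 1.09 Mb panel, sits at ~8.7 mutations/Mb.
    """

    model_config = ConfigDict(extra="forbid")

    n_patients: int = Field(default=200, ge=1)
    seed: int = 0
    tissue_fraction: float = Field(default=1.0, ge=0, le=1)

    cancer_type_mix: Dict[str, float] = Field(
        default={
            "NSCLC": 0.42, "colorectal": 0.09, "breast": 0.09, "UGI": 0.05,
            "HCC": 0.05, "SCLC": 0.03, "prostate": 0.02, "thyroid": 0.02,
            "renal": 0.03, "other": 0.20,
        }
    )
    stage_mix: Dict[str, float] = Field(
        default={"I": 0.04, "II": 0.04, "III": 0.04, "IV": 0.55,
                 "unknown": 0.33}
    )

    age_mean: float = 60.0
    age_sd: float = 13.0
    age_min: float = 18.0
    age_max: float = 95.0

    # logistic CH(age) anchors placed at the expected within-bin ages for the
    # <40 and >80 bins under the default age distribution, so the binned
    # prevalences land on the anchor values
    ch_anchor_young: Tuple[float, float] = (34.4, 0.091)
    ch_anchor_old: Tuple[float, float] = (85.4, 0.231)
    ch_curve: str = "logistic"  # or "linear"
    ch_count_mean_extra: float = 0.7  # CH variants per carrier = 1 + Poisson
    ch_af_beta: Tuple[float, float] = (2.0, 40.0)
    # upper bound kept below the 30% germline threshold: a CH clone at
    # germline-like AF in both compartments is indistinguishable from
    # germline and would be (correctly) removed by the cascade
    ch_af_bounds: Tuple[float, float] = (0.008, 0.28)

    overall_detection: float = Field(default=0.735, gt=0, lt=1)
    stage_detection_base: Dict[str, float] = Field(
        default={"I": 0.40, "II": 0.50, "III": 0.62, "IV": 0.80,
                 "unknown": 0.70}
    )
    type_detection_multiplier: Dict[str, float] = Field(
        default={"SCLC": 1.15, "prostate": 1.1, "thyroid": 0.6, "renal": 0.8}
    )

    # competent (bTMB-eligible) mutation count per detected sample:
    # max(1, round(LogNormal)); defaults place the upper quartile of
    # counts/1.09 Mb near 8.7 mutations/Mb
    mut_count_meanlog: float = math.log(3.6)
    mut_count_sdlog: float = 1.106
    subclonal_rate: float = 0.7  # subclonal tier ~ Poisson(rate * n_competent)
    noise_rate: float = 0.03  # plasma-only noise per somatic variant

    # per-sample maximal AF: LogNormal with stage-ordered medians
    max_af_median_by_stage: Dict[str, float] = Field(
        default={"I": 0.012, "II": 0.016, "III": 0.022, "IV": 0.05,
                 "unknown": 0.04}
    )
    max_af_sdlog: float = 0.8
    max_af_bounds: Tuple[float, float] = (0.008, 0.6)
    tissue_max_af: float = 0.4

    germline_het_mean: float = 3.0  # Poisson count per patient
    germline_af_sd: float = 0.05

    depth_plasma: Tuple[float, float, float, float] = (4429, 0.35, 1500, 30368)
    depth_wbc: Tuple[float, float, float, float] = (423, 0.30, 369, 7279)
    depth_tissue: Tuple[float, float, float, float] = (1808, 0.30, 600, 5525)

    driver_frac_top: float = 0.471  # P(driver gene | clonality >= 0.9)
    driver_frac_bottom: float = 0.095  # P(driver gene | clonality < 0.1)

    amplified_fraction: float = 0.10  # mutations sitting on a copy gain
    btmb_af_floor: float = 0.005

    actionable_plants: List[ActionablePlant] = Field(
        default=[
            ActionablePlant(cancer_type="NSCLC", gene="EGFR", pattern="e19del",
                            pattern_kind="positional_class", rate=0.18),
            ActionablePlant(cancer_type="NSCLC", gene="EGFR", pattern="L858R",
                            pattern_kind="protein_change", rate=0.12),
            ActionablePlant(cancer_type="breast", gene="PIK3CA",
                            pattern="H1047R", pattern_kind="protein_change",
                            rate=0.15),
        ]
    )

    @model_validator(mode="after")
    def _check_mixes(self) -> "GeneratorConfig":
        for name, mix in (("cancer_type_mix", self.cancer_type_mix),
                          ("stage_mix", self.stage_mix)):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"{name} must sum to 1, got {total}")
            if any(v < 0 for v in mix.values()):
                raise ValueError(f"{name} has negative fractions")
        if self.ch_curve not in ("logistic", "linear"):
            raise ValueError(f"unknown ch_curve {self.ch_curve!r}")
        return self


# ---------------------------------------------------------------------------
# CH(age) curve
# ---------------------------------------------------------------------------


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


def ch_probability(age: float, config: GeneratorConfig) -> float:
    """CH carrier probability at a given age under the configured curve."""
    (a1, p1), (a2, p2) = config.ch_anchor_young, config.ch_anchor_old
    if config.ch_curve == "linear":
        slope = (p2 - p1) / (a2 - a1)
        return min(0.99, max(0.001, p1 + slope * (age - a1)))
    slope = (_logit(p2) - _logit(p1)) / (a2 - a1)
    return 1.0 / (1.0 + math.exp(-(_logit(p1) + slope * (age - a1))))


# ---------------------------------------------------------------------------
# detection probability table
# ---------------------------------------------------------------------------


def detection_probabilities(config: GeneratorConfig) -> Dict[Tuple[str, str], float]:
    """Per-(type, stage) detection probabilities, rescaled so the
    mix-weighted mean equals ``overall_detection`` (iterative proportional
    scaling under a 0.98 cap)."""
    raw = {
        (t, s): config.stage_detection_base[s]
        * config.type_detection_multiplier.get(t, 1.0)
        for t in config.cancer_type_mix
        for s in config.stage_mix
    }
    target = config.overall_detection
    probs = dict(raw)
    for _ in range(25):
        expected = sum(
            config.cancer_type_mix[t] * config.stage_mix[s] * min(p, 0.98)
            for (t, s), p in probs.items()
        )
        if abs(expected - target) < 1e-9:
            break
        factor = target / expected
        probs = {k: min(p * factor, 0.98) for k, p in probs.items()}
    return {k: min(p, 0.98) for k, p in probs.items()}


# ---------------------------------------------------------------------------
# generator internals
# ---------------------------------------------------------------------------


class _KeyFactory:
    """Unique genomic keys per patient (collisions would alias variants)."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.used: set = set()

    def snv(self) -> Tuple[str, int, str, str]:
        while True:
            chrom = str(self.rng.integers(1, 23))
            pos = int(self.rng.integers(1_000_000, 50_000_000))
            if (chrom, pos) in self.used:
                continue
            self.used.add((chrom, pos))
            ref, alt = self.rng.choice(_BASES, size=2, replace=False)
            return chrom, pos, str(ref), str(alt)

    def indel(self, frameshift: bool) -> Tuple[str, int, str, str]:
        while True:
            chrom = str(self.rng.integers(1, 23))
            pos = int(self.rng.integers(1_000_000, 50_000_000))
            if (chrom, pos) in self.used:
                continue
            self.used.add((chrom, pos))
            anchor = str(self.rng.choice(_BASES))
            ndel = 2 if frameshift else 3
            tail = "".join(self.rng.choice(_BASES, size=ndel))
            return chrom, pos, anchor + tail, anchor


def _truncated_lognormal(
    rng: np.random.Generator, median: float, sdlog: float,
    lo: float, hi: float,
) -> float:
    return float(np.clip(rng.lognormal(math.log(median), sdlog), lo, hi))


def _depth(rng: np.random.Generator, params: Tuple[float, float, float, float]) -> int:
    median, sdlog, lo, hi = params
    return int(_truncated_lognormal(rng, median, sdlog, lo, hi))


def _reads(rng: np.random.Generator, af: float, depth: int) -> Tuple[int, int]:
    """(depth, hq_reads) for a variant: hq supporting reads are a fixed high
    fraction of alt reads, deterministic given af and depth."""
    alt = int(round(af * depth))
    hq_frac = float(rng.uniform(0.86, 0.95))
    return depth, max(0, min(depth, int(round(alt * hq_frac))))


def _weighted_choice(rng: np.random.Generator, weights: Dict[str, float]) -> str:
    keys = list(weights)
    w = np.asarray([weights[k] for k in keys], dtype=float)
    return str(rng.choice(keys, p=w / w.sum()))


def _driver_prob(clon: float, config: GeneratorConfig) -> float:
    # linear interpolation between the bottom-decile and top-decile anchors
    x = min(1.0, max(0.0, (clon - 0.05) / 0.9))
    return config.driver_frac_bottom + x * (
        config.driver_frac_top - config.driver_frac_bottom
    )


_SNV_CONSEQUENCES = (Consequence.MISSENSE, Consequence.NONSENSE,
                     Consequence.SPLICE_SITE)
_SNV_CONSEQ_P = (0.82, 0.12, 0.06)


@dataclass
class GroundTruth:
    """Planted truth, emitted alongside the cohort; pipeline-blind."""

    variants: pd.DataFrame  # sample_id, chrom, pos, ref, alt, true_source, true_clonality
    samples: pd.DataFrame  # sample_id, true_detected, true_ch_positive


def generate_cohort(config: GeneratorConfig) -> Tuple[CohortTable, GroundTruth]:
    """Generate a matched plasma/WBC(/tissue) cohort with ground truth.

    Deterministic for a fixed config (all randomness flows from the single
    seeded generator).
    """
    rng = np.random.default_rng(config.seed)
    det_probs = detection_probabilities(config)

    patients: List[PatientRecord] = []
    samples: List[SampleRecord] = []
    variants: List[VariantCall] = []
    truth_rows: List[dict] = []
    sample_truth: List[dict] = []

    types = list(config.cancer_type_mix)
    type_p = np.asarray([config.cancer_type_mix[t] for t in types])
    stages = list(config.stage_mix)
    stage_p = np.asarray([config.stage_mix[s] for s in stages])

    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd),
                            config.age_min, config.age_max))
        ctype = str(rng.choice(types, p=type_p))
        stage = str(rng.choice(stages, p=stage_p))
        gender = "female" if rng.random() < 0.5 else "male"
        patients.append(
            PatientRecord(pid, round(age, 1), gender, ctype, stage)
        )

        plasma_id, wbc_id, tissue_id = f"{pid}-PL", f"{pid}-WBC", f"{pid}-TIS"
        plasma_depth = _depth(rng, config.depth_plasma)
        wbc_depth = _depth(rng, config.depth_wbc)
        has_tissue = bool(rng.random() < config.tissue_fraction)
        samples.append(SampleRecord(plasma_id, pid, Compartment.PLASMA,
                                    plasma_depth,
                                    contamination_rate=float(rng.uniform(0, 0.008)),
                                    cfdna_concentration=round(
                                        _truncated_lognormal(rng, 25, 0.6, 1.05, 396), 2)))
        samples.append(SampleRecord(wbc_id, pid, Compartment.WBC, wbc_depth))
        tissue_depth = _depth(rng, config.depth_tissue)
        if has_tissue:
            samples.append(
                SampleRecord(tissue_id, pid, Compartment.TISSUE, tissue_depth)
            )

        keys = _KeyFactory(rng)

        def emit(sample_id, gene, key, vclass, conseq, af, depth,
                 copy_number=None, protein_change=None, positional_class=None,
                 popmax=None):
            d, hq = _reads(rng, af, depth)
            variants.append(
                VariantCall(
                    sample_id=sample_id, gene=gene, chrom=key[0], pos=key[1],
                    ref=key[2], alt=key[3], variant_class=vclass,
                    consequence=conseq, af=af, depth=d, hq_reads=hq,
                    copy_number=copy_number,
                    population_max_frequency=popmax,
                    protein_change=protein_change,
                    positional_class=positional_class,
                )
            )

        def record_truth(key, source, clon=None):
            truth_rows.append(
                {
                    "sample_id": plasma_id, "chrom": key[0], "pos": key[1],
                    "ref": key[2], "alt": key[3], "true_source": source,
                    "true_clonality": clon,
                }
            )

        # ------ germline heterozygous background (plasma + WBC + tissue) ----
        n_germ = int(rng.poisson(config.germline_het_mean))
        for _ in range(n_germ):
            key = keys.snv()
            gene = str(rng.choice(FILLER_GENES))
            conseq = (Consequence.SYNONYMOUS if rng.random() < 0.4
                      else Consequence.MISSENSE)
            af_pl = float(np.clip(rng.normal(0.5, config.germline_af_sd), 0.3, 0.7))
            af_wb = float(np.clip(rng.normal(0.5, config.germline_af_sd), 0.3, 0.7))
            emit(plasma_id, gene, key, VariantClass.SNV, conseq, af_pl,
                 plasma_depth, popmax=round(float(rng.uniform(0.02, 0.4)), 3))
            emit(wbc_id, gene, key, VariantClass.SNV, conseq, af_wb, wbc_depth)
            if has_tissue:
                af_ti = float(np.clip(rng.normal(0.5, config.germline_af_sd),
                                      0.3, 0.7))
                emit(tissue_id, gene, key, VariantClass.SNV, conseq, af_ti,
                     tissue_depth)
            record_truth(key, "germline")

        # ------ clonal hematopoiesis (plasma + WBC, low AF) -----------------
        is_ch = bool(rng.random() < ch_probability(age, config))
        if is_ch:
            n_ch = 1 + int(rng.poisson(config.ch_count_mean_extra))
            for _ in range(n_ch):
                gene = _weighted_choice(rng, _CH_GENE_WEIGHTS)
                a, b = config.ch_af_beta
                lo, hi = config.ch_af_bounds
                af = float(np.clip(rng.beta(a, b), lo, hi))
                r = rng.random()
                if r < 0.12:
                    key = keys.indel(frameshift=True)
                    vclass, conseq = VariantClass.INDEL, Consequence.FRAMESHIFT
                else:
                    key = keys.snv()
                    vclass = VariantClass.SNV
                    conseq = Consequence(
                        str(rng.choice([c.value for c in _SNV_CONSEQUENCES],
                                       p=_SNV_CONSEQ_P))
                    )
                emit(plasma_id, gene, key, vclass, conseq, af, plasma_depth)
                # same clone in WBC at a similar fraction
                af_wbc = float(np.clip(af * rng.uniform(0.8, 1.25), lo, hi))
                emit(wbc_id, gene, key, vclass, conseq, af_wbc, wbc_depth)
                record_truth(key, "ch")

        # ------ tumor-derived variants (plasma + tissue) --------------------
        detected = bool(rng.random() < det_probs[(ctype, stage)])
        if detected:
            max_af = _truncated_lognormal(
                rng, config.max_af_median_by_stage[stage],
                config.max_af_sdlog, *config.max_af_bounds,
            )
            n_comp = max(1, int(round(rng.lognormal(config.mut_count_meanlog,
                                                    config.mut_count_sdlog))))
            n_sub = int(rng.poisson(config.subclonal_rate * n_comp))
            clons = [1.0]
            clons += [float(np.clip(rng.beta(5, 1.5), 0.25, 1.0))
                      for _ in range(n_comp - 1)]
            clons += [float(np.clip(rng.beta(1.2, 12), 0.005, 0.24))
                      for _ in range(n_sub)]
            driver_weights = _DRIVER_WEIGHTS_BY_TYPE.get(
                ctype, _DRIVER_WEIGHTS_DEFAULT
            )
            plants = [
                p for p in config.actionable_plants if p.cancer_type == ctype
                and rng.random() < p.rate
            ]
            for j, clon in enumerate(clons):
                competent_tier = j < n_comp
                af = clon * max_af
                if competent_tier:
                    af = min(max(af, config.btmb_af_floor), max_af)
                    clon = af / max_af  # realized clonality after flooring
                if rng.random() < _driver_prob(clon, config):
                    gene = _weighted_choice(rng, driver_weights)
                else:
                    gene = str(rng.choice(FILLER_GENES))
                protein_change = positional_class = None
                cn = None
                af_obs = af
                if rng.random() < config.amplified_fraction:
                    # amplification inflates the observed AF by log2(CN);
                    # the pipeline's copy-number transform divides it back out
                    cn = round(float(rng.uniform(2.5, 8.0)), 2)
                    af_obs = min(0.95, af * math.log2(cn))
                if competent_tier and plants:
                    plant = plants.pop()
                    gene = plant.gene
                    if plant.pattern_kind == "protein_change":
                        protein_change = plant.pattern
                    else:
                        positional_class = plant.pattern
                if rng.random() < 0.15:
                    frameshift = rng.random() < 0.6
                    key = keys.indel(frameshift=frameshift)
                    vclass = VariantClass.INDEL
                    conseq = (Consequence.FRAMESHIFT if frameshift
                              else Consequence.INFRAME_INDEL)
                else:
                    key = keys.snv()
                    vclass = VariantClass.SNV
                    conseq = Consequence(
                        str(rng.choice([c.value for c in _SNV_CONSEQUENCES],
                                       p=_SNV_CONSEQ_P))
                    )
                emit(plasma_id, gene, key, vclass, conseq, af_obs,
                     plasma_depth, copy_number=cn,
                     protein_change=protein_change,
                     positional_class=positional_class)
                if has_tissue:
                    af_ti = min(0.95, clon * config.tissue_max_af)
                    emit(tissue_id, gene, key, vclass, conseq, af_ti,
                         tissue_depth, copy_number=cn,
                         protein_change=protein_change,
                         positional_class=positional_class)
                record_truth(key, "tumor", clon)

            # ------ plasma-only noise (VUSO analog) -------------------------
            n_noise = int(rng.poisson(config.noise_rate * (n_comp + n_sub)))
            for _ in range(n_noise):
                key = keys.snv()
                gene = str(rng.choice(FILLER_GENES))
                af = float(np.clip(rng.beta(1.5, 60), 0.004, 0.1))
                emit(plasma_id, gene, key, VariantClass.SNV,
                     Consequence.MISSENSE, af, plasma_depth)
                record_truth(key, "noise")

        sample_truth.append(
            {"sample_id": plasma_id, "true_detected": detected,
             "true_ch_positive": is_ch}
        )

    cohort = CohortTable.build(patients, samples, variants)
    cohort.log(
        f"simulate: n_patients={config.n_patients} seed={config.seed} "
        f"overall_detection={config.overall_detection}"
    )
    truth = GroundTruth(
        variants=pd.DataFrame(
            truth_rows,
            columns=["sample_id", "chrom", "pos", "ref", "alt", "true_source",
                     "true_clonality"],
        ),
        samples=pd.DataFrame(
            sample_truth, columns=["sample_id", "true_detected",
                                   "true_ch_positive"]
        ),
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# follow-up generator
# ---------------------------------------------------------------------------


def generate_followup(
    n_per_arm: Tuple[int, int],
    true_hr: float,
    median_low_burden_months: float = 12.8,
    seed: int = 0,
    day_range: Tuple[int, int] = (4, 1198),
) -> List[FollowUpRecord]:
    """Exponential PFS for two burden arms with a configured hazard ratio.

    Arm 0 (<=2 ctDNA mutations) progresses with median
    ``median_low_burden_months``; arm 1 (>2 mutations) has ``true_hr`` times
    the hazard. Times above the follow-up window are administratively
    censored at the upper bound; times below the lower bound are floored.
    """
    if true_hr <= 0:
        raise ValueError("true_hr must be positive")
    n0, n1 = n_per_arm
    if n0 < 1 or n1 < 1:
        raise ValueError("both arms need >=1 subject")
    rng = np.random.default_rng(seed)
    scale0 = median_low_burden_months * 30.44 / math.log(2)
    lo, hi = day_range
    records = []
    for arm, n, scale in ((0, n0, scale0), (1, n1, scale0 / true_hr)):
        times = rng.exponential(scale, size=n)
        for i, t in enumerate(times):
            days = int(round(t))
            event = True
            if days < lo:
                days = lo
            elif days > hi:
                days, event = hi, False  # administrative censoring
            records.append(
                FollowUpRecord(
                    patient_id=f"A{arm}-{i:04d}",
                    pfs_days=days,
                    event=event,
                    n_mutations=int(rng.integers(1, 3)) if arm == 0
                    else int(rng.integers(3, 9)),
                    max_af=float(rng.uniform(0.001, 0.01)) if arm == 0
                    else float(rng.uniform(0.011, 0.3)),
                )
            )
    return records
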