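"""Pathway-level alteration mapping and co-occurrence / mutual-exclusivity
testing across the 10 canonical oncogenic signaling pathways (cell cycle,
Hippo, Myc, Notch, Nrf2, PI3K, RTK-RAS, TGFbeta, p53, Wnt).

For each unordered pathway pair the association is summarized by a
conditional-fraction ratio — the fraction of A-altered samples that are
B-altered divided by the fraction of A-wildtype samples that are B-altered
(a relative risk) — with a two-sided Fisher exact p on the 2x2 table and
Benjamini-Hochberg q values over all pairs. Pairs with q < 0.1 are called
co-occurring (ratio > 1) or mutually exclusive (ratio < 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import CohortTable, Compartment, VariantCall
from .sources import WBC_MATCHED, SourceLabel, labels_to_map

PATHWAY_NAMES = (
    "cell cycle", "Hippo", "Myc", "Notch", "Nrf2", "PI3K", "RTK-RAS",
    "TGFbeta", "p53", "Wnt",
)

CO_OCCURRING = "co_occurring"
MUTUALLY_EXCLUSIVE = "mutually_exclusive"
NO_CALL = "none"


@dataclass
class PathwayCatalog:
    """gene -> set of pathways, with oncogene/TSG role per (pathway, gene)."""

    frame: pd.DataFrame  # columns: pathway, gene, role

    def __post_init__(self) -> None:
        required = {"pathway", "gene", "role"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"pathway catalog needs columns {sorted(required)}")
        if self.frame.empty:
            raise ValueError("pathway catalog is empty")
        bad = set(self.frame["pathway"]) - set(PATHWAY_NAMES)
        if bad:
            raise ValueError(f"unknown pathway label(s): {sorted(bad)}")
        bad_roles = set(self.frame["role"]) - {"oncogene", "tsg"}
        if bad_roles:
            raise ValueError(f"unknown role(s): {sorted(bad_roles)}")

    @property
    def pathways(self) -> List[str]:
        return [p for p in PATHWAY_NAMES if p in set(self.frame["pathway"])]

    def genes_of(self, pathway: str) -> frozenset:
        return frozenset(self.frame.loc[self.frame["pathway"] == pathway, "gene"])

    def pathways_of(self, gene: str) -> frozenset:
        return frozenset(self.frame.loc[self.frame["gene"] == gene, "pathway"])

    @property
    def genes(self) -> frozenset:
        return frozenset(self.frame["gene"])


def load_pathway_catalog(path=None) -> PathwayCatalog:
    """Load a pathway catalog TSV; the bundled catalog when ``path`` is None.

    The bundled file is an editable snapshot of the widely used 10-pathway
    curation; users with a different panel should supply their own.
    """
    if path is None:
        ref = resources.files("ctdna.data") / "pathways.tsv"
        with resources.as_file(ref) as p:
            frame = pd.read_csv(p, sep="\t")
    else:
        frame = pd.read_csv(path, sep="\t")
    return PathwayCatalog(frame)


def pathway_alteration_matrix(
    cohort: CohortTable,
    catalog: PathwayCatalog,
    labels: Optional[Sequence[SourceLabel]] = None,
    detected_only: bool = True,
) -> pd.DataFrame:
    """Sample x pathway boolean matrix of retained non-CH alterations.

    A cell is True iff the plasma sample carries >=1 retained non-CH
    alteration in any catalog gene of that pathway; a gene belonging to
    several pathways marks them all. ``detected_only`` keeps only samples
    with >=1 non-CH alteration, mirroring how alteration frequencies are
    reported per detected sample.
    """
    label_map = labels_to_map(labels) if labels is not None else None
    by_sample = cohort.variants_by_sample()
    pathways = catalog.pathways
    rows = {}
    for s in cohort.samples.values():
        if s.compartment != Compartment.PLASMA:
            continue
        pool = [
            v
            for v in by_sample[s.sample_id]
            if label_map is None
            or label_map.get((v.sample_id, v.key)) != WBC_MATCHED
        ]
        if detected_only and not pool:
            continue
        hit = dict.fromkeys(pathways, False)
        for v in pool:
            for p in catalog.pathways_of(v.gene):
                hit[p] = True
        rows[s.sample_id] = hit
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=pathways)
    return mat.astype(bool).sort_index()


def pathway_frequencies(matrix: pd.DataFrame) -> pd.Series:
    """Per-pathway alteration frequency (fraction of samples altered)."""
    return matrix.mean(axis=0)


@dataclass
class PathwayPairResult:
    pathway_a: str
    pathway_b: str
    n11: int  # both altered
    n10: int  # A only
    n01: int  # B only
    n00: int  # neither
    ratio: float  # may be inf; nan when degenerate
    p_value: float
    q_value: float
    call: str
    degenerate: bool = False


def _pair_stats(a: pd.Series, b: pd.Series):
    n11 = int((a & b).sum())
    n10 = int((a & ~b).sum())
    n01 = int((~a & b).sum())
    n00 = int((~a & ~b).sum())
    if (n11 + n10) == 0 or (n01 + n00) == 0:
        return n11, n10, n01, n00, float("nan"), 1.0, True
    frac_b_given_a = n11 / (n11 + n10)
    frac_b_given_not_a = n01 / (n01 + n00)
    if frac_b_given_not_a == 0:
        ratio = float("inf") if frac_b_given_a > 0 else float("nan")
    else:
        ratio = frac_b_given_a / frac_b_given_not_a
    _, p = stats.fisher_exact([[n11, n10], [n01, n00]], alternative="two-sided")
    return n11, n10, n01, n00, ratio, float(p), False


def pairwise_pathway_tests(
    matrix: pd.DataFrame, q_threshold: float = 0.1
) -> List[PathwayPairResult]:
    """Fisher-exact co-occurrence / exclusivity over unordered pathway pairs.

    q values come from Benjamini-Hochberg step-up across all pairs tested
    (45 for the full 10-pathway catalog). A pair is called only when
    q < ``q_threshold``; the direction follows the conditional-fraction
    ratio. Degenerate pairs (a pathway altered in all or no samples) get
    p = 1 and an undefined ratio.
    """
    pathways = list(matrix.columns)
    altered = [p for p in pathways if matrix[p].any()]
    if len(altered) < 2:
        raise ValueError("need >=2 pathways with >=1 altered sample")
    pairs = [
        (pathways[i], pathways[j])
        for i in range(len(pathways))
        for j in range(i + 1, len(pathways))
    ]
    results = []
    pvals = []
    for a, b in pairs:
        n11, n10, n01, n00, ratio, p, degenerate = _pair_stats(matrix[a], matrix[b])
        results.append(
            PathwayPairResult(
                pathway_a=a, pathway_b=b,
                n11=n11, n10=n10, n01=n01, n00=n00,
                ratio=ratio, p_value=p, q_value=1.0, call=NO_CALL,
                degenerate=degenerate,
            )
        )
        pvals.append(p)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    for r, q in zip(results, qvals):
        r.q_value = float(q)
        if not r.degenerate and r.q_value < q_threshold and not math.isnan(r.ratio):
            if r.ratio > 1:
                r.call = CO_OCCURRING
            elif r.ratio < 1:
                r.call = MUTUALLY_EXCLUSIVE
    return results


def pair_results_to_frame(results: Iterable[PathwayPairResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway_a": r.pathway_a,
                "pathway_b": r.pathway_b,
                "n_both": r.n11,
                "n_a_only": r.n10,
                "n_b_only": r.n01,
                "n_neither": r.n00,
                "ratio": r.ratio,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "call": r.call,
                "degenerate": r.degenerate,
            }
            for r in results
        ],
        columns=["pathway_a", "pathway_b", "n_both", "n_a_only", "n_b_only",
                 "n_neither", "ratio", "p_value", "q_value", "call", "degenerate"],
    )
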