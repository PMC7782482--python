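"""Kaplan-Meier estimation and log-rank comparison of progression-free
survival (PFS) between circulating-tumor-burden strata.

The hazard ratio is the O/E (Mantel-Haenszel-style) ratio from the log-rank
table, HR = (O1/E1)/(O2/E2), with CI exp(ln HR +/- 1.96 sqrt(1/E1 + 1/E2)) —
the quantity graphing packages print as a "log-rank hazard ratio". A Cox
partial-likelihood fit is available as an alternative. Medians are reported
in months using 30.44 days/month.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

DAYS_PER_MONTH = 30.44


@dataclass
class FollowUpRecord:
    patient_id: str
    pfs_days: int
    event: bool  # True = progression observed; False = censored
    n_mutations: Optional[int] = None
    max_af: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pfs_days < 1:
            raise ValueError(
                f"patient {self.patient_id}: pfs_days must be >= 1, "
                f"got {self.pfs_days}"
            )


@dataclass
class StratifiedComparison:
    strata: Tuple[str, str]
    n: Tuple[int, int]
    events: Tuple[int, int]
    median_pfs_months: Tuple[Optional[float], Optional[float]]
    hazard_ratio: float
    ci_low: float
    ci_high: float
    logrank_p: float


def km_median(records: Sequence[FollowUpRecord]) -> Optional[float]:
    """Kaplan-Meier median PFS in months; None when the curve never
    reaches 0.5 (flagged undefined)."""
    if not records:
        raise ValueError("cannot estimate a median from an empty stratum")
    kmf = KaplanMeierFitter()
    kmf.fit(
        [r.pfs_days for r in records],
        event_observed=[r.event for r in records],
    )
    med = kmf.median_survival_time_
    if med is None or math.isinf(med):
        return None
    return float(med) / DAYS_PER_MONTH


def logrank_observed_expected(
    times: Sequence[float],
    events: Sequence[bool],
    groups: Sequence[int],
) -> Tuple[float, float, float, float]:
    """Observed and expected event counts (O1, E1, O2, E2) from the
    log-rank table, using the standard hypergeometric expectation at each
    distinct event time (ties pooled)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups, dtype=int)
    o1 = float(np.sum(events & (groups == 0)))
    o2 = float(np.sum(events & (groups == 1)))
    e1 = e2 = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = float(at_risk.sum())
        n1 = float((at_risk & (groups == 0)).sum())
        d = float((events & (times == t)).sum())
        e1 += d * n1 / n
        e2 += d * (n - n1) / n
    return o1, e1, o2, e2


MUTATIONS_GT_2 = "mutations_gt_2"
MAX_AF_GT_0_01 = "max_af_gt_0.01"
CUSTOM = "custom"


def _stratify(
    records: Sequence[FollowUpRecord],
    threshold_rule: str,
    custom_labels: Optional[Sequence[int]] = None,
) -> Tuple[List[int], Tuple[str, str]]:
    if threshold_rule == MUTATIONS_GT_2:
        if any(r.n_mutations is None for r in records):
            raise ValueError("all records need n_mutations for the >2-mutation rule")
        return (
            [0 if r.n_mutations <= 2 else 1 for r in records],
            ("<=2 mutations", ">2 mutations"),
        )
    if threshold_rule == MAX_AF_GT_0_01:
        if any(r.max_af is None for r in records):
            raise ValueError("all records need max_af for the >0.01-AF rule")
        return (
            [0 if r.max_af <= 0.01 else 1 for r in records],
            ("<=0.01 AF", ">0.01 AF"),
        )
    if threshold_rule == CUSTOM:
        if custom_labels is None or len(custom_labels) != len(records):
            raise ValueError("custom rule requires one 0/1 label per record")
        return list(custom_labels), ("stratum_0", "stratum_1")
    raise ValueError(f"unknown threshold rule {threshold_rule!r}")


def logrank_compare(
    records: Sequence[FollowUpRecord],
    threshold_rule: str = MUTATIONS_GT_2,
    custom_labels: Optional[Sequence[int]] = None,
) -> StratifiedComparison:
    """Log-rank comparison of PFS between two burden strata.

    Both strata must be non-empty with >=1 observed event each; a stratum
    without events leaves O/E undefined and raises with a suggestion to use
    the custom rule on a different split.
    """
    groups, names = _stratify(records, threshold_rule, custom_labels)
    times = [float(r.pfs_days) for r in records]
    events = [bool(r.event) for r in records]
    n0 = groups.count(0)
    n1 = groups.count(1)
    if n0 == 0 or n1 == 0:
        raise ValueError(f"both strata must be non-empty ({names[0]}: {n0}, "
                         f"{names[1]}: {n1})")
    o1, e1, o2, e2 = logrank_observed_expected(times, events, groups)
    if o1 == 0 or o2 == 0:
        raise ValueError(
            "a stratum has zero observed events; the O/E hazard ratio is "
            "undefined — consider a custom stratification"
        )
    # hazard of the high-burden stratum (group 1) relative to the reference
    hr = (o2 / e2) / (o1 / e1)
    se = math.sqrt(1 / e1 + 1 / e2)
    ci_low = hr * math.exp(-1.959963984540054 * se)
    ci_high = hr * math.exp(1.959963984540054 * se)
    t0 = [t for t, g in zip(times, groups) if g == 0]
    t1 = [t for t, g in zip(times, groups) if g == 1]
    ev0 = [e for e, g in zip(events, groups) if g == 0]
    ev1 = [e for e, g in zip(events, groups) if g == 1]
    if t0 == t1 and ev0 == ev1:
        p = 1.0  # identical strata: the log-rank statistic is exactly zero
    else:
        p = float(
            logrank_test(t0, t1, event_observed_A=ev0, event_observed_B=ev1).p_value
        )
    rec0 = [r for r, g in zip(records, groups) if g == 0]
    rec1 = [r for r, g in zip(records, groups) if g == 1]
    return StratifiedComparison(
        strata=names,
        n=(n0, n1),
        events=(int(o1), int(o2)),
        median_pfs_months=(km_median(rec0), km_median(rec1)),
        hazard_ratio=hr,
        ci_low=ci_low,
        ci_high=ci_high,
        logrank_p=p,
    )


def cox_hazard_ratio(
    records: Sequence[FollowUpRecord],
    threshold_rule: str = MUTATIONS_GT_2,
    custom_labels: Optional[Sequence[int]] = None,
) -> Tuple[float, float, float]:
    """Cox proportional-hazards HR for the same stratification (alternative
    to the O/E ratio). Returns (hr, ci_low, ci_high)."""
    groups, _ = _stratify(records, threshold_rule, custom_labels)
    df = pd.DataFrame(
        {
            "t": [r.pfs_days for r in records],
            "e": [int(r.event) for r in records],
            "g": groups,
        }
    )
    cph = CoxPHFitter()
    cph.fit(df, duration_col="t", event_col="e")
    hr = float(np.exp(cph.params_["g"]))
    lo, hi = np.exp(cph.confidence_intervals_.loc["g"]).to_numpy()
    return hr, float(lo), float(hi)


# ---------------------------------------------------------------------------
# TSV round trip
# ---------------------------------------------------------------------------

FOLLOWUP_COLUMNS = ["patient_id", "pfs_days", "event", "n_mutations", "max_af"]


def read_followup(path) -> List[FollowUpRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    missing = [c for c in ("patient_id", "pfs_days", "event") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    out = []
    for r in df.itertuples(index=False):
        nm = getattr(r, "n_mutations", None)
        ma = getattr(r, "max_af", None)
        out.append(
            FollowUpRecord(
                patient_id=str(r.patient_id),
                pfs_days=int(r.pfs_days),
                event=bool(r.event),
                n_mutations=None if nm is None or pd.isna(nm) else int(nm),
                max_af=None if ma is None or pd.isna(ma) else float(ma),
            )
        )
    return out


def followup_to_frame(records: Iterable[FollowUpRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "pfs_days": r.pfs_days,
                "event": r.event,
                "n_mutations": r.n_mutations,
                "max_af": r.max_af,
            }
            for r in records
        ],
        columns=FOLLOWUP_COLUMNS,
    )


def comparison_to_dict(c: StratifiedComparison) -> dict:
    return {
        "strata": list(c.strata),
        "n": list(c.n),
        "events": list(c.events),
        "median_pfs_months": list(c.median_pfs_months),
        "hazard_ratio": c.hazard_ratio,
        "ci_low": c.ci_low,
        "ci_high": c.ci_high,
        "logrank_p": c.logrank_p,
    }
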