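"""Score–outcome evaluation for a treated cohort.

Given per-patient records of the administered agent, its AEL score, best
response (PR/SD/PD) and PFS/OS follow-up, this module computes the statistics
used to judge whether the evidence score tracks clinical benefit: disease
control rates by AEL tier, Kaplan–Meier survival with per-tier medians,
pairwise log-rank tests with the O/E ("log-rank method") hazard ratio, mean
AEL comparisons by t-test, and top-agent concordance.

Kaplan–Meier estimation is delegated to lifelines; the log-rank machinery is
computed explicitly because the hazard ratio reported here is the classic
observed/expected ratio HR = (O1/E1)/(O2/E2) with
CI = exp(ln HR ± 1.96·√(1/E1 + 1/E2)), which requires the per-group expected
event counts.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import stats

from .kb import DDAError, SchemaError
from .scoring import DDAResult, Tier, TierThresholds, classify_tier

RESPONSES = ("PR", "SD", "PD")
DISEASE_CONTROL = frozenset({"PR", "SD"})


@dataclass(frozen=True)
class CohortRecord:
    """One treated patient: administered agent, its AEL, and outcomes."""

    patient_id: str
    administered_mta: str
    ael: float
    response: Optional[str]  # PR / SD / PD, None if unknown
    pfs_months: float
    pfs_event: bool  # True = progression observed, False = censored
    os_months: float
    os_event: bool
    n_drivers: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "administered_mta", self.administered_mta.strip().lower())
        if self.response is not None and self.response not in RESPONSES:
            raise SchemaError(
                f"record {self.patient_id}: response must be one of {RESPONSES}, "
                f"got {self.response!r}"
            )
        if self.pfs_months < 0 or self.os_months < 0:
            raise SchemaError(f"record {self.patient_id}: survival times must be >= 0")

    @property
    def disease_control(self) -> bool:
        if self.response is None:
            raise DDAError(f"record {self.patient_id}: response missing")
        return self.response in DISEASE_CONTROL


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate on the observed time grid."""

    event_times: list[float]  # ascending; includes t=0
    survival_prob: list[float]
    n_at_risk: list[int]
    median: Optional[float]  # smallest t with S(t) <= 0.5; None if never

    def survival_at(self, t: float) -> float:
        s = 1.0
        for ti, si in zip(self.event_times, self.survival_prob):
            if ti <= t:
                s = si
            else:
                break
        return s

    def to_tsv(self) -> str:
        lines = ["time\tsurvival\tat_risk"]
        for t, s, n in zip(self.event_times, self.survival_prob, self.n_at_risk):
            lines.append(f"{t:.6g}\t{s:.6g}\t{n}")
        return "\n".join(lines) + "\n"


@dataclass
class LogRankResult:
    """1-df log-rank test with O/E hazard ratio for two groups."""

    chi_square: float
    p_value: float
    observed: tuple[float, float]
    expected: tuple[float, float]
    hazard_ratio: Optional[float]  # (O1/E1)/(O2/E2); None when undefined
    ci95: Optional[tuple[float, float]]

    def to_dict(self) -> dict:
        return {
            "chi_square": self.chi_square,
            "p_value": self.p_value,
            "observed": list(self.observed),
            "expected": list(self.expected),
            "hazard_ratio": self.hazard_ratio,
            "ci95": list(self.ci95) if self.ci95 else None,
        }


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimate.

    Censored subjects leave the risk set after their censoring time; the
    median is the smallest time at which the estimated survival drops to
    0.5 or below, undefined when the curve never reaches 0.5.
    """
    if len(times) != len(events):
        raise ValueError("times and events must have equal length")
    if len(times) == 0:
        raise ValueError("empty input")
    if any(t < 0 for t in times):
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=bool))
    sf = kmf.survival_function_
    grid = [float(t) for t in sf.index]
    surv = [float(s) for s in sf.iloc[:, 0]]
    at_risk = [int(kmf.event_table.loc[t, "at_risk"]) for t in sf.index]
    # smallest t with S(t) <= 0.5; tolerance absorbs float noise in the
    # product-limit estimate when S hits 0.5 exactly
    median = next((t for t, s in zip(grid, surv) if s <= 0.5 + 1e-9), None)
    return SurvivalCurve(grid, surv, at_risk, median)


def logrank_test(
    group_a: tuple[Sequence[float], Sequence[bool]],
    group_b: tuple[Sequence[float], Sequence[bool]],
) -> LogRankResult:
    """Two-group log-rank test with hypergeometric variance.

    At each distinct event time the observed events in group A are compared
    with the expectation under the null of a common hazard; the chi-square
    statistic is (O1−E1)²/V.  The hazard ratio is the observed/expected
    ratio (O1/E1)/(O2/E2); it is undefined (None, flagged) when either group
    has zero observed or expected events, though the test itself is still
    computed.
    """
    ta, ea = np.asarray(group_a[0], float), np.asarray(group_a[1], bool)
    tb, eb = np.asarray(group_b[0], float), np.asarray(group_b[1], bool)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    ingroup_a = np.concatenate([np.ones(len(ta), bool), np.zeros(len(tb), bool)])

    o1 = e1 = var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & ingroup_a).sum())
        dying = events & (times == t)
        d = int(dying.sum())
        d1 = int((dying & ingroup_a).sum())
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    o_total = float(events.sum())
    o2 = o_total - o1
    e2 = o_total - e1

    if var > 0:
        chi2 = (o1 - e1) ** 2 / var
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        chi2, p = 0.0, 1.0

    hr = ci = None
    if o1 > 0 and o2 > 0 and e1 > 0 and e2 > 0:
        hr = (o1 / e1) / (o2 / e2)
        half = 1.96 * math.sqrt(1.0 / e1 + 1.0 / e2)
        ci = (math.exp(math.log(hr) - half), math.exp(math.log(hr) + half))
    return LogRankResult(chi2, p, (o1, o2), (e1, e2), hr, ci)


def two_sample_t_test(
    x: Sequence[float], y: Sequence[float], equal_var: bool = True
) -> tuple[float, float]:
    """Two-sided two-sample t-test (Student's pooled by default; Welch via
    ``equal_var=False``).  Raises on degenerate input with zero variance in
    both samples."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(x) == 0 and np.var(y) == 0:
        raise ValueError("degenerate input: zero variance in both samples")
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def _t_test_allowing_constant(
    x: Sequence[float], y: Sequence[float], equal_var: bool
) -> tuple[float, float]:
    # all-equal AELs carry no evidence of a difference: t=0, p=1
    try:
        return two_sample_t_test(x, y, equal_var=equal_var)
    except ValueError:
        if (
            len(x) >= 1
            and len(y) >= 1
            and float(np.mean(x)) == float(np.mean(y))
        ):
            return 0.0, 1.0
        raise


# ---------------------------------------------------------------------------
# cohort-level statistics


def assign_tiers(
    records: Sequence[CohortRecord], th: TierThresholds = TierThresholds()
) -> dict[Tier, list[CohortRecord]]:
    """Group patients by the tier of their *administered* agent's AEL."""
    out: dict[Tier, list[CohortRecord]] = {t: [] for t in Tier}
    for r in records:
        out[classify_tier(r.ael, th)].append(r)
    return out


def dcr_by_tier(
    records: Sequence[CohortRecord], th: TierThresholds = TierThresholds()
) -> dict:
    """Disease control rate (PR or SD) overall and within each AEL tier.

    Empty tiers report None (rate undefined), never zero.
    """
    if not records:
        raise ValueError("empty cohort")
    overall = sum(r.disease_control for r in records) / len(records)
    per_tier = {}
    for tier, recs in assign_tiers(records, th).items():
        per_tier[tier.value] = (
            sum(r.disease_control for r in recs) / len(recs) if recs else None
        )
    return {"overall": overall, "per_tier": per_tier}


def mean_ael_by_response(
    records: Sequence[CohortRecord], equal_var: bool = True
) -> dict:
    """Mean administered-agent AEL in disease-control vs progression groups,
    with a two-sample t-test."""
    dc = [r.ael for r in records if r.disease_control]
    pd_ = [r.ael for r in records if not r.disease_control]
    if not dc or not pd_:
        raise ValueError("both response groups must be non-empty")
    t, p = _t_test_allowing_constant(dc, pd_, equal_var=equal_var)
    return {
        "mean_disease_control": float(np.mean(dc)),
        "mean_progressive_disease": float(np.mean(pd_)),
        "n_disease_control": len(dc),
        "n_progressive_disease": len(pd_),
        "t": t,
        "p": p,
    }


def mean_ael_by_pfs_median_split(
    records: Sequence[CohortRecord], equal_var: bool = True
) -> dict:
    """Mean AEL of patients above vs at-or-below the cohort's median PFS.

    The split point is the Kaplan–Meier median of the whole cohort's PFS
    (censoring respected); ties at the median go to the "below" group.
    """
    if len(records) < 4:
        raise ValueError("need at least 4 records")
    curve = km_estimate([r.pfs_months for r in records], [r.pfs_event for r in records])
    if curve.median is None:
        raise ValueError("cohort KM median PFS undefined (curve never reaches 0.5)")
    above = [r.ael for r in records if r.pfs_months > curve.median]
    below = [r.ael for r in records if r.pfs_months <= curve.median]
    t, p = _t_test_allowing_constant(above, below, equal_var=equal_var)
    return {
        "median_pfs": curve.median,
        "mean_above": float(np.mean(above)),
        "mean_below": float(np.mean(below)),
        "n_above": len(above),
        "n_below": len(below),
        "t": t,
        "p": p,
    }


def top_mta_concordance(
    results: Sequence[DDAResult],
    administered: dict[str, str],
    candidate_set: set[str],
    group_equivalents: Sequence[set[str]] = (),
) -> dict:
    """Fraction of patients whose top-AEL agent (within ``candidate_set``)
    matches the administered one.

    Ties in AEL break toward the alphabetically first name.  A match counts
    when the top-ranked and administered agents fall in the same equivalence
    group (e.g. two endocrine agents grouped as interchangeable); agents not
    named in any group are their own singleton.
    """
    candidate_set = {c.strip().lower() for c in candidate_set}
    groups = [{m.strip().lower() for m in g} for g in group_equivalents]

    def same_group(a: str, b: str) -> bool:
        if a == b:
            return True
        return any(a in g and b in g for g in groups)

    by_patient = {res.patient_id: res for res in results}
    matched = 0
    picks: dict[str, str] = {}
    for pid, adm in administered.items():
        adm = adm.strip().lower()
        if adm not in candidate_set:
            raise ValueError(f"administered MTA {adm!r} for {pid} not in candidate set")
        if pid not in by_patient:
            raise DDAError(f"patient {pid} missing from scored results")
        top = by_patient[pid].top_mta(candidate_set)
        if top is None:
            raise DDAError(f"patient {pid}: no candidate MTA scored")
        picks[pid] = top
        if same_group(top, adm):
            matched += 1
    n = len(administered)
    return {"matched": matched, "n": n, "fraction": matched / n if n else float("nan"), "picks": picks}


@dataclass
class CohortReport:
    """All cohort-level statistics, recomputable from the input records."""

    n: int
    tier_counts: dict
    tier_fractions: dict
    dcr: dict
    mean_ael_by_response: dict
    mean_ael_by_pfs_split: dict
    km_medians: dict  # endpoint -> {"all": m, "per_tier": {tier: m}}
    pairwise_logrank: dict  # endpoint -> {"low_vs_high": LogRankResult dict, ...}
    curves: dict = field(default_factory=dict)  # endpoint -> {group: SurvivalCurve}
    concordance: Optional[dict] = None

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "tier_counts": self.tier_counts,
            "tier_fractions": self.tier_fractions,
            "dcr": self.dcr,
            "mean_ael_by_response": self.mean_ael_by_response,
            "mean_ael_by_pfs_split": self.mean_ael_by_pfs_split,
            "km_medians": self.km_medians,
            "pairwise_logrank": self.pairwise_logrank,
            "concordance": (
                {k: v for k, v in self.concordance.items() if k != "picks"}
                if self.concordance
                else None
            ),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2) + "\n"


def _endpoint(records: Sequence[CohortRecord], which: str) -> tuple[list[float], list[bool]]:
    if which == "pfs":
        return [r.pfs_months for r in records], [r.pfs_event for r in records]
    if which == "os":
        return [r.os_months for r in records], [r.os_event for r in records]
    raise ValueError(f"unknown endpoint {which!r}")


def cohort_report(
    records: Sequence[CohortRecord],
    th: TierThresholds = TierThresholds(),
    results: Optional[Sequence[DDAResult]] = None,
    administered: Optional[dict[str, str]] = None,
    candidate_set: Optional[set[str]] = None,
    group_equivalents: Sequence[set[str]] = (),
    endpoints: Sequence[str] = ("pfs", "os"),
) -> CohortReport:
    """Compute the full score–outcome report for a treated cohort.

    Pairwise log-rank comparisons are emitted for every ordered tier pair in
    which both tiers are non-empty (a single-tier cohort yields none).  When
    scored results and the administered map are supplied, top-agent
    concordance is included.
    """
    if not records:
        raise ValueError("empty cohort")
    tiers = assign_tiers(records, th)
    n = len(records)
    tier_counts = {t.value: len(v) for t, v in tiers.items()}
    tier_fractions = {t.value: len(v) / n for t, v in tiers.items()}

    have_response = all(r.response is not None for r in records)
    dcr = dcr_by_tier(records, th) if have_response else {"overall": None, "per_tier": {}}
    try:
        by_resp = mean_ael_by_response(records) if have_response else None
    except ValueError:
        by_resp = None
    try:
        by_split = mean_ael_by_pfs_median_split(records)
    except ValueError:
        by_split = None

    km_medians: dict = {}
    pairwise: dict = {}
    curves: dict = {}
    for ep in endpoints:
        times, events = _endpoint(records, ep)
        overall = km_estimate(times, events)
        km_medians[ep] = {"all": overall.median, "per_tier": {}}
        curves[ep] = {"all": overall}
        for tier, recs in tiers.items():
            if recs:
                c = km_estimate(*_endpoint(recs, ep))
                km_medians[ep]["per_tier"][tier.value] = c.median
                curves[ep][tier.value] = c
            else:
                km_medians[ep]["per_tier"][tier.value] = None
        pairwise[ep] = {}
        tier_list = [t for t in Tier if tiers[t]]
        for i, ta in enumerate(tier_list):
            for tb in tier_list[i + 1 :]:
                res = logrank_test(_endpoint(tiers[ta], ep), _endpoint(tiers[tb], ep))
                pairwise[ep][f"{ta.value}_vs_{tb.value}"] = res.to_dict()

    concordance = None
    if results is not None and administered is not None:
        cand = candidate_set or {r.administered_mta for r in records}
        concordance = top_mta_concordance(results, administered, cand, group_equivalents)

    return CohortReport(
        n=n,
        tier_counts=tier_counts,
        tier_fractions=tier_fractions,
        dcr=dcr,
        mean_ael_by_response=by_resp or {},
        mean_ael_by_pfs_split=by_split or {},
        km_medians=km_medians,
        pairwise_logrank=pairwise,
        curves=curves,
        concordance=concordance,
    )


# ---------------------------------------------------------------------------
# cohort TSV i/o

_COHORT_COLUMNS = [
    "patient_id",
    "administered_mta",
    "ael",
    "response",
    "pfs_months",
    "pfs_event",
    "os_months",
    "os_event",
    "n_drivers",
]


def _parse_bool(s: str) -> bool:
    s = s.strip().lower()
    if s in {"1", "true", "t", "yes"}:
        return True
    if s in {"0", "false", "f", "no"}:
        return False
    raise SchemaError(f"cannot parse boolean {s!r}")


def read_cohort_tsv(path: str | Path) -> list[CohortRecord]:
    path = Path(path)
    if not path.exists():
        raise DDAError(f"cohort file not found: {path}")
    return parse_cohort_tsv(path.read_text())


def parse_cohort_tsv(text: str) -> list[CohortRecord]:
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    missing = [c for c in _COHORT_COLUMNS[:-1] if c not in (reader.fieldnames or [])]
    if missing:
        raise SchemaError(f"cohort TSV missing column(s): {', '.join(missing)}")
    records = []
    for row in reader:
        records.append(
            CohortRecord(
                patient_id=row["patient_id"],
                administered_mta=row["administered_mta"],
                ael=float(row["ael"]),
                response=(row["response"].strip().upper() or None) if row["response"] else None,
                pfs_months=float(row["pfs_months"]),
                pfs_event=_parse_bool(row["pfs_event"]),
                os_months=float(row["os_months"]),
                os_event=_parse_bool(row["os_event"]),
                n_drivers=(
                    int(row["n_drivers"])
                    if row.get("n_drivers") not in (None, "",)
                    else None
                ),
            )
        )
    if not records:
        raise SchemaError("cohort TSV contains no records")
    return records


def write_cohort_tsv(records: Iterable[CohortRecord], path: str | Path) -> None:
    lines = ["\t".join(_COHORT_COLUMNS)]
    for r in records:
        lines.append(
            "\t".join(
                [
                    r.patient_id,
                    r.administered_mta,
                    repr(r.ael),
                    r.response or "",
                    repr(r.pfs_months),
                    str(r.pfs_event).lower(),
                    repr(r.os_months),
                    str(r.os_event).lower(),
                    "" if r.n_drivers is None else str(r.n_drivers),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
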