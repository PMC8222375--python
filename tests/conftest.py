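"""Shared fixtures: toy knowledge-base builders and an independent
brute-force scoring oracle.

The oracle recomputes the whole cascade with direct double loops over the
rule list and its own matching logic — no indexing, no shared helpers with
the engine — so engine/oracle agreement is a genuine two-route check.
"""

from __future__ import annotations

import itertools

import pytest

from dda.kb import (
    AlterationClass,
    AlterationSpec,
    Direction,
    EvidenceClass,
    EvidenceRule,
    KnowledgeBase,
    MolecularProfile,
    MTAEntity,
    Registration,
    RuleKind,
    TargetNode,
    TargetStatus,
    TumorContext,
)
from dda.scoring import MatchLevel, TumorMatch, WeightConfig

BREAST = TumorContext("breast")
LUNG = TumorContext("lung")
PAN = TumorContext("pan_cancer")

_counter = itertools.count(1)


def alt(gene: str, alt_class: str = "snv", variant: str = "") -> AlterationSpec:
    return AlterationSpec(gene, AlterationClass(alt_class), variant)


def target(gene: str, status: str = "wild_type") -> TargetNode:
    return TargetNode(gene, TargetStatus(status))


def rule(
    kind: str,
    subject: AlterationSpec,
    *,
    object_target: TargetNode | None = None,
    object_mta: str | None = None,
    direction: str = "positive",
    evidence_class: str = "clinical",
    source_weight: float = 1.0,
    context: TumorContext = BREAST,
    rule_id: str | None = None,
) -> EvidenceRule:
    return EvidenceRule(
        rule_id=rule_id or f"T{next(_counter):04d}",
        kind=RuleKind(kind),
        subject=subject,
        object_target=object_target,
        object_mta=object_mta,
        direction=Direction(direction),
        evidence_class=EvidenceClass(evidence_class),
        source_weight=source_weight,
        context=context,
    )


def build_kb(
    rules: list[EvidenceRule],
    mtas: list[MTAEntity] | None = None,
    extra_targets: list[TargetNode] | None = None,
) -> KnowledgeBase:
    """Assemble a KB whose entity declarations cover the given rules."""
    mtas = mtas or []
    genes = {r.subject.gene for r in rules}
    targets = {r.object_target for r in rules if r.object_target is not None}
    targets |= {t for m in mtas for t in m.targets}
    targets |= set(extra_targets or [])
    genes |= {t.gene for t in targets}
    return KnowledgeBase(genes=genes, targets=targets, mtas=list(mtas), rules=list(rules))


def mta(name: str, targets: set[TargetNode], registration: str = "registered") -> MTAEntity:
    return MTAEntity(name, Registration(registration), frozenset(targets))


def profile(patient_id: str, tumor: TumorContext, alterations) -> MolecularProfile:
    return MolecularProfile(patient_id, tumor, tuple(alterations))


# ---------------------------------------------------------------------------
# independent brute-force oracle


def _oracle_factor_alteration(obs: AlterationSpec, subj: AlterationSpec, cfg: WeightConfig):
    if obs.gene != subj.gene:
        return None
    if obs.variant and subj.variant and obs.alt_class == subj.alt_class and obs.variant == subj.variant:
        return cfg.alteration_match_factor[MatchLevel.EXACT_VARIANT]
    if obs.variant and subj.variant:
        return cfg.alteration_match_factor[MatchLevel.DIFFERENT_VARIANT_SAME_GENE]
    if obs.alt_class == subj.alt_class and not subj.variant:
        return cfg.alteration_match_factor[MatchLevel.SAME_CLASS]
    return cfg.alteration_match_factor[MatchLevel.GENE_ONLY]


def _oracle_factor_tumor(patient: TumorContext, ctx: TumorContext, cfg: WeightConfig) -> float:
    if ctx.localization == "pan_cancer":
        return cfg.tumor_match_factor[TumorMatch.PAN_CANCER]
    if ctx.localization == patient.localization and ctx.histology in ("", patient.histology):
        return cfg.tumor_match_factor[TumorMatch.EXACT]
    return cfg.tumor_match_factor[TumorMatch.OTHER_TUMOR]


def _oracle_rule_weight(r: EvidenceRule, observed, tumor, cfg: WeightConfig):
    """Best signed weight of a rule over the observed alterations; None if no
    alteration of the subject gene matches."""
    best = None
    for a in observed:
        fa = _oracle_factor_alteration(a, r.subject, cfg)
        if fa is None:
            continue
        w = (
            cfg.base_weight[r.evidence_class]
            * r.source_weight
            * _oracle_factor_tumor(tumor, r.context, cfg)
            * fa
        )
        if best is None or w > best:
            best = w
    if best is None:
        return None
    return best if r.direction == Direction.POSITIVE else -best


def oracle_score(profile: MolecularProfile, kb: KnowledgeBase, cfg: WeightConfig):
    """Brute-force cascade: returns (driver_ael, potential, target_ael, mta_ael)
    as plain dicts keyed by gene / node / MTA name."""
    observed_by_gene: dict[str, list[AlterationSpec]] = {}
    for a in profile.alterations:
        if a.alt_class != AlterationClass.WILD_TYPE:
            observed_by_gene.setdefault(a.gene, []).append(a)

    driver = {}
    for g, observed in observed_by_gene.items():
        total = 0.0
        for r in kb.rules:
            if r.subject.gene != g:
                continue
            w = _oracle_rule_weight(r, observed, profile.tumor, cfg)
            if w is None:
                continue
            total += w if r.kind == RuleKind.DRIVER_FUNCTION else abs(w)
        driver[g] = total
    potential = {g: a for g, a in driver.items() if a > 0}

    target = {}
    for t in kb.targets:
        total = 0.0
        for r in kb.rules:
            if r.kind != RuleKind.DRIVER_TARGET or r.object_target != t:
                continue
            if r.subject.gene not in potential:
                continue
            w = _oracle_rule_weight(r, observed_by_gene[r.subject.gene], profile.tumor, cfg)
            if w is not None:
                total += w
        target[t] = total

    mta_scores = {}
    for m in kb.mtas:
        total = 0.0
        for g, d_ael in potential.items():
            s = 0.0
            for r in kb.rules:
                if r.kind != RuleKind.DRIVER_MTA or r.object_mta != m.name:
                    continue
                if r.subject.gene != g:
                    continue
                w = _oracle_rule_weight(r, observed_by_gene[g], profile.tumor, cfg)
                if w is not None:
                    s += w
            total += s
            if s > 0:
                total += d_ael
            elif s < 0:
                total -= d_ael
        for t in m.targets:
            total += target.get(t, 0.0)
        mta_scores[m.name] = total
    return driver, potential, target, mta_scores


@pytest.fixture
def oracle():
    return oracle_score


# ---------------------------------------------------------------------------
# log-rank permutation oracle

# frozen n=12 survival fixture; its asymptotic log-rank p was verified
# against the complete permutation distribution (all 924 equal-size splits)
PERM_TIMES = [10.9, 8.5, 11.4, 6.4, 1.5, 8.9, 11.4, 0.9, 7.7, 4.0, 5.1, 11.1]
PERM_EVENTS = [True, True, True, False, True, True, True, True, False, True, True, True]


def independent_logrank_chi2(times, events, labels):
    """Plain-loop log-rank chi-square; oracle for permutation tests."""
    times = list(times)
    o1 = e1 = var = 0.0
    for t in sorted({t for t, e in zip(times, events) if e}):
        n = n1 = d = d1 = 0
        for ti, ei, gi in zip(times, events, labels):
            if ti >= t:
                n += 1
                if gi:
                    n1 += 1
            if ei and ti == t:
                d += 1
                if gi:
                    d1 += 1
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (o1 - e1) ** 2 / var if var > 0 else 0.0


def exact_logrank_permutation_p(times, events, group_size, observed_chi2):
    """Exact permutation p over every equal-size label split."""
    count = total = 0
    for comb in itertools.combinations(range(len(times)), group_size):
        lab = [i in comb for i in range(len(times))]
        total += 1
        if independent_logrank_chi2(times, events, lab) >= observed_chi2 - 1e-12:
            count += 1
    return count / total
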