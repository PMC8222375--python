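"""Seeded generators: knowledge bases, patient profiles, outcome cohorts.

The real curated evidence network behind the scoring engine is proprietary,
so every stage of the pipeline is exercised on synthetic stand-ins that
reproduce its *structure*: a tripartite driver–target–MTA graph of signed,
weighted, context-tagged rules at roughly the per-tumor scale of a few
drivers linked to tens of targets and tens-to-hundreds of agents, and a
treated cohort whose survival and response depend (or, under the null, do
not depend) on the administered agent's AEL score.

Outcome model: PFS is exponential with rate λ0·exp(−β·AEL/1000) (β > 0 means
higher-scored agents delay progression), censoring is independent
exponential, best response is Bernoulli through a logistic link on AEL/1000,
and OS is PFS times a log-normal inflation factor.  AEL enters every effect
divided by 1000 so that the default coefficients are O(1) on the tier scale
(tier bounds 0 and 1000).

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .cohort import CohortRecord, cohort_report
from .kb import (
    AlterationClass,
    AlterationSpec,
    Direction,
    EvidenceClass,
    EvidenceRule,
    KnowledgeBase,
    MolecularProfile,
    MTAEntity,
    PAN_CANCER,
    Registration,
    RuleKind,
    TargetNode,
    TargetStatus,
    TumorContext,
    validate_knowledge_base,
)
from .scoring import TierThresholds, WeightConfig, score_profile

# plausible symbol pools; extended with numbered symbols when exhausted
_GENE_POOL = [
    "KRAS", "TP53", "PIK3CA", "PTEN", "EGFR", "BRAF", "STK11", "APC", "FLT3",
    "RICTOR", "INPP4B", "ERBB2", "NRAS", "AKT1", "MTOR", "CDK4", "CDK6",
    "ESR1", "PGR", "AR", "FGFR1", "FGFR2", "MET", "KIT", "ALK", "RET",
    "NOTCH1", "SMAD4", "CDKN2A", "RB1", "MYC", "CCND1", "ATM", "BRCA1",
    "BRCA2", "NF1", "MAP2K1", "JAK2", "IDH1", "CTNNB1",
]
_MTA_SUFFIXES = ["tinib", "ciclib", "rolimus", "mab", "lisib", "rafenib", "parib"]
_DEFAULT_TUMOR_TYPES = ["breast", "lung", "colorectal", PAN_CANCER]

_ALT_CLASS_POOL = [
    AlterationClass.SNV,
    AlterationClass.INDEL,
    AlterationClass.CNV_AMPLIFICATION,
    AlterationClass.CNV_LOSS,
    AlterationClass.EXPRESSION_OVER,
    AlterationClass.EXPRESSION_LOSS,
]
_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class KBGenParams:
    """Shape of a synthetic knowledge base.

    ``rules_per_gene`` counts driver_function rules per gene,
    ``rules_per_target`` driver→target rules per target node, and
    ``rules_per_mta`` driver→MTA rules per agent; the total rule count is
    therefore exact.  ``evidence_class_mix`` are draw probabilities
    (frequency-class draws are only honoured on driver_function rules, where
    such evidence is allowed; elsewhere the mix renormalizes over the
    functional classes).

    The defaults emulate the working scale of a curated clinical evidence
    network: a typical simulated tumor (3–4 altered genes of the 12) is
    touched by several hundred weighted interactions, which puts agent AELs
    on the thousands scale that the default tier bounds (0 / 1000) assume.
    Tests that need tiny enumerable networks pass smaller counts explicitly.
    """

    n_genes: int = 12
    n_targets: int = 20
    n_mtas: int = 40
    rules_per_gene: int = 30
    rules_per_target: int = 30
    rules_per_mta: int = 15
    p_negative: float = 0.25
    evidence_class_mix: dict = field(
        default_factory=lambda: {
            EvidenceClass.CLINICAL: 0.48,
            EvidenceClass.PRECLINICAL: 0.46,
            EvidenceClass.IN_SILICO: 0.03,
            EvidenceClass.FREQUENCY: 0.03,
        }
    )
    tumor_types: tuple = tuple(_DEFAULT_TUMOR_TYPES)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_targets", "n_mtas"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("rules_per_gene", "rules_per_target", "rules_per_mta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.p_negative <= 1.0:
            raise ValueError("p_negative must be in [0, 1]")
        if abs(sum(self.evidence_class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("evidence_class_mix probabilities must sum to 1")

    @property
    def n_rules(self) -> int:
        return (
            self.n_genes * self.rules_per_gene
            + self.n_targets * self.rules_per_target
            + self.n_mtas * self.rules_per_mta
        )

    @classmethod
    def with_total_rules(cls, n_rules: int, seed: int = 0, **kw) -> "KBGenParams":
        """Params whose exact total rule count is ``n_rules``.

        The total is split roughly half driver→MTA, a third driver→target,
        the rest driver_function (mirroring a network dominated by drug
        links); the remainder is absorbed by the per-gene count.
        """
        base = cls(seed=seed, **kw)
        per_mta = max(n_rules // 2 // base.n_mtas, 0)
        per_target = max(n_rules // 3 // base.n_targets, 0)
        rest = n_rules - per_mta * base.n_mtas - per_target * base.n_targets
        per_gene, leftover = divmod(rest, base.n_genes)
        if per_gene < 0:
            raise ValueError(f"n_rules={n_rules} too small for this entity count")
        # fold the leftover into extra target rules via a smaller gene count
        if leftover:
            # distribute the leftover as additional driver_function rules on
            # a KB with gcd-friendly counts: fall back to one gene absorbing
            # them is impossible with uniform per-entity counts, so grow the
            # per-gene count and shrink n_genes to divide evenly
            for g in range(base.n_genes, 0, -1):
                if rest % g == 0:
                    return cls(
                        n_genes=g,
                        n_targets=base.n_targets,
                        n_mtas=base.n_mtas,
                        rules_per_gene=rest // g,
                        rules_per_target=per_target,
                        rules_per_mta=per_mta,
                        p_negative=base.p_negative,
                        evidence_class_mix=base.evidence_class_mix,
                        tumor_types=base.tumor_types,
                        seed=seed,
                    )
        return replace(
            base,
            rules_per_gene=per_gene,
            rules_per_target=per_target,
            rules_per_mta=per_mta,
        )


@dataclass(frozen=True)
class OutcomeGenParams:
    """Outcome model for a simulated treated cohort.

    ``baseline_rate`` λ0 is the progression hazard (events/month) for an
    agent with AEL 0; ``effect`` β is the log-hazard reduction per 1000 AEL
    units; ``censor_rate`` the independent exponential censoring hazard;
    response is Bernoulli(logistic(intercept + slope·AEL/1000)) for disease
    control vs progression.  Defaults put the intermediate tier's median PFS
    near 3 months with roughly half the cohort achieving disease control,
    the scale of a heavily pretreated advanced-cancer population.
    """

    baseline_rate: float = 0.35
    effect: float = 1.0
    censor_rate: float = 0.05
    response_intercept: float = -1.0
    response_slope: float = 1.2
    pr_fraction: float = 0.25  # PR share among disease-control responses
    os_log_mean: float = 1.0
    os_log_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be > 0")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")
        if not 0.0 <= self.pr_fraction <= 1.0:
            raise ValueError("pr_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# knowledge-base generation


def _draw_class(rng: np.random.Generator, mix: dict, allow_frequency: bool) -> EvidenceClass:
    classes = list(mix)
    probs = np.array([mix[c] for c in classes], float)
    if not allow_frequency:
        keep = [i for i, c in enumerate(classes) if c is not EvidenceClass.FREQUENCY]
        classes = [classes[i] for i in keep]
        probs = probs[keep]
        probs = probs / probs.sum()
    return classes[int(rng.choice(len(classes), p=probs))]


def _draw_subject(rng: np.random.Generator, gene: str) -> AlterationSpec:
    alt = _ALT_CLASS_POOL[int(rng.integers(len(_ALT_CLASS_POOL)))]
    variant = ""
    if alt in (AlterationClass.SNV, AlterationClass.INDEL) and rng.random() < 0.6:
        variant = (
            _AA[int(rng.integers(20))]
            + str(int(rng.integers(1, 900)))
            + (_AA[int(rng.integers(20))] if alt is AlterationClass.SNV else "del")
        )
    return AlterationSpec(gene, alt, variant)


def _draw_context(rng: np.random.Generator, tumor_types: Sequence[str]) -> TumorContext:
    return TumorContext(tumor_types[int(rng.integers(len(tumor_types)))])


def generate_kb(params: KBGenParams = KBGenParams()) -> KnowledgeBase:
    """Generate a valid knowledge base with the exact rule counts requested.

    Deterministic: the same params (including seed) produce a byte-identical
    serialization.
    """
    rng = np.random.default_rng(params.seed)
    genes = [
        _GENE_POOL[i] if i < len(_GENE_POOL) else f"GENE{i - len(_GENE_POOL) + 1:03d}"
        for i in range(params.n_genes)
    ]
    target_gene_pool = genes + [f"TGT{i:03d}" for i in range(max(0, params.n_targets - params.n_genes))]
    targets: list[TargetNode] = []
    seen = set()
    i = 0
    while len(targets) < params.n_targets:
        g = target_gene_pool[i % len(target_gene_pool)]
        status = TargetStatus.WILD_TYPE if (g, TargetStatus.WILD_TYPE) not in seen else TargetStatus.MUTANT
        node = TargetNode(g, status)
        if (node.gene, node.status) not in seen:
            seen.add((node.gene, node.status))
            targets.append(node)
        i += 1

    mtas = []
    for j in range(params.n_mtas):
        stem = f"{_GENE_POOL[j % len(_GENE_POOL)].lower()}a"[:4]
        name = f"{stem}{_MTA_SUFFIXES[j % len(_MTA_SUFFIXES)]}-{j:03d}"
        k = int(rng.integers(1, min(3, len(targets)) + 1))
        tset = frozenset(targets[int(x)] for x in rng.choice(len(targets), size=k, replace=False))
        reg = Registration.REGISTERED if rng.random() < 0.4 else Registration.CLINICAL_DEVELOPMENT
        mtas.append(MTAEntity(name, reg, tset))

    def direction() -> Direction:
        return Direction.NEGATIVE if rng.random() < params.p_negative else Direction.POSITIVE

    def source_weight() -> float:
        return round(float(rng.uniform(0.5, 2.0)), 2)

    rules: list[EvidenceRule] = []
    rid = 0

    def next_id() -> str:
        nonlocal rid
        rid += 1
        return f"R{rid:05d}"

    for g in genes:
        for _ in range(params.rules_per_gene):
            rules.append(
                EvidenceRule(
                    rule_id=next_id(),
                    kind=RuleKind.DRIVER_FUNCTION,
                    subject=_draw_subject(rng, g),
                    direction=direction(),
                    evidence_class=_draw_class(rng, params.evidence_class_mix, True),
                    source_weight=source_weight(),
                    context=_draw_context(rng, params.tumor_types),
                    citation=f"PMID:{int(rng.integers(10_000_000, 40_000_000))}",
                )
            )
    for t in targets:
        for _ in range(params.rules_per_target):
            rules.append(
                EvidenceRule(
                    rule_id=next_id(),
                    kind=RuleKind.DRIVER_TARGET,
                    subject=_draw_subject(rng, genes[int(rng.integers(len(genes)))]),
                    object_target=t,
                    direction=direction(),
                    evidence_class=_draw_class(rng, params.evidence_class_mix, False),
                    source_weight=source_weight(),
                    context=_draw_context(rng, params.tumor_types),
                    citation=f"PMID:{int(rng.integers(10_000_000, 40_000_000))}",
                )
            )
    for m in mtas:
        for _ in range(params.rules_per_mta):
            rules.append(
                EvidenceRule(
                    rule_id=next_id(),
                    kind=RuleKind.DRIVER_MTA,
                    subject=_draw_subject(rng, genes[int(rng.integers(len(genes)))]),
                    object_mta=m.name,
                    direction=direction(),
                    evidence_class=_draw_class(rng, params.evidence_class_mix, False),
                    source_weight=source_weight(),
                    context=_draw_context(rng, params.tumor_types),
                    citation=f"PMID:{int(rng.integers(10_000_000, 40_000_000))}",
                )
            )

    kb = KnowledgeBase(
        genes=set(genes) | {t.gene for t in targets},
        targets=set(targets),
        mtas=mtas,
        rules=rules,
    )
    report = validate_knowledge_base(kb)
    report.raise_if_failed()
    return kb


def generate_profiles(
    kb: KnowledgeBase,
    n_patients: int,
    alterations_per_patient_mean: float = 3.5,
    seed: int = 0,
) -> list[MolecularProfile]:
    """Simulate patient profiles whose alterations are drawn from the KB's
    rule subjects, so that every profile has matching evidence.

    The per-patient alteration count is 1 + Poisson(mean − 1), mirroring the
    3–4 driver alterations a typical tumor carries.
    """
    if alterations_per_patient_mean < 1:
        raise ValueError("alterations_per_patient_mean must be >= 1")
    rng = np.random.default_rng(seed)
    subject_pool = sorted({r.subject for r in kb.rules})
    if not subject_pool:
        raise ValueError("knowledge base has no rules to draw alterations from")
    tumor_pool = sorted(
        {r.context.localization for r in kb.rules if not r.context.is_pan_cancer}
    ) or ["breast"]
    profiles = []
    for i in range(n_patients):
        k = 1 + int(rng.poisson(alterations_per_patient_mean - 1))
        k = min(k, len(subject_pool))
        idx = rng.choice(len(subject_pool), size=k, replace=False)
        alterations = tuple(subject_pool[int(j)] for j in sorted(idx))
        tumor = TumorContext(tumor_pool[int(rng.integers(len(tumor_pool)))])
        profiles.append(MolecularProfile(f"SIM{i + 1:04d}", tumor, alterations))
    return profiles


# ---------------------------------------------------------------------------
# outcome simulation


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def simulate_outcomes(
    aels: Sequence[float],
    params: OutcomeGenParams = OutcomeGenParams(),
    mta_names: Optional[Sequence[str]] = None,
    patient_ids: Optional[Sequence[str]] = None,
) -> list[CohortRecord]:
    """Simulate PFS/OS and best response for patients treated with agents of
    the given AEL scores.

    With ``censor_rate=0`` every event flag is True.  Deterministic in
    ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n = len(aels)
    mta_names = list(mta_names) if mta_names is not None else [f"agent-{i + 1:03d}" for i in range(n)]
    patient_ids = (
        list(patient_ids) if patient_ids is not None else [f"SIM{i + 1:04d}" for i in range(n)]
    )
    records = []
    for i, ael in enumerate(aels):
        a = ael / 1000.0
        rate = params.baseline_rate * math.exp(-params.effect * a)
        pfs_latent = float(rng.exponential(1.0 / rate))
        pfs_censor = (
            float(rng.exponential(1.0 / params.censor_rate))
            if params.censor_rate > 0
            else math.inf
        )
        pfs_event = pfs_latent <= pfs_censor
        pfs = min(pfs_latent, pfs_censor)

        os_latent = pfs_latent * float(rng.lognormal(params.os_log_mean, params.os_log_sd))
        os_censor = (
            float(rng.exponential(1.0 / params.censor_rate))
            if params.censor_rate > 0
            else math.inf
        )
        os_event = os_latent <= os_censor
        os_ = min(os_latent, os_censor)

        p_dc = _logistic(params.response_intercept + params.response_slope * a)
        if rng.random() < p_dc:
            response = "PR" if rng.random() < params.pr_fraction else "SD"
        else:
            response = "PD"
        records.append(
            CohortRecord(
                patient_id=patient_ids[i],
                administered_mta=mta_names[i],
                ael=float(ael),
                response=response,
                pfs_months=pfs,
                pfs_event=pfs_event,
                os_months=os_,
                os_event=os_event,
            )
        )
    return records


def recovery_experiment(
    kb_params: KBGenParams = KBGenParams(),
    outcome_params: OutcomeGenParams = OutcomeGenParams(),
    n: int = 120,
    seed: int = 0,
    th: TierThresholds = TierThresholds(),
    cfg: WeightConfig = WeightConfig(),
) -> dict:
    """End-to-end rehearsal: generate a KB and profiles, score them, treat
    each simulated patient with a randomly chosen scored agent, simulate
    outcomes from that agent's AEL, and summarize the cohort.

    Returns the cohort report dict plus the administered-AEL vector, so the
    caller can check that score–outcome associations present in the
    generator (``effect`` > 0) are recovered — and absent under the null.
    """
    rng = np.random.default_rng(seed)
    kb = generate_kb(replace(kb_params, seed=int(rng.integers(2**31 - 1))))
    profiles = generate_profiles(kb, n, seed=int(rng.integers(2**31 - 1)))
    aels = []
    names = []
    results = []
    for p in profiles:
        res = score_profile(p, kb, cfg, th, all_mtas=True)
        results.append(res)
        pick = res.mtas[int(rng.integers(len(res.mtas)))]
        aels.append(pick.ael)
        names.append(pick.mta)
    records = simulate_outcomes(
        aels,
        replace(outcome_params, seed=int(rng.integers(2**31 - 1))),
        mta_names=names,
        patient_ids=[p.patient_id for p in profiles],
    )
    report = cohort_report(
        records,
        th,
        results=results,
        administered={p.patient_id: nm for p, nm in zip(profiles, names)},
        candidate_set={m.name for m in kb.mtas},
    )
    out = report.to_dict()
    out["administered_ael"] = aels
    return out


# ---------------------------------------------------------------------------
# calibration / power experiments (the statistical acceptance surface)


def _spread_aels(rng: np.random.Generator, n: int) -> np.ndarray:
    """AEL draws spanning the tier scale (roughly −1500 … +3000)."""
    return rng.uniform(-1500.0, 3000.0, size=n)


def null_logrank_pvalues(
    n_seeds: int = 200,
    n: int = 60,
    base_seed: int = 0,
    params: OutcomeGenParams = OutcomeGenParams(),
) -> list[float]:
    """Log-rank p-values under the null (effect β = 0).

    For each replicate the cohort is split at the median administered AEL;
    with β = 0 the AEL carries no outcome information, so the p-values
    should be uniform on (0, 1).
    """
    from .cohort import logrank_test

    out = []
    ss = np.random.SeedSequence(base_seed)
    for child in ss.spawn(n_seeds):
        rng = np.random.default_rng(child)
        aels = _spread_aels(rng, n)
        recs = simulate_outcomes(
            aels,
            replace(params, effect=0.0, seed=int(rng.integers(2**31 - 1))),
        )
        cut = float(np.median(aels))
        grp_a = [(r.pfs_months, r.pfs_event) for r in recs if r.ael > cut]
        grp_b = [(r.pfs_months, r.pfs_event) for r in recs if r.ael <= cut]
        res = logrank_test(
            ([t for t, _ in grp_a], [e for _, e in grp_a]),
            ([t for t, _ in grp_b], [e for _, e in grp_b]),
        )
        out.append(res.p_value)
    return out


def tier_median_power(
    n_seeds: int = 100,
    n: int = 200,
    effect: float = 1.0,
    base_seed: int = 0,
    params: OutcomeGenParams = OutcomeGenParams(),
    th: TierThresholds = TierThresholds(),
) -> dict:
    """Fraction of replicates in which the high tier's KM median PFS exceeds
    the low tier's, under a positive AEL effect."""
    from .cohort import km_estimate

    wins = 0
    valid = 0
    ss = np.random.SeedSequence(base_seed)
    for child in ss.spawn(n_seeds):
        rng = np.random.default_rng(child)
        aels = _spread_aels(rng, n)
        recs = simulate_outcomes(
            aels,
            replace(params, effect=effect, seed=int(rng.integers(2**31 - 1))),
        )
        low = [r for r in recs if r.ael < th.low_upper]
        high = [r for r in recs if r.ael > th.high_lower]
        m_low = km_estimate([r.pfs_months for r in low], [r.pfs_event for r in low]).median
        m_high = km_estimate([r.pfs_months for r in high], [r.pfs_event for r in high]).median
        if m_low is None or m_high is None:
            continue
        valid += 1
        if m_high > m_low:
            wins += 1
    return {"wins": wins, "n_valid": valid, "n_seeds": n_seeds, "fraction": wins / n_seeds}
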