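"""The DDA scoring cascade.

Every association rule contributes a signed weight

    w(rule) = sign(direction) * base(evidence_class) * source_weight
              * f_tumor(tumor match) * f_alteration(alteration match)

and the engine aggregates those weights in three passes:

1. *Driver calculation* — the aggregated evidence level (AEL) of each mutated
   gene.  Evidence for/against functional relevance enters signed; drug
   sensitivity AND resistance links both evidence driverhood and enter at
   full magnitude ("count both ways").  Genes with AEL > 0 become *potential
   drivers*; everything downstream is gated on them.
2. *Target calculation* — the AEL of each druggable target node is the signed
   sum of driver→target rules over all potential drivers.
3. *MTA calculation* — for each agent m, with S(d,m) the signed sum of its
   direct driver→MTA rule weights from driver d:

       AEL(m) = Σ_d [ S(d,m) + sign(S(d,m)) · AEL(d) ]
              + Σ_{t ∈ targets(m)} AEL(t)

   so a driver's own AEL is inherited with the sign of its net association
   with the drug (sign(0)=0: exact cancellation inherits nothing), and the
   target AELs of the drug's declared targets are added (negative-AEL targets
   deduct).

Every score carries its full additive decomposition, so the contribution
lists always sum exactly to the reported AEL.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .kb import (
    AlterationClass,
    AlterationSpec,
    EvidenceClass,
    Direction,
    KnowledgeBase,
    MTAEntity,
    MolecularProfile,
    RuleKind,
    SchemaError,
    TargetNode,
    TumorContext,
    EvidenceRule,
)


class MatchLevel(str, enum.Enum):
    EXACT_VARIANT = "exact_variant"
    SAME_CLASS = "same_class"
    GENE_ONLY = "gene_only"
    DIFFERENT_VARIANT_SAME_GENE = "different_variant_same_gene"
    NONE = "none"


class TumorMatch(str, enum.Enum):
    EXACT = "exact"
    PAN_CANCER = "pan_cancer"
    OTHER_TUMOR = "other_tumor"


class Tier(str, enum.Enum):
    LOW = "low"
    INTERMEDIATE = "intermediate"
    HIGH = "high"


@dataclass(frozen=True)
class WeightConfig:
    """All tunable constants of the weighting scheme.

    Base weights encode the evidence hierarchy (clinical > preclinical >
    in-silico); matching factors discount evidence whose tumor type or
    alteration differs from the patient's.  ``source_weight_bounds`` is the
    conventional band for the per-publication journal-quality multiplier
    (values outside it are legal but flagged by KB validation).
    """

    base_weight: dict = field(
        default_factory=lambda: {
            EvidenceClass.CLINICAL: 10.0,
            EvidenceClass.PRECLINICAL: 5.0,
            EvidenceClass.IN_SILICO: 1.0,
            EvidenceClass.FREQUENCY: 2.0,
        }
    )
    tumor_match_factor: dict = field(
        default_factory=lambda: {
            TumorMatch.EXACT: 1.0,
            TumorMatch.PAN_CANCER: 0.75,
            TumorMatch.OTHER_TUMOR: 0.5,
        }
    )
    alteration_match_factor: dict = field(
        default_factory=lambda: {
            MatchLevel.EXACT_VARIANT: 1.0,
            MatchLevel.SAME_CLASS: 0.75,
            MatchLevel.GENE_ONLY: 0.5,
            MatchLevel.DIFFERENT_VARIANT_SAME_GENE: 0.25,
        }
    )
    source_weight_bounds: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        for level, f in {**self.tumor_match_factor, **self.alteration_match_factor}.items():
            if not (0.0 < f <= 1.0):
                raise SchemaError(f"match factor for {level} must be in (0, 1], got {f}")
        if self.tumor_match_factor[TumorMatch.EXACT] != 1.0:
            raise SchemaError("exact tumor match must have factor 1.0")
        if self.alteration_match_factor[MatchLevel.EXACT_VARIANT] != 1.0:
            raise SchemaError("exact variant match must have factor 1.0")
        bw = self.base_weight
        if not (
            bw[EvidenceClass.CLINICAL]
            >= bw[EvidenceClass.PRECLINICAL]
            >= bw[EvidenceClass.IN_SILICO]
            > 0
        ):
            raise SchemaError("base weights must satisfy clinical >= preclinical >= in_silico > 0")

    def scaled(self, c: float) -> "WeightConfig":
        """Config with every base weight multiplied by c (> 0)."""
        if c <= 0:
            raise SchemaError(f"scale factor must be > 0, got {c}")
        return WeightConfig(
            base_weight={k: v * c for k, v in self.base_weight.items()},
            tumor_match_factor=dict(self.tumor_match_factor),
            alteration_match_factor=dict(self.alteration_match_factor),
            source_weight_bounds=self.source_weight_bounds,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "WeightConfig":
        kw: dict = {}
        if "base_weight" in d:
            kw["base_weight"] = {EvidenceClass(k): float(v) for k, v in d["base_weight"].items()}
        if "tumor_match_factor" in d:
            kw["tumor_match_factor"] = {
                TumorMatch(k): float(v) for k, v in d["tumor_match_factor"].items()
            }
        if "alteration_match_factor" in d:
            kw["alteration_match_factor"] = {
                MatchLevel(k): float(v) for k, v in d["alteration_match_factor"].items()
            }
        if "source_weight_bounds" in d:
            kw["source_weight_bounds"] = tuple(d["source_weight_bounds"])
        return cls(**kw)

    def to_dict(self) -> dict:
        return {
            "base_weight": {k.value: v for k, v in self.base_weight.items()},
            "tumor_match_factor": {k.value: v for k, v in self.tumor_match_factor.items()},
            "alteration_match_factor": {
                k.value: v for k, v in self.alteration_match_factor.items()
            },
            "source_weight_bounds": list(self.source_weight_bounds),
        }


@dataclass(frozen=True)
class TierThresholds:
    """AEL tier bounds: low below ``low_upper``, high above ``high_lower``."""

    low_upper: float = 0.0
    high_lower: float = 1000.0

    def __post_init__(self) -> None:
        if not self.low_upper < self.high_lower:
            raise SchemaError("TierThresholds: low_upper must be < high_lower")


def classify_tier(ael: float, th: TierThresholds = TierThresholds()) -> Tier:
    """Tier of an AEL value; boundary values fall in the intermediate tier."""
    if ael < th.low_upper:
        return Tier.LOW
    if ael > th.high_lower:
        return Tier.HIGH
    return Tier.INTERMEDIATE


# ---------------------------------------------------------------------------
# matching


def alteration_match_level(observed: AlterationSpec, rule_subject: AlterationSpec) -> MatchLevel:
    """Similarity of an observed alteration to a rule's subject alteration."""
    if observed.gene != rule_subject.gene:
        return MatchLevel.NONE
    if (
        observed.variant
        and rule_subject.variant
        and observed.alt_class is rule_subject.alt_class
        and observed.variant == rule_subject.variant
    ):
        return MatchLevel.EXACT_VARIANT
    if observed.variant and rule_subject.variant:
        return MatchLevel.DIFFERENT_VARIANT_SAME_GENE
    if observed.alt_class is rule_subject.alt_class and not rule_subject.variant:
        return MatchLevel.SAME_CLASS
    return MatchLevel.GENE_ONLY


def tumor_match_level(patient: TumorContext, rule_context: TumorContext) -> TumorMatch:
    """Relevance of a rule's tumor context to the patient's tumor.

    Pan-cancer evidence applies everywhere at a discount; same localization
    with compatible histology (rule states none, or states the same) is an
    exact match; any other tumor type applies at the largest discount.
    """
    if rule_context.is_pan_cancer:
        return TumorMatch.PAN_CANCER
    if rule_context.localization == patient.localization and (
        not rule_context.histology or rule_context.histology == patient.histology
    ):
        return TumorMatch.EXACT
    return TumorMatch.OTHER_TUMOR


def rule_weight(
    rule: EvidenceRule,
    observed: AlterationSpec,
    tumor: TumorContext,
    cfg: WeightConfig,
) -> float:
    """Signed weight of one rule applied to one observed alteration."""
    level = alteration_match_level(observed, rule.subject)
    if level is MatchLevel.NONE:
        raise ValueError(
            f"rule {rule.rule_id}: subject gene {rule.subject.gene} does not match "
            f"observed {observed.gene}; caller must filter non-matching rules"
        )
    magnitude = (
        cfg.base_weight[rule.evidence_class]
        * rule.source_weight
        * cfg.tumor_match_factor[tumor_match_level(tumor, rule.context)]
        * cfg.alteration_match_factor[level]
    )
    return magnitude if rule.direction is Direction.POSITIVE else -magnitude


def _best_match_weight(
    rule: EvidenceRule,
    alterations: Sequence[AlterationSpec],
    tumor: TumorContext,
    cfg: WeightConfig,
) -> Optional[float]:
    """Signed weight of a rule against a gene's observed alterations.

    When several observed alterations of the same gene match one rule, only
    the best (highest-factor) match counts — one contribution per rule, no
    double counting.  Returns None if nothing matches.
    """
    best: Optional[float] = None
    for a in sorted(alterations):  # deterministic tie-break
        if alteration_match_level(a, rule.subject) is MatchLevel.NONE:
            continue
        w = rule_weight(rule, a, tumor, cfg)
        if best is None or abs(w) > abs(best):
            best = w
    return best


# ---------------------------------------------------------------------------
# score containers


@dataclass
class DriverScore:
    gene: str
    ael: float
    contributions: list[tuple[str, float]]  # (rule_id, signed contribution)

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "ael": self.ael,
            "contributions": [[r, c] for r, c in self.contributions],
        }


@dataclass
class TargetScore:
    node: TargetNode
    ael: float
    contributions: list[tuple[str, str, float]]  # (driver gene, rule_id, contribution)

    def to_dict(self) -> dict:
        return {
            "target": self.node.to_dict(),
            "label": self.node.label(),
            "ael": self.ael,
            "contributions": [[g, r, c] for g, r, c in self.contributions],
        }


@dataclass
class MTAScore:
    mta: str
    ael: float
    direct_component: float
    inherited_driver_component: float
    inherited_target_component: float
    per_driver_S: dict[str, float]
    tier: Tier = Tier.INTERMEDIATE

    def to_dict(self) -> dict:
        return {
            "mta": self.mta,
            "ael": self.ael,
            "tier": self.tier.value,
            "direct_component": self.direct_component,
            "inherited_driver_component": self.inherited_driver_component,
            "inherited_target_component": self.inherited_target_component,
            "per_driver_S": dict(sorted(self.per_driver_S.items())),
        }


@dataclass
class DDAResult:
    """Full scored output for one patient: ranked drivers, targets, MTAs."""

    patient_id: str
    drivers: list[DriverScore]
    targets: list[TargetScore]
    mtas: list[MTAScore]

    def mta_score(self, name: str) -> MTAScore:
        name = name.strip().lower()
        for s in self.mtas:
            if s.mta == name:
                return s
        raise KeyError(f"MTA {name!r} not in result for {self.patient_id}")

    def top_mta(self, candidate_set: Optional[set[str]] = None) -> Optional[str]:
        """Highest-AEL MTA (optionally within a candidate set); ties break
        toward the alphabetically first name."""
        pool = [
            s
            for s in self.mtas
            if candidate_set is None or s.mta in candidate_set
        ]
        if not pool:
            return None
        return min(pool, key=lambda s: (-s.ael, s.mta)).mta

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "drivers": [d.to_dict() for d in self.drivers],
            "targets": [t.to_dict() for t in self.targets],
            "mtas": [m.to_dict() for m in self.mtas],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2) + "\n"

    def to_tsv(self) -> str:
        """Flat entity/kind/ael/tier table mirroring the ranked listing."""
        lines = ["entity\tkind\tael\ttier"]
        for d in self.drivers:
            lines.append(f"{d.gene}\tdriver\t{d.ael:.6g}\t")
        for t in self.targets:
            lines.append(f"{t.node.label()}\ttarget\t{t.ael:.6g}\t")
        for m in self.mtas:
            lines.append(f"{m.mta}\tmta\t{m.ael:.6g}\t{m.tier.value}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# the cascade
#
# All three passes consume a single precomputed map rule_id -> signed weight
# (rules whose subject matches some observed alteration of a given gene set),
# so the full cascade is one weight evaluation plus three linear passes over
# the rule list — linear in |rules| regardless of KB size.


def _matched_weights(
    genes: set[str],
    profile: MolecularProfile,
    kb: KnowledgeBase,
    cfg: WeightConfig,
) -> dict[str, float]:
    """rule_id -> signed best-match weight, for rules whose subject gene is
    in ``genes`` and matches an observed alteration."""
    observed_by_gene = {g: profile.alterations_of(g) for g in genes}
    out: dict[str, float] = {}
    for rule in kb.rules:
        observed = observed_by_gene.get(rule.subject.gene)
        if not observed:
            continue
        w = _best_match_weight(rule, observed, profile.tumor, cfg)
        if w is not None:
            out[rule.rule_id] = w
    return out


def driver_ael(
    gene: str,
    profile: MolecularProfile,
    kb: KnowledgeBase,
    cfg: WeightConfig = WeightConfig(),
) -> DriverScore:
    """Aggregated evidence level of one mutated gene.

    driver_function rules enter signed (negative direction is evidence of
    functional irrelevance and deducts); driver→target and driver→MTA rules
    enter at |weight| — both sensitivity and resistance associations support
    the gene's functional significance ("count both ways").
    """
    gene = gene.upper()
    if not profile.alterations_of(gene):
        raise ValueError(f"gene {gene!r} has no observed alteration in {profile.patient_id}")
    weights = _matched_weights({gene}, profile, kb, cfg)
    return _driver_score_from_weights(gene, weights, kb)


def _driver_score_from_weights(
    gene: str, weights: dict[str, float], kb: KnowledgeBase
) -> DriverScore:
    contributions: list[tuple[str, float]] = []
    for rule in kb.rules:
        if rule.subject.gene != gene or rule.rule_id not in weights:
            continue
        w = weights[rule.rule_id]
        if rule.kind is RuleKind.DRIVER_FUNCTION:
            contributions.append((rule.rule_id, w))
        else:  # resistance links still evidence driverhood
            contributions.append((rule.rule_id, abs(w)))
    return DriverScore(gene, sum(c for _, c in contributions), contributions)


def select_potential_drivers(
    profile: MolecularProfile,
    kb: KnowledgeBase,
    cfg: WeightConfig = WeightConfig(),
) -> list[DriverScore]:
    """Mutated genes with driver AEL strictly above zero, ranked."""
    genes = set(profile.mutant_genes())
    weights = _matched_weights(genes, profile, kb, cfg)
    scores = [_driver_score_from_weights(g, weights, kb) for g in sorted(genes)]
    kept = [s for s in scores if s.ael > 0]
    kept.sort(key=lambda s: (-s.ael, s.gene))
    return kept


def target_ael(
    node: TargetNode,
    drivers: Sequence[DriverScore],
    profile: MolecularProfile,
    kb: KnowledgeBase,
    cfg: WeightConfig = WeightConfig(),
) -> TargetScore:
    """Signed AEL of one druggable target node over the potential drivers."""
    driver_genes = {d.gene for d in drivers}
    weights = _matched_weights(driver_genes, profile, kb, cfg)
    contributions: list[tuple[str, str, float]] = []
    for rule in kb.rules:
        if (
            rule.kind is RuleKind.DRIVER_TARGET
            and rule.object_target == node
            and rule.rule_id in weights
        ):
            contributions.append((rule.subject.gene, rule.rule_id, weights[rule.rule_id]))
    return TargetScore(node, sum(c for _, _, c in contributions), contributions)


def driver_mta_association(
    driver: DriverScore,
    mta: MTAEntity,
    profile: MolecularProfile,
    kb: KnowledgeBase,
    cfg: WeightConfig = WeightConfig(),
) -> float:
    """S(d, m): signed sum of the direct driver→MTA rule weights."""
    weights = _matched_weights({driver.gene}, profile, kb, cfg)
    total = 0.0
    for rule in kb.rules:
        if (
            rule.kind is RuleKind.DRIVER_MTA
            and rule.object_mta == mta.name
            and rule.subject.gene == driver.gene
            and rule.rule_id in weights
        ):
            total += weights[rule.rule_id]
    return total


def _sign(x: float) -> float:
    return 1.0 if x > 0 else (-1.0 if x < 0 else 0.0)


def _assemble_mta_score(
    mta: MTAEntity,
    drivers: Sequence[DriverScore],
    per_driver_S: dict[str, float],
    targets: dict[TargetNode, TargetScore],
    th: TierThresholds,
) -> MTAScore:
    direct = 0.0
    inherited_driver = 0.0
    nonzero_S: dict[str, float] = {}
    for d in drivers:
        s = per_driver_S.get(d.gene, 0.0)
        if s != 0.0:
            nonzero_S[d.gene] = s
        direct += s
        inherited_driver += _sign(s) * d.ael
    inherited_target = 0.0
    for t in sorted(mta.targets):
        ts = targets.get(t)
        if ts is not None:
            inherited_target += ts.ael
    ael = direct + inherited_driver + inherited_target
    return MTAScore(
        mta=mta.name,
        ael=ael,
        direct_component=direct,
        inherited_driver_component=inherited_driver,
        inherited_target_component=inherited_target,
        per_driver_S=nonzero_S,
        tier=classify_tier(ael, th),
    )


def mta_ael(
    mta: MTAEntity,
    drivers: Sequence[DriverScore],
    targets: dict[TargetNode, TargetScore],
    profile: MolecularProfile,
    kb: KnowledgeBase,
    cfg: WeightConfig = WeightConfig(),
    th: TierThresholds = TierThresholds(),
) -> MTAScore:
    """AEL of one agent: direct evidence, sign-gated driver inheritance, and
    the summed AELs of its declared targets.

    ``targets`` maps target nodes to their computed scores and must cover at
    least the agent's declared target set (missing nodes contribute 0).
    """
    per_driver_S = {
        d.gene: driver_mta_association(d, mta, profile, kb, cfg) for d in drivers
    }
    return _assemble_mta_score(mta, drivers, per_driver_S, targets, th)


def score_profile(
    profile: MolecularProfile,
    kb: KnowledgeBase,
    cfg: WeightConfig = WeightConfig(),
    th: TierThresholds = TierThresholds(),
    all_mtas: bool = False,
) -> DDAResult:
    """Run the full cascade for one patient.

    By default only MTAs with at least one nonzero score component are
    reported; ``all_mtas=True`` reports every agent in the knowledge base.
    Output ordering is total: AEL descending, then name ascending; scoring
    the same inputs twice yields bit-identical results.
    """
    genes = set(profile.mutant_genes())
    weights = _matched_weights(genes, profile, kb, cfg)
    drivers = [
        s
        for g in sorted(genes)
        if (s := _driver_score_from_weights(g, weights, kb)).ael > 0
    ]
    drivers.sort(key=lambda s: (-s.ael, s.gene))
    driver_genes = {d.gene for d in drivers}

    # one linear pass accumulates target contributions and S(d, m)
    target_contribs: dict[TargetNode, list[tuple[str, str, float]]] = {}
    S: dict[str, dict[str, float]] = {}  # mta name -> driver gene -> S(d,m)
    for rule in kb.rules:
        if rule.subject.gene not in driver_genes or rule.rule_id not in weights:
            continue
        w = weights[rule.rule_id]
        if rule.kind is RuleKind.DRIVER_TARGET:
            target_contribs.setdefault(rule.object_target, []).append(
                (rule.subject.gene, rule.rule_id, w)
            )
        elif rule.kind is RuleKind.DRIVER_MTA:
            per = S.setdefault(rule.object_mta, {})
            per[rule.subject.gene] = per.get(rule.subject.gene, 0.0) + w

    target_scores = {
        t: TargetScore(t, sum(c for _, _, c in contribs), contribs)
        for t, contribs in target_contribs.items()
    }
    for t in kb.targets - set(target_scores):
        target_scores[t] = TargetScore(t, 0.0, [])

    mta_scores = [
        _assemble_mta_score(m, drivers, S.get(m.name, {}), target_scores, th)
        for m in kb.mtas
    ]
    if not all_mtas:
        mta_scores = [
            s
            for s in mta_scores
            if s.direct_component != 0.0
            or s.inherited_driver_component != 0.0
            or s.inherited_target_component != 0.0
        ]
    reported_target_nodes = {t for m in kb.mtas for t in m.targets}
    targets = [
        ts
        for t, ts in target_scores.items()
        if ts.contributions or t in reported_target_nodes
    ]
    targets.sort(key=lambda s: (-s.ael, s.node))
    mta_scores.sort(key=lambda s: (-s.ael, s.mta))
    return DDAResult(profile.patient_id, drivers, targets, mta_scores)
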