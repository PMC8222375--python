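"""Knowledge-base and molecular-profile domain model.

The digital drug-assignment (DDA) engine operates on a tripartite evidence
network: mutated *driver* genes, *druggable targets* (gene products, possibly
qualified as wild-type or mutant), and *molecularly targeted agents* (MTAs).
Every edge of the network is an :class:`EvidenceRule` — a signed, weighted,
context-tagged association curated from published evidence.  This module
defines those entities, the JSON/TSV file formats, validation, and lossless
serialization; the scoring itself lives in :mod:`dda.scoring`.

Identity conventions: gene and target symbols are canonicalized to uppercase,
MTA names to lowercase.  A target node is identified by the *(gene, status)*
pair, so ``EGFR WILD-TYPE`` and ``EGFR MUTANT`` are two distinct nodes and
rules must name the qualified node explicitly.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence


class DDAError(Exception):
    """Base class for user-facing errors (bad files, bad references)."""


class SchemaError(DDAError):
    """A file does not match the expected schema; message names the field."""


class AlterationClass(str, enum.Enum):
    SNV = "snv"
    INDEL = "indel"
    CNV_AMPLIFICATION = "cnv_amplification"
    CNV_LOSS = "cnv_loss"
    EXPRESSION_OVER = "expression_over"
    EXPRESSION_LOSS = "expression_loss"
    FUSION = "fusion"
    TMB_HIGH = "tmb_high"
    MSI_HIGH = "msi_high"
    WILD_TYPE = "wild_type"


#: classes for which an exact variant descriptor (protein change, fusion
#: partner) is meaningful
VARIANT_CLASSES = frozenset(
    {AlterationClass.SNV, AlterationClass.INDEL, AlterationClass.FUSION}
)


class TargetStatus(str, enum.Enum):
    WILD_TYPE = "wild_type"
    MUTANT = "mutant"


class RuleKind(str, enum.Enum):
    DRIVER_FUNCTION = "driver_function"
    DRIVER_TARGET = "driver_target"
    DRIVER_MTA = "driver_mta"


class Direction(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


class EvidenceClass(str, enum.Enum):
    CLINICAL = "clinical"
    PRECLINICAL = "preclinical"
    IN_SILICO = "in_silico"
    FREQUENCY = "frequency"


class Registration(str, enum.Enum):
    REGISTERED = "registered"
    CLINICAL_DEVELOPMENT = "clinical_development"


PAN_CANCER = "pan_cancer"


@dataclass(frozen=True, order=True)
class AlterationSpec:
    """One molecular alteration: a gene plus its alteration class.

    ``variant`` carries the exact descriptor (e.g. protein change ``G12V``)
    and may be non-empty only for SNV/indel/fusion classes.
    """

    gene: str
    alt_class: AlterationClass
    variant: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", self.gene.strip().upper())
        object.__setattr__(self, "alt_class", AlterationClass(self.alt_class))
        object.__setattr__(self, "variant", (self.variant or "").strip())
        if not self.gene:
            raise SchemaError("AlterationSpec.gene must be non-empty")
        if self.variant and self.alt_class not in VARIANT_CLASSES:
            raise SchemaError(
                f"AlterationSpec: variant {self.variant!r} not allowed for "
                f"alt_class {self.alt_class.value!r} (gene {self.gene})"
            )

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "alt_class": self.alt_class.value,
            "variant": self.variant,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AlterationSpec":
        return cls(d["gene"], AlterationClass(d["alt_class"]), d.get("variant", ""))


@dataclass(frozen=True, order=True)
class TargetNode:
    """A druggable target node, identified by (gene, status)."""

    gene: str
    status: TargetStatus

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", self.gene.strip().upper())
        object.__setattr__(self, "status", TargetStatus(self.status))
        if not self.gene:
            raise SchemaError("TargetNode.gene must be non-empty")

    def to_dict(self) -> dict:
        return {"gene": self.gene, "status": self.status.value}

    @classmethod
    def from_dict(cls, d: dict) -> "TargetNode":
        return cls(d["gene"], TargetStatus(d["status"]))

    def label(self) -> str:
        return f"{self.gene} {self.status.value.replace('_', '-').upper()}"


@dataclass(frozen=True)
class MTAEntity:
    """A molecularly targeted agent with its declared target set."""

    name: str
    registration: Registration
    targets: frozenset[TargetNode]

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", self.name.strip().lower())
        object.__setattr__(self, "registration", Registration(self.registration))
        object.__setattr__(self, "targets", frozenset(self.targets))
        if not self.name:
            raise SchemaError("MTAEntity.name must be non-empty")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "registration": self.registration.value,
            "targets": [t.to_dict() for t in sorted(self.targets)],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MTAEntity":
        return cls(
            d["name"],
            Registration(d["registration"]),
            frozenset(TargetNode.from_dict(t) for t in d.get("targets", [])),
        )


@dataclass(frozen=True, order=True)
class TumorContext:
    """Tumor type: localization (or ``pan_cancer``) plus optional histology."""

    localization: str
    histology: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "localization", self.localization.strip().lower())
        object.__setattr__(self, "histology", (self.histology or "").strip().lower())
        if not self.localization:
            raise SchemaError("TumorContext.localization must be non-empty")
        if self.localization == PAN_CANCER and self.histology:
            raise SchemaError("TumorContext: pan_cancer context cannot carry a histology")

    @property
    def is_pan_cancer(self) -> bool:
        return self.localization == PAN_CANCER

    def to_dict(self) -> dict:
        return {"localization": self.localization, "histology": self.histology}

    @classmethod
    def from_dict(cls, d: dict) -> "TumorContext":
        return cls(d["localization"], d.get("histology", ""))


@dataclass(frozen=True)
class EvidenceRule:
    """One signed, weighted association in the evidence network.

    Kinds:

    ``driver_function``
        evidence for (positive) or against (negative) the functional
        relevance of the subject gene / alteration itself; the only kind
        that may carry frequency-class evidence.
    ``driver_target``
        drugs hitting ``object_target`` are more (positive) or less
        (negative) effective in the presence of the subject driver.
    ``driver_mta``
        ``object_mta`` is more (sensitivity) or less (resistance) effective
        in the presence of the subject driver.
    """

    rule_id: str
    kind: RuleKind
    subject: AlterationSpec
    direction: Direction
    evidence_class: EvidenceClass
    source_weight: float
    context: TumorContext
    object_target: Optional[TargetNode] = None
    object_mta: Optional[str] = None
    citation: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", RuleKind(self.kind))
        object.__setattr__(self, "direction", Direction(self.direction))
        object.__setattr__(self, "evidence_class", EvidenceClass(self.evidence_class))
        if self.object_mta is not None:
            object.__setattr__(self, "object_mta", self.object_mta.strip().lower())
        # structural defects (wrong object for kind, non-positive source
        # weight, frequency evidence outside driver_function) are deliberately
        # representable here; validate_knowledge_base reports them.

    def to_dict(self) -> dict:
        return {
            "rule_id": self.rule_id,
            "kind": self.kind.value,
            "subject": self.subject.to_dict(),
            "object_target": self.object_target.to_dict() if self.object_target else None,
            "object_mta": self.object_mta,
            "direction": self.direction.value,
            "evidence_class": self.evidence_class.value,
            "source_weight": self.source_weight,
            "context": self.context.to_dict(),
            "citation": self.citation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvidenceRule":
        return cls(
            rule_id=d["rule_id"],
            kind=RuleKind(d["kind"]),
            subject=AlterationSpec.from_dict(d["subject"]),
            object_target=(
                TargetNode.from_dict(d["object_target"]) if d.get("object_target") else None
            ),
            object_mta=d.get("object_mta"),
            direction=Direction(d["direction"]),
            evidence_class=EvidenceClass(d["evidence_class"]),
            source_weight=float(d["source_weight"]),
            context=TumorContext.from_dict(d["context"]),
            citation=d.get("citation", ""),
        )


def rule_defects(rule: EvidenceRule) -> list[str]:
    """Structural defects of a single rule (empty list when well-formed)."""
    out: list[str] = []
    if not rule.rule_id:
        out.append("rule_id must be non-empty")
    if rule.source_weight <= 0:
        out.append(f"source_weight must be > 0, got {rule.source_weight}")
    if rule.kind is RuleKind.DRIVER_FUNCTION:
        if rule.object_target is not None or rule.object_mta is not None:
            out.append("driver_function rule must not carry an object_target/object_mta")
    elif rule.kind is RuleKind.DRIVER_TARGET:
        if rule.object_target is None or rule.object_mta is not None:
            out.append("driver_target rule requires object_target (and no object_mta)")
    elif rule.kind is RuleKind.DRIVER_MTA:
        if rule.object_mta is None or rule.object_target is not None:
            out.append("driver_mta rule requires object_mta (and no object_target)")
    if (
        rule.evidence_class is EvidenceClass.FREQUENCY
        and rule.kind is not RuleKind.DRIVER_FUNCTION
    ):
        # frequency evidences driverhood only; it never links to targets/MTAs
        out.append("frequency-class evidence is only allowed on driver_function rules")
    return out


@dataclass
class ValidationReport:
    """Outcome of knowledge-base validation; loadable iff ``errors`` empty."""

    errors: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_if_failed(self) -> None:
        if self.errors:
            entity, msg = self.errors[0]
            more = f" (+{len(self.errors) - 1} more)" if len(self.errors) > 1 else ""
            raise SchemaError(f"{entity}: {msg}{more}")


@dataclass
class KnowledgeBase:
    """The full evidence network: entities plus association rules."""

    genes: set[str]
    targets: set[TargetNode]
    mtas: list[MTAEntity]
    rules: list[EvidenceRule]

    def mta(self, name: str) -> MTAEntity:
        name = name.strip().lower()
        for m in self.mtas:
            if m.name == name:
                return m
        raise KeyError(f"MTA {name!r} not in knowledge base")

    def to_dict(self) -> dict:
        return {
            "genes": sorted(self.genes),
            "targets": [t.to_dict() for t in sorted(self.targets)],
            "mtas": [m.to_dict() for m in sorted(self.mtas, key=lambda m: m.name)],
            "rules": [r.to_dict() for r in self.rules],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KnowledgeBase":
        try:
            kb = cls(
                genes={g.strip().upper() for g in d["genes"]},
                targets={TargetNode.from_dict(t) for t in d["targets"]},
                mtas=[MTAEntity.from_dict(m) for m in d["mtas"]],
                rules=[EvidenceRule.from_dict(r) for r in d["rules"]],
            )
        except KeyError as e:
            raise SchemaError(f"knowledge base JSON missing field {e.args[0]!r}") from e
        return kb


@dataclass(frozen=True)
class MolecularProfile:
    """A patient's tumor context plus observed molecular alterations."""

    patient_id: str
    tumor: TumorContext
    alterations: tuple[AlterationSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "alterations", tuple(self.alterations))
        if not self.alterations:
            raise SchemaError(f"profile {self.patient_id!r}: at least one alteration required")
        seen = set()
        for a in self.alterations:
            key = (a.gene, a.alt_class, a.variant)
            if key in seen:
                raise SchemaError(
                    f"profile {self.patient_id!r}: duplicate alteration "
                    f"{a.gene}/{a.alt_class.value}/{a.variant or '-'}"
                )
            seen.add(key)

    def mutant_genes(self) -> list[str]:
        """Genes with at least one observed (non wild-type) alteration."""
        return sorted(
            {a.gene for a in self.alterations if a.alt_class is not AlterationClass.WILD_TYPE}
        )

    def alterations_of(self, gene: str) -> list[AlterationSpec]:
        gene = gene.upper()
        return [
            a
            for a in self.alterations
            if a.gene == gene and a.alt_class is not AlterationClass.WILD_TYPE
        ]

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "tumor": self.tumor.to_dict(),
            "alterations": [a.to_dict() for a in self.alterations],
        }


# ---------------------------------------------------------------------------
# validation


def validate_knowledge_base(kb: KnowledgeBase) -> ValidationReport:
    """Check every structural invariant; errors make the KB unloadable.

    Warnings flag isolated entities (declared but untouched by any rule) and
    source weights outside the conventional [0.5, 2.0] band.
    """
    rep = ValidationReport()
    seen_ids: set[str] = set()
    mta_names = {m.name for m in kb.mtas}
    if len(mta_names) != len(kb.mtas):
        dupes = sorted(
            n for n in mta_names if sum(1 for m in kb.mtas if m.name == n) > 1
        )
        rep.errors.append(("mtas", f"duplicate MTA name(s): {', '.join(dupes)}"))

    for m in kb.mtas:
        if not m.targets:
            rep.errors.append((m.name, "MTA has an empty target set"))
        for t in m.targets:
            if t not in kb.targets:
                rep.errors.append((m.name, f"MTA target {t.label()} not declared in targets"))

    touched_genes: set[str] = set()
    touched_targets: set[TargetNode] = set()
    touched_mtas: set[str] = set()
    for r in kb.rules:
        if r.rule_id in seen_ids:
            rep.errors.append((r.rule_id, "duplicate rule_id"))
        seen_ids.add(r.rule_id)
        for msg in rule_defects(r):
            rep.errors.append((r.rule_id, msg))
        if r.subject.gene not in kb.genes:
            rep.errors.append((r.rule_id, f"subject gene {r.subject.gene!r} not declared"))
        if r.object_target is not None and r.object_target not in kb.targets:
            rep.errors.append(
                (r.rule_id, f"object_target {r.object_target.label()} not declared")
            )
        if r.object_mta is not None and r.object_mta not in mta_names:
            rep.errors.append((r.rule_id, f"object_mta {r.object_mta!r} not declared"))
        if not (0.5 <= r.source_weight <= 2.0):
            rep.warnings.append(
                (r.rule_id, f"source_weight {r.source_weight} outside usual [0.5, 2.0]")
            )
        touched_genes.add(r.subject.gene)
        if r.object_target is not None:
            touched_targets.add(r.object_target)
        if r.object_mta is not None:
            touched_mtas.add(r.object_mta)
    for m in kb.mtas:
        touched_targets |= m.targets

    for g in sorted(kb.genes - touched_genes - {t.gene for t in kb.targets}):
        rep.warnings.append((g, "isolated gene: no rule references it"))
    for t in sorted(kb.targets - touched_targets):
        rep.warnings.append((t.label(), "isolated target: no rule or MTA references it"))
    for n in sorted(mta_names - touched_mtas):
        rep.warnings.append((n, "isolated MTA: no rule references it"))
    return rep


def knowledge_base_stats(kb: KnowledgeBase) -> dict:
    """Entity and rule counts, broken down by evidence class and rule kind."""
    by_class = {c.value: 0 for c in EvidenceClass}
    by_kind = {k.value: 0 for k in RuleKind}
    for r in kb.rules:
        by_class[r.evidence_class.value] += 1
        by_kind[r.kind.value] += 1
    return {
        "genes": len(kb.genes),
        "targets": len(kb.targets),
        "mtas": len(kb.mtas),
        "rules_total": len(kb.rules),
        "rules_by_evidence_class": by_class,
        "rules_by_kind": by_kind,
    }


# ---------------------------------------------------------------------------
# serialization

_RULE_TSV_COLUMNS = [
    "rule_id",
    "kind",
    "gene",
    "alt_class",
    "variant",
    "object_target_gene",
    "object_target_status",
    "object_mta",
    "direction",
    "evidence_class",
    "source_weight",
    "tumor_localization",
    "tumor_histology",
    "citation",
]


def dumps_knowledge_base(kb: KnowledgeBase) -> str:
    """Canonical JSON text (sorted keys, 2-space indent, trailing newline)."""
    return json.dumps(kb.to_dict(), sort_keys=True, indent=2) + "\n"


def save_knowledge_base(kb: KnowledgeBase, path: str | Path) -> None:
    Path(path).write_text(dumps_knowledge_base(kb))


def load_knowledge_base(path: str | Path) -> KnowledgeBase:
    """Load and fully validate a knowledge base from canonical JSON.

    Raises :class:`DDAError` on a missing file, :class:`SchemaError` on a
    malformed document or on any invariant violation (dangling references
    are reported with the offending rule_id).
    """
    path = Path(path)
    if not path.exists():
        raise DDAError(f"knowledge base file not found: {path}")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise SchemaError(f"{path}: not valid JSON ({e})") from e
    kb = KnowledgeBase.from_dict(doc)
    validate_knowledge_base(kb).raise_if_failed()
    return kb


def rules_to_tsv(rules: Iterable[EvidenceRule]) -> str:
    """Flat TSV rendering of the rule list, for hand-editing."""
    lines = ["\t".join(_RULE_TSV_COLUMNS)]
    for r in rules:
        lines.append(
            "\t".join(
                [
                    r.rule_id,
                    r.kind.value,
                    r.subject.gene,
                    r.subject.alt_class.value,
                    r.subject.variant,
                    r.object_target.gene if r.object_target else "",
                    r.object_target.status.value if r.object_target else "",
                    r.object_mta or "",
                    r.direction.value,
                    r.evidence_class.value,
                    repr(r.source_weight),
                    r.context.localization,
                    r.context.histology,
                    r.citation,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def rules_from_tsv(text: str) -> list[EvidenceRule]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0].split("\t") != _RULE_TSV_COLUMNS:
        raise SchemaError(
            "rules TSV: first line must be the header " + "\t".join(_RULE_TSV_COLUMNS)
        )
    rules = []
    for ln in lines[1:]:
        f = dict(zip(_RULE_TSV_COLUMNS, ln.split("\t")))
        rules.append(
            EvidenceRule(
                rule_id=f["rule_id"],
                kind=RuleKind(f["kind"]),
                subject=AlterationSpec(f["gene"], AlterationClass(f["alt_class"]), f["variant"]),
                object_target=(
                    TargetNode(f["object_target_gene"], TargetStatus(f["object_target_status"]))
                    if f["object_target_gene"]
                    else None
                ),
                object_mta=f["object_mta"] or None,
                direction=Direction(f["direction"]),
                evidence_class=EvidenceClass(f["evidence_class"]),
                source_weight=float(f["source_weight"]),
                context=TumorContext(f["tumor_localization"], f["tumor_histology"]),
                citation=f.get("citation", ""),
            )
        )
    return rules


# ---------------------------------------------------------------------------
# profile TSV


def parse_profile(path: str | Path) -> MolecularProfile:
    """Read one patient profile from TSV.

    Format: ``#patient_id=``, ``#tumor_localization=`` (required) and
    ``#tumor_histology=`` (optional) header lines, then a column header
    ``gene  alt_class  variant  value`` and one alteration per row.  The
    numeric ``value`` column (e.g. a TMB) is accepted and ignored by scoring.
    """
    path = Path(path)
    if not path.exists():
        raise DDAError(f"profile file not found: {path}")
    return parse_profile_text(path.read_text(), name=str(path))


def parse_profile_text(text: str, name: str = "<profile>") -> MolecularProfile:
    meta: dict[str, str] = {}
    rows: list[AlterationSpec] = []
    header_seen = False
    columns: list[str] = []
    for lineno, ln in enumerate(text.splitlines(), start=1):
        if not ln.strip():
            continue
        if ln.startswith("#"):
            if "=" not in ln:
                raise SchemaError(f"{name}:{lineno}: malformed header line {ln!r}")
            k, v = ln[1:].split("=", 1)
            meta[k.strip()] = v.strip()
            continue
        cells = ln.rstrip("\n").split("\t")
        if not header_seen:
            columns = [c.strip() for c in cells]
            for required in ("gene", "alt_class"):
                if required not in columns:
                    raise SchemaError(f"{name}: column {required!r} missing from header")
            header_seen = True
            continue
        row = dict(zip(columns, cells))
        try:
            alt_class = AlterationClass(row.get("alt_class", "").strip())
        except ValueError:
            raise SchemaError(
                f"{name}:{lineno}: unknown alt_class {row.get('alt_class', '')!r}"
            ) from None
        rows.append(AlterationSpec(row.get("gene", ""), alt_class, row.get("variant", "")))
    if "tumor_localization" not in meta:
        raise SchemaError(f"{name}: missing '#tumor_localization=' header")
    tumor = TumorContext(meta["tumor_localization"], meta.get("tumor_histology", ""))
    return MolecularProfile(meta.get("patient_id", "anonymous"), tumor, tuple(rows))


def profile_to_tsv(profile: MolecularProfile) -> str:
    lines = [
        f"#patient_id={profile.patient_id}",
        f"#tumor_localization={profile.tumor.localization}",
    ]
    if profile.tumor.histology:
        lines.append(f"#tumor_histology={profile.tumor.histology}")
    lines.append("gene\talt_class\tvariant\tvalue")
    for a in profile.alterations:
        lines.append(f"{a.gene}\t{a.alt_class.value}\t{a.variant}\t")
    return "\n".join(lines) + "\n"
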