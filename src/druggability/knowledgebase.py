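"""Variant/drug knowledgebase: schema, validation, and duplicate resolution.

The knowledgebase is a curated table of variant -> drug interactions.  Each
entry links a genomic/transcriptomic event in a gene (an exact missense
change, an ambiguous single-residue change, a codon range, a loose
frameshift/nonsense category, or an expression/copy-number/fusion flag) to a
drug, a tumor-type context, a direction of effect (sensitive or resistant)
and an ordinal evidence tier.  All downstream matching, specificity and tier
logic is driven by this table.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

logger = logging.getLogger(__name__)

KB_COLUMNS = [
    "gene",
    "variant_class",
    "variant_spec",
    "tumor_type",
    "effect",
    "evidence_level",
    "drug",
    "drug_classes",
    "pubmed_id",
]

UNSPECIFIED = "UNSPECIFIED"


class VariantClass(str, Enum):
    MISSENSE_EXACT = "missense_exact"
    MISSENSE_POSITION = "missense_position"
    AA_RANGE = "aa_range"
    FRAMESHIFT = "frameshift"
    NONSENSE = "nonsense"
    INFRAME_INDEL_EXACT = "inframe_indel_exact"
    INFRAME_INDEL_RANGE = "inframe_indel_range"
    EXPRESSION_HIGH = "expression_high"
    EXPRESSION_LOW = "expression_low"
    CNA = "cna"
    CNL = "cnl"
    FUSION = "fusion"


#: classes whose variant_spec carries no amino-acid information
SPECLESS_CLASSES = {
    VariantClass.EXPRESSION_HIGH,
    VariantClass.EXPRESSION_LOW,
    VariantClass.CNA,
    VariantClass.CNL,
    VariantClass.FUSION,
}

EXPRESSION_CLASSES = {VariantClass.EXPRESSION_HIGH, VariantClass.EXPRESSION_LOW}


class Effect(str, Enum):
    SENSITIVE = "sensitive"
    RESISTANT = "resistant"


class EvidenceLevel(str, Enum):
    PRECLINICAL = "preclinical"
    CASE_REPORT = "case_report"
    CLINICAL_TRIAL = "clinical_trial"
    FDA_APPROVED = "fda_approved"


_EVIDENCE_RANK = {
    EvidenceLevel.PRECLINICAL: 1,
    EvidenceLevel.CASE_REPORT: 2,
    EvidenceLevel.CLINICAL_TRIAL: 3,
    EvidenceLevel.FDA_APPROVED: 4,
}

#: ordinal rank reserved for structure-cluster ("hotspot3d") putative calls,
#: strictly below preclinical in every cumulative summary
HOTSPOT3D_TIER = "hotspot3d"
HOTSPOT3D_RANK = 0


def evidence_rank(level: EvidenceLevel | str) -> int:
    """Ordinal rank of an evidence tier, preclinical=1 ... fda_approved=4.

    The hotspot3d pseudo-tier used for cluster-derived putative calls ranks 0.
    """
    if level == HOTSPOT3D_TIER:
        return HOTSPOT3D_RANK
    try:
        return _EVIDENCE_RANK[EvidenceLevel(level)]
    except (ValueError, KeyError):
        raise ValueError(f"unknown evidence level: {level!r}")


_MISSENSE_EXACT_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")
_MISSENSE_POS_RE = re.compile(r"^([A-Z])(\d+)$")
_RANGE_RE = re.compile(r"^(\d+)-(\d+)(?::([a-z_]+))?$")
_POSITION_OR_ANY_RE = re.compile(r"^(\*|\d+)$")
# inframe indel in HGVS-p short form, e.g. E746_A750del, M1del, A763_Y764insFQEA
_INFRAME_EXACT_RE = re.compile(
    r"^[A-Z]\d+(?:_[A-Z]\d+)?(?:del|ins[A-Z]*|delins[A-Z]+|dup)$"
)

_RANGE_SUBCLASSES = {"missense", "inframe_del", "inframe_ins"}


@dataclass(frozen=True)
class ParsedSpec:
    """Normalized view of a variant_spec used by the matcher."""

    ref_aa: str | None = None
    position: int | None = None
    alt_aa: str | None = None
    start: int | None = None
    end: int | None = None
    subclass: str | None = None  # constraint for range specs
    raw: str = ""


def parse_variant_spec(variant_class: VariantClass, spec: str) -> ParsedSpec:
    """Parse and validate a variant_spec under its class.

    Raises ValueError when the spec does not parse under the class.
    """
    spec = (spec or "").strip()
    if variant_class in SPECLESS_CLASSES:
        if spec not in ("", "-", "."):
            raise ValueError(
                f"{variant_class.value} entries carry no amino-acid spec, got {spec!r}"
            )
        return ParsedSpec(raw="")

    if variant_class is VariantClass.MISSENSE_EXACT:
        m = _MISSENSE_EXACT_RE.match(spec)
        if not m:
            raise ValueError(f"bad missense_exact spec {spec!r} (want e.g. V600E)")
        pos = int(m.group(2))
        if pos < 1:
            raise ValueError(f"position must be >= 1 in {spec!r}")
        return ParsedSpec(ref_aa=m.group(1), position=pos, alt_aa=m.group(3), raw=spec)

    if variant_class is VariantClass.MISSENSE_POSITION:
        m = _MISSENSE_POS_RE.match(spec)
        if not m:
            raise ValueError(f"bad missense_position spec {spec!r} (want e.g. V600)")
        pos = int(m.group(2))
        if pos < 1:
            raise ValueError(f"position must be >= 1 in {spec!r}")
        return ParsedSpec(ref_aa=m.group(1), position=pos, raw=spec)

    if variant_class in (VariantClass.AA_RANGE, VariantClass.INFRAME_INDEL_RANGE):
        m = _RANGE_RE.match(spec)
        if not m:
            raise ValueError(f"bad range spec {spec!r} (want e.g. 729-761:inframe_del)")
        start, end, sub = int(m.group(1)), int(m.group(2)), m.group(3)
        if start < 1 or start > end:
            raise ValueError(f"range must satisfy 1 <= start <= end in {spec!r}")
        if variant_class is VariantClass.INFRAME_INDEL_RANGE:
            if sub not in ("inframe_del", "inframe_ins"):
                raise ValueError(
                    f"inframe_indel_range needs an :inframe_del/:inframe_ins "
                    f"suffix, got {spec!r}"
                )
        elif sub is not None and sub not in _RANGE_SUBCLASSES:
            raise ValueError(f"unknown range subclass in {spec!r}")
        return ParsedSpec(start=start, end=end, subclass=sub, raw=spec)

    if variant_class in (VariantClass.FRAMESHIFT, VariantClass.NONSENSE):
        m = _POSITION_OR_ANY_RE.match(spec)
        if not m:
            raise ValueError(
                f"bad {variant_class.value} spec {spec!r} (want a codon number or '*')"
            )
        pos = None if spec == "*" else int(spec)
        if pos is not None and pos < 1:
            raise ValueError(f"position must be >= 1 in {spec!r}")
        return ParsedSpec(position=pos, raw=spec)

    if variant_class is VariantClass.INFRAME_INDEL_EXACT:
        if not _INFRAME_EXACT_RE.match(spec):
            raise ValueError(
                f"bad inframe_indel_exact spec {spec!r} (want e.g. E746_A750del)"
            )
        m = re.match(r"^[A-Z](\d+)", spec)
        return ParsedSpec(position=int(m.group(1)), raw=spec)

    raise ValueError(f"unknown variant class {variant_class!r}")


@dataclass(frozen=True)
class KnowledgebaseEntry:
    """One variant/drug interaction."""

    gene: str
    variant_class: VariantClass
    variant_spec: str
    tumor_type: str
    effect: Effect
    evidence_level: EvidenceLevel
    drug: str
    drug_classes: frozenset[str]
    pubmed_id: str
    entry_id: int = 0  # stable file order, used for tie-breaks and reporting
    parsed: ParsedSpec = field(default=ParsedSpec(), compare=False)

    @property
    def evidence(self) -> int:
        return evidence_rank(self.evidence_level)

    @property
    def variant_key(self) -> str:
        spec = self.variant_spec or self.variant_class.value
        return f"{self.gene}:{spec}"


@dataclass
class DrugClassMap:
    """Lookup drug name -> drug-class labels, plus the 10-class viz subset."""

    mapping: dict[str, frozenset[str]]
    viz_classes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.viz_classes and len(self.viz_classes) != 10:
            raise ValueError(
                f"visualization subset must have exactly 10 classes, "
                f"got {len(self.viz_classes)}"
            )

    def classes_for(self, drug: str) -> frozenset[str]:
        try:
            return self.mapping[drug]
        except KeyError:
            raise KeyError(f"drug {drug!r} missing from class map")

    @classmethod
    def from_tsv(cls, path, viz_classes: tuple[str, ...] = ()) -> "DrugClassMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"drug", "class"} <= set(df.columns):
            raise ValueError("drug-class map needs columns: drug, class")
        mapping: dict[str, set[str]] = {}
        for drug, klass in zip(df["drug"], df["class"]):
            mapping.setdefault(drug, set()).add(klass)
        return cls(
            {d: frozenset(c) for d, c in mapping.items()}, tuple(viz_classes)
        )


class KnowledgebaseError(ValueError):
    """Raised for malformed knowledgebase rows; message names the line."""


def load_knowledgebase(
    path,
    class_map: DrugClassMap,
    tumor_type_vocab: set[str] | None = None,
) -> list[KnowledgebaseEntry]:
    """Load and validate the knowledgebase TSV.

    ``tumor_type_vocab``, when given, restricts tumor-type codes (plus
    UNSPECIFIED, always legal); codes outside it are a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in KB_COLUMNS if c not in df.columns]
    if missing:
        raise KnowledgebaseError(f"knowledgebase missing columns: {missing}")
    entries: list[KnowledgebaseEntry] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line_no = idx + 2  # 1-based, after the header
        try:
            vc = VariantClass(row.variant_class)
        except ValueError:
            raise KnowledgebaseError(
                f"line {line_no}: unknown variant_class {row.variant_class!r}"
            )
        try:
            parsed = parse_variant_spec(vc, row.variant_spec)
            effect = Effect(row.effect)
            level = EvidenceLevel(row.evidence_level)
        except ValueError as exc:
            raise KnowledgebaseError(f"line {line_no}: {exc}") from exc
        tumor_type = (row.tumor_type or UNSPECIFIED).upper()
        if tumor_type_vocab is not None and tumor_type != UNSPECIFIED:
            if tumor_type not in tumor_type_vocab:
                raise KnowledgebaseError(
                    f"line {line_no}: tumor type {tumor_type!r} not in vocabulary"
                )
        try:
            classes = class_map.classes_for(row.drug)
        except KeyError as exc:
            raise KnowledgebaseError(f"line {line_no}: {exc}") from exc
        declared = frozenset(filter(None, (row.drug_classes or "").split(";")))
        entries.append(
            KnowledgebaseEntry(
                gene=row.gene,
                variant_class=vc,
                variant_spec=parsed.raw,
                tumor_type=tumor_type,
                effect=effect,
                evidence_level=level,
                drug=row.drug,
                drug_classes=declared or classes,
                pubmed_id=row.pubmed_id,
                entry_id=idx,
                parsed=parsed,
            )
        )
    if not entries:
        logger.warning("knowledgebase %s is empty", path)
    logger.info("loaded %d knowledgebase entries from %s", len(entries), path)
    return entries


def deduplicate_entries(
    entries: list[KnowledgebaseEntry],
) -> list[KnowledgebaseEntry]:
    """Resolve duplicate entries: identical (gene, class, spec, drug,
    tumor_type, effect) groups keep only the highest-evidence entry.

    Ties at equal evidence keep the first by file order (warning logged).
    Non-identical entries are all retained.  Idempotent.
    """
    groups: dict[tuple, KnowledgebaseEntry] = {}
    for e in entries:
        key = (e.gene, e.variant_class, e.variant_spec, e.drug, e.tumor_type, e.effect)
        kept = groups.get(key)
        if kept is None:
            groups[key] = e
        elif e.evidence > kept.evidence:
            groups[key] = e
        elif e.evidence == kept.evidence:
            logger.warning(
                "duplicate entries at equal evidence for %s %s / %s; "
                "keeping first by file order",
                e.gene,
                e.variant_spec,
                e.drug,
            )
    return sorted(groups.values(), key=lambda e: e.entry_id)


def write_knowledgebase(entries: list[KnowledgebaseEntry], path) -> None:
    """Write entries as TSV in the canonical column order."""
    rows = [
        {
            "gene": e.gene,
            "variant_class": e.variant_class.value,
            "variant_spec": e.variant_spec,
            "tumor_type": e.tumor_type,
            "effect": e.effect.value,
            "evidence_level": e.evidence_level.value,
            "drug": e.drug,
            "drug_classes": ";".join(sorted(e.drug_classes)),
            "pubmed_id": e.pubmed_id,
        }
        for e in entries
    ]
    pd.DataFrame(rows, columns=KB_COLUMNS).to_csv(path, sep="\t", index=False)
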