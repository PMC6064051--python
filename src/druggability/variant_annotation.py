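"""Match cohort mutations against the knowledgebase and resolve per-sample
druggability calls.

Matching uses three hash-table routes: exact protein changes (BRAF V600E),
ambiguous single-residue specs (BRAF V600, any substitution of the reference
valine), and codon ranges for class-restricted events (EGFR 729-761 in-frame
deletions), plus loose frameshift/nonsense categories keyed by gene and
optional position.

Resolution per (sample, mutation): a sensitive interaction wins over a
resistant one; among effect-consistent matches the drug with the globally
highest evidence tier (any tumor type) is chosen; the call is
cancer-type-specific when the sample's own cancer type attains that maximal
tier, otherwise the drug is "off-label" (non-specific, i.e. repurposed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .cohort_io import MutationRecord, parse_protein_change
from .knowledgebase import (
    UNSPECIFIED,
    Effect,
    EvidenceLevel,
    KnowledgebaseEntry,
    VariantClass,
    evidence_rank,
)

logger = logging.getLogger(__name__)

SPECIFIC = "cancer_type_specific"
NON_SPECIFIC = "non_specific"

EVIDENCE_ORDER = [
    EvidenceLevel.FDA_APPROVED,
    EvidenceLevel.CLINICAL_TRIAL,
    EvidenceLevel.CASE_REPORT,
    EvidenceLevel.PRECLINICAL,
]


@dataclass(frozen=True)
class DruggabilityCall:
    """A matched, resolved biomarker for one tumor sample."""

    sample_id: str
    cancer_type: str
    gene: str
    variant_key: str
    data_level: str  # mutation | mrna | protein | phosphoprotein | cluster_putative
    effect: Effect
    specificity: str  # cancer_type_specific | non_specific
    chosen_drug: str
    chosen_evidence: str  # evidence level value, or "hotspot3d" for putative calls
    all_matches: tuple[int, ...] = ()  # knowledgebase entry ids
    top_drugs: tuple[str, ...] = field(default=(), compare=False)

    @property
    def evidence(self) -> int:
        return evidence_rank(self.chosen_evidence)


class KnowledgebaseIndex:
    """Hash tables over the resolved knowledgebase for O(1) mutation lookup."""

    def __init__(self, entries: list[KnowledgebaseEntry]):
        self.entries = entries
        self.exact: dict[tuple[str, str], list[KnowledgebaseEntry]] = {}
        self.position: dict[tuple[str, str, int], list[KnowledgebaseEntry]] = {}
        self.ranges: dict[str, list[KnowledgebaseEntry]] = {}
        self.loose: dict[tuple[str, str], list[KnowledgebaseEntry]] = {}
        self.expression: dict[str, list[KnowledgebaseEntry]] = {}
        for e in entries:
            vc = e.variant_class
            if vc in (VariantClass.MISSENSE_EXACT, VariantClass.INFRAME_INDEL_EXACT):
                self.exact.setdefault((e.gene, e.variant_spec), []).append(e)
            elif vc is VariantClass.MISSENSE_POSITION:
                key = (e.gene, e.parsed.ref_aa, e.parsed.position)
                self.position.setdefault(key, []).append(e)
            elif vc in (VariantClass.AA_RANGE, VariantClass.INFRAME_INDEL_RANGE):
                self.ranges.setdefault(e.gene, []).append(e)
            elif vc in (VariantClass.FRAMESHIFT, VariantClass.NONSENSE):
                self.loose.setdefault((e.gene, vc.value), []).append(e)
            elif vc in (VariantClass.EXPRESSION_HIGH, VariantClass.EXPRESSION_LOW):
                self.expression.setdefault(e.gene, []).append(e)
            # cna/cnl/fusion entries are representable but matched only via
            # optional input channels not exercised here


def match_mutation(
    record: MutationRecord, index: KnowledgebaseIndex
) -> list[KnowledgebaseEntry]:
    """All knowledgebase entries the mutation maps onto (possibly empty).

    Routes: (i) exact (gene, protein_change); (ii) position-only, requiring
    the record's reference amino acid and residue to equal the ambiguous
    spec; (iii) codon-range, requiring class agreement and the record's start
    codon inside [start, end]; (iv) loose frameshift/nonsense categories.
    """
    hits: list[KnowledgebaseEntry] = []
    hits.extend(index.exact.get((record.gene, record.protein_change), ()))

    parsed = parse_protein_change(record.protein_change, record.mutation_class)
    if parsed is not None:
        ref_aa, pos, _alt = parsed
        if record.mutation_class == "missense":
            hits.extend(index.position.get((record.gene, ref_aa, pos), ()))
        for e in index.ranges.get(record.gene, ()):
            sub = e.parsed.subclass
            if e.variant_class is VariantClass.AA_RANGE and sub is None:
                class_ok = record.mutation_class in ("missense", "inframe_del", "inframe_ins")
            else:
                class_ok = record.mutation_class == sub
            if class_ok and e.parsed.start <= pos <= e.parsed.end:
                hits.append(e)
        if record.mutation_class in ("frameshift", "nonsense"):
            for e in index.loose.get((record.gene, record.mutation_class), ()):
                if e.parsed.position is None or e.parsed.position == pos:
                    hits.append(e)
    # drop duplicates while preserving knowledgebase order
    seen: set[int] = set()
    unique = []
    for e in sorted(hits, key=lambda e: e.entry_id):
        if e.entry_id not in seen:
            seen.add(e.entry_id)
            unique.append(e)
    return unique


def resolve_call(
    record: MutationRecord,
    matches: list[KnowledgebaseEntry],
    sample_cancer_type: str,
) -> DruggabilityCall | None:
    """Resolve matched entries to one call, or None without matches.

    Sensitive-over-resistant; the chosen drug carries the globally maximal
    evidence among effect-consistent matches; specificity requires the
    sample's cancer type to appear among the matches at that maximal tier
    (UNSPECIFIED tumor types never confer specificity).  Equal-evidence drug
    ties keep all drugs on the call and designate the alphabetically first.
    """
    if not matches:
        return None
    effect = (
        Effect.SENSITIVE
        if any(e.effect is Effect.SENSITIVE for e in matches)
        else Effect.RESISTANT
    )
    consistent = [e for e in matches if e.effect is effect]
    top = max(e.evidence for e in consistent)
    at_top = [e for e in consistent if e.evidence == top]
    top_drugs = tuple(sorted({e.drug for e in at_top}))
    specific = any(e.tumor_type == sample_cancer_type for e in at_top)
    return DruggabilityCall(
        sample_id=record.sample_id,
        cancer_type=sample_cancer_type,
        gene=record.gene,
        variant_key=record.variant_key,
        data_level="mutation",
        effect=effect,
        specificity=SPECIFIC if specific else NON_SPECIFIC,
        chosen_drug=top_drugs[0],
        chosen_evidence=at_top[0].evidence_level.value,
        all_matches=tuple(e.entry_id for e in matches),
        top_drugs=top_drugs,
    )


def annotate_cohort(
    records: list[MutationRecord], index: KnowledgebaseIndex
) -> list[DruggabilityCall]:
    """Match and resolve every mutation in the cohort; unmatched drop out."""
    calls = []
    for r in records:
        call = resolve_call(r, match_mutation(r, index), r.cancer_type)
        if call is not None:
            calls.append(call)
    logger.info("annotated %d druggability calls from %d mutations", len(calls), len(records))
    return calls


def summarize_mutation_druggability(
    calls: list[DruggabilityCall], cohort: dict[str, str]
) -> pd.DataFrame:
    """Per-cancer-type cumulative fraction of tumors druggable at >= each tier.

    ``cohort`` maps sample_id -> cancer_type for every QC-passing sample (the
    denominator).  Only sensitive calls count toward druggable fractions; a
    sample counts once, at its best tier, and cumulative tiers nest from
    fda_approved down to preclinical.  Columns: cancer_type, setting, tier,
    cumulative_fraction, n_samples.
    """
    best: dict[tuple[str, str], int] = {}  # (setting, sample) -> best rank
    for c in calls:
        if c.effect is not Effect.SENSITIVE or c.data_level != "mutation":
            continue
        for setting in ("specific", "non_specific"):
            if setting == "specific" and c.specificity != SPECIFIC:
                continue
            key = (setting, c.sample_id)
            best[key] = max(best.get(key, 0), c.evidence)
    rows = []
    by_type: dict[str, list[str]] = {}
    for sample, ctype in cohort.items():
        by_type.setdefault(ctype, []).append(sample)
    for ctype in sorted(by_type):
        samples = by_type[ctype]
        for setting in ("specific", "non_specific"):
            for tier in EVIDENCE_ORDER:
                rank = evidence_rank(tier)
                n_hit = sum(
                    1 for s in samples if best.get((setting, s), 0) >= rank
                )
                rows.append(
                    {
                        "cancer_type": ctype,
                        "setting": setting,
                        "tier": tier.value,
                        "cumulative_fraction": n_hit / len(samples),
                        "n_samples": len(samples),
                    }
                )
    return pd.DataFrame(
        rows, columns=["cancer_type", "setting", "tier", "cumulative_fraction", "n_samples"]
    )


def calls_to_frame(calls: list[DruggabilityCall]) -> pd.DataFrame:
    """Calls as the canonical output table."""
    rows = [
        {
            "sample_id": c.sample_id,
            "cancer_type": c.cancer_type,
            "gene": c.gene,
            "variant_key": c.variant_key,
            "data_level": c.data_level,
            "effect": c.effect.value,
            "specificity": c.specificity,
            "chosen_drug": c.chosen_drug,
            "chosen_evidence": c.chosen_evidence,
            "all_matches": ";".join(map(str, c.all_matches)),
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "cancer_type",
            "gene",
            "variant_key",
            "data_level",
            "effect",
            "specificity",
            "chosen_drug",
            "chosen_evidence",
            "all_matches",
        ],
    )
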