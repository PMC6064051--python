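"""Multi-omics integration: per-tumor druggability profiles, drug-class
sectors, co-occurrence reports, and cumulative evidence-tier summaries.

A tumor is multi-omics druggable when sensitive biomarkers support it on two
or more of the three data levels (mutation, mRNA, protein/phosphoprotein).
Cluster-derived putative mutations enter the cumulative summaries at a
pseudo-tier ("hotspot3d") strictly below preclinical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .cohort_io import MutationRecord, SampleTraits
from .expression_outliers import OutlierCall
from .knowledgebase import (
    EXPRESSION_CLASSES,
    HOTSPOT3D_TIER,
    Effect,
    KnowledgebaseEntry,
    VariantClass,
    evidence_rank,
)
from .variant_annotation import NON_SPECIFIC, SPECIFIC, DruggabilityCall

logger = logging.getLogger(__name__)

CUMULATIVE_TIERS = [
    "fda_approved",
    "clinical_trial",
    "case_report",
    "preclinical",
    HOTSPOT3D_TIER,
]

#: call data levels collapse onto the three profiled variant types
_LEVEL_TO_VARIANT_TYPE = {
    "mutation": "mutation",
    "cluster_putative": "mutation",
    "mrna": "mrna",
    "protein": "protein",
    "phosphoprotein": "protein",
}


@dataclass
class TumorDruggabilityProfile:
    sample_id: str
    cancer_type: str
    profiled_levels: frozenset[str]
    calls: list[DruggabilityCall] = field(default_factory=list)
    druggable_levels: frozenset[str] = frozenset()
    drug_class_hits: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    best_tier_specific: str | None = None
    best_tier_nonspecific: str | None = None


def expression_calls_to_druggability(
    outlier_calls: list[OutlierCall],
    kb: list[KnowledgebaseEntry],
    sample_cancer_types: dict[str, str],
) -> list[DruggabilityCall]:
    """Lift expression outlier calls to druggability calls via the
    knowledgebase's expression entries for the feature's gene.

    The drug is the gene's highest-evidence expression-linked drug in the
    matching direction regardless of cancer type; specificity follows the
    same maximal-tier rule as for mutations.
    """
    by_gene: dict[tuple[str, str], list[KnowledgebaseEntry]] = {}
    for e in kb:
        if e.variant_class in EXPRESSION_CLASSES and e.effect is Effect.SENSITIVE:
            direction = (
                "high" if e.variant_class is VariantClass.EXPRESSION_HIGH else "low"
            )
            by_gene.setdefault((e.gene, direction), []).append(e)

    calls: list[DruggabilityCall] = []
    for oc in outlier_calls:
        if not oc.is_outlier:
            continue
        gene = oc.feature.split(":", 1)[0]
        entries = by_gene.get((gene, oc.direction))
        if not entries:
            continue
        top = max(e.evidence for e in entries)
        at_top = [e for e in entries if e.evidence == top]
        ctype = sample_cancer_types.get(oc.sample_id, "")
        specific = any(e.tumor_type == ctype for e in at_top)
        drugs = sorted({e.drug for e in at_top})
        calls.append(
            DruggabilityCall(
                sample_id=oc.sample_id,
                cancer_type=ctype,
                gene=gene,
                variant_key=f"{oc.feature}:expression_{oc.direction}",
                data_level=oc.level,
                effect=Effect.SENSITIVE,
                specificity=SPECIFIC if specific else NON_SPECIFIC,
                chosen_drug=drugs[0],
                chosen_evidence=at_top[0].evidence_level.value,
                all_matches=tuple(e.entry_id for e in entries),
                top_drugs=tuple(drugs),
            )
        )
    return calls


def putative_calls_from_clusters(
    clusters,
    records: list[MutationRecord],
    index,
    kb: list[KnowledgebaseEntry],
) -> list[DruggabilityCall]:
    """Turn cluster co-location into per-sample putative druggability calls.

    Every cohort mutation at a member residue of a sensitive-containing
    cluster (or of a resistant-only, non-overlapping cluster) that the
    knowledgebase itself does not catalogue yields a call at data level
    ``cluster_putative`` and the hotspot3d pseudo-tier; the drug is borrowed
    from the gene's highest-evidence sensitive knowledgebase entry.
    """
    from .spatial_clustering import putative_residue_sets
    from .variant_annotation import match_mutation

    sensitive_residues, resistant_residues = putative_residue_sets(clusters)

    gene_drug: dict[str, tuple[str, int]] = {}
    for e in kb:
        if e.effect is Effect.SENSITIVE:
            cur = gene_drug.get(e.gene)
            if cur is None or e.evidence > cur[1] or (
                e.evidence == cur[1] and e.drug < cur[0]
            ):
                gene_drug[e.gene] = (e.drug, e.evidence)

    calls = []
    for r in records:
        pos = r.residue_position
        if pos is None:
            continue
        in_sensitive = (r.gene, pos) in sensitive_residues
        in_resistant = (r.gene, pos) in resistant_residues
        if not (in_sensitive or in_resistant):
            continue
        if match_mutation(r, index):
            continue  # catalogued mutation, already called upstream
        effect = Effect.SENSITIVE if in_sensitive else Effect.RESISTANT
        calls.append(
            DruggabilityCall(
                sample_id=r.sample_id,
                cancer_type=r.cancer_type,
                gene=r.gene,
                variant_key=r.variant_key,
                data_level="cluster_putative",
                effect=effect,
                specificity=NON_SPECIFIC,
                chosen_drug=gene_drug.get(r.gene, ("", 0))[0],
                chosen_evidence=HOTSPOT3D_TIER,
            )
        )
    return calls


def build_profiles(
    mutation_calls: list[DruggabilityCall],
    outlier_druggability_calls: list[DruggabilityCall],
    putative_calls: list[DruggabilityCall],
    traits: list[SampleTraits],
    profiled_levels: dict[str, frozenset[str]],
    require_complete: bool = True,
) -> list[TumorDruggabilityProfile]:
    """One profile per sample; with ``require_complete`` only samples profiled
    on all of mutation, mrna and protein enter (the multi-omics denominator).
    """
    trait_by_sample = {t.sample_id: t for t in traits}
    all_calls = mutation_calls + outlier_druggability_calls + putative_calls
    calls_by_sample: dict[str, list[DruggabilityCall]] = {}
    for c in all_calls:
        calls_by_sample.setdefault(c.sample_id, []).append(c)

    profiles = []
    for sample, levels in sorted(profiled_levels.items()):
        if require_complete and not {"mutation", "mrna", "protein"} <= levels:
            continue
        trait = trait_by_sample.get(sample)
        if trait is None:
            logger.warning("sample %s has calls but no traits; kept with unknown traits", sample)
        sample_calls = calls_by_sample.get(sample, [])
        sensitive = [c for c in sample_calls if c.effect is Effect.SENSITIVE]
        druggable_levels = frozenset(
            _LEVEL_TO_VARIANT_TYPE[c.data_level]
            for c in sensitive
            if c.data_level != "cluster_putative"
        ) | frozenset(
            "cluster_putative" for c in sensitive if c.data_level == "cluster_putative"
        )
        class_hits: dict[str, set[tuple[str, str]]] = {}
        for c in sensitive:
            for klass in _drug_classes_of(c):
                class_hits.setdefault(klass, set()).add((c.gene, c.data_level))
        best_spec = _best_tier(
            c.chosen_evidence for c in sensitive if c.specificity == SPECIFIC
        )
        best_nonspec = _best_tier(c.chosen_evidence for c in sensitive)
        profiles.append(
            TumorDruggabilityProfile(
                sample_id=sample,
                cancer_type=trait.cancer_type if trait else "UNKNOWN",
                profiled_levels=frozenset(levels),
                calls=sample_calls,
                druggable_levels=druggable_levels,
                drug_class_hits=class_hits,
                best_tier_specific=best_spec,
                best_tier_nonspecific=best_nonspec,
            )
        )
    return profiles


def _best_tier(tiers) -> str | None:
    ranks = [(evidence_rank(t), t) for t in tiers]
    return max(ranks)[1] if ranks else None


def _drug_classes_of(call: DruggabilityCall) -> frozenset[str]:
    classes = getattr(call, "drug_classes", None)
    return classes if classes else frozenset()


def attach_drug_classes(
    calls: list[DruggabilityCall], class_map
) -> list[DruggabilityCall]:
    """Annotate calls with their chosen drug's classes (stored out-of-band)."""
    for c in calls:
        try:
            object.__setattr__(c, "drug_classes", class_map.classes_for(c.chosen_drug))
        except KeyError:
            object.__setattr__(c, "drug_classes", frozenset())
    return calls


def multiomics_fraction(
    profiles: list[TumorDruggabilityProfile],
) -> tuple[float, int, int]:
    """(fraction, numerator, denominator) of complete-profile tumors with
    sensitive biomarkers on >= 2 of {mutation, mrna, protein}."""
    if not profiles:
        raise ValueError("no complete-profile samples: zero denominator")
    core = {"mutation", "mrna", "protein"}
    num = sum(1 for p in profiles if len(p.druggable_levels & core) >= 2)
    return num / len(profiles), num, len(profiles)


def drug_class_sectors(
    profiles: list[TumorDruggabilityProfile], viz_classes: tuple[str, ...]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Sector membership plus cross-class and within-class link tables.

    Returns (sectors, cross_links, within_links).  Calls whose drug class is
    outside the ten visualization classes are excluded from sectors but
    remain in the profiles.
    """
    if len(viz_classes) != 10:
        raise ValueError(f"need exactly 10 visualization classes, got {len(viz_classes)}")
    viz = set(viz_classes)
    sector_rows, cross_rows, within_rows = [], [], []
    for p in profiles:
        hit_classes = {k: v for k, v in p.drug_class_hits.items() if k in viz}
        for klass, pairs in sorted(hit_classes.items()):
            for gene, level in sorted(pairs):
                sector_rows.append(
                    {
                        "drug_class": klass,
                        "sample_id": p.sample_id,
                        "cancer_type": p.cancer_type,
                        "gene": gene,
                        "data_level": level,
                    }
                )
            if len({g for g, _ in pairs}) >= 2:
                within_rows.append(
                    {
                        "sample_id": p.sample_id,
                        "drug_class": klass,
                        "genes": ";".join(sorted({g for g, _ in pairs})),
                    }
                )
        if len(hit_classes) >= 2:
            classes = sorted(hit_classes)
            for a_i in range(len(classes)):
                for b_i in range(a_i + 1, len(classes)):
                    cross_rows.append(
                        {
                            "sample_id": p.sample_id,
                            "class_a": classes[a_i],
                            "class_b": classes[b_i],
                        }
                    )
    sectors = pd.DataFrame(
        sector_rows, columns=["drug_class", "sample_id", "cancer_type", "gene", "data_level"]
    )
    cross = pd.DataFrame(cross_rows, columns=["sample_id", "class_a", "class_b"])
    within = pd.DataFrame(within_rows, columns=["sample_id", "drug_class", "genes"])
    return sectors, cross, within


def cooccurrence_report(
    calls: list[DruggabilityCall],
) -> pd.DataFrame:
    """All unordered within-sample pairs of alterations across data levels.

    Flags sensitive+resistant pairs (potential therapy failure) and
    sensitive+sensitive pairs across distinct drug classes (combination
    candidates).
    """
    by_sample: dict[str, list[DruggabilityCall]] = {}
    for c in calls:
        by_sample.setdefault(c.sample_id, []).append(c)
    rows = []
    for sample, sample_calls in sorted(by_sample.items()):
        uniq = sorted(
            {(c.variant_key, c.data_level): c for c in sample_calls}.values(),
            key=lambda c: (c.variant_key, c.data_level),
        )
        for i in range(len(uniq)):
            for j in range(i + 1, len(uniq)):
                a, b = uniq[i], uniq[j]
                effects = {a.effect, b.effect}
                sens_res = effects == {Effect.SENSITIVE, Effect.RESISTANT}
                classes_a = _drug_classes_of(a)
                classes_b = _drug_classes_of(b)
                combo = (
                    effects == {Effect.SENSITIVE}
                    and bool(classes_a)
                    and bool(classes_b)
                    and not (classes_a & classes_b)
                )
                rows.append(
                    {
                        "sample_id": sample,
                        "cancer_type": a.cancer_type,
                        "alteration_a": f"{a.variant_key}@{a.data_level}",
                        "alteration_b": f"{b.variant_key}@{b.data_level}",
                        "effect_a": a.effect.value,
                        "effect_b": b.effect.value,
                        "sensitive_resistant_pair": sens_res,
                        "combination_candidate": combo,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "cancer_type",
            "alteration_a",
            "alteration_b",
            "effect_a",
            "effect_b",
            "sensitive_resistant_pair",
            "combination_candidate",
        ],
    )


def cumulative_tier_summary(
    calls: list[DruggabilityCall], cohort_samples: list[str]
) -> pd.DataFrame:
    """Cumulative fraction of tumors druggable at >= each tier, per setting.

    Tier order: fda_approved, clinical_trial, case_report, preclinical,
    hotspot3d.  Only sensitive calls count; a sample counts at its best tier.
    """
    n = len(cohort_samples)
    cohort = set(cohort_samples)
    best: dict[tuple[str, str], int] = {}
    for c in calls:
        if c.effect is not Effect.SENSITIVE or c.sample_id not in cohort:
            continue
        rank = evidence_rank(c.chosen_evidence)
        for setting in ("specific", "non_specific"):
            if setting == "specific" and c.specificity != SPECIFIC:
                continue
            key = (setting, c.sample_id)
            best[key] = max(best.get(key, -1), rank)
    rows = []
    for setting in ("specific", "non_specific"):
        for tier in CUMULATIVE_TIERS:
            rank = evidence_rank(tier)
            count = sum(
                1
                for (s, _sample), r in best.items()
                if s == setting and r >= rank
            )
            rows.append(
                {
                    "setting": setting,
                    "tier": tier,
                    "cumulative_fraction": count / n if n else 0.0,
                    "n_samples": n,
                }
            )
    return pd.DataFrame(rows, columns=["setting", "tier", "cumulative_fraction", "n_samples"])


def profiles_to_frame(profiles: list[TumorDruggabilityProfile]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": p.sample_id,
            "cancer_type": p.cancer_type,
            "profiled_levels": ";".join(sorted(p.profiled_levels)),
            "druggable_levels": ";".join(sorted(p.druggable_levels)),
            "n_drug_classes": len(p.drug_class_hits),
            "best_tier_specific": p.best_tier_specific or "",
            "best_tier_nonspecific": p.best_tier_nonspecific or "",
        }
        for p in profiles
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "cancer_type",
            "profiled_levels",
            "druggable_levels",
            "n_drug_classes",
            "best_tier_specific",
            "best_tier_nonspecific",
        ],
    )
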