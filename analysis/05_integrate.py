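#!/usr/bin/env python
"""Integrate mutation, expression, and cluster-derived calls per tumor.

Builds complete-profile tumor druggability profiles, the >= 2-of-3
multi-omics fraction, ten-drug-class sector/link tables, the co-occurrence
report (including sensitive+resistant pairs), and cumulative evidence-tier
curves down to the structure-cluster ("hotspot3d") pseudo-tier.
"""

from pathlib import Path

from druggability import (
    cohort_io,
    expression_outliers,
    integration,
    knowledgebase,
    spatial_clustering,
    synthetic,
    variant_annotation,
)
from druggability.pipeline import kb_residue_labels

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    inputs = RESULTS / "inputs"
    class_map = knowledgebase.DrugClassMap.from_tsv(
        inputs / "drug_classes.tsv", synthetic.DEFAULT_VIZ_CLASSES
    )
    kb = knowledgebase.deduplicate_entries(
        knowledgebase.load_knowledgebase(inputs / "knowledgebase.tsv", class_map)
    )
    index = variant_annotation.KnowledgebaseIndex(kb)
    records, dropped = cohort_io.apply_qc(cohort_io.read_maf(inputs / "cohort.maf.tsv"))
    traits = cohort_io.read_traits(inputs / "traits.tsv")
    cohort = {t.sample_id: t.cancer_type for t in traits if t.sample_id not in dropped}

    mutation_calls = variant_annotation.annotate_cohort(records, index)

    outlier_calls = []
    matrices = {}
    for level in ("mrna", "protein"):
        matrices[level] = cohort_io.read_expression_matrix(
            inputs / f"expression_{level}.tsv", level=level, mrna_log2=False
        )
        outlier_calls += expression_outliers.call_outliers(
            matrices[level], kb, sample_cancer_types=cohort, exclude_cancer_types=("LAML",)
        )
    expr_calls = integration.expression_calls_to_druggability(outlier_calls, kb, cohort)

    dsets = spatial_clustering.read_distance_tsv(inputs / "distances.tsv")
    recurrence: dict[str, dict[int, int]] = {}
    for r in records:
        pos = r.residue_position
        if pos is not None:
            recurrence.setdefault(r.gene, {}).setdefault(pos, 0)
            recurrence[r.gene][pos] += 1
    clusters = []
    for (sid, gene), dset in sorted(dsets.items()):
        mutated = sorted(
            set(recurrence.get(gene, {})) & {i for pair in dset.distances for i in pair}
        )
        if len(mutated) >= 2:
            clusters += spatial_clustering.cluster_structure(
                dset, mutated, recurrence.get(gene, {}),
                kb_labels=kb_residue_labels(kb, gene),
            )
    putative_calls = integration.putative_calls_from_clusters(clusters, records, index, kb)

    integration.attach_drug_classes(mutation_calls + expr_calls + putative_calls, class_map)
    maf_samples = {r.sample_id for r in records}
    profiled = {
        s: frozenset(
            (["mutation"] if s in maf_samples else [])
            + [lvl for lvl, m in matrices.items() if s in set(m.values.columns)]
        )
        for s in cohort
    }
    profiles = integration.build_profiles(
        mutation_calls, expr_calls, putative_calls, traits, profiled
    )
    frac, num, den = integration.multiomics_fraction(profiles)
    sectors, cross, within = integration.drug_class_sectors(
        profiles, synthetic.DEFAULT_VIZ_CLASSES
    )
    cooc = integration.cooccurrence_report(mutation_calls + expr_calls + putative_calls)
    cumulative = integration.cumulative_tier_summary(
        mutation_calls + expr_calls + putative_calls, sorted(cohort)
    )

    integration.profiles_to_frame(profiles).to_csv(RESULTS / "profiles.tsv", sep="\t", index=False)
    sectors.to_csv(RESULTS / "sectors.tsv", sep="\t", index=False)
    cross.to_csv(RESULTS / "cross_links.tsv", sep="\t", index=False)
    within.to_csv(RESULTS / "within_links.tsv", sep="\t", index=False)
    cooc.to_csv(RESULTS / "cooccurrence.tsv", sep="\t", index=False)
    cumulative.to_csv(RESULTS / "cumulative_tiers.tsv", sep="\t", index=False)

    print(f"{num}/{den} complete-profile tumors ({100 * frac:.1f}%) are druggable on >= 2 data levels")
    n_sr = int(cooc.sensitive_resistant_pair.sum())
    print(f"{len(cross)} cross-class links, {len(within)} within-class links, "
          f"{n_sr} sensitive+resistant co-occurrences")
    print(f"tables written under {RESULTS}")


if __name__ == "__main__":
    main()
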