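#!/usr/bin/env python
"""QC the cohort and match mutations against the knowledgebase.

Reads results/inputs/, applies the duplicate-sample / large-indel /
common-variant filters, resolves per-mutation druggability calls, and
writes the calls plus the per-cancer-type cumulative evidence-tier table.
"""

from pathlib import Path

from druggability import cohort_io, knowledgebase, variant_annotation

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    inputs = RESULTS / "inputs"
    class_map = knowledgebase.DrugClassMap.from_tsv(inputs / "drug_classes.tsv")
    kb = knowledgebase.deduplicate_entries(
        knowledgebase.load_knowledgebase(inputs / "knowledgebase.tsv", class_map)
    )
    records = cohort_io.read_maf(inputs / "cohort.maf.tsv")
    n_raw = len(records)
    records, dropped = cohort_io.apply_qc(records)
    traits = cohort_io.read_traits(inputs / "traits.tsv")
    cohort = {t.sample_id: t.cancer_type for t in traits if t.sample_id not in dropped}

    index = variant_annotation.KnowledgebaseIndex(kb)
    calls = variant_annotation.annotate_cohort(records, index)
    tiers = variant_annotation.summarize_mutation_druggability(calls, cohort)

    variant_annotation.calls_to_frame(calls).to_csv(
        RESULTS / "mutation_calls.tsv", sep="\t", index=False
    )
    tiers.to_csv(RESULTS / "mutation_tiers.tsv", sep="\t", index=False)

    n_druggable = len({c.sample_id for c in calls})
    print(f"QC: {n_raw} -> {len(records)} mutation records; dropped samples: {dropped}")
    print(f"{len(calls)} druggability calls across {n_druggable} tumors "
          f"({100 * n_druggable / len(cohort):.1f}% of the cohort)")
    print(f"tables written to {RESULTS}/mutation_calls.tsv and mutation_tiers.tsv")


if __name__ == "__main__":
    main()
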