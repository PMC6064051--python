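#!/usr/bin/env python
"""Druggability enrichment across sex and race.

Builds the per-(cancer type, druggable gene) log2-odds matrix between the
two largest trait categories, applies the eligibility thresholds, and runs
two-sided Fisher exact tests with Benjamini-Hochberg FDR at 0.05.
"""

from pathlib import Path

import pandas as pd

from druggability import cohort_io, demographics, knowledgebase, variant_annotation

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    inputs = RESULTS / "inputs"
    class_map = knowledgebase.DrugClassMap.from_tsv(inputs / "drug_classes.tsv")
    kb = knowledgebase.deduplicate_entries(
        knowledgebase.load_knowledgebase(inputs / "knowledgebase.tsv", class_map)
    )
    index = variant_annotation.KnowledgebaseIndex(kb)
    records, dropped = cohort_io.apply_qc(cohort_io.read_maf(inputs / "cohort.maf.tsv"))
    traits = cohort_io.read_traits(inputs / "traits.tsv")
    calls = variant_annotation.annotate_cohort(records, index)

    for trait in ("sex", "race"):
        cells = demographics.enrichment_tests(
            demographics.build_demographic_matrix(calls, traits, trait)
        )
        frame = demographics.cells_to_frame(cells)
        frame.to_csv(RESULTS / f"demographics_{trait}.tsv", sep="\t", index=False)
        sig = frame[frame.significant]
        print(f"{trait}: {len(frame)} matrix cells, {len(sig)} significant after FDR")
        for row in sig.itertuples(index=False):
            print(f"  {row.cancer_type} {row.feature}: log-odds {row.log_odds:+.2f} "
                  f"({row.trait_a} {row.dA}/{row.nA} vs {row.trait_b} {row.dB}/{row.nB}, "
                  f"q = {row.fdr_q:.2g})")
    print(f"tables written under {RESULTS}")


if __name__ == "__main__":
    main()
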