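#!/usr/bin/env python
"""Call druggable expression outliers at the mRNA and protein levels.

Quartiles are taken across the pan-cancer cohort (acute myeloid leukemia
excluded); a value more than 1.5 IQRs past the fence in the knowledgebase's
direction is an outlier, ranked within its tumor sample.
"""

from pathlib import Path

from druggability import cohort_io, expression_outliers, knowledgebase

RESULTS = Path(__file__).resolve().parent.parent / "results"
EXCLUDED = ("LAML",)


def main() -> None:
    inputs = RESULTS / "inputs"
    class_map = knowledgebase.DrugClassMap.from_tsv(inputs / "drug_classes.tsv")
    kb = knowledgebase.deduplicate_entries(
        knowledgebase.load_knowledgebase(inputs / "knowledgebase.tsv", class_map)
    )
    traits = cohort_io.read_traits(inputs / "traits.tsv")
    ctypes = {t.sample_id: t.cancer_type for t in traits}

    all_calls = []
    for level in ("mrna", "protein"):
        matrix = cohort_io.read_expression_matrix(
            inputs / f"expression_{level}.tsv", level=level, mrna_log2=False
        )
        calls = expression_outliers.rank_within_sample(
            expression_outliers.call_outliers(
                matrix, kb, sample_cancer_types=ctypes, exclude_cancer_types=EXCLUDED
            )
        )
        n_tumors = len({c.sample_id for c in calls})
        print(f"{level}: {len(calls)} outlier calls in {n_tumors} tumors")
        all_calls.extend(calls)

    expression_outliers.outlier_calls_to_frame(all_calls).to_csv(
        RESULTS / "expression_outliers.tsv", sep="\t", index=False
    )
    print(f"table written to {RESULTS}/expression_outliers.tsv")


if __name__ == "__main__":
    main()
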