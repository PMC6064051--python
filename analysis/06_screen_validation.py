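#!/usr/bin/env python
"""Validate biomarkers against the cell-line drug screen.

Compares LN(IC50) of knowledgebase-mutant cell lines with the full
background (Mann-Whitney, globally and per variant/drug combination with
>= 5 mutant lines), then regresses LN(IC50) on per-probe expression outlier
scores and reports genes validated by a significant negative slope.
"""

from pathlib import Path

import pandas as pd

from druggability import cohort_io, knowledgebase, screen_validation, variant_annotation
from druggability.pipeline import probe_outlier_scores

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    inputs = RESULTS / "inputs"
    class_map = knowledgebase.DrugClassMap.from_tsv(inputs / "drug_classes.tsv")
    kb = knowledgebase.deduplicate_entries(
        knowledgebase.load_knowledgebase(inputs / "knowledgebase.tsv", class_map)
    )
    index = variant_annotation.KnowledgebaseIndex(kb)
    screen = screen_validation.read_screen(inputs / "screen.tsv")
    cl_records = cohort_io.read_maf(inputs / "cell_lines.maf.tsv")
    map_table = pd.read_csv(inputs / "drug_map.tsv", sep="\t", dtype=str)
    drug_map, unmapped = screen_validation.map_drugs(kb, map_table)
    if unmapped:
        print(f"unmapped knowledgebase drugs: {unmapped}")

    rows = []
    for setting in ("specific", "non_specific"):
        global_result, combos = screen_validation.mutation_sensitivity_test(
            screen, index, cl_records, drug_map, setting=setting
        )
        if global_result:
            print(f"{setting}: global Mann-Whitney p = {global_result.p_value:.3g} "
                  f"(n = {global_result.n_group} mutant measurements)")
            rows.append(global_result)
        rows.extend(combos)
        n_sig = sum(1 for c in combos if c.p_value < 0.05)
        print(f"{setting}: {n_sig}/{len(combos)} variant/drug combinations significant")
    pd.DataFrame(
        [
            {"label": r.label, "n_group": r.n_group, "n_background": r.n_background,
             "U": r.u_statistic, "p_value": r.p_value}
            for r in rows
        ]
    ).to_csv(RESULTS / "screen_mannwhitney.tsv", sep="\t", index=False)

    expr = pd.read_csv(inputs / "cell_line_expression.tsv", sep="\t", index_col=0)
    probe_map = pd.read_csv(inputs / "probe_map.tsv", sep="\t", dtype=str)
    scores = probe_outlier_scores(expr)
    gene_drugs: dict[str, set[str]] = {}
    for gene in probe_map.gene.unique():
        ids = set()
        for e in kb:
            if e.gene == gene:
                ids |= drug_map.get(e.drug, set())
        if ids:
            gene_drugs[gene] = ids
    regressions, validated = screen_validation.expression_sensitivity_regression(
        scores, screen, probe_map, gene_drugs
    )
    pd.DataFrame(
        [
            {"probe_id": r.probe_id, "gene": r.gene, "drug_id": r.drug_id,
             "slope": r.slope, "intercept": r.intercept, "p_value": r.p_value,
             "n": r.n, "significant": r.significant}
            for r in regressions
        ]
    ).to_csv(RESULTS / "screen_regressions.tsv", sep="\t", index=False)
    print(f"{len(regressions)} probe/drug regressions; validated genes: {validated}")
    print(f"tables written under {RESULTS}")


if __name__ == "__main__":
    main()
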