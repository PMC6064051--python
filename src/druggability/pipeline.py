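"""End-to-end pipeline: simulate -> annotate -> outliers -> cluster ->
integrate -> screen-validate -> demographics.

Every stage writes its canonical TSV under the output directory with fixed
float formatting, so two runs with the same seed produce byte-identical
trees.  The returned summary dict carries the headline numbers each stage
computed.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import (
    cohort_io,
    demographics,
    expression_outliers,
    integration,
    knowledgebase,
    screen_validation,
    spatial_clustering,
    synthetic,
    variant_annotation,
)
from .knowledgebase import Effect, VariantClass
from .synthetic import FLOAT_FORMAT, SimulationConfig

EXCLUDED_EXPRESSION_TYPES = ("LAML",)


def kb_residue_labels(entries, gene: str) -> dict[int, str]:
    """Known sensitive/resistant residues of a gene for cluster labelling."""
    labels: dict[int, str] = {}
    for e in entries:
        if e.gene != gene or e.parsed.position is None:
            continue
        if e.variant_class not in (
            VariantClass.MISSENSE_EXACT,
            VariantClass.MISSENSE_POSITION,
            VariantClass.INFRAME_INDEL_EXACT,
        ):
            continue
        tag = (
            spatial_clustering.LABEL_KNOWN_SENSITIVE
            if e.effect is Effect.SENSITIVE
            else spatial_clustering.LABEL_KNOWN_RESISTANT
        )
        prev = labels.get(e.parsed.position)
        if prev != spatial_clustering.LABEL_KNOWN_SENSITIVE:
            labels[e.parsed.position] = tag
    return labels


def run_pipeline(config: SimulationConfig, outdir) -> dict:
    """Run every stage on a synthetic cohort; returns the summary numbers."""
    outdir = Path(outdir)
    (outdir / "inputs").mkdir(parents=True, exist_ok=True)

    # ---- simulate -----------------------------------------------------
    cohort = synthetic.simulate_cohort(config)
    structures = synthetic.simulate_structures(config)
    screen_sim = synthetic.simulate_screen(config)
    cohort.write(outdir / "inputs")
    screen_sim.write(outdir / "inputs")
    synthetic.structures_to_distance_tsv(structures, outdir / "inputs" / "distances.tsv")

    # ---- knowledgebase ------------------------------------------------
    class_map = knowledgebase.DrugClassMap.from_tsv(
        outdir / "inputs" / "drug_classes.tsv", synthetic.DEFAULT_VIZ_CLASSES
    )
    kb = knowledgebase.deduplicate_entries(
        knowledgebase.load_knowledgebase(outdir / "inputs" / "knowledgebase.tsv", class_map)
    )
    index = variant_annotation.KnowledgebaseIndex(kb)

    # ---- cohort QC ----------------------------------------------------
    records = cohort_io.read_maf(outdir / "inputs" / "cohort.maf.tsv")
    records, dropped = cohort_io.apply_qc(records)
    traits = cohort_io.read_traits(outdir / "inputs" / "traits.tsv")
    cohort_samples = {
        t.sample_id: t.cancer_type for t in traits if t.sample_id not in dropped
    }

    # ---- mutation annotation -----------------------------------------
    mutation_calls = variant_annotation.annotate_cohort(records, index)
    tier_table = variant_annotation.summarize_mutation_druggability(
        mutation_calls, cohort_samples
    )
    _write(variant_annotation.calls_to_frame(mutation_calls), outdir / "mutation_calls.tsv")
    _write(tier_table, outdir / "mutation_tiers.tsv")

    # ---- expression outliers -----------------------------------------
    outlier_calls = []
    for level in ("mrna", "protein"):
        matrix = cohort_io.read_expression_matrix(
            outdir / "inputs" / f"expression_{level}.tsv",
            level=level,
            mrna_log2=False,  # synthetic matrices are generated on log scale
        )
        calls = expression_outliers.call_outliers(
            matrix,
            kb,
            sample_cancer_types=cohort_samples,
            exclude_cancer_types=EXCLUDED_EXPRESSION_TYPES,
        )
        outlier_calls.extend(expression_outliers.rank_within_sample(calls))
    _write(
        expression_outliers.outlier_calls_to_frame(outlier_calls),
        outdir / "expression_outliers.tsv",
    )

    # ---- spatial clustering ------------------------------------------
    recurrence: dict[str, dict[int, int]] = {}
    residues_by_gene: dict[str, set[int]] = {}
    for r in records:
        pos = r.residue_position
        if pos is None:
            continue
        recurrence.setdefault(r.gene, {})
        recurrence[r.gene][pos] = recurrence[r.gene].get(pos, 0) + 1
        residues_by_gene.setdefault(r.gene, set()).add(pos)
    clusters = []
    for s in structures:
        mutated = sorted(
            residues_by_gene.get(s.gene, set()) & set(s.coordinates)
        )
        if len(mutated) < 2:
            continue
        dset = spatial_clustering.distance_set_from_coordinates(
            s.structure_id, s.gene, s.coordinates
        )
        clusters.extend(
            spatial_clustering.cluster_structure(
                dset,
                mutated,
                recurrence.get(s.gene, {}),
                kb_labels=kb_residue_labels(kb, s.gene),
            )
        )
    putative_table = spatial_clustering.propagate_labels(clusters)
    _write(putative_table, outdir / "clusters.tsv")
    putative_calls = integration.putative_calls_from_clusters(clusters, records, index, kb)

    # ---- integration --------------------------------------------------
    expr_calls = integration.expression_calls_to_druggability(
        outlier_calls, kb, cohort_samples
    )
    integration.attach_drug_classes(mutation_calls + expr_calls + putative_calls, class_map)
    profiled: dict[str, frozenset] = {}
    maf_samples = {r.sample_id for r in records}
    level_samples = {
        "mrna": set(cohort.expression["mrna"].columns),
        "protein": set(cohort.expression["protein"].columns),
    }
    for sample in cohort_samples:
        levels = set()
        if sample in maf_samples:
            levels.add("mutation")
        for level, present in level_samples.items():
            if sample in present:
                levels.add(level)
        profiled[sample] = frozenset(levels)
    profiles = integration.build_profiles(
        mutation_calls, expr_calls, putative_calls, traits, profiled
    )
    frac, n_multi, n_complete = integration.multiomics_fraction(profiles)
    sectors, cross_links, within_links = integration.drug_class_sectors(
        profiles, synthetic.DEFAULT_VIZ_CLASSES
    )
    cooccurrence = integration.cooccurrence_report(
        mutation_calls + expr_calls + putative_calls
    )
    cumulative = integration.cumulative_tier_summary(
        mutation_calls + expr_calls + putative_calls, sorted(cohort_samples)
    )
    _write(integration.profiles_to_frame(profiles), outdir / "profiles.tsv")
    _write(sectors, outdir / "sectors.tsv")
    _write(cross_links, outdir / "cross_links.tsv")
    _write(within_links, outdir / "within_links.tsv")
    _write(cooccurrence, outdir / "cooccurrence.tsv")
    _write(cumulative, outdir / "cumulative_tiers.tsv")

    # ---- screen validation -------------------------------------------
    screen = screen_validation.read_screen(outdir / "inputs" / "screen.tsv")
    cl_records = cohort_io.read_maf(outdir / "inputs" / "cell_lines.maf.tsv")
    drug_map, _unmapped = screen_validation.map_drugs(
        kb, screen_sim.drug_map_table
    )
    global_results = {}
    combo_counts = {}
    for setting in ("specific", "non_specific"):
        g, combos = screen_validation.mutation_sensitivity_test(
            screen, index, cl_records, drug_map, setting=setting
        )
        global_results[setting] = g
        combo_counts[setting] = sum(
            1 for c in combos if c.p_value < screen_validation.SIGNIFICANCE_ALPHA
        )
    expr_matrix = pd.read_csv(
        outdir / "inputs" / "cell_line_expression.tsv", sep="\t", index_col=0
    )
    scores = probe_outlier_scores(expr_matrix)
    gene_drugs = {
        gene: drug_map.get(drug, set())
        for gene, (drug, _n) in config.regression_genes.items()
    }
    regressions, validated_genes = screen_validation.expression_sensitivity_regression(
        scores, screen, screen_sim.probe_map, gene_drugs
    )
    reg_frame = pd.DataFrame(
        [
            {
                "probe_id": r.probe_id,
                "gene": r.gene,
                "drug_id": r.drug_id,
                "slope": r.slope,
                "intercept": r.intercept,
                "p_value": r.p_value,
                "n": r.n,
                "significant": r.significant,
            }
            for r in regressions
        ]
    )
    _write(reg_frame, outdir / "screen_regressions.tsv")

    # ---- demographics -------------------------------------------------
    demo_counts = {}
    for trait in ("sex", "race"):
        cells = demographics.enrichment_tests(
            demographics.build_demographic_matrix(
                mutation_calls + expr_calls, traits, trait
            )
        )
        _write(demographics.cells_to_frame(cells), outdir / f"demographics_{trait}.tsv")
        demo_counts[trait] = sum(1 for c in cells if c.significant)

    # ---- summary ------------------------------------------------------
    def tier_fraction(setting: str, tier: str) -> float:
        sub = cumulative[(cumulative.setting == setting) & (cumulative.tier == tier)]
        return float(sub.cumulative_fraction.iloc[0])

    summary = {
        "n_cohort_samples": len(cohort_samples),
        "n_qc_dropped_samples": len(dropped),
        "n_mutation_calls": len(mutation_calls),
        "fraction_specific_fda": tier_fraction("specific", "fda_approved"),
        "fraction_specific_preclinical": tier_fraction("specific", "preclinical"),
        "fraction_nonspecific_fda": tier_fraction("non_specific", "fda_approved"),
        "fraction_nonspecific_hotspot3d": tier_fraction("non_specific", "hotspot3d"),
        "n_outlier_calls": sum(1 for c in outlier_calls if c.is_outlier),
        "n_clusters": len(clusters),
        "n_putative_mutations": len({c.variant_key for c in putative_calls}),
        "multiomics_fraction": frac,
        "n_multiomics_druggable": n_multi,
        "n_complete_profiles": n_complete,
        "screen_global_p_specific": (
            global_results["specific"].p_value if global_results["specific"] else None
        ),
        "screen_global_p_nonspecific": (
            global_results["non_specific"].p_value
            if global_results["non_specific"]
            else None
        ),
        "n_significant_combinations_nonspecific": combo_counts["non_specific"],
        "n_regressions": len(regressions),
        "n_validated_genes": len(validated_genes),
        "n_significant_demographic_cells_sex": demo_counts["sex"],
        "n_significant_demographic_cells_race": demo_counts["race"],
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def probe_outlier_scores(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-probe outlier scores over the cell-line panel (high direction)."""
    rows = {}
    for probe in expr.index:
        v = expr.loc[probe].to_numpy(dtype=float)
        q1, q3, iqr = expression_outliers.cohort_quartiles(v)
        rows[probe] = (expr.loc[probe] - q3) / iqr
    out = pd.DataFrame(rows).T
    out.index.name = "probe_id"
    return out


def _write(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
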