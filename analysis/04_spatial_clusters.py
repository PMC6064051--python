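#!/usr/bin/env python
"""Proximity-cluster cohort mutations on protein structures.

Builds the significant-pair graph (empirical p < 0.05 and distance < 5 A),
focuses single-link clusters within a 5 A graph radius of the centroid,
recurses on the remainder, and nominates uncatalogued mutations that
co-cluster with known drug-sensitive (or resistant) mutations.
"""

from pathlib import Path

from druggability import cohort_io, knowledgebase, spatial_clustering, variant_annotation
from druggability.pipeline import kb_residue_labels

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    inputs = RESULTS / "inputs"
    class_map = knowledgebase.DrugClassMap.from_tsv(inputs / "drug_classes.tsv")
    kb = knowledgebase.deduplicate_entries(
        knowledgebase.load_knowledgebase(inputs / "knowledgebase.tsv", class_map)
    )
    records, _ = cohort_io.apply_qc(cohort_io.read_maf(inputs / "cohort.maf.tsv"))
    dsets = spatial_clustering.read_distance_tsv(inputs / "distances.tsv")

    recurrence: dict[str, dict[int, int]] = {}
    for r in records:
        pos = r.residue_position
        if pos is not None:
            recurrence.setdefault(r.gene, {}).setdefault(pos, 0)
            recurrence[r.gene][pos] += 1

    clusters = []
    for (sid, gene), dset in sorted(dsets.items()):
        structure_residues = {i for pair in dset.distances for i in pair}
        mutated = sorted(set(recurrence.get(gene, {})) & structure_residues)
        if len(mutated) < 2:
            continue
        clusters.extend(
            spatial_clustering.cluster_structure(
                dset, mutated, recurrence.get(gene, {}),
                kb_labels=kb_residue_labels(kb, gene),
            )
        )

    table = spatial_clustering.propagate_labels(clusters)
    table.to_csv(RESULTS / "clusters.tsv", sep="\t", index=False)
    n_putative = (table.putative_call != "").sum()
    for c in clusters:
        known = [m for m, l in c.labels.items() if l != "putative"]
        print(f"cluster {c.cluster_id}: members {c.members}, centroid {c.centroid}, "
              f"known residues {known}")
    print(f"{len(clusters)} clusters; {n_putative} putative residues; "
          f"table written to {RESULTS}/clusters.tsv")


if __name__ == "__main__":
    main()
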