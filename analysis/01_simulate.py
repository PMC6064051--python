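#!/usr/bin/env python
"""Generate the synthetic study inputs with known ground truth.

Writes the knowledgebase, drug-class map, cohort MAF, traits, expression
matrices, residue distance table, cell-line screen, and every truth table
under results/inputs/.
"""

from pathlib import Path

from druggability import synthetic

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 0) -> None:
    config = synthetic.SimulationConfig(seed=seed)
    outdir = RESULTS / "inputs"
    cohort = synthetic.simulate_cohort(config)
    cohort.write(outdir)
    synthetic.simulate_screen(config).write(outdir)
    synthetic.structures_to_distance_tsv(
        synthetic.simulate_structures(config), outdir / "distances.tsv"
    )
    n_samples = cohort.traits.shape[0]
    print(f"simulated {n_samples} tumors across {len(config.cancer_types)} cancer types")
    print(f"planted {len(cohort.truth_druggable)} druggable mutations, "
          f"{len(cohort.truth_outliers)} expression outliers, "
          f"{len(cohort.truth_duplicates)} duplicate/identical sample pairs")
    print(f"inputs written to {outdir}")


if __name__ == "__main__":
    main()
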