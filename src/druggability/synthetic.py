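"""Synthetic cohort, structure, and drug-screen generator with ground truth.

Every input the pipeline consumes — knowledgebase TSV, MAF-dialect mutation
table, expression matrices, clinical traits, residue distance tables, and a
cell-line screen — is generated here with planted, recorded effects:
druggable mutations at set per-cancer-type frequencies, expression values
shifted beyond the Tukey fence by a chosen multiple of the IQR, mutational
hotspots packed inside a small 3D ball with distant decoy residues, LN(IC50)
shifts for lines carrying sensitive mutations, and linear expression-response
relationships.  Truth tables make every stage scorable without re-deriving
truth.

All randomness flows from one integer seed through numpy's PCG64 generator
(``numpy.random.default_rng``); a fixed seed reproduces every file byte for
byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_io import ExpressionMatrix
from .expression_outliers import cohort_quartiles

FLOAT_FORMAT = "%.6g"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: canonical drug -> class lookup for the default scenario
DEFAULT_DRUG_CLASSES = {
    "dabrafenib": "B-Raf inhibitor",
    "vemurafenib": "B-Raf inhibitor",
    "trametinib": "MEK inhibitor",
    "binimetinib": "MEK inhibitor",
    "erlotinib": "EGFR inhibitor",
    "gefitinib": "EGFR inhibitor",
    "alpelisib": "PI3K inhibitor",
    "capivasertib": "AKT inhibitor",
    "lapatinib": "HER2 inhibitor",
    "tamoxifen": "Hormone therapy",
    "enzalutamide": "Hormone therapy",
    "palbociclib": "CDK inhibitor",
    "nutlin-3a": "MDM2 inhibitor",
    "rovalpituzumab": "Antibody-drug conjugate",
    "sorafenib": "Multikinase inhibitor",
}

DEFAULT_VIZ_CLASSES = (
    "B-Raf inhibitor",
    "MEK inhibitor",
    "EGFR inhibitor",
    "PI3K inhibitor",
    "AKT inhibitor",
    "HER2 inhibitor",
    "Hormone therapy",
    "CDK inhibitor",
    "MDM2 inhibitor",
    "Multikinase inhibitor",
)

#: knowledgebase rows: gene, class, spec, tumor type, effect, evidence, drug
DEFAULT_KB_ROWS = [
    ("BRAF", "missense_exact", "V600E", "SKCM", "sensitive", "fda_approved", "dabrafenib"),
    ("BRAF", "missense_exact", "V600E", "SKCM", "sensitive", "preclinical", "dabrafenib"),
    ("BRAF", "missense_exact", "V600E", "THCA", "sensitive", "clinical_trial", "vemurafenib"),
    ("BRAF", "missense_position", "V600", "SKCM", "sensitive", "clinical_trial", "trametinib"),
    ("NRAS", "missense_position", "Q61", "SKCM", "sensitive", "preclinical", "binimetinib"),
    ("EGFR", "inframe_indel_range", "729-761:inframe_del", "LUAD", "sensitive", "fda_approved", "erlotinib"),
    ("PIK3CA", "missense_exact", "E545K", "COADREAD", "sensitive", "clinical_trial", "alpelisib"),
    ("KRAS", "missense_exact", "G12D", "UNSPECIFIED", "sensitive", "preclinical", "trametinib"),
    ("AKT1", "missense_exact", "E17K", "BRCA", "sensitive", "case_report", "capivasertib"),
    ("RAC1", "missense_exact", "P29S", "SKCM", "resistant", "preclinical", "dabrafenib"),
    ("TP53", "nonsense", "*", "UNSPECIFIED", "sensitive", "preclinical", "sorafenib"),
    ("ERBB2", "expression_high", "", "BRCA", "sensitive", "fda_approved", "lapatinib"),
    ("ESR1", "expression_high", "", "BRCA", "sensitive", "fda_approved", "tamoxifen"),
    ("PGR", "expression_high", "", "BRCA", "sensitive", "clinical_trial", "tamoxifen"),
    ("EGFR", "expression_high", "", "LUAD", "sensitive", "clinical_trial", "erlotinib"),
    ("MDM2", "expression_high", "", "UNSPECIFIED", "sensitive", "preclinical", "nutlin-3a"),
    ("DLL3", "expression_high", "", "GBM", "sensitive", "clinical_trial", "rovalpituzumab"),
    ("AKT3", "expression_high", "", "UNSPECIFIED", "sensitive", "preclinical", "capivasertib"),
]

#: planted somatic mutation frequencies: (cancer type, gene, HGVSp-short,
#: MAF Variant_Classification, indel bp) -> frequency among that type
DEFAULT_MUTATION_FREQS = {
    ("SKCM", "BRAF", "V600E", "Missense_Mutation", 0): 0.40,
    ("SKCM", "BRAF", "V600K", "Missense_Mutation", 0): 0.05,
    ("SKCM", "NRAS", "Q61K", "Missense_Mutation", 0): 0.12,
    ("SKCM", "RAC1", "P29S", "Missense_Mutation", 0): 0.05,
    ("SKCM", "BRAF", "K601E", "Missense_Mutation", 0): 0.03,
    ("SKCM", "BRAF", "W604L", "Missense_Mutation", 0): 0.02,
    ("SKCM", "BRAF", "G596D", "Missense_Mutation", 0): 0.02,
    ("SKCM", "RAC1", "P29L", "Missense_Mutation", 0): 0.02,
    ("SKCM", "RAC1", "C18Y", "Missense_Mutation", 0): 0.02,
    ("THCA", "BRAF", "V600E", "Missense_Mutation", 0): 0.60,
    ("COADREAD", "PIK3CA", "E545K", "Missense_Mutation", 0): 0.052,
    ("COADREAD", "KRAS", "G12D", "Missense_Mutation", 0): 0.20,
    ("COADREAD", "BRAF", "V600E", "Missense_Mutation", 0): 0.076,
    ("COADREAD", "TP53", "R306*", "Nonsense_Mutation", 0): 0.10,
    ("LUAD", "EGFR", "E746_A750del", "In_Frame_Del", 15): 0.10,
    ("LUAD", "KRAS", "G12D", "Missense_Mutation", 0): 0.15,
    ("BRCA", "AKT1", "E17K", "Missense_Mutation", 0): 0.04,
    ("BRCA", "PIK3CA", "E545K", "Missense_Mutation", 0): 0.10,
    ("GBM", "EGFR", "A289V", "Missense_Mutation", 0): 0.10,
}

#: hotspot geometry per gene: (hotspot residue groups, extra mutated decoy
#: residues far away, number of unmutated decoys)
DEFAULT_STRUCTURES = {
    "BRAF": {"hotspots": [[596, 600, 601, 604]], "far_mutated": [665], "n_decoys": 40},
    "RAC1": {"hotspots": [[18, 29, 31]], "far_mutated": [], "n_decoys": 40},
}

DEFAULT_EXPRESSION_FEATURES = {
    "mrna": ["ERBB2", "ESR1", "PGR", "EGFR", "MDM2", "DLL3", "AKT3"],
    "protein": ["ERBB2", "ESR1", "EGFR", "AKT3", "EGFR:pY1068", "ESR1:pS118"],
}
N_BACKGROUND_GENES = 12  # non-druggable expression rows per matrix

DEFAULT_SCREEN_MUTATIONS = {
    # variant -> (gene, protein change, n mutant lines, drug name)
    "BRAF:V600E": ("BRAF", "V600E", 14, "dabrafenib"),
    "PIK3CA:E545K": ("PIK3CA", "E545K", 10, "alpelisib"),
}

DEFAULT_REGRESSION_GENES = {
    # gene -> (drug name, probes)
    "MDM2": ("nutlin-3a", 3),
    "EGFR": ("erlotinib", 2),
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the statistical structure the pipeline assumes: a
    melanoma-dominated BRAF V600E scenario (40% of SKCM, 60% of THCA),
    expression outliers shifted 3 IQRs past the upper fence in ~3% of
    covered samples, 4-Angstrom mutational hotspots against 15-Angstrom
    decoy spacing, a 2-unit LN(IC50) drop in sensitive mutant lines, and a
    -0.8 expression-response slope.
    """

    seed: int = 0
    cancer_types: tuple[str, ...] = (
        "SKCM",
        "THCA",
        "COADREAD",
        "LUAD",
        "BRCA",
        "GBM",
        "LAML",
    )
    n_samples_per_type: int = 150
    kb_rows: list = field(default_factory=lambda: list(DEFAULT_KB_ROWS))
    mutation_freqs: dict = field(default_factory=lambda: dict(DEFAULT_MUTATION_FREQS))
    passenger_rate: float = 8.0  # Poisson mean of passenger mutations/sample
    n_duplicate_pairs: int = 2
    duplicate_concordance: float = 0.8
    plant_small_identical_pair: bool = True
    common_variant_rate: float = 0.02  # fraction of samples given a common SNP
    common_variant_af: float = 0.002
    n_large_indels: int = 3
    large_indel_bp: int = 150
    n_boundary_indels: int = 2  # exactly 100 bp, must survive QC
    # expression
    expression_features: dict = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_EXPRESSION_FEATURES.items()}
    )
    mrna_mu: float = 8.0
    mrna_sigma: float = 1.0
    protein_sigma: float = 1.0
    mrna_coverage: float = 0.9
    protein_coverage: float = 0.8
    protein_missing_rate: float = 0.10
    outlier_fraction: float = 0.03
    outlier_shift_iqr: float = 3.0
    heavy_tails: bool = False  # t(3) baseline instead of normal
    # structures
    structures: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_STRUCTURES.items()})
    hotspot_ball_radius: float = 4.0
    decoy_spacing: float = 15.0
    # screen
    n_cell_lines: int = 60
    screen_mu: float = 3.0
    screen_sigma: float = 1.0
    screen_delta: float = 2.0  # LN(IC50) drop in sensitive mutant lines
    screen_beta: float = -0.8  # expression-response slope
    screen_noise: float = 0.5
    screen_mutations: dict = field(default_factory=lambda: dict(DEFAULT_SCREEN_MUTATIONS))
    regression_genes: dict = field(default_factory=lambda: dict(DEFAULT_REGRESSION_GENES))
    # traits
    sex_probs: dict = field(default_factory=lambda: {"male": 0.5, "female": 0.5})
    race_probs: dict = field(
        default_factory=lambda: {"white": 0.6, "black": 0.2, "asian": 0.15, "other": 0.05}
    )
    #: gene -> (trait, favoured category, odds) enrichment of druggable
    #: mutation carriage
    enrichment: dict = field(
        default_factory=lambda: {"BRAF": ("sex", "male", 4.0)}
    )

    def validate(self) -> None:
        for probs in (self.sex_probs, self.race_probs):
            if not all(0 <= p <= 1 for p in probs.values()):
                raise ValueError("category probabilities must lie in [0, 1]")
            if abs(sum(probs.values()) - 1) > 1e-9:
                raise ValueError("category probabilities must sum to 1")
        for f in self.mutation_freqs.values():
            if not 0 <= f <= 1:
                raise ValueError("mutation frequencies must lie in [0, 1]")
        for gene, spec in self.structures.items():
            for group in spec["hotspots"]:
                if len(group) > 2 + spec["n_decoys"] + len(group):
                    raise ValueError(f"hotspot larger than structure for {gene}")
        if self.hotspot_ball_radius >= self.decoy_spacing:
            raise ValueError("decoy spacing must exceed the hotspot ball radius")


@dataclass
class SimulatedCohort:
    kb: pd.DataFrame
    drug_class_map: pd.DataFrame
    maf: pd.DataFrame
    traits: pd.DataFrame
    expression: dict[str, pd.DataFrame]  # level -> feature x sample
    truth_druggable: pd.DataFrame
    truth_outliers: pd.DataFrame
    truth_duplicates: pd.DataFrame
    truth_common: pd.DataFrame

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.kb.to_csv(outdir / "knowledgebase.tsv", sep="\t", index=False)
        self.drug_class_map.to_csv(outdir / "drug_classes.tsv", sep="\t", index=False)
        self.maf.to_csv(outdir / "cohort.maf.tsv", sep="\t", index=False)
        self.traits.to_csv(outdir / "traits.tsv", sep="\t", index=False)
        for level, df in self.expression.items():
            df.to_csv(
                outdir / f"expression_{level}.tsv", sep="\t", float_format=FLOAT_FORMAT
            )
        self.truth_druggable.to_csv(outdir / "truth_druggable.tsv", sep="\t", index=False)
        self.truth_outliers.to_csv(outdir / "truth_outliers.tsv", sep="\t", index=False)
        self.truth_duplicates.to_csv(outdir / "truth_duplicates.tsv", sep="\t", index=False)
        self.truth_common.to_csv(outdir / "truth_common.tsv", sep="\t", index=False)


@dataclass
class SimulatedStructure:
    structure_id: str
    gene: str
    coordinates: dict[int, np.ndarray]
    hotspots: list[list[int]]
    mutated_residues: list[int]

    def distance_frame(self) -> pd.DataFrame:
        residues = sorted(self.coordinates)
        rows = []
        for a, i in enumerate(residues):
            for j in residues[a + 1 :]:
                d = float(np.linalg.norm(self.coordinates[i] - self.coordinates[j]))
                rows.append(
                    {
                        "structure_id": self.structure_id,
                        "gene": self.gene,
                        "res_i": i,
                        "res_j": j,
                        "distance_A": round(d, 4),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class SimulatedScreen:
    screen: pd.DataFrame
    cell_line_maf: pd.DataFrame
    cell_line_expression: pd.DataFrame  # probe x line
    probe_map: pd.DataFrame
    drug_map_table: pd.DataFrame
    truth_shifts: pd.DataFrame
    truth_slopes: pd.DataFrame

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.screen.to_csv(outdir / "screen.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)
        self.cell_line_maf.to_csv(outdir / "cell_lines.maf.tsv", sep="\t", index=False)
        self.cell_line_expression.to_csv(
            outdir / "cell_line_expression.tsv", sep="\t", float_format=FLOAT_FORMAT
        )
        self.probe_map.to_csv(outdir / "probe_map.tsv", sep="\t", index=False)
        self.drug_map_table.to_csv(outdir / "drug_map.tsv", sep="\t", index=False)
        self.truth_shifts.to_csv(outdir / "truth_screen_shifts.tsv", sep="\t", index=False)
        self.truth_slopes.to_csv(outdir / "truth_screen_slopes.tsv", sep="\t", index=False)


def _kb_frame(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = []
    for i, (gene, vclass, spec, ttype, effect, level, drug) in enumerate(config.kb_rows):
        rows.append(
            {
                "gene": gene,
                "variant_class": vclass,
                "variant_spec": spec,
                "tumor_type": ttype,
                "effect": effect,
                "evidence_level": level,
                "drug": drug,
                "drug_classes": DEFAULT_DRUG_CLASSES[drug],
                "pubmed_id": f"PMID{10_000_000 + i}",
            }
        )
    kb = pd.DataFrame(rows)
    class_map = pd.DataFrame(
        [{"drug": d, "class": c} for d, c in sorted(DEFAULT_DRUG_CLASSES.items())]
    )
    return kb, class_map


def _weighted_carriers(
    rng: np.random.Generator,
    samples: list[str],
    weights: np.ndarray,
    n_carriers: int,
) -> list[str]:
    if n_carriers == 0:
        return []
    p = weights / weights.sum()
    idx = rng.choice(len(samples), size=min(n_carriers, len(samples)), replace=False, p=p)
    return [samples[i] for i in sorted(idx)]


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate the full tumor cohort with planted effects and truth tables."""
    config.validate()
    root = np.random.default_rng(config.seed)
    rngs = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ["traits", "mutations", "passengers", "qc", "expression"],
            root.integers(0, 2**31 - 1, size=5),
        )
    }

    kb, class_map = _kb_frame(config)

    # ---- traits -------------------------------------------------------
    samples, trait_rows = [], []
    sex_cats = sorted(config.sex_probs)
    sex_p = [config.sex_probs[c] for c in sex_cats]
    race_cats = sorted(config.race_probs)
    race_p = [config.race_probs[c] for c in race_cats]
    rng = rngs["traits"]
    for ctype in config.cancer_types:
        for i in range(config.n_samples_per_type):
            sid = f"{ctype}-{i:04d}"
            samples.append(sid)
            trait_rows.append(
                {
                    "sample_id": sid,
                    "cancer_type": ctype,
                    "sex": rng.choice(sex_cats, p=sex_p),
                    "race": rng.choice(race_cats, p=race_p),
                }
            )
    traits = pd.DataFrame(trait_rows)
    sex_of = dict(zip(traits.sample_id, traits.sex))
    ctype_of = dict(zip(traits.sample_id, traits.cancer_type))
    race_of = dict(zip(traits.sample_id, traits.race))

    # ---- planted druggable / hotspot mutations ------------------------
    rng = rngs["mutations"]
    maf_rows: list[dict] = []
    truth_rows: list[dict] = []
    kb_gene_variants = {(r["gene"], r["variant_spec"]) for _, r in kb.iterrows()}

    def add_maf_row(sid, gene, change, classification, indel_bp, af="", pathogenic="false"):
        maf_rows.append(
            {
                "Tumor_Sample_Barcode": sid,
                "Hugo_Symbol": gene,
                "Variant_Classification": classification,
                "HGVSp_Short": f"p.{change}" if change else "",
                "Indel_Length": indel_bp,
                "Population_AF": af,
                "Pathogenic_Flag": pathogenic,
                "Cancer_Type": ctype_of.get(sid, sid.split("-")[0]),
            }
        )

    by_type: dict[str, list[str]] = {}
    for sid in samples:
        by_type.setdefault(ctype_of[sid], []).append(sid)

    for (ctype, gene, change, classification, indel_bp), freq in sorted(
        config.mutation_freqs.items()
    ):
        pool = by_type.get(ctype, [])
        if not pool:
            continue
        n_carriers = int(round(freq * len(pool)))
        enrich = config.enrichment.get(gene)
        weights = np.ones(len(pool))
        if enrich is not None:
            trait_name, favoured, odds = enrich
            values = sex_of if trait_name == "sex" else race_of
            weights = np.array(
                [odds if values[s] == favoured else 1.0 for s in pool]
            )
        carriers = _weighted_carriers(rng, pool, weights, n_carriers)
        for sid in carriers:
            add_maf_row(sid, gene, change, classification, indel_bp)
            truth_rows.append(
                {
                    "sample_id": sid,
                    "cancer_type": ctype,
                    "gene": gene,
                    "protein_change": change,
                    "in_knowledgebase": (gene, change) in kb_gene_variants
                    or _matches_loose(kb, gene, change, classification),
                }
            )

    # ---- passengers ---------------------------------------------------
    rng = rngs["passengers"]
    passenger_genes = [f"PSG{i}" for i in range(1, 25)]
    for sid in samples:
        for _ in range(rng.poisson(config.passenger_rate)):
            gene = passenger_genes[rng.integers(len(passenger_genes))]
            pos = int(rng.integers(1, 500))
            ref, alt = rng.choice(list(AMINO_ACIDS), size=2, replace=False)
            add_maf_row(sid, gene, f"{ref}{pos}{alt}", "Missense_Mutation", 0)

    # ---- QC plants: duplicates, small pair, common SNPs, big indels ---
    rng = rngs["qc"]
    dup_rows = []
    for d in range(config.n_duplicate_pairs):
        a, b = f"DUPA-{d:02d}", f"DUPB-{d:02d}"
        ctype = config.cancer_types[0]
        for sid in (a, b):
            trait_rows.append(
                {"sample_id": sid, "cancer_type": ctype, "sex": "male", "race": "white"}
            )
            ctype_of[sid] = ctype
        shared = []
        for k in range(10):
            gene = passenger_genes[rng.integers(len(passenger_genes))]
            pos = int(rng.integers(1, 500))
            ref, alt = rng.choice(list(AMINO_ACIDS), size=2, replace=False)
            shared.append((gene, f"{ref}{pos}{alt}"))
        n_shared = int(round(config.duplicate_concordance * 10))
        for gene, change in shared:
            add_maf_row(a, gene, change, "Missense_Mutation", 0)
        for gene, change in shared[:n_shared]:
            add_maf_row(b, gene, change, "Missense_Mutation", 0)
        for k in range(10 - n_shared):
            add_maf_row(b, f"PSGX{d}", f"A{100 + k}V", "Missense_Mutation", 0)
        dup_rows.append({"sample_a": a, "sample_b": b, "concordance": config.duplicate_concordance})
    if config.plant_small_identical_pair:
        a, b = "SMALLA-00", "SMALLB-00"
        ctype = config.cancer_types[0]
        for sid in (a, b):
            trait_rows.append(
                {"sample_id": sid, "cancer_type": ctype, "sex": "female", "race": "white"}
            )
            ctype_of[sid] = ctype
            for gene, change in [("PSG1", "A10V"), ("PSG2", "C20Y"), ("PSG3", "D30N")]:
                add_maf_row(sid, gene, change, "Missense_Mutation", 0)
        dup_rows.append({"sample_a": a, "sample_b": b, "concordance": 1.0})
    truth_duplicates = pd.DataFrame(
        dup_rows, columns=["sample_a", "sample_b", "concordance"]
    )
    traits = pd.DataFrame(trait_rows)

    common_rows = []
    n_common = int(round(config.common_variant_rate * len(samples)))
    for sid in rng.choice(samples, size=n_common, replace=False):
        add_maf_row(
            sid, "CVGENE", "M1L", "Missense_Mutation", 0,
            af=str(config.common_variant_af), pathogenic="false",
        )
        common_rows.append({"sample_id": sid, "gene": "CVGENE", "protein_change": "M1L"})
    truth_common = pd.DataFrame(common_rows, columns=["sample_id", "gene", "protein_change"])

    for k in range(config.n_large_indels):
        sid = samples[int(rng.integers(len(samples)))]
        add_maf_row(sid, "BIGINDEL", "", "Frame_Shift_Del", config.large_indel_bp)
    for k in range(config.n_boundary_indels):
        sid = samples[int(rng.integers(len(samples)))]
        add_maf_row(sid, "EDGEINDEL", f"K{50 + k}del", "In_Frame_Del", 100)

    maf = pd.DataFrame(maf_rows).sort_values(
        ["Tumor_Sample_Barcode", "Hugo_Symbol", "HGVSp_Short"], kind="mergesort"
    ).reset_index(drop=True)

    # ---- expression ---------------------------------------------------
    rng = rngs["expression"]
    expression: dict[str, pd.DataFrame] = {}
    outlier_rows = []
    non_laml = [s for s in samples if ctype_of[s] != "LAML"]
    for level, features in config.expression_features.items():
        coverage = config.mrna_coverage if level == "mrna" else config.protein_coverage
        covered = sorted(
            rng.choice(samples, size=int(round(coverage * len(samples))), replace=False)
        )
        all_features = list(features) + [
            f"BG{level.upper()}{i}" for i in range(1, N_BACKGROUND_GENES + 1)
        ]
        mu = config.mrna_mu if level == "mrna" else 0.0
        sigma = config.mrna_sigma if level == "mrna" else config.protein_sigma
        if config.heavy_tails:
            data = mu + sigma * rng.standard_t(3, size=(len(all_features), len(covered)))
        else:
            data = rng.normal(mu, sigma, size=(len(all_features), len(covered)))
        df = pd.DataFrame(data, index=all_features, columns=covered)
        if level != "mrna" and config.protein_missing_rate > 0:
            mask = rng.random(df.shape) < config.protein_missing_rate
            df = df.mask(mask)
        # plant outliers on druggable features among covered non-LAML samples
        plantable = [s for s in covered if s in set(non_laml)]
        for feature in features:
            base = df.loc[feature].to_numpy(dtype=float)
            q1, q3, iqr = cohort_quartiles(base)
            n_out = int(round(config.outlier_fraction * len(plantable)))
            chosen = rng.choice(plantable, size=n_out, replace=False)
            for sid in sorted(chosen):
                jitter = 0.05 * (1 + rng.random())
                df.loc[feature, sid] = q3 + (config.outlier_shift_iqr + jitter) * iqr
                outlier_rows.append(
                    {
                        "feature": feature,
                        "sample_id": sid,
                        "level": level,
                        "shift_iqr": config.outlier_shift_iqr,
                    }
                )
        df.index.name = "feature"
        expression[level] = df
    truth_outliers = pd.DataFrame(
        outlier_rows, columns=["feature", "sample_id", "level", "shift_iqr"]
    )

    truth_druggable = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "cancer_type", "gene", "protein_change", "in_knowledgebase"],
    )
    return SimulatedCohort(
        kb=kb,
        drug_class_map=class_map,
        maf=maf,
        traits=traits,
        expression=expression,
        truth_druggable=truth_druggable,
        truth_outliers=truth_outliers,
        truth_duplicates=truth_duplicates,
        truth_common=truth_common,
    )


def _matches_loose(kb: pd.DataFrame, gene: str, change: str, classification: str) -> bool:
    """True when a planted mutation maps onto an ambiguous/range/loose entry."""
    import re

    m = re.match(r"^[A-Z](\d+)", change or "")
    pos = int(m.group(1)) if m else None
    for _, row in kb[kb.gene == gene].iterrows():
        vc, spec = row.variant_class, row.variant_spec
        if vc == "missense_position" and classification == "Missense_Mutation":
            if change and spec and change.startswith(spec):
                return True
        elif vc in ("aa_range", "inframe_indel_range") and pos is not None:
            rm = re.match(r"^(\d+)-(\d+)", spec)
            if rm and int(rm.group(1)) <= pos <= int(rm.group(2)):
                sub = spec.split(":")[1] if ":" in spec else None
                if sub == "inframe_del" and classification != "In_Frame_Del":
                    continue
                return True
        elif vc == "nonsense" and classification == "Nonsense_Mutation":
            if spec == "*" or (pos is not None and spec == str(pos)):
                return True
        elif vc == "frameshift" and classification.startswith("Frame_Shift"):
            if spec == "*" or (pos is not None and spec == str(pos)):
                return True
    return False


def simulate_structure(
    gene: str,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedStructure:
    """Place hotspot residues inside a tight 3D ball and decoys far away.

    Residues in one hotspot group land within a ball of diameter
    ``hotspot_ball_radius`` (so all pairwise distances are below it); decoy
    residues sit on a line at ``decoy_spacing`` intervals, at least that far
    from every hotspot and from each other.
    """
    spec = config.structures[gene]
    if rng is None:
        gene_offset = sum(ord(ch) for ch in gene)  # stable across processes
        rng = np.random.default_rng(config.seed + gene_offset)
    r = config.hotspot_ball_radius / 2.0
    coords: dict[int, np.ndarray] = {}
    mutated: list[int] = []
    for g, group in enumerate(spec["hotspots"]):
        center = np.array([0.0, 10 * config.decoy_spacing * (g + 1), 0.0])
        for residue in group:
            while True:
                point = rng.uniform(-r, r, size=3)
                if np.linalg.norm(point) <= r:
                    break
            coords[residue] = center + point
            mutated.append(residue)
    taken = set(coords)
    far_line_y = -10 * config.decoy_spacing
    decoy_positions = [p for p in range(1, 2000) if p not in taken]
    placed = 0
    for residue in spec.get("far_mutated", []):
        coords[residue] = np.array([config.decoy_spacing * (placed + 1), far_line_y, 0.0])
        mutated.append(residue)
        placed += 1
    for residue in decoy_positions:
        if placed >= spec["n_decoys"] + len(spec.get("far_mutated", [])):
            break
        if residue in coords:
            continue
        coords[residue] = np.array([config.decoy_spacing * (placed + 1), far_line_y, 0.0])
        placed += 1
    return SimulatedStructure(
        structure_id=f"SYN_{gene}",
        gene=gene,
        coordinates=coords,
        hotspots=[list(g) for g in spec["hotspots"]],
        mutated_residues=sorted(mutated),
    )


def simulate_structures(config: SimulationConfig) -> list[SimulatedStructure]:
    rng = np.random.default_rng(np.random.default_rng(config.seed + 1).integers(2**31 - 1))
    return [simulate_structure(g, config, rng) for g in sorted(config.structures)]


def structures_to_distance_tsv(structures: list[SimulatedStructure], path) -> None:
    pd.concat([s.distance_frame() for s in structures], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )


def simulate_screen(config: SimulationConfig) -> SimulatedScreen:
    """Generate the cell-line screen with planted IC50 shifts and slopes."""
    config.validate()
    rng = np.random.default_rng(config.seed + 7)
    lines = [f"CL{i:04d}" for i in range(config.n_cell_lines)]
    tissue_pool = [t for t in config.cancer_types if t != "LAML"]
    tissues = {line: tissue_pool[int(rng.integers(len(tissue_pool)))] for line in lines}

    # compounds: mutation-paired drugs + regression drugs
    compounds = {}
    for vk, (gene, change, n_mut, drug) in sorted(config.screen_mutations.items()):
        compounds.setdefault(drug, gene)
    for gene, (drug, _np) in sorted(config.regression_genes.items()):
        compounds.setdefault(drug, gene)
    drug_ids = {drug: f"D{i:03d}" for i, drug in enumerate(sorted(compounds))}
    drug_map_table = pd.DataFrame(
        [
            {
                "drug_id": drug_ids[drug],
                "name": drug,
                "synonyms": drug.upper(),
                "target": compounds[drug],
            }
            for drug in sorted(compounds)
        ]
    )

    # mutant lines
    cl_maf_rows = []
    mutant_lines: dict[str, list[str]] = {}
    for vk, (gene, change, n_mut, drug) in sorted(config.screen_mutations.items()):
        chosen = sorted(rng.choice(lines, size=min(n_mut, len(lines)), replace=False))
        mutant_lines[vk] = chosen
        for line in chosen:
            cl_maf_rows.append(
                {
                    "Tumor_Sample_Barcode": line,
                    "Hugo_Symbol": gene,
                    "Variant_Classification": "Missense_Mutation",
                    "HGVSp_Short": f"p.{change}",
                    "Indel_Length": 0,
                    "Population_AF": "",
                    "Pathogenic_Flag": "false",
                    "Cancer_Type": tissues[line],
                }
            )
    cell_line_maf = pd.DataFrame(
        cl_maf_rows,
        columns=[
            "Tumor_Sample_Barcode",
            "Hugo_Symbol",
            "Variant_Classification",
            "HGVSp_Short",
            "Indel_Length",
            "Population_AF",
            "Pathogenic_Flag",
            "Cancer_Type",
        ],
    )

    # probe expression and outlier scores (panel itself is the reference)
    probe_rows, probe_map_rows = [], []
    for gene, (drug, n_probes) in sorted(config.regression_genes.items()):
        for p in range(1, n_probes + 1):
            probe_rows.append(f"P_{gene}_{p}")
            probe_map_rows.append({"probe_id": f"P_{gene}_{p}", "gene": gene})
    expr = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(len(probe_rows), len(lines))),
        index=probe_rows,
        columns=lines,
    )
    expr.index.name = "probe_id"
    probe_map = pd.DataFrame(probe_map_rows)

    from .expression_outliers import outlier_score  # local to avoid cycle at import

    scores = {}
    for probe in expr.index:
        v = expr.loc[probe].to_numpy(dtype=float)
        q1, q3, iqr = cohort_quartiles(v)
        scores[probe] = {
            line: outlier_score(x, q1, q3, iqr, "high")
            for line, x in zip(lines, v)
        }

    # LN(IC50) table
    shift_rows, slope_rows = [], []
    mutation_drug_ids = {
        vk: drug_ids[drug] for vk, (_g, _c, _n, drug) in config.screen_mutations.items()
    }
    regression_drug_ids = {
        gene: drug_ids[drug] for gene, (drug, _n) in config.regression_genes.items()
    }
    screen_rows = []
    gene_probe = {g: [p for p in probe_rows if p.startswith(f"P_{g}_")] for g in config.regression_genes}
    for line in lines:
        for drug, did in sorted(drug_ids.items(), key=lambda kv: kv[1]):
            y = rng.normal(config.screen_mu, config.screen_sigma)
            reg_gene = next(
                (g for g, rdid in regression_drug_ids.items() if rdid == did), None
            )
            if reg_gene is not None:
                # response is linear in the gene's first-probe outlier score
                x = scores[gene_probe[reg_gene][0]][line]
                y = config.screen_mu + config.screen_beta * x + rng.normal(0, config.screen_noise)
            for vk, mdid in mutation_drug_ids.items():
                if mdid == did and line in mutant_lines[vk]:
                    y -= config.screen_delta
            screen_rows.append(
                {
                    "cell_line_id": line,
                    "tissue_type": tissues[line],
                    "drug_id": did,
                    "ln_ic50": round(float(y), 6),
                    "auc": "",
                }
            )
    for vk, did in sorted(mutation_drug_ids.items()):
        shift_rows.append(
            {"variant_key": vk, "drug_id": did, "delta": config.screen_delta,
             "n_lines": len(mutant_lines[vk])}
        )
    for gene, did in sorted(regression_drug_ids.items()):
        slope_rows.append({"gene": gene, "drug_id": did, "beta": config.screen_beta})

    return SimulatedScreen(
        screen=pd.DataFrame(screen_rows),
        cell_line_maf=cell_line_maf,
        cell_line_expression=expr,
        probe_map=probe_map,
        drug_map_table=drug_map_table,
        truth_shifts=pd.DataFrame(shift_rows),
        truth_slopes=pd.DataFrame(slope_rows),
    )
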