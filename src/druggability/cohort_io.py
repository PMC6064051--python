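"""Cohort input/output: MAF-dialect mutation tables, expression matrices,
clinical traits, and the cohort-level quality-control filters.

QC removes large/complex indels (> 100 bp), near-duplicate tumor samples
(> 60% variant concordance unless both samples are tiny), and common
non-pathogenic variants (population allele frequency > 0.05%).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MAF_REQUIRED_COLUMNS = [
    "Tumor_Sample_Barcode",
    "Hugo_Symbol",
    "Variant_Classification",
    "HGVSp_Short",
    "Indel_Length",
    "Population_AF",
    "Pathogenic_Flag",
    "Cancer_Type",
]

#: MAF Variant_Classification -> internal mutation class
_CLASSIFICATION_MAP = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Frame_Shift_Del": "frameshift",
    "Frame_Shift_Ins": "frameshift",
    "In_Frame_Del": "inframe_del",
    "In_Frame_Ins": "inframe_ins",
}

#: Variant_Type tokens flagged as complex indels (configurable)
DEFAULT_COMPLEX_TOKENS = ("Complex", "COMPLEX", "complex_indel")

_MISSENSE_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")
_NONSENSE_RE = re.compile(r"^([A-Z])(\d+)\*$")
_FRAMESHIFT_RE = re.compile(r"^([A-Z])(\d+)[A-Za-z]*fs")
_INFRAME_RE = re.compile(r"^([A-Z])(\d+)(?:_([A-Z])(\d+))?(del|ins|delins|dup)")


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation in one tumor sample, protein-level annotated."""

    sample_id: str
    cancer_type: str
    gene: str
    protein_change: str  # HGVS-p short form without the leading "p."
    mutation_class: str  # missense|nonsense|frameshift|inframe_del|inframe_ins|other
    indel_length: int = 0
    population_af: float | None = None
    pathogenic_flag: bool = False

    def __post_init__(self) -> None:
        if self.indel_length < 0:
            raise ValueError("indel_length must be >= 0")
        if self.population_af is not None and not 0 <= self.population_af <= 1:
            raise ValueError("population_af must lie in [0, 1]")

    @property
    def variant_key(self) -> str:
        return f"{self.gene}:{self.protein_change or self.mutation_class}"

    @property
    def residue_position(self) -> int | None:
        """Start codon of the protein change, when it parses."""
        parsed = parse_protein_change(self.protein_change, self.mutation_class)
        return parsed[1] if parsed else None

    @property
    def ref_aa(self) -> str | None:
        parsed = parse_protein_change(self.protein_change, self.mutation_class)
        return parsed[0] if parsed else None


def parse_protein_change(
    change: str, mutation_class: str
) -> tuple[str | None, int, str | None] | None:
    """Return (ref_aa, start_position, alt_aa) or None when unparseable."""
    if not change:
        return None
    if mutation_class == "missense":
        m = _MISSENSE_RE.match(change)
        return (m.group(1), int(m.group(2)), m.group(3)) if m else None
    if mutation_class == "nonsense":
        m = _NONSENSE_RE.match(change)
        return (m.group(1), int(m.group(2)), "*") if m else None
    if mutation_class == "frameshift":
        m = _FRAMESHIFT_RE.match(change)
        return (m.group(1), int(m.group(2)), None) if m else None
    if mutation_class in ("inframe_del", "inframe_ins"):
        m = _INFRAME_RE.match(change)
        return (m.group(1), int(m.group(2)), None) if m else None
    return None


@dataclass(frozen=True)
class SampleTraits:
    sample_id: str
    cancer_type: str
    sex: str | None = None
    race: str | None = None


def read_maf(path) -> list[MutationRecord]:
    """Read a MAF-dialect TSV into mutation records.

    Unparseable protein changes are kept with mutation_class 'other' and a
    warning; a missing required column is a hard error.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in MAF_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"MAF missing required columns: {missing}")
    records: list[MutationRecord] = []
    n_unparsed = 0
    for row in df.itertuples(index=False):
        change = row.HGVSp_Short or ""
        if change.startswith("p."):
            change = change[2:]
        mclass = _CLASSIFICATION_MAP.get(row.Variant_Classification, "other")
        if mclass in ("missense", "nonsense", "frameshift", "inframe_del", "inframe_ins"):
            if change and parse_protein_change(change, mclass) is None:
                n_unparsed += 1
                mclass = "other"
        af_text = (row.Population_AF or "").strip()
        af = float(af_text) if af_text not in ("", ".", "NA") else None
        records.append(
            MutationRecord(
                sample_id=row.Tumor_Sample_Barcode,
                cancer_type=row.Cancer_Type,
                gene=row.Hugo_Symbol,
                protein_change=change,
                mutation_class=mclass,
                indel_length=int(row.Indel_Length or 0),
                population_af=af,
                pathogenic_flag=str(row.Pathogenic_Flag).strip().lower()
                in ("true", "1", "yes"),
            )
        )
    if n_unparsed:
        logger.warning("%d protein changes did not parse; kept as class=other", n_unparsed)
    return records


def filter_large_complex_indels(
    records: list[MutationRecord],
    max_indel_bp: int = 100,
    complex_classes: tuple[str, ...] = (),
) -> list[MutationRecord]:
    """Drop indels longer than ``max_indel_bp`` (strict >) and records whose
    mutation class is in the configured complex-indel token list."""
    kept = [
        r
        for r in records
        if r.indel_length <= max_indel_bp and r.mutation_class not in complex_classes
    ]
    logger.info("large/complex indel filter removed %d records", len(records) - len(kept))
    return kept


def _concordance(a: frozenset, b: frozenset) -> float:
    smaller = min(len(a), len(b))
    if smaller == 0:
        return 0.0
    return len(a & b) / smaller


def remove_duplicate_samples(
    records: list[MutationRecord],
    concordance_threshold: float = 0.60,
    small_sample_max_variants: int = 5,
) -> tuple[list[MutationRecord], list[str]]:
    """Drop one sample of each pair sharing > 60% of variants.

    Concordance is shared-variant count over the smaller sample's variant
    count.  Pairs where both samples have <= 5 variants are exempt.  Of a
    flagged pair the sample with fewer variants is dropped; at equal counts
    the lexicographically later barcode goes.  Returns (records, dropped ids).
    """
    by_sample: dict[str, set] = {}
    for r in records:
        by_sample.setdefault(r.sample_id, set()).add((r.gene, r.protein_change, r.mutation_class))
    variant_sets = {s: frozenset(v) for s, v in by_sample.items()}
    dropped: set[str] = set()
    samples = sorted(variant_sets)
    for i, a in enumerate(samples):
        if a in dropped:
            continue
        for b in samples[i + 1 :]:
            if b in dropped:
                continue
            va, vb = variant_sets[a], variant_sets[b]
            if len(va) <= small_sample_max_variants and len(vb) <= small_sample_max_variants:
                continue
            if _concordance(va, vb) > concordance_threshold:
                if len(va) < len(vb):
                    victim = a
                elif len(vb) < len(va):
                    victim = b
                else:
                    victim = max(a, b)
                dropped.add(victim)
                logger.info("duplicate-sample filter dropping %s (pair %s/%s)", victim, a, b)
                if victim == a:
                    break
    kept = [r for r in records if r.sample_id not in dropped]
    return kept, sorted(dropped)


def filter_common_variants(
    records: list[MutationRecord], af_threshold: float = 0.0005
) -> list[MutationRecord]:
    """Drop variants with population AF > 0.05% that are not pathogenic.

    Missing allele frequencies are treated as rare (kept)."""
    kept = [
        r
        for r in records
        if r.population_af is None
        or r.population_af <= af_threshold
        or r.pathogenic_flag
    ]
    logger.info("common-variant filter removed %d records", len(records) - len(kept))
    return kept


def apply_qc(
    records: list[MutationRecord],
    max_indel_bp: int = 100,
    complex_classes: tuple[str, ...] = (),
    concordance_threshold: float = 0.60,
    af_threshold: float = 0.0005,
) -> tuple[list[MutationRecord], list[str]]:
    """All QC filters in the published order; returns (records, dropped samples)."""
    records = filter_large_complex_indels(records, max_indel_bp, complex_classes)
    records, dropped = remove_duplicate_samples(records, concordance_threshold)
    records = filter_common_variants(records, af_threshold)
    return records, dropped


@dataclass
class ExpressionMatrix:
    """Gene (or phosphosite) x sample matrix at one molecular level.

    Phosphosite rows are labelled ``GENE:pSNNN``.
    """

    level: str  # mrna | protein | phosphoprotein
    values: pd.DataFrame  # rows: features, columns: sample barcodes

    def __post_init__(self) -> None:
        if self.level not in ("mrna", "protein", "phosphoprotein"):
            raise ValueError(f"unknown expression level {self.level!r}")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate row labels: {dupes}")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def read_expression_matrix(
    path, level: str, mrna_log2: bool = True, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """Read a feature x sample expression TSV.

    mRNA matrices are log2(x + pseudocount)-transformed by default; protein
    and phosphoprotein panels arrive normalized and are used as-is.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.astype(float)
    if level == "mrna" and mrna_log2:
        df = np.log2(df + pseudocount)
    return ExpressionMatrix(level=level, values=df)


def read_traits(path) -> list[SampleTraits]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "cancer_type"}
    if not required <= set(df.columns):
        raise ValueError("traits TSV needs columns: sample_id, cancer_type[, sex, race]")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in traits")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SampleTraits(
                sample_id=row.sample_id,
                cancer_type=row.cancer_type,
                sex=getattr(row, "sex", "") or None,
                race=getattr(row, "race", "") or None,
            )
        )
    return out
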