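"""Druggability enrichment across demographic traits (sex, race).

Per (cancer type, druggable gene) cell the statistic is the log-odds of
druggability between two trait categories,

    log2( (druggable A / A) / (druggable B / B) ),

with infinite values clamped to +/-3 for display.  Eligibility follows the
published thresholds: a cancer type needs >= 20 tumors in each category, a
gene must be druggable in >= 40 (race) or >= 150 (sex) tumors cohort-wide,
and a cell is only computed when >= 10 tumors of that cancer type carry the
druggable gene.  Two-sided Fisher exact tests with Benjamini-Hochberg FDR at
0.05 flag significant cells.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort_io import SampleTraits
from .knowledgebase import Effect
from .variant_annotation import DruggabilityCall

logger = logging.getLogger(__name__)

LOG_ODDS_CLAMP = 3.0
MIN_TUMORS_PER_CATEGORY = 20
MIN_GENE_TUMORS = {"race": 40, "sex": 150}
MIN_CELL_TUMORS = 10
FDR_ALPHA = 0.05

#: cancer types excluded from the sex analysis (sex-specific organs)
DEFAULT_SEX_EXCLUDED = ("BRCA", "CESC", "PRAD", "OV", "UCEC", "UCS")


@dataclass(frozen=True)
class DemographicCell:
    cancer_type: str
    gene: str
    trait_a: str
    trait_b: str
    druggable_a: int
    total_a: int
    druggable_b: int
    total_b: int
    log_odds: float
    fisher_p: float = math.nan
    fdr_q: float = math.nan

    @property
    def significant(self) -> bool:
        return self.fdr_q < FDR_ALPHA


def log_odds(dA: int, nA: int, dB: int, nB: int, clamp: float = LOG_ODDS_CLAMP) -> float:
    """log2 of the rate ratio, clamped to +/-clamp at zero rates."""
    if min(dA, nA - dA, dB, nB - dB) < 0 or nA == 0 or nB == 0:
        raise ValueError("counts must be non-negative with positive totals")
    if dA == 0 and dB == 0:
        return 0.0
    if dB == 0:
        return clamp
    if dA == 0:
        return -clamp
    value = math.log2((dA / nA) / (dB / nB))
    return max(-clamp, min(clamp, value))


def build_demographic_matrix(
    calls: list[DruggabilityCall],
    traits: list[SampleTraits],
    trait: str,
    categories: tuple[str, str] | None = None,
    sex_excluded_cancer_types: tuple[str, ...] = DEFAULT_SEX_EXCLUDED,
    min_tumors_per_category: int = MIN_TUMORS_PER_CATEGORY,
    min_gene_tumors: int | None = None,
    min_cell_tumors: int = MIN_CELL_TUMORS,
) -> list[DemographicCell]:
    """Log-odds matrix of druggable genes x cancer types for one trait.

    ``categories`` fixes the (A, B) contrast; by default the two largest
    categories in the cohort are used (A = larger).  Samples with a missing
    trait value are ignored.
    """
    if trait not in ("sex", "race"):
        raise ValueError("trait must be 'sex' or 'race'")
    if min_gene_tumors is None:
        min_gene_tumors = MIN_GENE_TUMORS[trait]

    trait_of = {
        t.sample_id: getattr(t, trait)
        for t in traits
        if getattr(t, trait)
    }
    ctype_of = {t.sample_id: t.cancer_type for t in traits}
    if trait == "sex":
        trait_of = {
            s: v
            for s, v in trait_of.items()
            if ctype_of[s] not in sex_excluded_cancer_types
        }

    counts = pd.Series(list(trait_of.values())).value_counts()
    if len(counts) < 2:
        raise ValueError(f"trait {trait!r} has fewer than 2 categories")
    if categories is None:
        categories = tuple(counts.index[:2])
    cat_a, cat_b = categories

    # sample universes per (cancer type, category)
    members: dict[tuple[str, str], set[str]] = {}
    for s, v in trait_of.items():
        if v in (cat_a, cat_b):
            members.setdefault((ctype_of[s], v), set()).add(s)

    eligible_types = sorted(
        ct
        for ct in {ctype_of[s] for s in trait_of}
        if len(members.get((ct, cat_a), ())) >= min_tumors_per_category
        and len(members.get((ct, cat_b), ())) >= min_tumors_per_category
    )

    # druggable (sample, gene) pairs from sensitive calls at any level
    druggable: dict[str, set[str]] = {}
    for c in calls:
        if c.effect is Effect.SENSITIVE and c.sample_id in trait_of:
            druggable.setdefault(c.gene, set()).add(c.sample_id)
    eligible_genes = sorted(
        g for g, samples in druggable.items() if len(samples) >= min_gene_tumors
    )

    cells = []
    for ct in eligible_types:
        group_a = members[(ct, cat_a)]
        group_b = members[(ct, cat_b)]
        for gene in eligible_genes:
            carriers = druggable[gene]
            n_cell = len(carriers & (group_a | group_b))
            if n_cell < min_cell_tumors:
                continue
            dA = len(carriers & group_a)
            dB = len(carriers & group_b)
            cells.append(
                DemographicCell(
                    cancer_type=ct,
                    gene=gene,
                    trait_a=cat_a,
                    trait_b=cat_b,
                    druggable_a=dA,
                    total_a=len(group_a),
                    druggable_b=dB,
                    total_b=len(group_b),
                    log_odds=log_odds(dA, len(group_a), dB, len(group_b)),
                )
            )
    logger.info(
        "demographic matrix (%s): %d cells over %d cancer types x %d genes",
        trait,
        len(cells),
        len(eligible_types),
        len(eligible_genes),
    )
    return cells


def enrichment_tests(cells: list[DemographicCell]) -> list[DemographicCell]:
    """Two-sided Fisher exact per cell plus Benjamini-Hochberg q-values
    across all cells of the matrix."""
    if not cells:
        return []
    pvalues = []
    for c in cells:
        table = [
            [c.druggable_a, c.total_a - c.druggable_a],
            [c.druggable_b, c.total_b - c.druggable_b],
        ]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        pvalues.append(p)
    _, qvalues, _, _ = multipletests(pvalues, method="fdr_bh")
    return [
        DemographicCell(
            **{
                **c.__dict__,
                "fisher_p": float(p),
                "fdr_q": float(q),
            }
        )
        for c, p, q in zip(cells, pvalues, qvalues)
    ]


def cells_to_frame(cells: list[DemographicCell]) -> pd.DataFrame:
    rows = [
        {
            "cancer_type": c.cancer_type,
            "feature": c.gene,
            "trait_a": c.trait_a,
            "trait_b": c.trait_b,
            "dA": c.druggable_a,
            "nA": c.total_a,
            "dB": c.druggable_b,
            "nB": c.total_b,
            "log_odds": c.log_odds,
            "fisher_p": c.fisher_p,
            "fdr_q": c.fdr_q,
            "significant": c.significant,
        }
        for c in cells
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "cancer_type",
            "feature",
            "trait_a",
            "trait_b",
            "dA",
            "nA",
            "dB",
            "nB",
            "log_odds",
            "fisher_p",
            "fdr_q",
            "significant",
        ],
    )
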