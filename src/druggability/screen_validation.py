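"""Cell-line drug-screen validation of druggability biomarkers.

Two routes: (i) LN(IC50) distributions of cell lines carrying knowledgebase
sensitive mutations are compared with background via the two-sided
Mann-Whitney U test, globally and per (mutation, drug) combination with at
least five mutant lines; (ii) per-probe ordinary least-squares regressions
of LN(IC50) on the expression outlier score, where a gene counts as
validated when at least one probe is significant (P < 0.05) with a negative
slope.

No multiple-testing correction is applied across the probe/drug combination
family; results are reported raw, as in the screening analysis this module
emulates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import MutationRecord
from .knowledgebase import Effect, KnowledgebaseEntry
from .variant_annotation import (
    KnowledgebaseIndex,
    annotate_cohort,
)

logger = logging.getLogger(__name__)

MIN_LINES = 5
SIGNIFICANCE_ALPHA = 0.05


@dataclass(frozen=True)
class ScreenRecord:
    cell_line_id: str
    tissue_type: str
    drug_id: str
    ln_ic50: float
    auc: float | None = None


@dataclass(frozen=True)
class MannWhitneyResult:
    label: str
    n_group: int
    n_background: int
    u_statistic: float
    p_value: float


@dataclass(frozen=True)
class RegressionResult:
    probe_id: str
    gene: str
    drug_id: str
    slope: float
    intercept: float
    p_value: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_ALPHA and self.slope < 0


def read_screen(path) -> list[ScreenRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"cell_line_id", "tissue_type", "drug_id", "ln_ic50"}
    if not required <= set(df.columns):
        raise ValueError(f"screen TSV needs columns {sorted(required)}")
    seen = set()
    records = []
    for row in df.itertuples(index=False):
        key = (row.cell_line_id, row.drug_id)
        if key in seen:
            raise ValueError(f"duplicate (cell_line, drug) record {key}")
        seen.add(key)
        auc_text = getattr(row, "auc", "")
        records.append(
            ScreenRecord(
                cell_line_id=row.cell_line_id,
                tissue_type=row.tissue_type,
                drug_id=row.drug_id,
                ln_ic50=float(row.ln_ic50),
                auc=float(auc_text) if auc_text else None,
            )
        )
    return records


def map_drugs(
    kb: list[KnowledgebaseEntry],
    mapping_table: pd.DataFrame,
) -> tuple[dict[str, set[str]], list[str]]:
    """Map knowledgebase drug names onto screen drug ids.

    ``mapping_table`` columns: drug_id, name, synonyms (';'-separated),
    target.  A knowledgebase drug maps to a screen compound when the name or
    a synonym matches case-insensitively, or when the knowledgebase entry's
    gene equals the compound's annotated gene target.  Returns
    (kb drug -> screen drug ids, unmapped kb drugs).
    """
    by_name: dict[str, set[str]] = {}
    by_target: dict[str, set[str]] = {}
    for row in mapping_table.itertuples(index=False):
        names = {str(row.name).lower()}
        syns = getattr(row, "synonyms", "") or ""
        names |= {s.strip().lower() for s in str(syns).split(";") if s.strip()}
        for n in names:
            by_name.setdefault(n, set()).add(row.drug_id)
        target = getattr(row, "target", "") or ""
        if target:
            by_target.setdefault(str(target), set()).add(row.drug_id)

    kb_drugs = sorted({e.drug for e in kb})
    drug_genes: dict[str, set[str]] = {}
    for e in kb:
        drug_genes.setdefault(e.drug, set()).add(e.gene)

    mapping: dict[str, set[str]] = {}
    unmapped = []
    for drug in kb_drugs:
        ids = set(by_name.get(drug.lower(), set()))
        for gene in drug_genes[drug]:
            ids |= by_target.get(gene, set())
        if ids:
            mapping[drug] = ids
        else:
            unmapped.append(drug)
    if unmapped:
        logger.info("unmapped knowledgebase drugs: %s", unmapped)
    return mapping, unmapped


def _annotate_cell_lines(
    cl_mutations: list[MutationRecord], index: KnowledgebaseIndex
):
    """Resolve knowledgebase calls on cell lines (tissue type as cancer type)."""
    return annotate_cohort(cl_mutations, index)


def mutation_sensitivity_test(
    screen: list[ScreenRecord],
    index: KnowledgebaseIndex,
    cl_mutations: list[MutationRecord],
    drug_map: dict[str, set[str]],
    setting: str = "non_specific",
    min_lines: int = MIN_LINES,
) -> tuple[MannWhitneyResult | None, list[MannWhitneyResult]]:
    """Mann-Whitney comparisons of mutant-line LN(IC50) against background.

    The background distribution is every LN(IC50) of every (cell line, drug)
    record, whether or not the line carries a knowledgebase mutation.  The
    global test pools LN(IC50) of (line, mapped drug) pairs for lines with a
    sensitive knowledgebase mutation; per-(mutation, drug) tests require at
    least ``min_lines`` mutant lines and compare against that drug's own
    background.  ``setting`` 'specific' restricts to calls whose tissue type
    attains the variant's maximal evidence tier.
    """
    background = np.array([r.ln_ic50 for r in screen], dtype=float)
    by_drug: dict[str, list[float]] = {}
    by_line_drug: dict[tuple[str, str], float] = {}
    for r in screen:
        by_drug.setdefault(r.drug_id, []).append(r.ln_ic50)
        by_line_drug[(r.cell_line_id, r.drug_id)] = r.ln_ic50

    calls = _annotate_cell_lines(cl_mutations, index)
    eligible = [
        c
        for c in calls
        if c.effect is Effect.SENSITIVE
        and (setting == "non_specific" or c.specificity == "cancer_type_specific")
    ]
    if not eligible:
        logger.warning("no eligible cell lines for setting %s", setting)
        return None, []

    pooled: list[float] = []
    per_combo: dict[tuple[str, str], list[float]] = {}
    for c in eligible:
        for drug in getattr(c, "top_drugs", (c.chosen_drug,)) or (c.chosen_drug,):
            for drug_id in sorted(drug_map.get(drug, ())):
                y = by_line_drug.get((c.sample_id, drug_id))
                if y is None:
                    continue
                pooled.append(y)
                per_combo.setdefault((c.variant_key, drug_id), []).append(y)

    global_result = None
    if pooled:
        u, p = mann_whitney(np.array(pooled), background)
        global_result = MannWhitneyResult(
            label=f"global_{setting}",
            n_group=len(pooled),
            n_background=background.size,
            u_statistic=u,
            p_value=p,
        )

    combo_results = []
    for (variant_key, drug_id), ys in sorted(per_combo.items()):
        if len(ys) < min_lines:
            continue
        drug_background = np.array(by_drug[drug_id], dtype=float)
        u, p = mann_whitney(np.array(ys), drug_background)
        combo_results.append(
            MannWhitneyResult(
                label=f"{variant_key}|{drug_id}",
                n_group=len(ys),
                n_background=drug_background.size,
                u_statistic=u,
                p_value=p,
            )
        )
    return global_result, combo_results


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact for small tie-free groups, otherwise
    the tie-corrected normal approximation with continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    small = max(x.size, y.size) <= 8
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def expression_sensitivity_regression(
    scores: pd.DataFrame,
    screen: list[ScreenRecord],
    probe_map: pd.DataFrame,
    gene_drugs: dict[str, set[str]],
    min_lines: int = MIN_LINES,
) -> tuple[list[RegressionResult], list[str]]:
    """Per probe-drug OLS of LN(IC50) on the expression outlier score.

    ``scores``: probe x cell-line matrix of outlier scores (the cell-line
    panel itself is the reference cohort).  ``probe_map`` columns: probe_id,
    gene.  ``gene_drugs``: gene -> screen drug ids to pair with its probes.
    Combinations with fewer than ``min_lines`` lines or zero score variance
    are skipped.  Returns (results, validated genes).
    """
    probe_gene = dict(zip(probe_map["probe_id"], probe_map["gene"]))
    by_line_drug = {(r.cell_line_id, r.drug_id): r.ln_ic50 for r in screen}

    results: list[RegressionResult] = []
    for probe in scores.index:
        gene = probe_gene.get(probe)
        if gene is None or gene not in gene_drugs:
            continue
        x_all = scores.loc[probe]
        for drug_id in sorted(gene_drugs[gene]):
            xs, ys = [], []
            for line, x in x_all.items():
                if np.isnan(x):
                    continue
                y = by_line_drug.get((line, drug_id))
                if y is not None:
                    xs.append(x)
                    ys.append(y)
            if len(xs) < min_lines:
                continue
            xs_arr = np.array(xs)
            if np.ptp(xs_arr) == 0:
                logger.info("probe %s vs %s has zero score variance; skipped", probe, drug_id)
                continue
            fit = stats.linregress(xs_arr, np.array(ys))
            results.append(
                RegressionResult(
                    probe_id=probe,
                    gene=gene,
                    drug_id=drug_id,
                    slope=float(fit.slope),
                    intercept=float(fit.intercept),
                    p_value=float(fit.pvalue),
                    n=len(xs),
                )
            )
    validated = sorted({r.gene for r in results if r.significant})
    logger.info("%d probe-drug regressions, %d validated genes", len(results), len(validated))
    return results, validated
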