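"""Tukey-fence expression outlier scoring across a pan-cancer cohort.

For each druggable feature (gene or phosphosite) the cohort first and third
quartiles are computed; a sample's outlier score is (x - Q3)/IQR for
high-expression biomarkers or (Q1 - x)/IQR for low-expression ones, and a
score strictly greater than 1.5 calls the sample an outlier.  Scores are
location-scale free, so the calls are invariant to affine rescaling of a
feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_io import ExpressionMatrix
from .knowledgebase import (
    EXPRESSION_CLASSES,
    Effect,
    KnowledgebaseEntry,
    VariantClass,
)

logger = logging.getLogger(__name__)

OUTLIER_THRESHOLD = 1.5
MIN_SAMPLES = 10  # a feature must be observed in at least this many samples


@dataclass(frozen=True)
class OutlierCall:
    sample_id: str
    feature: str  # gene or GENE:pSNNN
    level: str  # mrna | protein | phosphoprotein
    x: float
    q1: float
    q3: float
    iqr: float
    score: float
    direction: str  # high | low
    is_outlier: bool
    rank_in_sample: int | None = None


def cohort_quartiles(values: np.ndarray) -> tuple[float, float, float]:
    """(Q1, Q3, IQR) of a feature across the cohort.

    Missing values are ignored; fewer than 4 non-missing values raises
    ValueError (caller skips the feature).  Quantiles use linear
    interpolation between order statistics.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 4:
        raise ValueError(f"need >= 4 non-missing values, got {v.size}")
    q1, q3 = np.percentile(v, [25, 75])
    return float(q1), float(q3), float(q3 - q1)


def outlier_score(
    x: float, q1: float, q3: float, iqr: float, direction: str
) -> float:
    """(x - Q3)/IQR for direction 'high', (Q1 - x)/IQR for 'low'."""
    if iqr <= 0:
        raise ValueError("outlier score undefined for IQR <= 0")
    if direction == "high":
        return (x - q3) / iqr
    if direction == "low":
        return (q1 - x) / iqr
    raise ValueError(f"unknown direction {direction!r}")


def druggable_features(
    kb: list[KnowledgebaseEntry],
    sensitive_only: bool = True,
    include_cna: bool = True,
) -> dict[str, str]:
    """Feature -> direction for knowledgebase expression-linked entries.

    The druggability search targets genes whose overexpression (or copy
    number amplification) is associated with drug sensitivity; low-direction
    (tumor suppressor) entries are honoured when present.
    """
    out: dict[str, str] = {}
    for e in kb:
        if sensitive_only and e.effect is not Effect.SENSITIVE:
            continue
        if e.variant_class in EXPRESSION_CLASSES:
            out[e.gene] = (
                "high" if e.variant_class is VariantClass.EXPRESSION_HIGH else "low"
            )
        elif include_cna and e.variant_class is VariantClass.CNA:
            out.setdefault(e.gene, "high")
    return out


def call_outliers(
    matrix: ExpressionMatrix,
    kb: list[KnowledgebaseEntry],
    sample_cancer_types: dict[str, str] | None = None,
    exclude_cancer_types: tuple[str, ...] = (),
    min_samples: int = MIN_SAMPLES,
    threshold: float = OUTLIER_THRESHOLD,
    phosphosite_inherit_gene: bool = True,
    outliers_only: bool = True,
) -> list[OutlierCall]:
    """Score knowledgebase-linked features and call expression outliers.

    Samples from excluded cancer types are removed before quartiles are
    taken, so they contribute neither to the reference distribution nor to
    calls.  Features observed in fewer than ``min_samples`` samples are
    skipped.  Phosphosite rows (GENE:pSNNN) inherit their parent gene's
    knowledgebase direction when ``phosphosite_inherit_gene`` is set.
    """
    directions = druggable_features(kb)
    values = matrix.values
    if exclude_cancer_types and sample_cancer_types is not None:
        keep = [
            s
            for s in values.columns
            if sample_cancer_types.get(s) not in exclude_cancer_types
        ]
        values = values[keep]

    calls: list[OutlierCall] = []
    for feature in values.index:
        gene = feature.split(":", 1)[0] if phosphosite_inherit_gene else feature
        direction = directions.get(feature) or directions.get(gene)
        if direction is None:
            continue
        row = values.loc[feature].to_numpy(dtype=float)
        n_obs = int(np.sum(~np.isnan(row)))
        if n_obs < min_samples:
            logger.info("feature %s observed in %d samples; skipped", feature, n_obs)
            continue
        try:
            q1, q3, iqr = cohort_quartiles(row)
        except ValueError:
            logger.warning("feature %s has too few values; skipped", feature)
            continue
        if iqr == 0:
            logger.warning("feature %s is degenerate (IQR=0); calls suppressed", feature)
            continue
        for sample, x in zip(values.columns, row):
            if np.isnan(x):
                continue
            score = outlier_score(x, q1, q3, iqr, direction)
            is_out = score > threshold
            if is_out or not outliers_only:
                calls.append(
                    OutlierCall(
                        sample_id=sample,
                        feature=feature,
                        level=matrix.level,
                        x=float(x),
                        q1=q1,
                        q3=q3,
                        iqr=iqr,
                        score=float(score),
                        direction=direction,
                        is_outlier=bool(is_out),
                    )
                )
    logger.info("%d outlier calls at level %s", sum(c.is_outlier for c in calls), matrix.level)
    return calls


def rank_within_sample(calls: list[OutlierCall]) -> list[OutlierCall]:
    """Dense-rank calls within each sample, rank 1 = highest score; ties share."""
    by_sample: dict[str, list[OutlierCall]] = {}
    for c in calls:
        by_sample.setdefault(c.sample_id, []).append(c)
    ranked: list[OutlierCall] = []
    for sample_calls in by_sample.values():
        distinct = sorted({c.score for c in sample_calls}, reverse=True)
        rank_of = {s: i + 1 for i, s in enumerate(distinct)}
        for c in sample_calls:
            ranked.append(
                OutlierCall(**{**c.__dict__, "rank_in_sample": rank_of[c.score]})
            )
    return ranked


def outlier_calls_to_frame(calls: list[OutlierCall]) -> pd.DataFrame:
    cols = [
        "sample_id",
        "feature",
        "level",
        "x",
        "q1",
        "q3",
        "iqr",
        "score",
        "direction",
        "is_outlier",
        "rank_in_sample",
    ]
    return pd.DataFrame([{k: getattr(c, k) for k in cols} for c in calls], columns=cols)
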