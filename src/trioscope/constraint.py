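"""Gene-constraint (LOEUF) annotation, gating, and category comparisons.

LOEUF — the loss-of-function observed/expected upper bound fraction — marks
genes depleted of LoF variation in the general population; low values flag
likely haploinsufficient genes. The gate used for prioritization is
``loeuf <= threshold`` with a default threshold of 0.35 (the inclusive
boundary is the more permissive reading; the threshold is configurable).
Genes without a score fail the gate but are never excluded from
phenotype-panel screening, which is not constraint-driven.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import GeneAnnotation

logger = logging.getLogger(__name__)

DEFAULT_LOEUF_THRESHOLD = 0.35

X_CATEGORIES = ("XLD", "XLR", "XLDR", "X_other")
AUTOSOMAL_CATEGORIES = ("AD", "ADR", "AR", "A_other")


@dataclass(frozen=True)
class ConstraintComparison:
    """Welch two-sample comparison of LOEUF between two gene categories."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t_statistic: float
    degrees_freedom: float
    p_value: float


def annotate_genes(variants, constraint_table: dict) -> list:
    """Attach GeneAnnotation to each variant by case-sensitive symbol join.

    Genes absent from the table are annotated with loeuf=None so they can
    still flow through panel-based screening.
    """
    out = []
    for v in variants:
        ann = constraint_table.get(v.gene) if v.gene else None
        if ann is None and v.gene:
            ann = GeneAnnotation(
                gene=v.gene,
                chrom_class="chrX" if v.is_x else "autosome",
                loeuf=None,
            )
        v.extra_annotations["gene_annotation"] = ann
        out.append(v)
    return out


def passes_constraint_gate(annotation, threshold: float = DEFAULT_LOEUF_THRESHOLD) -> bool:
    """True iff the gene has a LOEUF score and it is <= threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if annotation is None or annotation.loeuf is None:
        return False
    return annotation.loeuf <= threshold


def mode_category(annotation: GeneAnnotation) -> str:
    """Collapse a gene's inheritance-mode set to one plotting category.

    Categories follow the usual constraint-by-inheritance breakdown:
    AD / ADR / AR / A_other on autosomes, XLD / XLR / XLDR / X_other on X.
    """
    modes = set(annotation.modes)
    x_modes = modes & {"XLD", "XLR", "XLDR"}
    if annotation.chrom_class == "autosome":
        if x_modes:
            raise ValueError(f"autosomal gene {annotation.gene} carries X-linked modes")
        if "ADR" in modes or {"AD", "AR"} <= modes:
            return "ADR"
        if "AD" in modes:
            return "AD"
        if "AR" in modes:
            return "AR"
        return "A_other"
    if "XLDR" in x_modes or {"XLD", "XLR"} <= x_modes:
        return "XLDR"
    if "XLD" in x_modes:
        return "XLD"
    if "XLR" in x_modes:
        return "XLR"
    return "X_other"


def welch_t_test(values_a, values_b, labels=("a", "b")) -> ConstraintComparison:
    """Welch's unequal-variance two-sample t-test (two-sided).

    t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b), with
    Welch-Satterthwaite degrees of freedom. Degenerate zero-variance groups
    with equal means return t=0, p=1.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("welch_t_test requires at least 2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return ConstraintComparison(
                labels[0], labels[1], len(a), len(b), a.mean(), b.mean(), 0.0, float(len(a) + len(b) - 2), 1.0
            )
        raise ValueError("degenerate variance in both groups with unequal means")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.ttest_ind(a, b, equal_var=False)
    return ConstraintComparison(
        group_a=labels[0],
        group_b=labels[1],
        n_a=len(a),
        n_b=len(b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t_statistic=float(res.statistic),
        degrees_freedom=float(res.df),
        p_value=float(res.pvalue),
    )


def category_summary(constraint_table: dict) -> pd.DataFrame:
    """Tidy per-category summary (n, mean, median LOEUF) for plotting."""
    rows = []
    for ann in constraint_table.values():
        if ann.loeuf is None:
            continue
        rows.append({"category": mode_category(ann), "loeuf": ann.loeuf})
    if not rows:
        return pd.DataFrame(columns=["category", "n", "mean", "median"])
    df = pd.DataFrame(rows)
    summary = (
        df.groupby("category")["loeuf"]
        .agg(n="count", mean="mean", median="median")
        .reset_index()
    )
    order = list(AUTOSOMAL_CATEGORIES) + list(X_CATEGORIES)
    summary["category"] = pd.Categorical(summary["category"], categories=order, ordered=True)
    return summary.sort_values("category").reset_index(drop=True)


def compare_loeuf_by_inheritance(constraint_table: dict):
    """Compare each X-linked category's LOEUF against autosomal-dominant.

    Returns (comparisons, summary): one Welch test per X category vs AD (a
    Bonferroni-adjusted p-value over the performed comparisons is attached to
    each comparison as ``p_bonferroni`` in the tidy frame), plus the
    per-category summary. Categories with fewer than 2 scored genes are
    skipped with a warning.
    """
    by_cat = {}
    for ann in constraint_table.values():
        if ann.loeuf is None:
            continue
        by_cat.setdefault(mode_category(ann), []).append(ann.loeuf)

    ad = by_cat.get("AD", [])
    comparisons = []
    if len(ad) < 2:
        logger.warning("fewer than 2 scored AD genes; no comparisons performed")
        return comparisons, category_summary(constraint_table)
    for cat in X_CATEGORIES:
        vals = by_cat.get(cat, [])
        if len(vals) < 2:
            logger.warning("category %s has < 2 scored genes; comparison skipped", cat)
            continue
        comparisons.append(welch_t_test(vals, ad, labels=(cat, "AD")))
    return comparisons, category_summary(constraint_table)


def comparisons_frame(comparisons) -> pd.DataFrame:
    """Tidy frame of comparisons with a labelled Bonferroni-adjusted column."""
    rows = [vars(c).copy() for c in comparisons]
    df = pd.DataFrame(rows)
    if len(df):
        df["p_bonferroni"] = np.minimum(df["p_value"] * len(df), 1.0)
    return df
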