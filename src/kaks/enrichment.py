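"""Functional-category enrichment and the expression-by-class comparison.

Enrichment of a gene class (e.g. the fast-evolving genes) against a
background is tested per category with Fisher's exact test, corrected
across categories within an annotation level by the Holm (Bonferroni
step-down) procedure, at a default threshold of 0.1 on the adjusted p;
only over-represented categories (observed > expected) are flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .stats import rank_sum_test

__all__ = [
    "EnrichmentResult",
    "fisher_exact_2x2",
    "holm_adjust",
    "enrich",
    "compare_expression_by_class",
]


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]] (summing
    hypergeometric probabilities no greater than the observed table's)."""
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("counts must be nonnegative integers")
    if a + b + c + d == 0:
        return 1.0
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def holm_adjust(pvals) -> list[float]:
    """Holm step-down adjusted p-values, returned in input order."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="holm")[1])


@dataclass(frozen=True)
class EnrichmentResult:
    category_id: str
    category_name: str
    level: str
    a: int  # class genes in category
    b: int  # class genes not in category
    c: int  # background-only genes in category
    d: int  # background-only genes in neither
    expected: float
    p_raw: float
    p_adj: float
    enriched: bool


def enrich(
    class_genes,
    background,
    annotation: pd.DataFrame,
    threshold: float = 0.1,
    adjusted: bool = True,
) -> list[EnrichmentResult]:
    """Category enrichment of ``class_genes`` against ``background``.

    ``annotation`` has columns gene_id, level, category_id, category_name
    (a gene may carry many categories).  One 2x2 Fisher test is run per
    category containing at least one class gene; Holm correction is
    applied within each level.  A category is enriched when the
    (adjusted, by default) p falls below ``threshold`` and the observed
    class count exceeds its independence expectation.
    """
    class_set = set(class_genes)
    bg = set(background)
    if not class_set:
        raise ValueError("empty gene class")
    if not class_set <= bg:
        raise ValueError("class genes must be a subset of the background")
    n_class = len(class_set)
    n_bg = len(bg)

    ann = annotation[annotation["gene_id"].isin(bg)]
    results: list[EnrichmentResult] = []
    for level, level_ann in ann.groupby("level"):
        rows = []
        for (cat_id, cat_name), grp in level_ann.groupby(
            ["category_id", "category_name"], sort=True
        ):
            members = set(grp["gene_id"])
            a = len(class_set & members)
            if a == 0:
                continue
            b = n_class - a
            c = len(members) - a
            d = n_bg - n_class - c
            expected = n_class * len(members) / n_bg
            rows.append((cat_id, cat_name, a, b, c, d, expected, fisher_exact_2x2(a, b, c, d)))
        if not rows:
            continue
        adj = holm_adjust([r[-1] for r in rows])
        for (cat_id, cat_name, a, b, c, d, expected, p_raw), p_adj in zip(rows, adj):
            p_used = p_adj if adjusted else p_raw
            results.append(
                EnrichmentResult(
                    cat_id, cat_name, level, a, b, c, d, expected,
                    p_raw, p_adj, bool(p_used < threshold and a > expected),
                )
            )
    return results


def enrichment_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


_PAIRS = (("slow", "fast"), ("intermediate", "fast"), ("slow", "intermediate"))


def compare_expression_by_class(classes: pd.DataFrame, tpm) -> dict:
    """Rank-sum comparisons of expression (TPM) between evolution classes.

    ``classes`` is a classification table (gene_id, class); ``tpm`` maps
    gene_id to expression.  Genes without expression are dropped (the
    count is reported).  Returns per-pair test results and per-class
    mean/median summaries.
    """
    tpm = dict(tpm)
    values: dict[str, list[float]] = {}
    dropped = 0
    for _, row in classes.iterrows():
        cls = row["class"]
        if cls == "unclassified":
            continue
        v = tpm.get(row["gene_id"])
        if v is None or (isinstance(v, float) and math.isnan(v)):
            dropped += 1
            continue
        values.setdefault(cls, []).append(float(v))

    summary = {
        cls: {"n": len(v), "mean": float(np.mean(v)), "median": float(np.median(v))}
        for cls, v in values.items()
    }
    tests = {}
    for x_cls, y_cls in _PAIRS:
        x, y = values.get(x_cls, []), values.get(y_cls, [])
        if len(x) >= 2 and len(y) >= 2:
            stat, p = rank_sum_test(x, y)
            tests[f"{x_cls}_vs_{y_cls}"] = {"statistic": stat, "p_value": p}
    return {"tests": tests, "summary": summary, "n_dropped": dropped}
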