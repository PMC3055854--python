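"""Cross-method consistency of Ka, Ks and Ka/Ks.

Two per-gene divergence indexes quantify how much the eight methods
disagree on one gene pair: (i) sample standard deviation normalized by
the mean and (ii) range (max minus min) normalized by the mean.  The
shared-gene percentage quantifies how similarly two methods *rank* genes:
the overlap of their top (or bottom) cutoff-fraction gene sets divided by
the set size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import rank_sum_test

__all__ = [
    "MethodTable",
    "DivergenceRecord",
    "filter_complete_genes",
    "divergence_index",
    "divergence_records",
    "compare_divergence",
    "shared_gene_percentage",
    "shared_percentage_matrix",
    "CANONICAL_CUTOFFS",
]

CANONICAL_CUTOFFS = (0.05, 0.10, 0.20, 0.30, 0.40, 0.50)


@dataclass
class MethodTable:
    """Genes x methods matrices of Ka, Ks and Ka/Ks (NaN marks NA)."""

    ka: pd.DataFrame
    ks: pd.DataFrame
    omega: pd.DataFrame

    def __post_init__(self):
        for df in (self.ks, self.omega):
            if not (df.index.equals(self.ka.index) and df.columns.equals(self.ka.columns)):
                raise ValueError("ka/ks/omega frames must share genes and methods")

    @property
    def genes(self) -> list[str]:
        return list(self.ka.index)

    @property
    def methods(self) -> list[str]:
        return list(self.ka.columns)

    def statistic(self, name: str) -> pd.DataFrame:
        return {"ka": self.ka, "ks": self.ks, "omega": self.omega}[name]

    @classmethod
    def from_estimates(cls, estimates, methods=None) -> "MethodTable":
        from .estimate import METHODS

        methods = list(methods or METHODS)
        frames = {}
        for stat in ("ka", "ks", "omega"):
            data: dict[str, dict[str, float]] = {}
            for e in estimates:
                na = getattr(e, f"{stat}_na")
                data.setdefault(e.gene_id, {})[e.method] = (
                    math.nan if na else getattr(e, stat)
                )
            frames[stat] = pd.DataFrame.from_dict(data, orient="index").reindex(
                columns=methods
            )
        genes = frames["ka"].index
        return cls(frames["ka"], frames["ks"].loc[genes], frames["omega"].loc[genes])


def filter_complete_genes(table: MethodTable) -> MethodTable:
    """Keep only genes with every method's Ka and Ks defined (the NA
    elimination rule of the consistency analyses)."""
    keep = table.ka.notna().all(axis=1) & table.ks.notna().all(axis=1)
    if not keep.any():
        warnings.warn("no gene has all methods defined; returning empty table")
    return MethodTable(table.ka[keep], table.ks[keep], table.omega[keep])


def divergence_index(values, mode: str = "sd_over_mean") -> float:
    """Cross-method dispersion of one gene's estimates.

    ``sd_over_mean`` uses the sample (n-1) standard deviation;
    ``range_over_mean`` uses (max - min).  NaN when the mean is not
    positive or any value is undefined.
    """
    v = np.asarray(list(values), dtype=float)
    if np.isnan(v).any():
        return math.nan
    m = v.mean()
    if not m > 0:
        return math.nan
    if mode == "sd_over_mean":
        return float(v.std(ddof=1) / m)
    if mode == "range_over_mean":
        return float((v.max() - v.min()) / m)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class DivergenceRecord:
    gene_id: str
    d_sd_ka: float
    d_sd_ks: float
    d_range_ka: float
    d_range_ks: float


def divergence_records(table: MethodTable) -> list[DivergenceRecord]:
    """Per-gene divergence indexes over the methods of a (typically
    NA-filtered) method table."""
    out = []
    for gene in table.genes:
        ka = table.ka.loc[gene].to_numpy()
        ks = table.ks.loc[gene].to_numpy()
        out.append(
            DivergenceRecord(
                gene,
                divergence_index(ka, "sd_over_mean"),
                divergence_index(ks, "sd_over_mean"),
                divergence_index(ka, "range_over_mean"),
                divergence_index(ks, "range_over_mean"),
            )
        )
    return out


def compare_divergence(records, mode: str = "sd") -> dict:
    """Two-sided rank-sum comparison of the Ka vs Ks divergence indexes."""
    attr_ka = f"d_{mode}_ka"
    attr_ks = f"d_{mode}_ks"
    d_ka = [getattr(r, attr_ka) for r in records]
    d_ks = [getattr(r, attr_ks) for r in records]
    d_ka = [v for v in d_ka if not math.isnan(v)]
    d_ks = [v for v in d_ks if not math.isnan(v)]
    if len(d_ka) < 2 or len(d_ks) < 2:
        raise ValueError("need at least two defined divergence indexes per group")
    stat, p = rank_sum_test(d_ka, d_ks)
    return {
        "statistic": stat,
        "p_value": p,
        "median_ka_index": float(np.median(d_ka)),
        "median_ks_index": float(np.median(d_ks)),
        "n": min(len(d_ka), len(d_ks)),
    }


def _ranked_set(series: pd.Series, k: int, tail: str) -> set:
    ordered = series.to_frame("v").reset_index(names="gene")
    ordered = ordered.sort_values(["v", "gene"], kind="stable")
    genes = list(ordered["gene"])
    return set(genes[:k]) if tail == "slow" else set(genes[-k:])


def shared_gene_percentage(
    table: MethodTable,
    statistic: str,
    reference: str,
    other: str,
    cutoff: float,
    tail: str = "fast",
) -> float:
    """Overlap of the two methods' top (fast) or bottom (slow)
    floor(cutoff*n) gene sets, as a percentage of the set size.

    Ties are broken by (value, gene_id) so boundary membership is
    deterministic.
    """
    if tail not in ("fast", "slow"):
        raise ValueError("tail must be 'fast' or 'slow'")
    if not 0 < cutoff <= 0.5:
        raise ValueError("cutoff must be in (0, 0.5]")
    if round(cutoff, 10) not in [round(c, 10) for c in CANONICAL_CUTOFFS]:
        warnings.warn(f"non-canonical cutoff {cutoff}")
    df = table.statistic(statistic)
    k = int(math.floor(cutoff * len(df)))
    if k == 0:
        raise ValueError(f"cutoff {cutoff} selects zero genes from {len(df)}")
    set_ref = _ranked_set(df[reference], k, tail)
    set_oth = _ranked_set(df[other], k, tail)
    return 100.0 * len(set_ref & set_oth) / k


def shared_percentage_matrix(
    table: MethodTable,
    reference: str = "GY",
    cutoffs=CANONICAL_CUTOFFS,
    statistics=("ka", "ks", "omega"),
    tails=("fast", "slow"),
) -> pd.DataFrame:
    """Shared-gene percentages of the reference method against every other
    method, for each statistic, cutoff and tail."""
    rows = []
    others = [m for m in table.methods if m != reference]
    for stat in statistics:
        for cutoff in cutoffs:
            for tail in tails:
                for other in others:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        pct = shared_gene_percentage(
                            table, stat, reference, other, cutoff, tail
                        )
                    rows.append(
                        {
                            "statistic": stat,
                            "cutoff": cutoff,
                            "tail": tail,
                            "reference": reference,
                            "other": other,
                            "shared_pct": pct,
                        }
                    )
    return pd.DataFrame(rows)
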