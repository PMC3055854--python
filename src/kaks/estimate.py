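"""Dispatch over the eight Ka/Ks estimation methods."""

from __future__ import annotations

import pandas as pd

from .codon_core import CodonAlignment
from .counting import COUNTING_METHODS, RateEstimate, estimate_counting
from .ml import ML_METHODS, estimate_gy, estimate_yn

__all__ = ["METHODS", "estimate", "estimate_all", "estimates_to_frame"]

#: the eight methods, in increasing model complexity
METHODS = (*COUNTING_METHODS, *ML_METHODS)


def estimate(aln: CodonAlignment, method: str) -> RateEstimate:
    """Run one named method on one codon alignment."""
    if method in COUNTING_METHODS:
        return estimate_counting(aln, method)
    if method in ("YN", "MYN"):
        return estimate_yn(aln, variant=method)
    if method == "GY":
        return estimate_gy(aln)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def estimate_all(aln: CodonAlignment, methods=None) -> list[RateEstimate]:
    return [estimate(aln, m) for m in (methods or METHODS)]


def estimates_to_frame(estimates) -> pd.DataFrame:
    """One row per (gene, method), ready for TSV export."""
    rows = []
    for e in estimates:
        rows.append(
            {
                "gene_id": e.gene_id,
                "method": e.method,
                "ka": e.ka,
                "ks": e.ks,
                "omega": e.omega,
                "kappa": e.kappa,
                "kappa_R": e.kappa_R,
                "kappa_Y": e.kappa_Y,
                "t": e.t,
                "ka_na": e.ka_na,
                "ks_na": e.ks_na,
                "omega_na": e.omega_na,
            }
        )
    return pd.DataFrame(rows)
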