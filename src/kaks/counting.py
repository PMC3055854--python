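"""The five approximate (counting) Ka/Ks methods: NG, LWL, MLWL, LPB, MLPB.

NG counts synonymous/nonsynonymous sites and pathway-averaged differences
and corrects the two raw proportions separately with Jukes-Cantor.  The
LWL family stratifies sites by degeneracy fold class (non-degenerate,
two-fold, four-fold), corrects per-class transition and transversion
proportions with the Kimura two-parameter formula, and combines the class
distances; LPB/MLPB combine them with a flexible transition/transversion
treatment of the two-fold sites, and MLWL/MLPB additionally repair the
arginine two-fold sites where the synonymous change is a transversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from . import codon_core as cc
from .codon_core import (
    CodonAlignment,
    FoldClassCounts,
    distance_jc,
    distance_k2p,
)

__all__ = ["RateEstimate", "COUNTING_METHODS", "estimate_counting", "estimate_ng"]

COUNTING_METHODS = ("NG", "LWL", "MLWL", "LPB", "MLPB")

# Arginine exception sites: at the first position of these codons the base
# degeneracy table yields a two-fold class, but the single synonymous
# alternative (AGA<->CGA, AGG<->CGG) is a *transversion* while both
# transitions are nonsynonymous -- the inverse of the two-fold pattern the
# LWL weighting assumes.  MLWL/MLPB swap the transition/transversion roles
# at exactly these four sites when accumulating class-stratified counts.
ARGININE_SITES = frozenset({("CGA", 0), ("CGG", 0), ("AGA", 0), ("AGG", 0)})


@dataclass
class RateEstimate:
    """One method's Ka/Ks output for one gene pair."""

    gene_id: str
    method: str
    ka: float = math.nan
    ks: float = math.nan
    omega: float = math.nan
    kappa: float = math.nan
    kappa_R: float = math.nan
    kappa_Y: float = math.nan
    t: float = math.nan
    ka_na: bool = False
    ks_na: bool = False
    omega_na: bool = False
    note: str = ""

    def _finish_omega(self):
        if self.ka_na or self.ks_na or not self.ks > 0.0:
            self.omega = math.nan
            self.omega_na = True
        else:
            self.omega = self.ka / self.ks
        return self


def estimate_counting(aln: CodonAlignment, method: str) -> RateEstimate:
    """Run one of the five counting methods on a codon alignment."""
    if method == "NG":
        return estimate_ng(aln)
    if method in ("LWL", "MLWL", "LPB", "MLPB"):
        return _estimate_lwl_family(aln, method)
    raise ValueError(f"unknown counting method {method!r}")


def estimate_ng(aln: CodonAlignment) -> RateEstimate:
    N, S = cc.count_sites_ng(aln)
    Sd = Nd = 0.0
    for ca, cb in zip(aln.codons_a, aln.codons_b):
        sd, nd = cc.pathway_diff_counts(ca, cb)
        Sd += sd
        Nd += nd
    est = RateEstimate(aln.gene_id, "NG")
    pn = Nd / N if N > 0 else 0.0
    ps = Sd / S if S > 0 else 0.0
    dn = distance_jc(pn)
    ds = distance_jc(ps)
    est.ka, est.ka_na = (dn.d, False) if not dn.na else (math.nan, True)
    est.ks, est.ks_na = (ds.d, False) if not ds.na else (math.nan, True)
    return est._finish_omega()


# ---------------------------------------------------------------------------
# LWL family


def _site_class(codon: str, pos: int) -> int:
    return cc.degeneracy(codon)[pos]


@lru_cache(maxsize=None)
def _class_diff_counts(codon_a: str, codon_b: str, arginine_fix: bool):
    """Pathway-averaged transition/transversion difference counts per fold
    class for one codon pair.

    Each single-base step contributes 0.5 to the fold class of its position
    in the step's source codon and 0.5 to that in its destination codon.
    With ``arginine_fix`` the ts/tv roles are swapped for any half landing
    on an arginine exception site.
    """
    paths = cc.enumerate_pathways(codon_a, codon_b)
    ts = {0: 0.0, 2: 0.0, 4: 0.0}
    tv = {0: 0.0, 2: 0.0, 4: 0.0}
    if not paths:
        return ts, tv
    w = 0.5 / len(paths)
    for path in paths:
        for pos, frm, to in path:
            transition = cc.is_transition(frm[pos], to[pos])
            for codon in (frm, to):
                if codon in cc.STOP_CODONS:
                    # only reachable on the all-paths-blocked fallback;
                    # attribute the half to the other codon's class instead
                    codon = to if codon is frm else frm
                    if codon in cc.STOP_CODONS:
                        continue
                cls = _site_class(codon, pos)
                eff_transition = transition
                if arginine_fix and (codon, pos) in ARGININE_SITES:
                    eff_transition = not transition
                (ts if eff_transition else tv)[cls] += w
    return ts, tv


def _fold_class_sites(aln: CodonAlignment) -> FoldClassCounts:
    counts = {0: 0.0, 2: 0.0, 4: 0.0}
    for codons in (aln.codons_a, aln.codons_b):
        for codon in codons:
            for cls in cc.degeneracy(codon):
                counts[cls] += 0.5
    return FoldClassCounts(counts[0], counts[2], counts[4])


def _estimate_lwl_family(aln: CodonAlignment, method: str) -> RateEstimate:
    arg_fix = method in ("MLWL", "MLPB")
    L = _fold_class_sites(aln)
    ts = {0: 0.0, 2: 0.0, 4: 0.0}
    tv = {0: 0.0, 2: 0.0, 4: 0.0}
    for ca, cb in zip(aln.codons_a, aln.codons_b):
        t1, t2 = _class_diff_counts(ca, cb, arg_fix)
        for cls in (0, 2, 4):
            ts[cls] += t1[cls]
            tv[cls] += t2[cls]

    Lmap = {0: L.L0, 2: L.L2, 4: L.L4}
    A, B = {}, {}
    na = False
    for cls in (0, 2, 4):
        if Lmap[cls] <= 0:
            A[cls] = B[cls] = 0.0
            continue
        res = distance_k2p(ts[cls] / Lmap[cls], tv[cls] / Lmap[cls])
        if res.na:
            na = True
            A[cls] = B[cls] = math.nan
        else:
            A[cls], B[cls] = res.ts, res.tv

    est = RateEstimate(aln.gene_id, method)
    if na:
        est.ka_na = est.ks_na = True
        return est._finish_omega()

    if method == "MLWL":
        kappa = _pooled_kappa(ts, tv, Lmap)
        est.kappa = kappa
        w2_syn = kappa / (kappa + 2.0)
    else:
        w2_syn = 1.0 / 3.0

    if method in ("LWL", "MLWL"):
        S_sites = L.L2 * w2_syn + L.L4
        N_sites = L.L0 + L.L2 * (1.0 - w2_syn)
        ks = (L.L2 * A[2] + L.L4 * (A[4] + B[4])) / S_sites if S_sites > 0 else math.nan
        ka = (L.L0 * (A[0] + B[0]) + L.L2 * B[2]) / N_sites if N_sites > 0 else math.nan
    else:  # LPB / MLPB
        ks = (
            (L.L2 * A[2] + L.L4 * A[4]) / (L.L2 + L.L4) + B[4]
            if (L.L2 + L.L4) > 0
            else math.nan
        )
        ka = (
            A[0] + (L.L0 * B[0] + L.L2 * B[2]) / (L.L0 + L.L2)
            if (L.L0 + L.L2) > 0
            else math.nan
        )

    est.ks, est.ks_na = (ks, False) if not math.isnan(ks) else (math.nan, True)
    est.ka, est.ka_na = (ka, False) if not math.isnan(ka) else (math.nan, True)
    return est._finish_omega()


def _pooled_kappa(ts: dict, tv: dict, Lmap: dict) -> float:
    """Transition/transversion rate ratio from K2P-corrected proportions
    pooled over all site classes; falls back to 2 when undefined."""
    Ltot = sum(Lmap.values())
    if Ltot <= 0:
        return 2.0
    P = sum(ts.values()) / Ltot
    Q = sum(tv.values()) / Ltot
    res = distance_k2p(P, Q)
    if res.na or not math.isfinite(res.kappa) or res.kappa <= 0:
        return 2.0
    return res.kappa
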