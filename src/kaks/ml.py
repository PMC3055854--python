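"""Model-based Ka/Ks estimators: GY (maximum likelihood) and YN/MYN
(iterative approximate).

GY fits a 61-state Markov codon model (F3x4 equilibrium frequencies,
transition/transversion ratio kappa, nonsynonymous/synonymous rate ratio
omega, divergence t in substitutions per codon) to the pairwise codon
data by maximum likelihood and converts the fitted parameters to Ka and
Ks under the mutational-opportunity site convention.

YN estimates kappa from degeneracy-stratified nucleotide comparisons,
weights site counting by codon-position frequencies and kappa, counts
differences with omega-weighted pathway averaging, corrects with the
Kimura two-parameter formula, and iterates the omega weighting to a fixed
point.  MYN does the same with separate purine (A<->G) and pyrimidine
(C<->T) transition classes and a Tamura-Nei correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize

from . import codon_core as cc
from .codon_core import CodonAlignment, distance_k2p, distance_tn93
from .counting import RateEstimate

__all__ = [
    "CodonModelParams",
    "f3x4_frequencies",
    "build_rate_matrix",
    "transition_probs",
    "flux_and_site_fractions",
    "estimate_gy",
    "estimate_yn",
    "ML_METHODS",
]

log = logging.getLogger(__name__)

ML_METHODS = ("YN", "MYN", "GY")

_N = len(cc.SENSE_CODONS)  # 61


@dataclass
class CodonModelParams:
    """Parameters of the pairwise codon substitution model."""

    t: float
    kappa: float = 2.0
    omega: float = 1.0
    kappa_R: float | None = None
    kappa_Y: float | None = None
    pi: np.ndarray | None = None  # over the 61 sense codons

    def resolved_kappas(self) -> tuple[float, float]:
        if self.kappa_R is not None or self.kappa_Y is not None:
            return (
                self.kappa if self.kappa_R is None else self.kappa_R,
                self.kappa if self.kappa_Y is None else self.kappa_Y,
            )
        return self.kappa, self.kappa


def _structure_masks():
    """Boolean 61x61 masks for single-base-change codon pairs."""
    single = np.zeros((_N, _N), bool)
    syn = np.zeros((_N, _N), bool)
    ts_R = np.zeros((_N, _N), bool)
    ts_Y = np.zeros((_N, _N), bool)
    for i, ci in enumerate(cc.SENSE_CODONS):
        for j, cj in enumerate(cc.SENSE_CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            single[i, j] = True
            syn[i, j] = cc.AA[ci] == cc.AA[cj]
            if cc.is_transition(ci[k], cj[k]):
                if cc.is_purine_transition(ci[k], cj[k]):
                    ts_R[i, j] = True
                else:
                    ts_Y[i, j] = True
    return single, syn, ts_R, ts_Y

_SINGLE, _SYN, _TS_R, _TS_Y = _structure_masks()
_TV = _SINGLE & ~_TS_R & ~_TS_Y
_NONSYN = _SINGLE & ~_SYN

_BASE_INDEX = {b: i for i, b in enumerate("TCAG")}
_CODON_POS_BASE = np.array(
    [[_BASE_INDEX[c[p]] for p in range(3)] for c in cc.SENSE_CODONS]
)


def f3x4_frequencies(aln: CodonAlignment, eps: float = 1e-6) -> np.ndarray:
    """F3x4 codon frequencies: the product of position-specific nucleotide
    frequencies estimated from both sequences, renormalized over the 61
    sense codons.  Zero positional frequencies get epsilon smoothing."""
    counts = np.zeros((3, 4))
    for codons in (aln.codons_a, aln.codons_b):
        for codon in codons:
            for p in range(3):
                counts[p, _BASE_INDEX[codon[p]]] += 1
    if (counts == 0).any():
        log.debug("%s: zero positional base count, epsilon-smoothing", aln.gene_id)
        counts = counts + eps * counts.sum(axis=1, keepdims=True).clip(min=1.0)
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = (
        freqs[0, _CODON_POS_BASE[:, 0]]
        * freqs[1, _CODON_POS_BASE[:, 1]]
        * freqs[2, _CODON_POS_BASE[:, 2]]
    )
    return pi / pi.sum()


def build_rate_matrix(params: CodonModelParams) -> np.ndarray:
    """Scaled 61x61 generator of the codon model.

    Off-diagonal rate i->j for single-base changes is pi_j times 1
    (synonymous transversion), kappa (synonymous transition), omega
    (nonsynonymous transversion) or omega*kappa (nonsynonymous
    transition); kappa splits into kappa_R / kappa_Y when those are set.
    Rows sum to zero and the matrix is scaled to mean rate 1, so t is
    measured in expected substitutions per codon.
    """
    pi = params.pi if params.pi is not None else np.full(_N, 1.0 / _N)
    kR, kY = params.resolved_kappas()
    omega = params.omega
    mult = np.zeros((_N, _N))
    mult[_TV] = 1.0
    mult[_TS_R] = kR
    mult[_TS_Y] = kY
    mult[_NONSYN] *= omega
    Q = mult * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -(pi * np.diag(Q)).sum()
    if rate > 0:
        Q /= rate
    return Q


def transition_probs(Q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t) via eigendecomposition of the reversible generator."""
    lam, U, dh, dhi = _eig_cache(Q, pi)
    return _probs_from_eig(lam, U, dh, dhi, t)


def _eig(Q: np.ndarray, pi: np.ndarray):
    dh = np.sqrt(pi)
    dhi = 1.0 / dh
    B = (Q * dh[:, None]) * dhi[None, :]
    B = 0.5 * (B + B.T)  # exactly symmetric under detailed balance
    lam, U = np.linalg.eigh(B)
    return lam, U, dh, dhi


_last_eig: list = [None, None]


def _eig_cache(Q: np.ndarray, pi: np.ndarray):
    key = (Q[0, 1], Q[1, 0], Q[-1, -2], Q.trace())
    if _last_eig[0] != key:
        _last_eig[0] = key
        _last_eig[1] = _eig(Q, pi)
    return _last_eig[1]


def _probs_from_eig(lam, U, dh, dhi, t):
    M = (U * np.exp(lam * t)) @ U.T
    P = (M * dhi[:, None]) * dh[None, :]
    return np.clip(P, 0.0, None)


def flux_and_site_fractions(params: CodonModelParams):
    """Nonsynonymous/synonymous flux fractions of the scaled generator and
    the mutational-opportunity site fractions (the same fluxes at
    omega = 1, kappa(s) and pi held fixed)."""
    pi = params.pi if params.pi is not None else np.full(_N, 1.0 / _N)
    Q = build_rate_matrix(params)
    flux = pi[:, None] * Q
    rho_N = flux[_NONSYN].sum()
    rho_S = flux[_SYN].sum()
    kR, kY = params.resolved_kappas()
    neutral = CodonModelParams(t=params.t, kappa_R=kR, kappa_Y=kY, omega=1.0, pi=pi)
    Q1 = build_rate_matrix(neutral)
    flux1 = pi[:, None] * Q1
    f_N = flux1[_NONSYN].sum()
    f_S = flux1[_SYN].sum()
    return rho_N, rho_S, f_N, f_S


def rates_from_params(params: CodonModelParams) -> tuple[float, float]:
    """(Ka, Ks) implied by the model parameters: t * flux_fraction /
    (3 * site_fraction), per the mutational-opportunity convention."""
    rho_N, rho_S, f_N, f_S = flux_and_site_fractions(params)
    ka = params.t * rho_N / (3.0 * f_N) if f_N > 0 else math.nan
    ks = params.t * rho_S / (3.0 * f_S) if f_S > 0 else math.nan
    return ka, ks


# ---------------------------------------------------------------------------
# GY maximum likelihood

_GY_STARTS = ((0.2, 2.0, 0.3), (1.0, 2.0, 1.0), (0.05, 1.0, 0.1))
_GY_BOUNDS = ((math.log(1e-4), math.log(60.0)),
              (math.log(0.05), math.log(100.0)),
              (math.log(1e-4), math.log(60.0)))


def estimate_gy(aln: CodonAlignment) -> RateEstimate:
    """Maximum-likelihood fit of (t, kappa, omega) on the pairwise codon
    data, with F3x4 frequencies and multi-start bounded quasi-Newton on
    the log-transformed parameters."""
    est = RateEstimate(aln.gene_id, "GY")
    if aln.identical:
        est.ka = est.ks = est.t = 0.0
        return est._finish_omega()

    pi = f3x4_frequencies(aln)
    pat: dict[tuple[int, int], int] = {}
    for ca, cb in zip(aln.codons_a, aln.codons_b):
        key = (cc.CODON_INDEX[ca], cc.CODON_INDEX[cb])
        pat[key] = pat.get(key, 0) + 1
    ii = np.array([k[0] for k in pat])
    jj = np.array([k[1] for k in pat])
    nn = np.array(list(pat.values()), dtype=float)
    log_pi_i = np.log(pi[ii])

    def nll(x):
        t, kappa, omega = np.exp(x)
        Q = build_rate_matrix(CodonModelParams(t=t, kappa=kappa, omega=omega, pi=pi))
        P = transition_probs(Q, pi, t)
        lik = P[ii, jj]
        return -float(np.sum(nn * (log_pi_i + np.log(np.maximum(lik, 1e-300)))))

    best = None
    for t0, k0, w0 in _GY_STARTS:
        res = minimize(
            nll,
            np.log([t0, k0, w0]),
            method="L-BFGS-B",
            bounds=_GY_BOUNDS,
            options={"maxiter": 200, "ftol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        est.ka_na = est.ks_na = True
        est.note = "optimizer failure"
        return est._finish_omega()

    t, kappa, omega = np.exp(best.x)
    est.t, est.kappa = float(t), float(kappa)
    params = CodonModelParams(t=float(t), kappa=float(kappa), omega=float(omega), pi=pi)
    est.ka, est.ks = rates_from_params(params)
    if not best.success:
        est.note = f"optimizer: {best.message}"
    return est._finish_omega()


# ---------------------------------------------------------------------------
# YN / MYN iterative approximate estimators


def _stratified_kappas(aln: CodonAlignment, variant: str):
    """Kappa estimate(s) from nucleotide comparisons at positions that are
    non-degenerate or four-fold degenerate in both sequences."""
    L = 0.0
    tsR = tsY = tv = 0.0
    base_counts = {b: 0.0 for b in "ACGT"}
    for ca, cb in zip(aln.codons_a, aln.codons_b):
        da, db = cc.degeneracy(ca), cc.degeneracy(cb)
        for p in range(3):
            for b in (ca[p], cb[p]):
                base_counts[b] += 1.0
            if da[p] != db[p] or da[p] == 2:
                continue
            L += 1.0
            x, y = ca[p], cb[p]
            if x == y:
                continue
            if cc.is_transition(x, y):
                if cc.is_purine_transition(x, y):
                    tsR += 1.0
                else:
                    tsY += 1.0
            else:
                tv += 1.0
    total = sum(base_counts.values())
    freqs = {b: v / total for b, v in base_counts.items()}
    if L <= 0:
        return 2.0, 2.0, freqs
    if variant == "YN":
        res = distance_k2p((tsR + tsY) / L, tv / L)
        k = res.kappa if (not res.na and math.isfinite(res.kappa) and res.kappa > 0) else 2.0
        return k, k, freqs
    res = distance_tn93(tsR / L, tsY / L, tv / L, freqs)
    if res.na or not (math.isfinite(res.kappa_R) and math.isfinite(res.kappa_Y)):
        return 2.0, 2.0, freqs
    return max(res.kappa_R, 1e-6), max(res.kappa_Y, 1e-6), freqs


def _kappa_mult(b1: str, b2: str, kR: float, kY: float) -> float:
    if cc.is_transition(b1, b2):
        return kR if cc.is_purine_transition(b1, b2) else kY
    return 1.0


def _weighted_sites(aln: CodonAlignment, kR: float, kY: float, pos_freqs) -> tuple[float, float]:
    """(N, S) with each single-base mutational opportunity weighted by the
    kappa class of the change and the positional frequency of the target
    base; stop-codon targets are excluded, so N + S = 3 * n_codons."""
    @lru_cache(maxsize=None)
    def codon_syn(codon: str) -> float:
        aa = cc.AA[codon]
        s = 0.0
        for p in range(3):
            w_syn = w_all = 0.0
            for b in cc.BASES:
                if b == codon[p]:
                    continue
                alt = codon[:p] + b + codon[p + 1 :]
                if alt in cc.STOP_CODONS:
                    continue
                w = _kappa_mult(codon[p], b, kR, kY) * pos_freqs[p][b]
                w_all += w
                if cc.AA[alt] == aa:
                    w_syn += w
            if w_all > 0:
                s += w_syn / w_all
        return s

    S = 0.5 * sum(codon_syn(c) for c in aln.codons_a) + 0.5 * sum(
        codon_syn(c) for c in aln.codons_b
    )
    return 3.0 * aln.n_codons - S, S


def _weighted_diffs(aln: CodonAlignment, kR: float, kY: float, omega: float):
    """Pathway difference counts with pathway weights proportional to the
    product over steps of kappa-class and omega multipliers.  Returns
    (syn, nonsyn) each split into (purine-ts, pyrimidine-ts, tv)."""
    syn = np.zeros(3)
    nonsyn = np.zeros(3)
    pair_counts: dict[tuple[str, str], int] = {}
    for ca, cb in zip(aln.codons_a, aln.codons_b):
        if ca != cb:
            pair_counts[(ca, cb)] = pair_counts.get((ca, cb), 0) + 1
    for (ca, cb), n in pair_counts.items():
        paths = cc.enumerate_pathways(ca, cb)
        if not paths:
            continue
        weights = []
        contribs = []
        for path in paths:
            w = 1.0
            contrib_s = np.zeros(3)
            contrib_n = np.zeros(3)
            for pos, frm, to in path:
                b1, b2 = frm[pos], to[pos]
                is_syn = cc._step_is_syn(frm, to)
                w *= _kappa_mult(b1, b2, kR, kY) * (1.0 if is_syn else omega)
                if cc.is_transition(b1, b2):
                    idx = 0 if cc.is_purine_transition(b1, b2) else 1
                else:
                    idx = 2
                (contrib_s if is_syn else contrib_n)[idx] += 1.0
            weights.append(w)
            contribs.append((contrib_s, contrib_n))
        wsum = sum(weights)
        if wsum <= 0:
            weights = [1.0] * len(paths)
            wsum = float(len(paths))
        for w, (cs, cn) in zip(weights, contribs):
            syn += n * (w / wsum) * cs
            nonsyn += n * (w / wsum) * cn
    return syn, nonsyn


def _corrected_distance(P1: float, P2: float, Q: float, variant: str, freqs) -> float:
    """Multiple-hit correction of one class's difference proportions:
    Tamura-Nei with two transition classes for MYN, falling back to the
    Kimura two-parameter form when the inversion is unidentified (e.g. a
    difference class is empty); plain K2P for YN."""
    if variant == "MYN":
        res = distance_tn93(P1, P2, Q, freqs)
        if not res.na:
            return res.d
        if P1 + P2 + Q >= 0.95:
            return math.nan
    res2 = distance_k2p(P1 + P2, Q)
    return math.nan if res2.na else res2.d


def estimate_yn(aln: CodonAlignment, variant: str = "YN") -> RateEstimate:
    """Iterative approximate estimator (YN) or its two-transition-class
    refinement (MYN)."""
    if variant not in ("YN", "MYN"):
        raise ValueError(f"unknown variant {variant!r}")
    est = RateEstimate(aln.gene_id, variant)
    kR, kY, base_freqs = _stratified_kappas(aln, variant)
    if variant == "YN":
        est.kappa = kR
    else:
        est.kappa_R, est.kappa_Y = kR, kY
        est.kappa = 0.5 * (kR + kY)
    if aln.identical:
        est.ka = est.ks = 0.0
        return est._finish_omega()

    # position-specific target-base frequencies for site weighting (F3x4)
    counts = [[0.0] * 4 for _ in range(3)]
    for codons in (aln.codons_a, aln.codons_b):
        for codon in codons:
            for p in range(3):
                counts[p][_BASE_INDEX[codon[p]]] += 1.0
    pos_freqs = []
    for p in range(3):
        tot = sum(counts[p]) or 1.0
        pos_freqs.append({b: max(counts[p][_BASE_INDEX[b]] / tot, 1e-6) for b in "ACGT"})
    pos_freqs = tuple(pos_freqs)

    N, S = _weighted_sites(aln, kR, kY, pos_freqs)
    omega = 1.0
    ka = ks = math.nan
    converged = False
    for _ in range(100):
        syn, nonsyn = _weighted_diffs(aln, kR, kY, omega)
        if S <= 0 or N <= 0:
            break
        ks_new = _corrected_distance(syn[0] / S, syn[1] / S, syn[2] / S, variant, base_freqs)
        ka_new = _corrected_distance(
            nonsyn[0] / N, nonsyn[1] / N, nonsyn[2] / N, variant, base_freqs
        )
        ka, ks = ka_new, ks_new
        if math.isnan(ka) or math.isnan(ks):
            break
        if ks > 0 and ka >= 0:
            omega_new = ka / ks if ka > 0 else 1e-6
        else:
            converged = True
            break
        if abs(omega_new - omega) <= 1e-8 * max(omega, 1e-12):
            omega = omega_new
            converged = True
            break
        omega = omega_new
    if not converged:
        est.note = "iteration did not converge" if not math.isnan(ka) else "saturation"
    est.ka, est.ka_na = (ka, False) if not math.isnan(ka) else (math.nan, True)
    est.ks, est.ks_na = (ks, False) if not math.isnan(ks) else (math.nan, True)
    return est._finish_omega()
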