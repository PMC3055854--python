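"""Genetic-code services shared by every Ka/Ks estimator.

Degeneracy classification, mutation-pathway enumeration between codons,
site and difference counting, and the nucleotide distance corrections
(Jukes-Cantor, Kimura two-parameter, Tamura-Nei) used to correct raw
difference proportions for multiple hits.

All tables are built for the standard (universal) genetic code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
from Bio.Data import CodonTable

__all__ = [
    "BASES",
    "SENSE_CODONS",
    "STOP_CODONS",
    "AA",
    "CodonAlignment",
    "SiteCounts",
    "FoldClassCounts",
    "DistanceResult",
    "K2PResult",
    "TN93Result",
    "EmptyAlignmentError",
    "FrameError",
    "build_codon_alignment",
    "degeneracy",
    "count_sites_ng",
    "enumerate_pathways",
    "pathway_diff_counts",
    "distance_jc",
    "distance_k2p",
    "distance_tn93",
    "is_transition",
    "is_purine_transition",
]

BASES = "TCAG"

_table = CodonTable.unambiguous_dna_by_id[1]
#: codon -> one-letter amino acid, sense codons only
AA: dict[str, str] = dict(_table.forward_table)
STOP_CODONS = frozenset(_table.stop_codons)
ALL_CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def is_transition(b1: str, b2: str) -> bool:
    """True when the base change b1->b2 is a transition (A<->G or C<->T)."""
    s = {b1, b2}
    return s == _PURINES or s == _PYRIMIDINES


def is_purine_transition(b1: str, b2: str) -> bool:
    return {b1, b2} == _PURINES


class FrameError(ValueError):
    """Sequence length is not a multiple of three."""


class EmptyAlignmentError(ValueError):
    """No codon columns survive filtering."""


@dataclass(frozen=True)
class CodonAlignment:
    """A gap/ambiguity/stop-filtered pair of in-frame coding sequences.

    The universal input to all eight estimators: equal numbers of
    unambiguous sense codons in each sequence.
    """

    gene_id: str
    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]

    def __post_init__(self):
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError(f"{self.gene_id}: unequal codon counts")
        for cod in (*self.codons_a, *self.codons_b):
            if cod in STOP_CODONS or cod not in CODON_INDEX:
                raise ValueError(f"{self.gene_id}: invalid codon {cod!r}")

    @property
    def n_codons(self) -> int:
        return len(self.codons_a)

    @property
    def identical(self) -> bool:
        return self.codons_a == self.codons_b


@dataclass(frozen=True)
class SiteCounts:
    """Nonsynonymous/synonymous site and difference totals for one pair."""

    N: float
    S: float
    Nd: float
    Sd: float


@dataclass(frozen=True)
class FoldClassCounts:
    """Counts of non-degenerate (L0), two-fold (L2) and four-fold (L4) sites."""

    L0: float
    L2: float
    L4: float


@dataclass(frozen=True)
class DistanceResult:
    p: float
    P: float
    Q: float
    d: float
    na: bool = False


@dataclass(frozen=True)
class K2PResult:
    """Kimura two-parameter correction split into its components.

    ``ts`` and ``tv`` are the corrected transition and transversion parts
    (d = ts + tv); ``kappa`` is the implied transition/transversion *rate*
    ratio 2*ts/tv (two transversion directions per site against one
    transition direction).
    """

    d: float
    ts: float
    tv: float
    kappa: float
    na: bool = False


@dataclass(frozen=True)
class TN93Result:
    """Tamura-Nei correction with separate purine/pyrimidine transitions."""

    d: float
    kappa_R: float
    kappa_Y: float
    na: bool = False


_AMBIG_OK = frozenset("ACGT")


def build_codon_alignment(pair) -> CodonAlignment:
    """Filter a :class:`~kaks.seq_io.SequencePair` down to clean codon columns.

    Codon columns containing a gap, an ambiguous base (anything outside
    ACGT) or a stop codon in either sequence are dropped whole; the rest
    are kept in frame and in order.
    """
    a, b = pair.seq_a, pair.seq_b
    if len(a) % 3 != 0:
        raise FrameError(f"{pair.gene_id}: length {len(a)} not divisible by 3")
    cods_a, cods_b = [], []
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if not (set(ca) <= _AMBIG_OK and set(cb) <= _AMBIG_OK):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        cods_a.append(ca)
        cods_b.append(cb)
    if not cods_a:
        raise EmptyAlignmentError(f"{pair.gene_id}: no codon columns survive filtering")
    return CodonAlignment(pair.gene_id, tuple(cods_a), tuple(cods_b))


@lru_cache(maxsize=None)
def degeneracy(codon: str) -> tuple[int, int, int]:
    """Fold class (0, 2 or 4) of each position of a sense codon.

    A position is four-fold if all three alternative bases are synonymous,
    non-degenerate if none is, and two-fold otherwise.  The three-fold
    isoleucine third position falls in the two-fold class under this rule
    (the LWL convention).  Changes to stop codons count as nonsynonymous.
    """
    if codon in STOP_CODONS or codon not in CODON_INDEX:
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = AA[codon]
    out = []
    for pos in range(3):
        n_syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in STOP_CODONS and AA[alt] == aa:
                n_syn += 1
        out.append(4 if n_syn == 3 else (0 if n_syn == 0 else 2))
    return tuple(out)


@lru_cache(maxsize=None)
def _syn_site_fraction(codon: str) -> float:
    """Synonymous sites of one codon: (#synonymous single-base changes)/3 per
    position, summed.  Stop-codon targets count as nonsynonymous so that the
    per-codon total of synonymous + nonsynonymous sites is exactly 3."""
    aa = AA[codon]
    s = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in STOP_CODONS and AA[alt] == aa:
                s += 1.0
    return s / 3.0


def count_sites_ng(aln: CodonAlignment) -> tuple[float, float]:
    """Nei-Gojobori style (N, S) site counts, averaged between sequences."""
    s_a = sum(_syn_site_fraction(c) for c in aln.codons_a)
    s_b = sum(_syn_site_fraction(c) for c in aln.codons_b)
    S = 0.5 * (s_a + s_b)
    N = 3.0 * aln.n_codons - S
    return N, S


@lru_cache(maxsize=None)
def enumerate_pathways(codon_a: str, codon_b: str):
    """All mutation pathways between two sense codons.

    Each pathway is a tuple of single-base steps ``(pos, from_codon,
    to_codon)`` following one ordering of the differing positions.
    Pathways passing through a stop codon are discarded; if *every*
    ordering crosses a stop, the unfiltered enumeration is returned so
    that difference counts stay defined.
    """
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]

    def walk(skip_stops: bool):
        paths = []
        for order in permutations(diffs):
            cur = codon_a
            steps = []
            ok = True
            for pos in order:
                nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
                if skip_stops and nxt in STOP_CODONS:
                    ok = False
                    break
                steps.append((pos, cur, nxt))
                cur = nxt
            if ok:
                paths.append(tuple(steps))
        return tuple(paths)

    if not diffs:
        return ()
    paths = walk(skip_stops=True)
    if not paths:
        paths = walk(skip_stops=False)
    return paths


def _step_is_syn(frm: str, to: str) -> bool:
    # a step may touch a stop codon only on the no-stop-free-path fallback;
    # count any step into/out of a stop as nonsynonymous
    if frm in STOP_CODONS or to in STOP_CODONS:
        return False
    return AA[frm] == AA[to]


@lru_cache(maxsize=None)
def pathway_diff_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts."""
    paths = enumerate_pathways(codon_a, codon_b)
    if not paths:
        return 0.0, 0.0
    sd = nd = 0.0
    for path in paths:
        for pos, frm, to in path:
            if _step_is_syn(frm, to):
                sd += 1.0
            else:
                nd += 1.0
    k = len(paths)
    return sd / k, nd / k


def distance_jc(p: float) -> DistanceResult:
    """Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3); NA at saturation."""
    if p < 0:
        raise ValueError("negative proportion")
    if p == 0:
        return DistanceResult(p=0.0, P=0.0, Q=0.0, d=0.0)
    if p >= 0.75:
        return DistanceResult(p=p, P=math.nan, Q=math.nan, d=math.nan, na=True)
    return DistanceResult(p=p, P=math.nan, Q=math.nan, d=-0.75 * math.log1p(-4.0 * p / 3.0))


def distance_k2p(P: float, Q: float) -> K2PResult:
    """Kimura two-parameter correction from transition/transversion proportions."""
    if P < 0 or Q < 0:
        raise ValueError("negative proportion")
    arg1 = 1.0 - 2.0 * P - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0.0 or arg2 <= 0.0:
        return K2PResult(math.nan, math.nan, math.nan, math.nan, na=True)
    tv = -0.5 * math.log(arg2)
    d = -0.5 * math.log(arg1) - 0.25 * math.log(arg2)
    ts = d - tv
    kappa = 2.0 * ts / tv if tv > 0 else math.inf
    return K2PResult(d=d, ts=ts, tv=tv, kappa=kappa)


_B2I = {"A": 0, "C": 1, "G": 2, "T": 3}


def _tn93_expected(d: float, kR: float, kY: float, g: np.ndarray):
    """Expected (P1, P2, Q) difference proportions for a pair separated by
    d substitutions per site under the Tamura-Nei model.

    The generator uses per-target rate multipliers: kR for A<->G, kY for
    C<->T, 1 for transversions, times the target base frequency, scaled to
    mean rate one so d is directly comparable across parameter values.
    """
    mult = np.ones((4, 4))
    mult[0, 2] = mult[2, 0] = kR
    mult[1, 3] = mult[3, 1] = kY
    Q = mult * g[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -(g * np.diag(Q)).sum()
    Q /= rate
    # symmetrized eigendecomposition (the chain is reversible)
    dh = np.sqrt(g)
    B = (Q * dh[:, None]) / dh[None, :]
    lam, U = np.linalg.eigh(0.5 * (B + B.T))
    P = ((U * np.exp(lam * d)) @ U.T) / dh[:, None] * dh[None, :]
    joint = g[:, None] * P  # probability of observing base pair (i, j)
    p1 = joint[0, 2] + joint[2, 0]
    p2 = joint[1, 3] + joint[3, 1]
    q = joint.sum() - np.trace(joint) - p1 - p2
    return p1, p2, q


def distance_tn93(P1: float, P2: float, Q: float, freqs: dict[str, float]) -> TN93Result:
    """Tamura-Nei correction with two transition classes.

    ``P1`` is the observed A<->G (purine) transition proportion, ``P2``
    the C<->T (pyrimidine) one, ``Q`` the transversion proportion and
    ``freqs`` the equilibrium base frequencies.  The model (separate
    purine/pyrimidine transition rate multipliers kappa_R, kappa_Y over a
    unit transversion rate) is inverted numerically for the distance and
    the two multipliers; undefined inversions (saturation, missing
    difference classes) return the NA flag.
    """
    from scipy.optimize import root

    g = np.array([max(freqs.get(b, 0.0), 1e-9) for b in "ACGT"])
    g = g / g.sum()
    if P1 < 0 or P2 < 0 or Q < 0:
        raise ValueError("negative proportion")
    p_tot = P1 + P2 + Q
    if p_tot == 0.0:
        return TN93Result(d=0.0, kappa_R=math.nan, kappa_Y=math.nan, na=False)
    if min(P1, P2, Q) <= 0.0 or p_tot >= 0.95:
        # a missing class leaves a multiplier unidentified; very high raw
        # divergence is treated as saturated
        return TN93Result(math.nan, math.nan, math.nan, na=True)

    target = np.array([P1, P2, Q])

    def resid(x):
        d, kR, kY = np.exp(x)
        return np.array(_tn93_expected(d, kR, kY, g)) - target

    sol = root(resid, np.log([max(p_tot, 1e-3), 2.0, 2.0]), method="hybr")
    if not sol.success or not np.all(np.isfinite(sol.x)) or np.max(np.abs(sol.fun)) > 1e-8:
        return TN93Result(math.nan, math.nan, math.nan, na=True)
    d, kR, kY = np.exp(sol.x)
    if d > 30:
        return TN93Result(math.nan, math.nan, math.nan, na=True)
    return TN93Result(d=float(d), kappa_R=float(kR), kappa_Y=float(kY))


# ---------------------------------------------------------------------------
# debug / inspection helpers

def per_codon_site_table(aln: CodonAlignment):
    """Per-codon-column NG site bookkeeping, for inspection dumps."""
    rows = []
    for i, (ca, cb) in enumerate(zip(aln.codons_a, aln.codons_b)):
        sd, nd = pathway_diff_counts(ca, cb)
        s = 0.5 * (_syn_site_fraction(ca) + _syn_site_fraction(cb))
        rows.append(
            {
                "column": i,
                "codon_a": ca,
                "codon_b": cb,
                "S_sites": s,
                "N_sites": 3.0 - s,
                "Sd": sd,
                "Nd": nd,
            }
        )
    return rows
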