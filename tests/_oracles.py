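"""Independent brute-force oracles, sharing no code with the package.

Every table here is derived directly from the standard genetic code via
Biopython, and every calculation is a literal transcription of the
definition being checked (exhaustive enumeration, closed forms).
"""

import math
from itertools import permutations

from scipy.stats import hypergeom

GENETIC_CODE = {}
_BASES = "TCAG"
_AAS = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, (_a) in enumerate(_AAS):
    _codon = _BASES[_i // 16] + _BASES[(_i // 4) % 4] + _BASES[_i % 4]
    GENETIC_CODE[_codon] = _a
STOPS = {c for c, a in GENETIC_CODE.items() if a == "*"}


def oracle_syn_sites(codon):
    """Synonymous sites of a codon: synonymous single-base changes / 3 per
    position, stops counting as nonsynonymous."""
    s = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in STOPS and GENETIC_CODE[alt] == GENETIC_CODE[codon]:
                s += 1 / 3
    return s


def oracle_pathway_counts(c1, c2):
    """Equal-weight pathway-averaged (syn, nonsyn) difference counts,
    skipping stop-crossing orderings (falling back to all orderings when
    every one is blocked)."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0

    def enumerate_paths(allow_stops):
        results = []
        for order in permutations(diffs):
            cur = c1
            steps = []
            blocked = False
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if nxt in STOPS and not allow_stops:
                    blocked = True
                    break
                steps.append((cur, nxt))
                cur = nxt
            if not blocked:
                results.append(steps)
        return results

    paths = enumerate_paths(False) or enumerate_paths(True)
    sd = nd = 0.0
    for steps in paths:
        for cur, nxt in steps:
            if (
                cur not in STOPS
                and nxt not in STOPS
                and GENETIC_CODE[cur] == GENETIC_CODE[nxt]
            ):
                sd += 1
            else:
                nd += 1
    return sd / len(paths), nd / len(paths)


def oracle_ng(codons_a, codons_b):
    """Brute-force NG: site counts averaged between sequences, pathway
    differences, separate Jukes-Cantor corrections.  Returns (ka, ks),
    NaN at saturation."""
    n = len(codons_a)
    S = 0.5 * (
        sum(oracle_syn_sites(c) for c in codons_a)
        + sum(oracle_syn_sites(c) for c in codons_b)
    )
    N = 3 * n - S
    Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        sd, nd = oracle_pathway_counts(ca, cb)
        Sd += sd
        Nd += nd

    def jc(p):
        if p >= 0.75:
            return math.nan
        return -0.75 * math.log(1 - 4 * p / 3)

    return jc(Nd / N), jc(Sd / S)


def oracle_fisher_two_sided(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration over
    all tables with the observed margins."""
    row1, col1, total = a + b, a + c, a + b + c + d
    if total == 0:
        return 1.0
    p_obs = hypergeom.pmf(a, total, col1, row1)
    p = 0.0
    for x in range(max(0, row1 + col1 - total), min(row1, col1) + 1):
        px = hypergeom.pmf(x, total, col1, row1)
        if px <= p_obs * (1 + 1e-7):
            p += px
    return min(p, 1.0)


def oracle_holm(pvals):
    """Literal Holm step-down: sort ascending, adjusted_(i) is the running
    maximum of (m - i + 1) * p_(i), capped at one, mapped back."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted
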