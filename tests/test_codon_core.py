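"""Genetic-code services: degeneracy, pathways, site counts, distances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kaks.codon_core import (
    AA,
    SENSE_CODONS,
    STOP_CODONS,
    CodonAlignment,
    EmptyAlignmentError,
    FrameError,
    build_codon_alignment,
    count_sites_ng,
    degeneracy,
    distance_jc,
    distance_k2p,
    distance_tn93,
    enumerate_pathways,
    pathway_diff_counts,
)
from kaks.seq_io import SequencePair

from _oracles import GENETIC_CODE, oracle_pathway_counts, oracle_syn_sites

sense = st.sampled_from(SENSE_CODONS)


def test_genetic_code_agrees_with_independent_table():
    for codon in SENSE_CODONS:
        assert AA[codon] == GENETIC_CODE[codon]
    assert STOP_CODONS == {c for c, a in GENETIC_CODE.items() if a == "*"}


class TestBuildCodonAlignment:
    def test_gap_codon_column_dropped(self):
        aln = build_codon_alignment(SequencePair("g", "ATG---AAA", "ATGGCGAAA"))
        assert aln.codons_a == ("ATG", "AAA")
        assert aln.codons_b == ("ATG", "AAA")

    def test_stop_codon_column_dropped(self):
        aln = build_codon_alignment(SequencePair("g", "ATGTAA", "ATGCAA"))
        assert aln.n_codons == 1 and aln.codons_a == ("ATG",)

    def test_ambiguous_codon_column_dropped(self):
        aln = build_codon_alignment(SequencePair("g", "ATNAAA", "ATGAAA"))
        assert aln.n_codons == 1 and aln.codons_a == ("AAA",)

    def test_frame_error(self):
        with pytest.raises(FrameError):
            build_codon_alignment(SequencePair("g", "ATGA", "ATGA"))

    def test_nothing_left(self):
        with pytest.raises(EmptyAlignmentError):
            build_codon_alignment(SequencePair("g", "NNN", "AAA"))


class TestDegeneracy:
    @pytest.mark.parametrize(
        "codon,expected", [("GGG", (0, 0, 4)), ("TTT", (0, 0, 2)), ("ATG", (0, 0, 0))]
    )
    def test_known_codons(self, codon, expected):
        assert degeneracy(codon) == expected

    def test_matches_exhaustive_enumeration(self):
        # independent recount of synonymous alternatives for all 61 codons
        for codon in SENSE_CODONS:
            for pos, cls in enumerate(degeneracy(codon)):
                n_syn = sum(
                    1
                    for b in "TCAG"
                    if b != codon[pos]
                    and (alt := codon[:pos] + b + codon[pos + 1 :]) not in STOP_CODONS
                    and GENETIC_CODE[alt] == GENETIC_CODE[codon]
                )
                assert cls == {0: 0, 1: 2, 2: 2, 3: 4}[n_syn]

    def test_arginine_cga_first_position_synonymous_transversion(self):
        # CGA -> AGA is synonymous yet a transversion: the irregularity the
        # modified LWL-family methods single out
        assert degeneracy("CGA")[0] == 2
        assert GENETIC_CODE["CGA"] == GENETIC_CODE["AGA"] == "R"

    def test_stop_rejected(self):
        with pytest.raises(ValueError):
            degeneracy("TAA")


class TestPathways:
    def test_two_difference_example(self):
        # TTT vs GTA: the path via GTT has 1 syn + 1 nonsyn step, the path
        # via TTA has 2 nonsyn steps
        paths = enumerate_pathways("TTT", "GTA")
        assert len(paths) == 2
        sd, nd = pathway_diff_counts("TTT", "GTA")
        assert sd == pytest.approx(0.5) and nd == pytest.approx(1.5)

    def test_identical_codons(self):
        assert enumerate_pathways("AAA", "AAA") == ()
        assert pathway_diff_counts("AAA", "AAA") == (0.0, 0.0)

    def test_stop_crossing_orderings_removed(self):
        # TAT vs TGG differs at positions 2 and 3; the ordering through
        # TAG (a stop) is discarded, leaving the single path via TGT
        paths = enumerate_pathways("TAT", "TGG")
        assert len(paths) == 1
        intermediates = [to for _, _, to in paths[0][:-1]]
        assert intermediates == ["TGT"]

    def test_three_difference_pair_bounded_and_stop_free(self):
        for c1, c2 in [("TTT", "GCA"), ("AAA", "TGC")]:
            paths = enumerate_pathways(c1, c2)
            assert 1 <= len(paths) <= 6
            for path in paths:
                for _, _, to in path[:-1]:
                    assert to not in STOP_CODONS

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(sense, sense)
    def test_counts_match_independent_oracle(self, c1, c2):
        sd, nd = pathway_diff_counts(c1, c2)
        osd, ond = oracle_pathway_counts(c1, c2)
        assert sd == pytest.approx(osd, abs=1e-12)
        assert nd == pytest.approx(ond, abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(sense, sense)
    def test_pathway_count_bounded_by_factorial(self, c1, c2):
        k = sum(a != b for a, b in zip(c1, c2))
        assert len(enumerate_pathways(c1, c2)) <= math.factorial(k) if k else True


class TestSiteCounts:
    def test_single_codon_examples(self):
        # TTT: one synonymous change (TTT->TTC) out of nine
        aln = CodonAlignment("g", ("TTT",), ("TTT",))
        N, S = count_sites_ng(aln)
        assert S == pytest.approx(1 / 3) and N == pytest.approx(8 / 3)
        aln = CodonAlignment("g", ("CCC",), ("CCC",))
        N, S = count_sites_ng(aln)
        assert S == pytest.approx(1.0) and N == pytest.approx(2.0)

    def test_conservation_and_oracle_on_random_alignments(self, rng):
        from conftest import random_alignment

        for _ in range(50):
            aln = random_alignment(rng, n_codons=20)
            N, S = count_sites_ng(aln)
            assert N + S == pytest.approx(3 * aln.n_codons, abs=1e-9)
            S_oracle = 0.5 * (
                sum(oracle_syn_sites(c) for c in aln.codons_a)
                + sum(oracle_syn_sites(c) for c in aln.codons_b)
            )
            assert S == pytest.approx(S_oracle, abs=1e-9)


class TestDistances:
    def test_jc_values(self):
        assert distance_jc(0.0).d == 0.0
        assert distance_jc(0.3).d == pytest.approx(0.38312, abs=1e-5)
        assert distance_jc(0.75).na

    def test_k2p_values(self):
        assert distance_k2p(0.0, 0.0).d == 0.0
        res = distance_k2p(0.2, 0.1)
        expected = -0.5 * math.log(1 - 0.4 - 0.1) - 0.25 * math.log(1 - 0.2)
        assert res.d == pytest.approx(expected)
        assert res.ts + res.tv == pytest.approx(res.d)
        assert distance_k2p(0.5, 0.0).na

    def test_k2p_reduces_to_jc_for_one_to_two_pattern(self):
        # P:Q = 1:2 is the equal-rate pattern where K2P collapses to JC
        p = 0.15
        assert distance_k2p(p / 3, 2 * p / 3).d == pytest.approx(distance_jc(p).d, rel=1e-9)

    @pytest.mark.parametrize("p", [0.05, 0.2, 0.5, 0.7])
    def test_corrections_inflate_raw_proportion(self, p):
        assert distance_jc(p).d >= p
        res = distance_k2p(p / 3, 2 * p / 3)
        assert res.d >= p

    def test_monotonicity(self):
        jc = [distance_jc(p).d for p in np.linspace(0.01, 0.7, 20)]
        assert all(b > a for a, b in zip(jc, jc[1:]))
        k2p = [distance_k2p(P, 0.05).d for P in np.linspace(0.01, 0.4, 10)]
        assert all(b > a for a, b in zip(k2p, k2p[1:]))

    def test_tn93_round_trip(self):
        # generate proportions from known multipliers, invert, recover them
        from kaks.codon_core import _tn93_expected

        g = np.array([0.3, 0.2, 0.3, 0.2])
        p1, p2, q = _tn93_expected(0.4, 4.0, 1.5, g)
        res = distance_tn93(p1, p2, q, dict(zip("ACGT", g)))
        assert not res.na
        assert res.d == pytest.approx(0.4, rel=1e-6)
        assert res.kappa_R == pytest.approx(4.0, rel=1e-5)
        assert res.kappa_Y == pytest.approx(1.5, rel=1e-5)

    def test_tn93_degenerate_inputs(self):
        res = distance_tn93(0.0, 0.0, 0.0, {b: 0.25 for b in "ACGT"})
        assert res.d == 0.0 and not res.na
        assert distance_tn93(0.0, 0.1, 0.1, {b: 0.25 for b in "ACGT"}).na
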