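"""Reading, validating and quality-checking pairwise coding alignments.

Supports AXT blocks (header line plus two sequence lines per block) and
FASTA files holding an even number of records paired by adjacency, plus
back-translation of gapped protein alignments onto their source CDS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from statistics import mean, stdev

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "SequencePair",
    "QcRecord",
    "MalformedPairError",
    "BackTranslationError",
    "read_pairwise_alignments",
    "write_axt",
    "write_fasta_pairs",
    "backtranslate",
    "qc_pair",
    "qc_dataset",
]

_ALPHABET = frozenset("ACGTN-")


class MalformedPairError(ValueError):
    """A sequence pair violates the pairing or length contract."""


class BackTranslationError(ValueError):
    """Protein alignment and CDS disagree during back-translation."""


def _normalize(seq: str, gene_id: str) -> str:
    s = seq.strip().upper().replace("U", "T")
    bad = set(s) - _ALPHABET
    if bad:
        raise MalformedPairError(f"{gene_id}: invalid characters {sorted(bad)}")
    return s


@dataclass(frozen=True)
class SequencePair:
    """One aligned one-to-one ortholog pair (equal-length, IUPAC + gaps)."""

    gene_id: str
    seq_a: str
    seq_b: str

    def __post_init__(self):
        a = _normalize(self.seq_a, self.gene_id)
        b = _normalize(self.seq_b, self.gene_id)
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        if len(a) != len(b):
            raise MalformedPairError(
                f"{self.gene_id}: aligned lengths differ ({len(a)} vs {len(b)})"
            )


@dataclass(frozen=True)
class QcRecord:
    """Per-pair alignment quality statistics.

    Identity is computed over columns where neither sequence has a gap;
    the gap percentage counts columns with a gap in either sequence; the
    N fraction is Ns over nucleotide (non-gap) characters of both
    sequences pooled.
    """

    gene_id: str
    pct_identity: float
    pct_gap: float
    n_fraction: float
    has_n: bool


def read_pairwise_alignments(source, format: str = "axt") -> list[SequencePair]:
    """Read pairwise alignments from an AXT or paired-FASTA file.

    AXT blocks are a header line, two sequence lines and a blank
    separator; the full header line (stripped) is kept as the gene id.
    FASTA input must hold an even number of records; consecutive records
    are paired and the first record's id names the pair.
    """
    path = Path(source)
    if format == "axt":
        return _read_axt(path)
    if format == "fasta_pairs":
        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) % 2:
            raise MalformedPairError(
                f"{path}: odd number of FASTA records ({len(records)}); "
                "consecutive records must pair"
            )
        return [
            SequencePair(records[i].id, str(records[i].seq), str(records[i + 1].seq))
            for i in range(0, len(records), 2)
        ]
    raise ValueError(f"unknown format {format!r}")


def _read_axt(path: Path) -> list[SequencePair]:
    pairs = []
    block: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                if block:
                    pairs.append(_axt_block(block))
                    block = []
                continue
            block.append(line)
    if block:
        pairs.append(_axt_block(block))
    return pairs


def _axt_block(block: list[str]) -> SequencePair:
    if len(block) != 3:
        head = block[0] if block else "<empty>"
        raise MalformedPairError(f"AXT block {head!r}: expected 3 lines, got {len(block)}")
    gene_id = block[0].strip()
    a, b = block[1].strip(), block[2].strip()
    if len(a) != len(b):
        raise MalformedPairError(
            f"{gene_id}: AXT sequence lines differ in length ({len(a)} vs {len(b)})"
        )
    return SequencePair(gene_id, a, b)


def write_axt(pairs, path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{p.gene_id}\n{p.seq_a}\n{p.seq_b}\n\n")


def write_fasta_pairs(pairs, path, suffixes=("a", "b")) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f">{p.gene_id}_{suffixes[0]}\n{p.seq_a}\n")
            fh.write(f">{p.gene_id}_{suffixes[1]}\n{p.seq_b}\n")


_STOPS = {"TAA", "TAG", "TGA"}


def _strip_terminal_stop(cds: str) -> str:
    if len(cds) >= 3 and cds[-3:] in _STOPS:
        return cds[:-3]
    return cds


def _backtranslate_one(prot_aln: str, cds: str, label: str) -> str:
    cds = _strip_terminal_stop(_normalize(cds, label).replace("-", ""))
    residues = prot_aln.strip().upper()
    n_res = sum(1 for r in residues if r != "-")
    if n_res * 3 != len(cds):
        raise BackTranslationError(
            f"{label}: {n_res} residues need {n_res * 3} nt, CDS has {len(cds)}"
        )
    out = []
    k = 0
    for i, r in enumerate(residues):
        if r == "-":
            out.append("---")
            continue
        codon = cds[3 * k : 3 * k + 3]
        trans = str(Seq(codon).translate())
        if trans != r:
            raise BackTranslationError(
                f"{label}: residue {i + 1} is {r!r} but codon {codon} encodes {trans!r}"
            )
        out.append(codon)
        k += 1
    return "".join(out)


def backtranslate(
    protein_aln_a: str, protein_aln_b: str, cds_a: str, cds_b: str, gene_id: str = "pair"
) -> SequencePair:
    """Thread each CDS back through its gapped protein alignment.

    Each residue is replaced by its source codon and each residue gap by
    '---', yielding a codon-aware nucleotide alignment.  Terminal stop
    codons on the CDS are stripped first.
    """
    a = _backtranslate_one(protein_aln_a, cds_a, f"{gene_id}/a")
    b = _backtranslate_one(protein_aln_b, cds_b, f"{gene_id}/b")
    if len(a) != len(b):
        raise BackTranslationError(
            f"{gene_id}: back-translated lengths differ ({len(a)} vs {len(b)})"
        )
    return SequencePair(gene_id, a, b)


def qc_pair(pair: SequencePair) -> QcRecord:
    a, b = pair.seq_a, pair.seq_b
    n_cols = len(a)
    gap_cols = 0
    nongap_cols = 0
    matches = 0
    n_count = 0
    nt_count = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            gap_cols += 1
        else:
            nongap_cols += 1
            if x == y:
                matches += 1
        for c in (x, y):
            if c != "-":
                nt_count += 1
                if c == "N":
                    n_count += 1
    pct_identity = 100.0 * matches / nongap_cols if nongap_cols else math.nan
    pct_gap = 100.0 * gap_cols / n_cols if n_cols else math.nan
    n_fraction = n_count / nt_count if nt_count else 0.0
    return QcRecord(pair.gene_id, pct_identity, pct_gap, n_fraction, n_count > 0)


def qc_dataset(records) -> dict:
    """Dataset-level quality summary (mean/sd of the N fraction, the
    percentage of pairs containing any N, and the mean identity over pairs
    with a defined identity)."""
    records = list(records)
    if not records:
        raise ValueError("no QC records")
    fracs = [r.n_fraction for r in records]
    idents = [r.pct_identity for r in records if not math.isnan(r.pct_identity)]
    return {
        "n_pairs": len(records),
        "mean_n_fraction": mean(fracs),
        "sd_n_fraction": stdev(fracs) if len(fracs) > 1 else 0.0,
        "pct_pairs_with_n": 100.0 * sum(r.has_n for r in records) / len(records),
        "mean_identity": mean(idents) if idents else math.nan,
    }
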