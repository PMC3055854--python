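import numpy as np
import pytest

from kaks.codon_core import SENSE_CODONS, CodonAlignment


def random_alignment(rng, n_codons=30, p_diff=0.25, gene_id="rand"):
    """Random codon-pair alignment: each column is either one shared sense
    codon or two independent ones."""
    codons_a, codons_b = [], []
    for _ in range(n_codons):
        ca = SENSE_CODONS[rng.integers(len(SENSE_CODONS))]
        if rng.random() < p_diff:
            cb = SENSE_CODONS[rng.integers(len(SENSE_CODONS))]
        else:
            cb = ca
        codons_a.append(ca)
        codons_b.append(cb)
    return CodonAlignment(gene_id, tuple(codons_a), tuple(codons_b))


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def identical_alignment():
    rng = np.random.default_rng(7)
    aln = random_alignment(rng, n_codons=100, p_diff=0.0, gene_id="ident")
    assert aln.identical
    return aln


@pytest.fixture(scope="session")
def moderate_alignment():
    """One simulated pair at moderate divergence, reused across tests."""
    from kaks.simulate import SimParams, simulate_pair

    return simulate_pair(
        SimParams(seed=11, n_codons=500, t=0.3, kappa=2.0, omega=0.25), gene_id="mod"
    )
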