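import numpy as np
import pytest

from polydiv.alignment import Alignment


@pytest.fixture
def tiny_aln():
    """4 sequences x 12 bp, one segregating site at column 2."""
    return Alignment.from_sequences(
        ["ACGTACGTACGT", "ACCTACGTACGT", "ACGTACGTACGT", "ACCTACGTACGT"],
        labels=["EC01_All1", "EC01_All2", "EC02_All1", "EC02_All2"],
        species=["Euc"] * 4,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_alignment(rng, n=8, L=40, p_var=0.3):
    """Random fixture with unconstrained columns (for brute-force oracles)."""
    base = rng.choice(list("ACGT"), size=L)
    matrix = np.tile(base, (n, 1))
    for j in range(L):
        if rng.random() < p_var:
            alt = rng.choice([b for b in "ACGT" if b != base[j]])
            carriers = rng.random(n) < rng.uniform(0.1, 0.9)
            matrix[carriers, j] = alt
    return Alignment.from_sequences(["".join(row) for row in matrix])
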