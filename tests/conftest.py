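import numpy as np
import pytest

from ceafam.seqio import Sequence, build_codon_alignment

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def make_aln(*rows: str, ids=None):
    """Codon alignment from raw nucleotide strings."""
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return build_codon_alignment([Sequence(i, r) for i, r in zip(ids, rows)])


def random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def random_aa(rng: np.random.Generator, n: int) -> str:
    return "".join(AA20[i] for i in rng.integers(0, 20, size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)
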