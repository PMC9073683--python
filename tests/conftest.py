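import numpy as np
import pytest

from spacerscan.scan import MotifPairQuery


def brute_find(residues: str, motif: str) -> list[int]:
    """Window-enumeration oracle for motif matching."""
    m = len(motif)
    return [i for i in range(len(residues) - m + 1) if residues[i : i + m] == motif]


def brute_pairs(residues: str, query: MotifPairQuery):
    """O(occurrences^2) nested-loop oracle for pair scanning."""
    out = []
    llen = len(query.left_motif)
    for l in brute_find(residues, query.left_motif):
        for r in brute_find(residues, query.right_motif):
            n = r - (l + llen)
            if query.min_spacer <= n <= query.max_spacer:
                out.append((l, n, residues[l + llen : r]))
    out.sort()
    return out


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.36) -> str:
    at = (1 - gc) / 2
    return "".join(
        rng.choice(list("ACGT"), size=length, p=[at, gc / 2, gc / 2, at])
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def default_query():
    return MotifPairQuery("AAAG", "ACGT", 0, 30)
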