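import numpy as np
import pytest

from nucpos import Fragment

BASES = np.array(list("ACGT"))


def random_fragments(
    rng: np.random.Generator,
    n: int,
    length: int = 147,
    contig: str = "chr1",
    contig_length: int = 100_000,
    p: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> list[Fragment]:
    """Uniform-composition fragments at random positions (test helper)."""
    starts = rng.integers(0, contig_length - length, size=n)
    codes = rng.choice(4, size=(n, length), p=list(p))
    frags = []
    for i in range(n):
        seq = "".join(BASES[codes[i]])
        frags.append(
            Fragment(contig, int(starts[i]), int(starts[i]) + length, sequence=seq)
        )
    return frags


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


REVCOMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(REVCOMP)[::-1]
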