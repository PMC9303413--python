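import numpy as np
import pytest

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def mutate_copy(
    rng: np.random.Generator, seq: str, n_subs: int = 0, n_indels: int = 0
) -> str:
    """A copy of seq with the given number of substitutions and 1-base indels."""
    s = list(seq)
    for _ in range(n_subs):
        p = int(rng.integers(len(s)))
        s[p] = BASES[(BASES.index(s[p]) + 1 + int(rng.integers(3))) % 4] if s[p] in BASES else "A"
    for _ in range(n_indels):
        p = int(rng.integers(len(s)))
        if rng.random() < 0.5 and len(s) > 2:
            del s[p]
        else:
            s.insert(p, BASES[int(rng.integers(4))])
    return "".join(s)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
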