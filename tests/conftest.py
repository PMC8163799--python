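import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_seq(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def random_mer30(rng, canonical: bool = True) -> str:
    s = list(random_seq(rng, 30))
    if canonical:
        s[25] = "G"
        s[26] = "G"
    return "".join(s)


@pytest.fixture
def guide_panel(rng):
    """120 random canonical-PAM 30mers (unique)."""
    seen, out = set(), []
    while len(out) < 120:
        m = random_mer30(rng)
        if m not in seen:
            seen.add(m)
            out.append(m)
    return out
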