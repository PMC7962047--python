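import numpy as np
import pytest

from repeatlens.patterns import load_fixtures


@pytest.fixture(scope="session")
def fixtures():
    """Bundled literature allele patterns with fixed n-values."""
    return load_fixtures()


@pytest.fixture(scope="session")
def fixture_map(fixtures):
    return {f.label: f for f in fixtures}


BASES = "ACGT"


def make_error_tract(rng: np.random.Generator, max_errors: int = 2) -> str:
    """Short repeat tract (<= 60 nt) with up to ``max_errors`` injected errors."""
    units = ["CTG"] * int(rng.integers(5, 13))
    if rng.random() < 0.5:
        units += [str(rng.choice(["CCG", "CAG", "CTC"]))] * int(rng.integers(1, 3))
        units += ["CTG"] * int(rng.integers(3, 8))
    s = "".join(units)[:60]
    for _ in range(int(rng.integers(0, max_errors + 1))):
        i = int(rng.integers(0, len(s)))
        kind = int(rng.integers(0, 3))
        if kind == 0:  # substitution
            s = s[:i] + str(rng.choice([b for b in BASES if b != s[i]])) + s[i + 1 :]
        elif kind == 1:  # insertion
            s = s[:i] + str(rng.choice(list(BASES))) + s[i:]
        else:  # deletion
            s = s[:i] + s[i + 1 :]
    return s
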