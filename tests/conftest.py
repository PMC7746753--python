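import numpy as np
import pytest

from matrixgc.motif import PFM, build_pwm
from matrixgc.synthetic import DEMO_CONSENSUS, demo_pfm


@pytest.fixture(scope="session")
def pfm() -> PFM:
    return demo_pfm()


@pytest.fixture(scope="session")
def pwm(pfm):
    return build_pwm(pfm)


@pytest.fixture(scope="session")
def consensus() -> str:
    return DEMO_CONSENSUS


def random_pfm(rng: np.random.Generator, width: int) -> PFM:
    """Random count matrix with every column total positive."""
    counts = rng.integers(0, 10, size=(4, width)).astype(float)
    for j in np.flatnonzero(counts.sum(axis=0) == 0):
        counts[rng.integers(0, 4), j] = 1
    return PFM(counts=counts)


def random_seq(rng: np.random.Generator, length: int, n_rate: float = 0.0) -> str:
    bases = rng.choice(list("ACGT"), size=length)
    if n_rate > 0:
        bases[rng.random(length) < n_rate] = "N"
    return "".join(bases)
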