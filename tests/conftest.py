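import numpy as np
import pytest

from cfdash.guide_design import DesignParams, TargetSet


@pytest.fixture(scope="session")
def default_params():
    return DesignParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, length, gc=0.5):
    bases = np.array(list("ACGT"))
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(bases, size=length, p=probs))


@pytest.fixture()
def small_targets(rng):
    return TargetSet(entries=(
        ("rna1", random_seq(rng, 500), "rRNA"),
        ("rna2", random_seq(rng, 300), "mtRNA"),
    ))
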