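import numpy as np
import pytest

import ldpopsize as lp

DATA = __file__.rsplit("/", 1)[0] + "/data"


@pytest.fixture(scope="session")
def mackerel_freqs():
    """One fixed draw from the seven-locus panel spectrum."""
    return lp.synthesize_spectrum(lp.mackerel_spectrum(), seed=12345)


def make_gm(calls, loci=None):
    """Build a GenotypeMatrix from nested call lists."""
    calls = np.asarray(calls)
    if loci is None:
        loci = [f"L{i + 1}" for i in range(calls.shape[1])]
    return lp.GenotypeMatrix(calls, loci)
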