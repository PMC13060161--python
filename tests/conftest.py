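import numpy as np
import pytest

from seglift.sl_fitness import SeasonalLocusParams, sample_locus_params


@pytest.fixture
def rng():
    return np.random.default_rng(20260401)


@pytest.fixture
def symmetric_locus():
    """A locus with identical summer/winter parameters and dominance
    reversal; its deterministic trajectory oscillates symmetrically about
    one half."""
    return SeasonalLocusParams(
        locus_id=0, d_s=0.7, d_w=0.7, delta_s=1.0, delta_w=1.0)


@pytest.fixture
def small_loci(rng):
    return sample_locus_params(12, rng)
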