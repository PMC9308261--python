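import numpy as np
import pytest

from qsarc import synthgen
from qsarc.qio import QualityLine


@pytest.fixture
def small_corpus():
    """A few hundred correlated lines with a mixed-repetition tail."""
    prof = synthgen.profile("illumina_binned", n_reads=400, seed=11)
    return synthgen.generate(prof)


@pytest.fixture
def variable_corpus():
    prof = synthgen.profile("pacbio_wide", n_reads=300, seed=5)
    return synthgen.generate(prof)


def make_lines(strings):
    return [QualityLine(i + 1, s) for i, s in enumerate(strings)]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
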