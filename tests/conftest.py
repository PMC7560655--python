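import numpy as np
import pandas as pd
import pytest

from nbsomatic.copy_number import SEGMENT_COLUMNS, SegmentProfile
from nbsomatic.genome import make_genome_spec
from nbsomatic.synthetic_signatures import synthetic_signature_matrix


@pytest.fixture(scope="session")
def toy_genome():
    return make_genome_spec("toy")


@pytest.fixture(scope="session")
def grch37():
    return make_genome_spec("grch37-arms")


@pytest.fixture(scope="session")
def sigs():
    return synthetic_signature_matrix()


def make_profile(rows, sample="t"):
    """Profile from (chrom, start, end, copy[, loh]) tuples."""
    full = [(r + (False,))[:5] for r in rows]
    return SegmentProfile(sample, pd.DataFrame(full, columns=SEGMENT_COLUMNS))


def uniform_profile(genome, copy=2.0, sample="t", loh=False):
    """One segment per chromosome at a uniform copy level."""
    rows = [(spec.name, 1, spec.length, copy, loh) for spec in genome]
    return SegmentProfile(sample, pd.DataFrame(rows, columns=SEGMENT_COLUMNS))


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)
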