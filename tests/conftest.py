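import numpy as np
import pytest

from pterotax.popgen import SequenceAlignment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_alignment(seqs, ids=None, locus="test"):
    if ids is None:
        ids = [f"s{i}" for i in range(len(seqs))]
    return SequenceAlignment(ids=list(ids), seqs=list(seqs), locus=locus)


@pytest.fixture
def aln_builder():
    return make_alignment
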