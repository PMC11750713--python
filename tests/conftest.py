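import numpy as np
import pytest

from ctdna_mrd import (
    SUBSTITUTION_CLASSES,
    AlignedReadPair,
    SubstitutionErrorModel,
)


@pytest.fixture
def flat_error_model():
    """All 12 classes at 1e-6 per molecule."""
    return SubstitutionErrorModel(
        rates={c: 1e-6 for c in SUBSTITUTION_CLASSES},
        n_background_samples=200,
    )


def make_pair(
    key=("1", 100, 110),
    strand="top",
    bases=None,
    quals=None,
    read_id="r0",
):
    length = key[2] - key[1]
    if bases is None:
        bases = "A" * length
    if quals is None:
        quals = np.full(length, 37, dtype=np.int16)
    return AlignedReadPair(
        fragment_key=key, strand_tag=strand, bases=bases,
        quals=np.asarray(quals, dtype=np.int16), read_id=read_id,
    )


@pytest.fixture
def pair_factory():
    return make_pair
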