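import numpy as np
import pytest

from f5cseq.simulate import SimConfig, SpikeInDesign, make_truth_table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_ref():
    """One short transcript with a single central cytosine site."""
    #        0123456789012345678901234567890
    seq = "ATGATTAGGATTAGACGGATTAGGATTAGA"
    assert seq[15] == "C"
    return {"tx1": seq}


@pytest.fixture
def toy_truth():
    return make_truth_table([("tx1", 15, "+", 0.5)])


def full_cover_config(**kw) -> SimConfig:
    """Config whose fragments always span the whole (short) transcript."""
    defaults = dict(
        seed=0,
        reads_per_transcript=100,
        fragment_length_mean=60.0,
        fragment_length_sd=0.0,
        fragment_length_min=60,
        background_ct_error=0.0,
        generic_seq_error=0.0,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture
def spike_design():
    return SpikeInDesign()
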