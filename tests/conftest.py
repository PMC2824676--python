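import numpy as np
import pytest

from junctionscan import simulate as sim


@pytest.fixture(scope="session")
def small_centromere():
    """A compact nested-insertion centromere (~120 kb) with ground truth."""
    return sim.simulate_centromere(
        seed=11,
        n_insertions=8,
        satellite_copies=300,
        flank_len=8000,
    )


@pytest.fixture(scope="session")
def small_evidence(small_centromere):
    """Noise-free evidence for the compact centromere."""
    return sim.emit_evidence(
        small_centromere, query_id="simq", noise=0, n_decoys=12,
        n_reads=400, enriched=(0, small_centromere.length), rng=5,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
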