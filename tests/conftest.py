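import numpy as np
import pytest

from snpmprm.seed_sites import MirnaFamily


@pytest.fixture
def example_family() -> MirnaFamily:
    # mature nt1-8 = TAGCTTAT, so seed7 (nt2-8) = AGCTTAT, core = TAAGCT, m8 = A
    return MirnaFamily("mir-x", "AGCTTAT", ("hsa-mir-x",))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
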