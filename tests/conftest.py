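import numpy as np
import pytest

import colkit as ck


@pytest.fixture
def slab():
    """10x10x4 flat slab at 0.8 mm: the canonical coarse test patch."""
    return ck.make_flat_slab(10, 10, 4, 0.8)


@pytest.fixture
def fine_slab():
    """Upsampled-resolution slab (0.2 mm): fine enough for the 0.6 mm cylinder
    to span several in-plane columns, as with empirical upsampled maps."""
    return ck.make_flat_slab(40, 40, 12, 0.2)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
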